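"""Synthetic RIP-seq experiments with planted interaction-profile structure.

Generates (i) a ground truth: genes assigned to k profile clusters, each
cluster carrying a planted log2(IP/total) enrichment pattern across factors;
(ii) paired IP/total NB count matrices from that truth; (iii) transcript
annotations (5'UTR/CDS/3'UTR lengths and sequences) whose composition can
shift by cluster; and (iv) per-gene property tables (half-life, ribosome
occupancy, ...) whose distributions shift by cluster.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Planted structure underlying a simulated experiment.

    cluster_labels maps gene -> cluster index in 1..k; center_matrix is the
    planted cluster x factor mean LFC (log2 units); gene_lfc adds per-gene
    Gaussian noise around the member's center row; baseline_abundance is the
    expected total-extract mean count per gene.
    """

    cluster_labels: pd.Series
    center_matrix: pd.DataFrame
    gene_lfc: pd.DataFrame
    baseline_abundance: pd.Series
    seed: int

    @property
    def k(self) -> int:
        return self.center_matrix.shape[0]

    @property
    def factors(self) -> list[str]:
        return list(self.center_matrix.columns)


def _draw_centers(rng, k, n_factors, sep):
    """Ternary {-sep, 0, +sep} planted patterns, pairwise well separated."""
    if sep == 0:
        return np.zeros((k, n_factors))
    centers = np.empty((k, n_factors))
    i = 0
    attempts = 0
    while i < k:
        attempts += 1
        if attempts > 10000:
            raise ValueError(
                "could not place pairwise-distinct cluster centers; "
                "increase n_factors or center_separation"
            )
        row = sep * rng.choice([-1.0, 0.0, 1.0], size=n_factors, p=[0.3, 0.4, 0.3])
        if not np.any(np.abs(row) >= sep):  # reject silent clusters
            continue
        if i > 0:
            d = np.sqrt(((centers[:i] - row) ** 2).sum(axis=1))
            if np.min(d) < sep:
                continue
        centers[i] = row
        i += 1
    return centers


def generate_truth(
    n_genes: int,
    n_factors: int = 12,
    k: int = 7,
    center_separation: float = 2.0,
    gene_noise_sd: float = 0.3,
    seed: int = 0,
    cluster_sizes: Sequence[int] | None = None,
    mean_count: float = 200.0,
    abundance_log_sd: float = 0.5,
    centers: np.ndarray | None = None,
) -> SyntheticTruth:
    """Plant k interaction-profile clusters over genes x factors.

    Cluster sizes are balanced (differ by at most one) unless an explicit
    size vector is supplied.  Per-gene LFC = center row + N(0, gene_noise_sd).
    Baseline abundance is lognormal with mean ``mean_count``.  An explicit
    k x n_factors ``centers`` matrix overrides the random planted patterns.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_genes < k:
        raise ValueError(f"k ({k}) may not exceed n_genes ({n_genes})")
    if center_separation < 0:
        raise ValueError("center_separation must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    factors = [f"F{j + 1:02d}" for j in range(n_factors)]

    if cluster_sizes is None:
        base, extra = divmod(n_genes, k)
        sizes = [base + (1 if c < extra else 0) for c in range(k)]
    else:
        sizes = list(cluster_sizes)
        if len(sizes) != k or sum(sizes) != n_genes:
            raise ValueError("cluster_sizes must have length k and sum to n_genes")
    labels = np.repeat(np.arange(1, k + 1), sizes)
    labels = labels[rng.permutation(n_genes)]

    if centers is None:
        centers = _draw_centers(rng, k, n_factors, center_separation)
    else:
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (k, n_factors):
            raise ValueError(f"centers must have shape ({k}, {n_factors})")
    lfc = centers[labels - 1] + rng.normal(0.0, gene_noise_sd, (n_genes, n_factors))

    mu_log = np.log(mean_count) - 0.5 * abundance_log_sd**2
    baseline = rng.lognormal(mu_log, abundance_log_sd, n_genes)

    return SyntheticTruth(
        cluster_labels=pd.Series(labels, index=genes, name="cluster"),
        center_matrix=pd.DataFrame(
            centers, index=pd.RangeIndex(1, k + 1, name="cluster"), columns=factors
        ),
        gene_lfc=pd.DataFrame(lfc, index=genes, columns=factors),
        baseline_abundance=pd.Series(baseline, index=genes, name="baseline"),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# annotation / sequences


@dataclass
class CompositionSpec:
    """5'UTR base composition for one cluster.

    probs are (A, C, G, T) probabilities.  If ``window`` is given as
    (from_pos, to_pos) in start-codon-anchored coordinates (e.g. (-10, -1)),
    the probabilities apply only inside that window and the background
    composition is used elsewhere.
    """

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    window: tuple[int, int] | None = None

    def validate(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("composition probabilities must be 4 values in [0,1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition probabilities must sum to 1, got {p.sum()}")


@dataclass
class TranscriptAnnotation:
    """Per-gene region lengths and sequences (DNA alphabet)."""

    lengths: pd.DataFrame  # columns utr5_len, cds_len, utr3_len
    utr5: dict = field(default_factory=dict)
    cds: dict = field(default_factory=dict)
    utr3: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.lengths.index)

    def transcript(self, gene: str) -> str:
        return self.utr5[gene] + self.cds[gene] + self.utr3[gene]


def _draw_lengths(rng, dist, n):
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, int(dist[1]))
    if kind == "lognormal":
        _, mean_log, sd_log = dist[:3]
        minimum = dist[3] if len(dist) > 3 else 1
        return np.maximum(np.round(rng.lognormal(mean_log, sd_log, n)), minimum).astype(int)
    raise ValueError(f"unknown length distribution {kind!r}")


DEFAULT_LENGTHS = {
    # yeast-like medians: ~60 nt 5'UTR, ~1200 nt CDS, ~120 nt 3'UTR
    "utr5": ("lognormal", np.log(60.0), 0.6, 5),
    "cds": ("lognormal", np.log(1200.0), 0.5, 30),
    "utr3": ("lognormal", np.log(120.0), 0.5, 5),
}


def _random_seq(rng, length, probs):
    if length <= 0:
        return ""
    idx = rng.choice(4, size=length, p=np.asarray(probs, dtype=float))
    return "".join(_BASES[idx])


def _random_cds(rng, n_codons, probs):
    """ATG + random internal codons (stops rejection-resampled) + one stop."""
    n_body = n_codons - 2
    probs = np.asarray(probs, dtype=float)
    idx = rng.choice(4, size=(n_body, 3), p=probs)
    stops = {tuple(_BASES.searchsorted(list(s))) for s in STOP_CODONS}
    stop_set = np.array(sorted(stops))
    while True:
        is_stop = (idx[:, None, :] == stop_set[None, :, :]).all(axis=2).any(axis=1)
        if not is_stop.any():
            break
        idx[is_stop] = rng.choice(4, size=(int(is_stop.sum()), 3), p=probs)
    body = "".join(_BASES[idx].ravel())
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + body + stop


def generate_annotation(
    n_genes: int,
    length_distributions: Mapping | None = None,
    composition_by_cluster: Mapping[int, CompositionSpec] | None = None,
    labels: pd.Series | None = None,
    seed: int = 0,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> TranscriptAnnotation:
    """Generate per-gene 5'UTR/CDS/3'UTR lengths and sequences.

    ``composition_by_cluster`` overrides the background 5'UTR composition for
    genes in the named clusters (optionally only within a start-codon-anchored
    window), which is how adenosine-rich cohorts are planted.
    """
    rng = np.random.default_rng(seed)
    dists = dict(DEFAULT_LENGTHS)
    if length_distributions:
        dists.update(length_distributions)
    comp = {c: s for c, s in (composition_by_cluster or {}).items()}
    for spec in comp.values():
        spec.validate()
    CompositionSpec(background).validate()
    if comp and labels is None:
        raise ValueError("labels required when composition_by_cluster is given")
    if labels is not None and comp:
        unknown = set(comp) - set(pd.unique(labels))
        if unknown:
            raise ValueError(f"composition_by_cluster names unknown clusters: {sorted(unknown)}")

    if labels is not None:
        genes = list(labels.index)
        if len(genes) != n_genes:
            raise ValueError("labels length must equal n_genes")
    else:
        genes = [f"G{i:05d}" for i in range(n_genes)]

    utr5_len = _draw_lengths(rng, dists["utr5"], n_genes)
    cds_len = _draw_lengths(rng, dists["cds"], n_genes)
    cds_len = np.maximum((cds_len // 3) * 3, 9)  # multiple of 3, room for >=1 codon
    utr3_len = _draw_lengths(rng, dists["utr3"], n_genes)

    utr5, cds, utr3 = {}, {}, {}
    for i, g in enumerate(genes):
        spec = comp.get(int(labels.loc[g]), None) if labels is not None else None
        L = int(utr5_len[i])
        if spec is None:
            seq5 = _random_seq(rng, L, background)
        elif spec.window is None:
            seq5 = _random_seq(rng, L, spec.probs)
        else:
            # window positions: -1 is the base immediately 5' of ATG
            lo, hi = min(spec.window), max(spec.window)
            chars = list(_random_seq(rng, L, background))
            for pos in range(lo, hi + 1):
                idx = L + pos  # pos is negative
                if 0 <= idx < L:
                    chars[idx] = _random_seq(rng, 1, spec.probs)
            seq5 = "".join(chars)
        utr5[g] = seq5
        cds[g] = _random_cds(rng, int(cds_len[i]) // 3, background)
        utr3[g] = _random_seq(rng, int(utr3_len[i]), background)

    lengths = pd.DataFrame(
        {"utr5_len": utr5_len, "cds_len": cds_len, "utr3_len": utr3_len}, index=genes
    )
    return TranscriptAnnotation(lengths=lengths, utr5=utr5, cds=cds, utr3=utr3)


# ---------------------------------------------------------------------------
# counts


@dataclass
class NBParams:
    """NB sampling parameters: Var = mu + dispersion * mu^2."""

    dispersion: float | pd.Series = 0.1
    library_sizes: pd.Series | None = None  # per-sample scale factors
    n_replicates: int = 3


@dataclass
class CountExperimentData:
    counts: pd.DataFrame
    samples: pd.DataFrame


def _nb_draw(rng, mean, phi):
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi == 0
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    truth: SyntheticTruth,
    nb_params: NBParams | None = None,
    seed: int = 0,
    annotation: TranscriptAnnotation | None = None,
) -> CountExperimentData:
    """Simulate paired IP/total counts for every factor and replicate.

    Total samples draw NB(libsize * baseline, phi); the paired IP sample
    draws NB(libsize * baseline * 2^LFC, phi).  Sample names are
    ``<factor>_rep<r>_<role>`` and the metadata table records the
    (factor, replicate, role) triple that defines the pairing.
    """
    del annotation  # sequences do not influence counts
    nb_params = nb_params or NBParams()
    phi = nb_params.dispersion
    if np.any(np.asarray(phi, dtype=float) < 0):
        raise ValueError("dispersion must be non-negative")
    if isinstance(phi, pd.Series):
        phi = phi.reindex(truth.gene_lfc.index).to_numpy()
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_lfc.index)
    base = truth.baseline_abundance.to_numpy()

    cols, meta = [], []
    data = {}
    for f in truth.factors:
        lfc = truth.gene_lfc[f].to_numpy()
        for r in range(1, nb_params.n_replicates + 1):
            for role, mean in (
                ("total", base),
                ("IP", base * np.exp2(lfc)),
            ):
                name = f"{f}_rep{r}_{role}"
                lib = 1.0
                if nb_params.library_sizes is not None:
                    if name not in nb_params.library_sizes.index:
                        raise ValueError(f"missing library size for sample {name}")
                    lib = float(nb_params.library_sizes.loc[name])
                    if lib <= 0:
                        raise ValueError(f"library size for {name} must be positive")
                data[name] = _nb_draw(rng, lib * mean, phi)
                cols.append(name)
                meta.append({"sample_id": name, "factor": f, "replicate": r, "role": role})

    counts = pd.DataFrame(data, index=genes, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return CountExperimentData(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# property tables


@dataclass
class PropertyEffect:
    """One property's generating law: a base distribution plus per-cluster
    location shifts.

    base: ("normal", loc, scale) or ("lognormal", mean_log, sd_log); shifts
    move the location parameter (the underlying normal mean for lognormal).
    """

    base: tuple
    shifts: Mapping[int, float] = field(default_factory=dict)
    missing_rate: float = 0.0


DEFAULT_PROPERTY_EFFECTS = {
    # synthetic stand-ins for the external per-gene datasets; units arbitrary
    "half_life": PropertyEffect(("lognormal", np.log(20.0), 0.7), {6: -0.6}),
    "ribosome_occupancy": PropertyEffect(("lognormal", 0.0, 0.5), {6: -0.3, 7: -0.15}),
    "ssu_ratio": PropertyEffect(("lognormal", 0.0, 0.4), {1: 0.3}),
    "protein_fraction": PropertyEffect(("lognormal", np.log(1e-4), 1.2), {4: 1.0, 5: 1.2}),
    "structure_score": PropertyEffect(("normal", 0.5, 0.12), {7: -0.08}),
}


def generate_property_tables(
    labels: pd.Series,
    effect_spec: Mapping[str, PropertyEffect] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-gene properties whose cluster medians shift as configured."""
    effect_spec = effect_spec or DEFAULT_PROPERTY_EFFECTS
    rng = np.random.default_rng(seed)
    clusters = set(int(c) for c in pd.unique(labels))
    out = {}
    for prop, eff in effect_spec.items():
        unknown = set(eff.shifts) - clusters
        if unknown:
            raise ValueError(
                f"effect_spec for {prop!r} names unknown clusters: {sorted(unknown)}"
            )
        kind, loc, scale = eff.base[0], float(eff.base[1]), float(eff.base[2])
        shift = labels.map(lambda c: eff.shifts.get(int(c), 0.0)).to_numpy(dtype=float)
        if kind == "normal":
            vals = rng.normal(loc + shift, scale)
        elif kind == "lognormal":
            vals = rng.lognormal(loc + shift, scale)
        else:
            raise ValueError(f"unknown base distribution {kind!r}")
        if eff.missing_rate > 0:
            vals = np.where(rng.random(len(vals)) < eff.missing_rate, np.nan, vals)
        out[prop] = vals
    return pd.DataFrame(out, index=labels.index)


# ---------------------------------------------------------------------------
# synthetic tRNA gene copy numbers (for the codon-metrics stage)


def generate_tgcn(seed: int = 0, mean_copies: float = 6.0) -> pd.Series:
    """Synthetic anticodon -> tRNA gene copy number table.

    Roughly half of all sense anticodons get Poisson-distributed positive
    copy numbers and the rest zero, mimicking the sparse decoding table of a
    real genome; purely synthetic, not any organism's gene set.
    """
    from .tai import sense_codons, revcomp

    rng = np.random.default_rng(seed)
    anticodons = sorted({revcomp(c) for c in sense_codons()})
    copies = rng.poisson(mean_copies, len(anticodons))
    copies[rng.random(len(anticodons)) < 0.45] = 0
    if copies.sum() == 0:
        copies[0] = 1
    return pd.Series(copies, index=anticodons, name="copies")
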
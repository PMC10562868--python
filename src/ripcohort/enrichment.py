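"""Paired IP-vs-total negative-binomial enrichment testing.

The model: for each RNA-binding factor, each replicate contributes a paired
(IP, total) sample.  Per gene, counts follow NB(mu, phi) with
log mu = log(effective library size) + replicate effect + beta_IP * [role=IP],
so beta_IP is the natural-log IP enrichment and LFC = beta_IP / ln 2 the
log2(IP/total) fold change.  Significance comes from a likelihood-ratio test
of beta_IP (chi-square, 1 df) with Benjamini-Hochberg correction within each
factor.  Library sizes are normalized by trimmed mean of M-values (TMM);
dispersions are estimated by Cox-Reid adjusted profile likelihood, with
tagwise values shrunk toward the common value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from ._glm import adjusted_profile_loglik, fit_nb_glm

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# experiment container


@dataclass
class CountExperiment:
    """Gene x sample integer count matrix with paired-sample metadata.

    ``samples`` is indexed by sample id with columns factor, replicate and
    role (IP or total); every (factor, replicate) must own exactly one IP
    and one total sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        for key in ("factor", "replicate", "role"):
            if key not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {key!r}")
        bad_roles = set(self.samples["role"]) - {"IP", "total"}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        grouped = self.samples.groupby(["factor", "replicate"])["role"]
        for (f, r), roles in grouped:
            if sorted(roles) != ["IP", "total"]:
                raise ValueError(
                    f"factor {f} replicate {r} must have exactly one IP and one total sample"
                )

    @property
    def factors(self) -> list[str]:
        seen = []
        for f in self.samples["factor"]:
            if f not in seen:
                seen.append(f)
        return seen

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def factor_samples(self, factor: str) -> pd.DataFrame:
        sub = self.samples[self.samples["factor"] == factor]
        if sub.empty:
            raise ValueError(f"factor {factor!r} absent from sample metadata")
        return sub

    def total_sample_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "total"])


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair_factor(obs, ref, lib_obs, lib_ref, m_trim=0.30, a_trim=0.05):
    """edgeR-convention pairwise TMM factor of ``obs`` against ``ref``."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    if np.max(np.abs(M)) < 1e-6:  # columns proportional
        return 1.0
    n = M.size
    lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 1.0
    # asymptotic (delta-method) binomial variance of M as inverse weight
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    w = 1.0 / np.maximum(v[keep2], 1e-12)
    f = 2.0 ** (np.sum(w * M[keep2]) / np.sum(w))
    return f if np.isfinite(f) and f > 0 else 1.0


def normalize_libsizes(counts: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05):
    """TMM effective library sizes.

    Returns ``(eff_sizes, factors)`` as Series over samples.  The reference
    column is the one whose log raw library size is closest to the mean log
    size; factors are rescaled so their log values sum to zero.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero count column(s): {list(zero)}")
    loglib = np.log(lib.to_numpy())
    ref_idx = int(np.argmin(np.abs(loglib - loglib.mean())))
    ref = counts.iloc[:, ref_idx].to_numpy()
    facs = np.array(
        [
            _tmm_pair_factor(counts.iloc[:, j].to_numpy(), ref, lib.iloc[j], lib.iloc[ref_idx],
                             m_trim, a_trim)
            for j in range(counts.shape[1])
        ]
    )
    facs = facs / np.exp(np.mean(np.log(facs)))
    factors = pd.Series(facs, index=counts.columns, name="norm_factor")
    eff = lib * factors
    eff.name = "eff_lib_size"
    return eff, factors


# ---------------------------------------------------------------------------
# design matrices


def _paired_design(sub: pd.DataFrame):
    """Full/reduced design for one factor: replicate blocks + IP indicator."""
    reps = sorted(sub["replicate"].unique())
    S = len(sub)
    Xr = np.zeros((S, len(reps)))
    for i, (sid, row) in enumerate(sub.iterrows()):
        Xr[i, reps.index(row["replicate"])] = 1.0
    ip = (sub["role"] == "IP").to_numpy(dtype=float)[:, None]
    return np.hstack([Xr, ip]), Xr  # full, reduced; beta_IP is last column


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class NBFit:
    """Fitted normalization and dispersion state shared by all factor tests."""

    phi_common: float
    phi_tagwise: pd.Series  # over testable genes
    eff_lib_sizes: pd.Series
    norm_factors: pd.Series
    prior_df: float
    testable: pd.Series  # bool per gene (expression floor)
    residual_df: int


def estimate_dispersion(
    experiment: CountExperiment,
    prior_df: float = 10.0,
    expression_floor: float = 1.0,
    phi_max: float = 10.0,
) -> NBFit:
    """Common + tagwise NB dispersion by Cox-Reid adjusted profile likelihood.

    The common value maximizes the APL summed over all testable genes and
    factors; per-gene maximizers (on a log-spaced grid) are shrunk toward the
    common value with weight ``prior_df`` against the per-gene residual df.
    """
    eff, facs = normalize_libsizes(experiment.counts)
    testable = experiment.counts.mean(axis=1) >= expression_floor
    if int(testable.sum()) == 0:
        raise ValueError("no gene passes the expression floor")
    y_all = experiment.counts.loc[testable]

    blocks = []  # (y, X_full, offset) per factor
    df_res = 0
    for f in experiment.factors:
        sub = experiment.samples[experiment.samples["factor"] == f]
        if sub["replicate"].nunique() < 2:
            raise ValueError(
                f"factor {f!r} has a single replicate pair; dispersion unidentifiable"
            )
        X_full, _ = _paired_design(sub)
        offset = np.log(eff.loc[sub.index].to_numpy())
        blocks.append((y_all[sub.index].to_numpy(), X_full, offset))
        df_res += len(sub) - X_full.shape[1]

    def neg_apl(log10_phi):
        phi = 10.0**log10_phi
        return -sum(
            adjusted_profile_loglik(phi, y, X, off).sum() for y, X, off in blocks
        )

    res = minimize_scalar(
        neg_apl, bounds=(-6.0, np.log10(phi_max)), method="bounded",
        options={"xatol": 1e-2},
    )
    phi_common = float(10.0**res.x)
    if phi_common <= 2e-6:
        phi_common = 0.0

    # per-gene profile likelihood on a grid
    grid = np.concatenate([[1e-6], np.logspace(-4, np.log10(phi_max), 14)])
    apl = np.zeros((y_all.shape[0], grid.size))
    for j, phi in enumerate(grid):
        apl[:, j] = sum(adjusted_profile_loglik(phi, y, X, off) for y, X, off in blocks)
    phi_gene = grid[np.argmax(apl, axis=1)]
    phi_gene = np.where(phi_gene <= 2e-6, 0.0, phi_gene)

    w = df_res / (df_res + prior_df) if np.isfinite(prior_df) else 0.0
    phi_tag = np.clip(w * phi_gene + (1.0 - w) * phi_common, 0.0, phi_max)

    return NBFit(
        phi_common=phi_common,
        phi_tagwise=pd.Series(phi_tag, index=y_all.index, name="phi"),
        eff_lib_sizes=eff,
        norm_factors=facs,
        prior_df=prior_df,
        testable=testable,
        residual_df=df_res,
    )


# ---------------------------------------------------------------------------
# the enrichment test


def test_enrichment(experiment: CountExperiment, fit: NBFit, factor: str) -> pd.DataFrame:
    """Per-gene paired LRT for one factor.

    Returns a DataFrame indexed by every gene of the experiment with columns
    LFC (log2), p, FDR and the factor's per-replicate total counts; genes
    below the expression floor carry NaN and are excluded from the BH batch.
    """
    sub = experiment.factor_samples(factor)
    X_full, X_red = _paired_design(sub)
    offset = np.log(fit.eff_lib_sizes.loc[sub.index].to_numpy())
    genes = fit.phi_tagwise.index
    y = experiment.counts.loc[genes, sub.index].to_numpy()
    phi = fit.phi_tagwise.to_numpy()

    beta, _, dev_full = fit_nb_glm(y, X_full, offset, phi)
    _, _, dev_red = fit_nb_glm(y, X_red, offset, phi)
    lrt = np.maximum(dev_red - dev_full, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    lfc = beta[:, -1] / LN2

    out = pd.DataFrame(
        index=experiment.counts.index,
        data={"LFC": np.nan, "p": np.nan, "FDR": np.nan},
    )
    out.loc[genes, "LFC"] = lfc
    out.loc[genes, "p"] = p
    out.loc[genes, "FDR"] = fdr
    totals = sub.index[sub["role"] == "total"]
    for sid in totals:
        out[f"total_{sid}"] = experiment.counts[sid]
    out.attrs["factor"] = factor
    return out


def filter_transcripts(
    results_all_factors: dict[str, pd.DataFrame],
    experiment: CountExperiment,
    fdr_max: float = 0.01,
    min_total_reads: int = 20,
) -> list[str]:
    """The analysis universe: genes significant somewhere and well covered.

    A gene is kept iff its FDR is below ``fdr_max`` in at least one factor
    (enriched or underrepresented) AND its raw count strictly exceeds
    ``min_total_reads`` in every total-extract sample.  Output preserves the
    experiment's gene order.
    """
    sig = pd.Series(False, index=experiment.counts.index)
    for res in results_all_factors.values():
        fdr = res["FDR"].reindex(sig.index)
        sig |= (fdr < fdr_max).fillna(False)
    totals = experiment.counts[experiment.total_sample_ids()]
    covered = (totals > min_total_reads).all(axis=1)
    keep = sig & covered
    return [g for g in experiment.counts.index if keep.loc[g]]


# ---------------------------------------------------------------------------
# model / results surface


class RIPEnrichment:
    """Paired IP-vs-total enrichment model over a :class:`CountExperiment`.

    Parameters
    ----------
    experiment
        Count matrix plus (factor, replicate, role) sample metadata.

    ``fit()`` normalizes library sizes, estimates dispersions and runs the
    paired LRT for every factor, returning :class:`RIPEnrichmentResults`.
    """

    def __init__(self, experiment: CountExperiment):
        self.experiment = experiment

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, samples: pd.DataFrame) -> "RIPEnrichment":
        return cls(CountExperiment(counts=counts, samples=samples))

    def fit(
        self, prior_df: float = 10.0, expression_floor: float = 1.0
    ) -> "RIPEnrichmentResults":
        nbfit = estimate_dispersion(
            self.experiment, prior_df=prior_df, expression_floor=expression_floor
        )
        results = {
            f: test_enrichment(self.experiment, nbfit, f) for f in self.experiment.factors
        }
        return RIPEnrichmentResults(self, nbfit, results)


class RIPEnrichmentResults:
    """Per-factor enrichment tables plus the fitted normalization state."""

    def __init__(self, model: RIPEnrichment, nbfit: NBFit, results: dict[str, pd.DataFrame]):
        self.model = model
        self.nbfit = nbfit
        self.results = results

    @property
    def factors(self) -> list[str]:
        return list(self.results)

    def filter_universe(self, fdr_max: float = 0.01, min_total_reads: int = 20) -> list[str]:
        return filter_transcripts(
            self.results, self.model.experiment, fdr_max=fdr_max,
            min_total_reads=min_total_reads,
        )

    def summary(self, fdr_max: float = 0.01) -> str:
        exp = self.model.experiment
        lines = [
            "Paired NB enrichment (IP vs total)",
            f"  genes: {exp.counts.shape[0]}  samples: {exp.counts.shape[1]}  "
            f"factors: {len(self.factors)}",
            f"  testable genes (floor): {int(self.nbfit.testable.sum())}",
            f"  common dispersion: {self.nbfit.phi_common:.4g}  "
            f"(prior df {self.nbfit.prior_df})",
            f"  {'factor':<10} {'tested':>7} {'FDR<' + format(fdr_max, 'g'):>9} "
            f"{'up':>6} {'down':>6}",
        ]
        for f, res in self.results.items():
            tested = res["p"].notna()
            sig = (res["FDR"] < fdr_max).fillna(False)
            up = int((sig & (res["LFC"] > 0)).sum())
            down = int((sig & (res["LFC"] < 0)).sum())
            lines.append(
                f"  {f:<10} {int(tested.sum()):>7} {int(sig.sum()):>9} {up:>6} {down:>6}"
            )
        return "\n".join(lines)
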
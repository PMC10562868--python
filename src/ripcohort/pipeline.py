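"""End-to-end orchestration: simulate -> enrich -> filter -> cluster ->
properties -> tai -> overlap, with a YAML config, derived per-stage seeds
and a JSON manifest of checksums so runs are reproducible and each stage can
be rerun from the previous stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import io as rio
from .clustering import ProfileClustering, build_lfc_matrix, pairwise_r2, upgma
from .enrichment import CountExperiment, RIPEnrichment
from .overlap import hypergeom_overlap, mc_multiway_overlap, term_enrichment
from .properties import compare_properties, positional_a_enrichment, utr_a_fraction
from .simulate import (
    CompositionSpec,
    NBParams,
    generate_annotation,
    generate_property_tables,
    generate_tgcn,
    generate_truth,
    simulate_counts,
)
from .tai import gene_te_table, tai_weights

log = logging.getLogger("ripcohort")

STAGES = ("simulate", "enrich", "filter", "cluster", "properties", "tai", "overlap")


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(2000, gt=0)
    n_factors: int = Field(12, gt=0)
    k: int = Field(7, gt=0)
    center_separation: float = Field(2.0, ge=0)
    gene_noise_sd: float = Field(0.3, ge=0)
    dispersion: float = Field(0.1, ge=0)
    mean_count: float = Field(200.0, gt=0)
    n_replicates: int = Field(3, gt=1)
    a_rich_cluster: int | None = 1
    a_rich_prob: float = Field(0.5, ge=0, le=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outdir: str = "ripcohort_run"
    seed: int = 0
    counts: str | None = None
    samples: str | None = None
    simulate: SimulateConfig = SimulateConfig()
    fdr_max: float = Field(0.01, gt=0)
    min_total_reads: int = Field(20, gt=0)
    prior_df: float = Field(10.0, gt=0)
    expression_floor: float = Field(1.0, ge=0)
    k: int = Field(7, gt=0)
    n_starts: int = Field(50, gt=0)
    n_draws: int = Field(1_000_000, gt=0)
    significance: float = Field(0.05, gt=0)

    @field_validator("counts", "samples")
    @classmethod
    def _exists(cls, v):
        if v is not None and not Path(v).exists():
            raise ValueError(f"path does not exist: {v}")
        return v


def validate_config(path) -> RunConfig:
    """Load a YAML config, fill defaults, reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "tool": "ripcohort 0.1.0",
            "config_hash": hashlib.sha256(
                json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": config.seed,
            "stages": [],
        }

    def record(self, name: str, outdir: Path, outputs: list[str], seed: int,
               t0: float) -> None:
        self.data["stages"].append({
            "stage": name,
            "seed": seed,
            "outputs": {f: _sha256(outdir / f) for f in outputs},
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def stage_checksums(self) -> dict:
        return {s["stage"]: s["outputs"] for s in self.data["stages"]}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage; each writes rerunnable plain-text outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config)
    stage = "?"
    try:
        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        sc = config.simulate
        if config.counts is not None:
            counts = rio.read_counts(config.counts)
            samples = rio.read_samples(config.samples)
            truth = None
            annotation = None
            props = None
            sim_outputs: list[str] = []
        else:
            truth = generate_truth(
                sc.n_genes, sc.n_factors, sc.k, sc.center_separation,
                sc.gene_noise_sd, seed=seed, mean_count=sc.mean_count,
            )
            comp = None
            if sc.a_rich_cluster is not None and sc.k >= sc.a_rich_cluster:
                rest = (1.0 - sc.a_rich_prob) / 3.0
                comp = {sc.a_rich_cluster: CompositionSpec(
                    (sc.a_rich_prob, rest, rest, rest))}
            annotation = generate_annotation(
                sc.n_genes, composition_by_cluster=comp,
                labels=truth.cluster_labels, seed=seed + 1,
            )
            data = simulate_counts(
                truth, NBParams(dispersion=sc.dispersion,
                                n_replicates=sc.n_replicates),
                seed=seed + 2,
            )
            counts, samples = data.counts, data.samples
            from .simulate import DEFAULT_PROPERTY_EFFECTS, PropertyEffect
            effects = {
                p: PropertyEffect(
                    e.base,
                    {c: d for c, d in e.shifts.items() if c <= sc.k},
                    e.missing_rate,
                )
                for p, e in DEFAULT_PROPERTY_EFFECTS.items()
            }
            props = generate_property_tables(truth.cluster_labels, effects,
                                             seed=seed + 3)
            tgcn = generate_tgcn(seed=seed + 4)
            rio.write_counts(counts, outdir / "counts.tsv")
            rio.write_samples(samples, outdir / "samples.tsv")
            rio.write_table(props, outdir / "properties.tsv")
            rio.write_annotation_fasta(annotation, outdir / "transcripts.fa")
            rio.write_annotation_gff3(annotation, outdir / "annotation.gff3")
            rio.write_truth(truth, outdir)
            tgcn.to_frame().to_csv(outdir / "tgcn.tsv", sep="\t",
                                   index_label="anticodon")
            sim_outputs = ["counts.tsv", "samples.tsv", "properties.tsv",
                           "transcripts.fa", "annotation.gff3", "truth_labels.tsv",
                           "truth_centers.tsv", "truth_lfc.tsv",
                           "truth_baseline.tsv", "tgcn.tsv"]
        manifest.record(stage, outdir, sim_outputs, seed, t0)
        log.info("stage simulate done (%d genes, %d samples)",
                 counts.shape[0], counts.shape[1])

        # ---- enrich ------------------------------------------------------
        stage = "enrich"
        t0 = time.time()
        model = RIPEnrichment(CountExperiment(counts=counts, samples=samples))
        fit = model.fit(prior_df=config.prior_df,
                        expression_floor=config.expression_floor)
        enrich_outputs = []
        for f, res in fit.results.items():
            name = f"enrichment_{f}.tsv"
            rio.write_table(res, outdir / name)
            enrich_outputs.append(name)
        manifest.record(stage, outdir, enrich_outputs, 0, t0)
        log.info("stage enrich done\n%s", fit.summary(config.fdr_max))

        # ---- filter ------------------------------------------------------
        stage = "filter"
        t0 = time.time()
        universe = fit.filter_universe(config.fdr_max, config.min_total_reads)
        rio.write_universe(universe, outdir / "universe.txt")
        manifest.record(stage, outdir, ["universe.txt"], 0, t0)
        log.info("stage filter done (%d genes in universe)", len(universe))
        if len(universe) < max(3, config.k):
            raise RuntimeError("universe too small to cluster")

        # ---- cluster -----------------------------------------------------
        stage = "cluster"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        profile = build_lfc_matrix(fit.results, universe)
        corr = pairwise_r2(profile)
        exp_tree = upgma(corr.D)
        cm = ProfileClustering(profile, k=config.k,
                               n_starts=config.n_starts).fit(seed=seed)
        rio.write_table(profile, outdir / "lfc_matrix.tsv")
        rio.write_table(corr.R2, outdir / "r2_matrix.tsv", index_label="factor")
        rio.write_table(corr.D, outdir / "dissimilarity.tsv", index_label="factor")
        (outdir / "experiment_tree.nwk").write_text(exp_tree.to_newick() + "\n")
        if cm.cluster_tree is not None:
            (outdir / "cluster_tree.nwk").write_text(
                cm.cluster_tree.to_newick() + "\n")
        rio.write_table(cm.labels.to_frame(), outdir / "clusters.tsv")
        rio.write_table(cm.centers, outdir / "centers.tsv", index_label="cluster")
        cluster_outputs = ["lfc_matrix.tsv", "r2_matrix.tsv", "dissimilarity.tsv",
                           "experiment_tree.nwk", "clusters.tsv", "centers.tsv"]
        if cm.cluster_tree is not None:
            cluster_outputs.append("cluster_tree.nwk")
        manifest.record(stage, outdir, cluster_outputs, seed, t0)
        log.info("stage cluster done\n%s", cm.summary())

        # ---- properties --------------------------------------------------
        stage = "properties"
        t0 = time.time()
        prop_outputs = []
        if props is None and (outdir / "properties.tsv").exists():
            props = rio.read_table(outdir / "properties.tsv")
        if annotation is None and (outdir / "annotation.gff3").exists():
            annotation = rio.read_annotation_gff3(outdir / "annotation.gff3",
                                                  outdir / "transcripts.fa")
        if props is not None:
            labels = cm.labels
            prop_universe = props.loc[props.index.intersection(labels.index)]
            table = prop_universe.copy()
            if annotation is not None:
                lens = annotation.lengths.reindex(labels.index)
                table = table.join(lens, how="left")
                table["transcript_len"] = lens.sum(axis=1)
                afrac = utr_a_fraction(annotation)
                table["utr5_a_fraction"] = afrac.reindex(labels.index)
            comparisons = compare_properties(table.loc[labels.index], labels)
            rio.write_table(comparisons, outdir / "comparisons.tsv",
                            index_label="row")
            box = comparisons[["property", "cluster", "n", "median", "Q1", "Q3",
                               "notch_low", "notch_high"]]
            rio.write_table(box, outdir / "boxstats.tsv", index_label="row")
            prop_outputs += ["comparisons.tsv", "boxstats.tsv"]
        if annotation is not None:
            prof = positional_a_enrichment(annotation, cm.labels)
            rio.write_table(prof, outdir / "positional_profile.tsv",
                            index_label="row")
            prop_outputs.append("positional_profile.tsv")
        manifest.record(stage, outdir, prop_outputs, 0, t0)
        log.info("stage properties done")

        # ---- tai ---------------------------------------------------------
        stage = "tai"
        t0 = time.time()
        tai_outputs = []
        if (outdir / "tgcn.tsv").exists() and annotation is not None:
            tgcn = rio.read_table(outdir / "tgcn.tsv")["copies"]
            tmodel = tai_weights(tgcn)
            rio.write_table(tmodel.w.to_frame(), outdir / "codon_weights.tsv",
                            index_label="codon")
            te = gene_te_table(annotation.cds, tmodel)
            rio.write_table(te, outdir / "gene_te.tsv")
            tai_outputs = ["codon_weights.tsv", "gene_te.tsv"]
        manifest.record(stage, outdir, tai_outputs, 0, t0)
        log.info("stage tai done")

        # ---- overlap -----------------------------------------------------
        stage = "overlap"
        t0 = time.time()
        seed = stage_seed(config.seed, stage)
        enriched = {
            f: set(res.index[(res["FDR"] < config.fdr_max).fillna(False)
                             & res.index.isin(universe)])
            for f, res in fit.results.items()
        }
        factors = [f for f, s in enriched.items() if len(s) >= 3]
        rows = []
        for i, fa in enumerate(factors):
            for fb in factors[i + 1:]:
                r = hypergeom_overlap(enriched[fa], enriched[fb], universe)
                rows.append({"setA": fa, "setB": fb, "N": r.N, "K": r.K,
                             "n": r.n, "x": r.x, "p": r.p,
                             "enrichment_ratio": r.enrichment_ratio,
                             "method": r.method})
        if len(factors) >= 3:
            r = mc_multiway_overlap([enriched[f] for f in factors[:3]], universe,
                                    n_draws=config.n_draws, seed=seed)
            rows.append({"setA": factors[0], "setB": f"{factors[1]}+{factors[2]}",
                         "N": r.N, "K": r.K, "n": r.n, "x": r.x, "p": r.p,
                         "enrichment_ratio": r.enrichment_ratio,
                         "method": r.method})
        pd.DataFrame(rows).to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
        overlap_outputs = ["overlaps.tsv"]
        # term over-representation of clusters against synthetic truth terms
        if truth is not None:
            rng = np.random.default_rng(seed + 1)
            t2g = {}
            for c in range(1, truth.k + 1):
                members = [g for g in universe
                           if truth.cluster_labels.loc[g] == c]
                if len(members) >= 6:
                    take = rng.choice(members, size=len(members) // 2,
                                      replace=False)
                    noise = rng.choice(universe, size=max(3, len(take) // 5),
                                       replace=False)
                    t2g[f"TERM_planted_{c}"] = set(take) | set(noise)
            for j in range(5):
                t2g[f"TERM_random_{j}"] = set(
                    rng.choice(universe, size=min(50, len(universe)),
                               replace=False))
            queries = {f"cluster_{c}": set(cm.labels.index[cm.labels == c])
                       for c in range(1, cm.k + 1)}
            terms = term_enrichment(queries, t2g, universe)
            terms.to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
            overlap_outputs.append("term_enrichment.tsv")
        manifest.record(stage, outdir, overlap_outputs, seed, t0)
        log.info("stage overlap done")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest.save(outdir / "manifest.json")
    return manifest
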
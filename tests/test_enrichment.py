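"""TMM normalization, dispersion estimation, the paired LRT and filtering."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripcohort import (
    CountExperiment,
    NBParams,
    RIPEnrichment,
    estimate_dispersion,
    filter_transcripts,
    generate_truth,
    normalize_libsizes,
    simulate_counts,
)
from ripcohort.enrichment import test_enrichment as run_enrichment_test


def _experiment(counts, factor="F01"):
    n_pairs = counts.shape[1] // 2
    meta = []
    cols = []
    for r in range(1, n_pairs + 1):
        for role in ("total", "IP"):
            cols.append(f"{factor}_rep{r}_{role}")
            meta.append({"sample_id": cols[-1], "factor": factor,
                         "replicate": r, "role": role})
    counts = counts.copy()
    counts.columns = cols
    return CountExperiment(counts=counts,
                           samples=pd.DataFrame(meta).set_index("sample_id"))


class TestTMM:
    def test_identical_columns_factor_one(self, rng):
        col = rng.poisson(100, 300)
        counts = pd.DataFrame({"a": col, "b": col})
        eff, facs = normalize_libsizes(counts)
        np.testing.assert_allclose(facs.to_numpy(), 1.0)
        np.testing.assert_allclose(eff["a"], eff["b"])

    def test_pure_depth_change(self, rng):
        col = rng.poisson(100, 300) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        eff, facs = normalize_libsizes(counts)
        np.testing.assert_allclose(facs["a"], facs["b"], rtol=1e-12)
        assert abs(eff["b"] / eff["a"] - 2.0) < 1e-12

    def test_all_zero_column_names_sample(self):
        counts = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_libsizes(counts)

    def test_against_naive_trimmed_mean_oracle(self, rng):
        # 500 genes, 5% strongly DE in sample b
        base = rng.poisson(rng.lognormal(4, 1, 500)).astype(float) + 1
        b = base.copy()
        de = rng.choice(500, 25, replace=False)
        b[de] *= 8
        counts = pd.DataFrame({"a": base, "b": rng.poisson(b).astype(float) + 1})
        _, facs = normalize_libsizes(counts)
        # independent unweighted trimmed-mean evaluation (30% M-trim, 5% A-trim)
        la, lb = counts["a"].sum(), counts["b"].sum()
        M = np.log2((counts["b"] / lb) / (counts["a"] / la))
        A = 0.5 * np.log2((counts["b"] / lb) * (counts["a"] / la))
        mlo, mhi = np.quantile(M, [0.30, 0.70])
        alo, ahi = np.quantile(A, [0.05, 0.95])
        keep = (M >= mlo) & (M <= mhi) & (A >= alo) & (A <= ahi)
        f_oracle = 2 ** M[keep].mean()
        ratio = (facs["b"] / facs["a"]) / np.sqrt(1.0)
        # our factors are geometric-mean centred; compare the pair ratio
        assert abs((facs["b"] / facs["a"]) / f_oracle - 1.0) < 0.05

    def test_against_edger_calcnormfactors(self, rng, tmp_path):
        base = rng.poisson(rng.lognormal(4.5, 1, 400)).astype(int) + 1
        other = rng.poisson(1.7 * base).astype(int) + 1
        other[:20] *= 6
        counts = pd.DataFrame({"s1": base, "s2": other})
        counts.to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("%s"))
            f <- calcNormFactors(x, method="TMM")
            cat(f, sep="\\n")
        """ % (tmp_path / "c.tsv"))
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        _, facs = normalize_libsizes(counts)
        np.testing.assert_allclose(facs.to_numpy(), ref, rtol=0.05)


class TestDispersion:
    def test_poisson_data_gives_near_zero_common(self):
        truth = generate_truth(2000, n_factors=1, k=1, center_separation=0.0,
                               gene_noise_sd=0.0, seed=1, mean_count=300)
        data = simulate_counts(truth, NBParams(dispersion=0.0, n_replicates=3),
                               seed=2)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        fit = estimate_dispersion(exp)
        assert fit.phi_common < 0.01

    def test_known_dispersion_recovered(self):
        truth = generate_truth(2000, n_factors=1, k=1, center_separation=0.0,
                               gene_noise_sd=0.0, seed=3, mean_count=300,
                               abundance_log_sd=0.3)
        data = simulate_counts(truth, NBParams(dispersion=0.2, n_replicates=3),
                               seed=4)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        fit = estimate_dispersion(exp)
        assert 0.15 <= fit.phi_common <= 0.25

    def test_infinite_prior_collapses_to_common(self, demo_run):
        exp = demo_run["experiment"]
        fit = estimate_dispersion(exp, prior_df=np.inf)
        np.testing.assert_allclose(fit.phi_tagwise.to_numpy(), fit.phi_common)

    def test_single_replicate_rejected(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (50, 2)).astype(float))
        exp = _experiment(counts)
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(exp)


class TestEnrichmentTest:
    def test_identical_pairs_give_zero_lfc(self, rng):
        col = rng.poisson(200, 400)
        cols = {}
        for r in (1, 2, 3):
            jitter = rng.poisson(200, 400)
            cols[f"F01_rep{r}_total"] = jitter
            cols[f"F01_rep{r}_IP"] = jitter
        counts = pd.DataFrame(cols)
        meta = pd.DataFrame(
            [{"sample_id": c, "factor": "F01",
              "replicate": int(c.split("rep")[1][0]),
              "role": "IP" if c.endswith("IP") else "total"} for c in cols]
        ).set_index("sample_id")
        exp = CountExperiment(counts=counts, samples=meta)
        fit = estimate_dispersion(exp)
        res = run_enrichment_test(exp, fit, "F01")
        assert np.nanmax(np.abs(res["LFC"].to_numpy())) < 1e-6

    def test_null_pvalues_uniform_and_fdr_controlled(self):
        truth = generate_truth(2000, n_factors=1, k=1, center_separation=0.0,
                               gene_noise_sd=0.0, seed=5, mean_count=200)
        data = simulate_counts(truth, NBParams(dispersion=0.1, n_replicates=3),
                               seed=6)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        res = RIPEnrichment(exp).fit().results["F01"]
        p = res["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01
        assert (res["FDR"].dropna() < 0.01).mean() <= 0.02

    def test_null_calibration_across_seeds(self):
        # pooled across 3 independent null simulations: one KS test at n=2400
        pooled = []
        for seed in (21, 22, 23):
            truth = generate_truth(800, n_factors=1, k=1, center_separation=0.0,
                                   gene_noise_sd=0.0, seed=seed, mean_count=200)
            data = simulate_counts(truth,
                                   NBParams(dispersion=0.1, n_replicates=3),
                                   seed=seed + 100)
            exp = CountExperiment(counts=data.counts, samples=data.samples)
            res = RIPEnrichment(exp).fit().results["F01"]
            pooled.append(res["p"].dropna().to_numpy())
            assert (res["FDR"].dropna() < 0.01).mean() <= 0.02
        assert stats.kstest(np.concatenate(pooled), "uniform").pvalue > 0.01

    def test_planted_lfc_recovered(self):
        # +2 planted on a 10% minority so normalization keeps its anchor
        truth = generate_truth(600, n_factors=1, k=1, center_separation=0.0,
                               gene_noise_sd=0.0, seed=7, mean_count=1000,
                               abundance_log_sd=0.2)
        planted = truth.gene_lfc.index[:60]
        truth.gene_lfc.loc[planted, "F01"] = 2.0
        data = simulate_counts(truth, NBParams(dispersion=0.05, n_replicates=3),
                               seed=8)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        res = RIPEnrichment(exp).fit().results["F01"]
        assert 1.8 <= res.loc[planted, "LFC"].median() <= 2.2

    def test_missing_factor_rejected(self, demo_run):
        with pytest.raises(ValueError, match="absent"):
            run_enrichment_test(demo_run["experiment"],
                            demo_run["results"].nbfit, "NOPE")

    def test_swapping_roles_negates_lfc(self, rng):
        truth = generate_truth(300, n_factors=1, k=2, center_separation=1.5,
                               gene_noise_sd=0.2, seed=9)
        data = simulate_counts(truth, NBParams(dispersion=0.1, n_replicates=3),
                               seed=10)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        fit = estimate_dispersion(exp)
        res = run_enrichment_test(exp, fit, "F01")
        swapped_meta = data.samples.copy()
        swapped_meta["role"] = swapped_meta["role"].map(
            {"IP": "total", "total": "IP"})
        exp2 = CountExperiment(counts=data.counts, samples=swapped_meta)
        fit2 = estimate_dispersion(exp2)
        res2 = run_enrichment_test(exp2, fit2, "F01")
        np.testing.assert_allclose(res2["LFC"].to_numpy(),
                                   -res["LFC"].to_numpy(), atol=1e-6)
        np.testing.assert_allclose(res2["p"].to_numpy(), res["p"].to_numpy(),
                                   atol=1e-6)

    def test_bh_monotone_in_sorted_p(self, demo_run):
        for res in demo_run["results"].results.values():
            sub = res.dropna(subset=["p"]).sort_values("p")
            assert (np.diff(sub["FDR"].to_numpy()) >= -1e-12).all()
            assert (sub["FDR"] >= sub["p"] - 1e-12).all()


class TestFilter:
    @staticmethod
    def _fake_results(fdrs):
        # fdrs: dict factor -> per-gene FDR list over genes g0..gN
        out = {}
        genes = [f"g{i}" for i in range(len(next(iter(fdrs.values()))))]
        for f, vals in fdrs.items():
            out[f] = pd.DataFrame({"LFC": 1.0, "p": vals, "FDR": vals},
                                  index=genes)
        return out, genes

    @staticmethod
    def _uniform_experiment(genes, count=25):
        counts = pd.DataFrame(
            {c: [count] * len(genes)
             for c in ("F01_rep1_total", "F01_rep1_IP",
                       "F01_rep2_total", "F01_rep2_IP")}, index=genes)
        meta = pd.DataFrame(
            [{"sample_id": c, "factor": "F01",
              "replicate": int(c.split("rep")[1][0]),
              "role": "IP" if c.endswith("IP") else "total"}
             for c in counts.columns]).set_index("sample_id")
        return CountExperiment(counts=counts, samples=meta)

    def test_kept_with_one_significant_factor(self):
        res, genes = self._fake_results({"A": [0.005], "B": [0.5]})
        exp = self._uniform_experiment(genes, count=21)
        assert filter_transcripts(res, exp) == ["g0"]

    def test_dropped_when_never_significant(self):
        res, genes = self._fake_results({"A": [0.02], "B": [0.3]})
        exp = self._uniform_experiment(genes, count=1000)
        assert filter_transcripts(res, exp) == []

    def test_dropped_when_any_total_at_or_below_20(self):
        res, genes = self._fake_results({"A": [0.001]})
        exp = self._uniform_experiment(genes, count=20)  # 20 is not > 20
        assert filter_transcripts(res, exp) == []
        exp15 = self._uniform_experiment(genes, count=15)
        assert filter_transcripts(res, exp15) == []

    def test_order_follows_experiment(self, demo_run):
        uni = demo_run["universe"]
        order = {g: i for i, g in
                 enumerate(demo_run["experiment"].counts.index)}
        assert uni == sorted(uni, key=order.__getitem__)


class TestScaleInvariance:
    def test_scaling_absorbed_by_offsets(self):
        # depth changes handed to the offsets do not move the estimates:
        # a global count x c with library sizes x c leaves every LFC
        # unchanged to machine precision, and a single-column x c with a
        # compensated library size is absorbed up to likelihood reweighting
        # (two orders of magnitude below the uncompensated log2(c) shift)
        truth = generate_truth(200, n_factors=1, k=2, center_separation=1.0,
                               gene_noise_sd=0.2, seed=11, mean_count=300)
        data = simulate_counts(truth, NBParams(dispersion=0.0, n_replicates=3),
                               seed=12)
        exp = CountExperiment(counts=data.counts, samples=data.samples)
        fit = estimate_dispersion(exp)
        fit.phi_tagwise[:] = 0.0
        res = run_enrichment_test(exp, fit, "F01")

        c = 3
        glob = CountExperiment(counts=data.counts * c, samples=data.samples)
        fit_g = estimate_dispersion(glob)
        fit_g.eff_lib_sizes = fit.eff_lib_sizes * c
        fit_g.phi_tagwise = fit.phi_tagwise
        res_g = run_enrichment_test(glob, fit_g, "F01")
        np.testing.assert_allclose(res_g["LFC"], res["LFC"], atol=1e-8)

        counts2 = data.counts.copy()
        counts2["F01_rep1_IP"] = counts2["F01_rep1_IP"] * c
        exp2 = CountExperiment(counts=counts2, samples=data.samples)
        fit2 = estimate_dispersion(exp2)
        fit2.eff_lib_sizes = fit.eff_lib_sizes.copy()
        fit2.eff_lib_sizes["F01_rep1_IP"] *= c
        fit2.phi_tagwise = fit.phi_tagwise
        res2 = run_enrichment_test(exp2, fit2, "F01")
        diff = (res2["LFC"] - res["LFC"]).abs()
        assert diff.median() < 0.02 and diff.max() < 0.2  # vs log2(3)=1.58
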
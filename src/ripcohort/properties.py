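"""Cluster-vs-all property comparisons and 5'UTR adenosine profiles.

Each cluster's distribution of a per-gene property (length, half-life,
ribosome occupancy, ...) is compared against the all-gene distribution
(cluster members included, one-vs-all) with the two-sided Mann-Whitney U
test; p-values are BH-adjusted jointly over every (cluster, property) pair
of a run.  Boxplot summaries use linearly interpolated quartiles and the
notch convention median +/- 1.58 * IQR / sqrt(n) (an approximate 95% CI of
the median).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import TranscriptAnnotation

EXACT_MAX_PRODUCT = 400  # exact enumeration when n1*n2 <= this and no ties


def mannwhitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x vs y.

    Exact enumeration for small tie-free samples (n1*n2 <= 400), otherwise
    the normal approximation with continuity and tie correction.  Returns
    (U of x, p).  Fully tied data gives U = n1*n2/2, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return n1 * n2 / 2.0, 1.0
    ties = len(np.unique(pooled)) < n1 + n2
    method = "exact" if (n1 * n2 <= EXACT_MAX_PRODUCT and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_box(values) -> dict:
    """Median, linearly interpolated quartiles and the notch interval."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 1:
        raise ValueError("summarize_box needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    half = 1.58 * (q3 - q1) / np.sqrt(v.size)
    return {
        "n": int(v.size), "median": float(med), "Q1": float(q1), "Q3": float(q3),
        "notch_low": float(med - half), "notch_high": float(med + half),
    }


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def compare_property(
    values: pd.Series,
    labels: pd.Series,
    property_name: str,
    adjust: bool = True,
) -> pd.DataFrame:
    """Each cluster vs the all-gene distribution for one property.

    When called standalone the BH batch is this property's clusters; the
    pipeline instead adjusts jointly across properties via
    :func:`compare_properties`.
    """
    vals = values.reindex(labels.index)
    if vals.dropna().empty:
        raise ValueError(f"property {property_name!r} has no non-missing values")
    all_vals = vals.dropna().to_numpy()
    rows = []
    for cluster in sorted(pd.unique(labels)):
        cl = vals[labels == cluster].dropna().to_numpy()
        if len(cl) < 3 or len(all_vals) < 3:
            continue
        U, p = mannwhitney_u(cl, all_vals)
        box = summarize_box(cl)
        rows.append({"property": property_name, "cluster": int(cluster),
                     "U": U, "p": p, **box})
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        out = _bh_adjust(out)
    return out


def _bh_adjust(table: pd.DataFrame) -> pd.DataFrame:
    _, p_adj, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table = table.copy()
    table["p_adj"] = p_adj
    table["stars"] = [_stars(q) for q in p_adj]
    return table


def compare_properties(props: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """All (cluster x property) comparisons with one joint BH correction."""
    parts = [
        compare_property(props[c], labels, c, adjust=False) for c in props.columns
    ]
    table = pd.concat([p for p in parts if not p.empty], ignore_index=True)
    return _bh_adjust(table)


# ---------------------------------------------------------------------------
# 5'UTR adenosine composition


def _check_seq(gene: str, seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValueError(
                f"non-ACGT character {ch!r} in 5'UTR of {gene} at position {i}"
            )


def utr_a_fraction(annotation: TranscriptAnnotation) -> pd.Series:
    """Per-gene proportion of adenosine in the 5'UTR (zero-length excluded)."""
    out = {}
    for g in annotation.genes:
        seq = annotation.utr5[g]
        if len(seq) == 0:
            continue
        _check_seq(g, seq)
        out[g] = seq.count("A") / len(seq)
    return pd.Series(out, name="utr5_a_fraction")


def positional_a_enrichment(
    annotation: TranscriptAnnotation,
    labels: pd.Series,
    max_depth: int = 100,
    min_coverage: int = 25,
) -> pd.DataFrame:
    """Adenosine frequency by 5'UTR position (start-codon anchored), per
    cluster, relative to the all-gene frequency at the same position.

    Position -1 is the base immediately 5' of the AUG; only UTRs long enough
    to span a position contribute there.  Rows with fewer than
    ``min_coverage`` covering UTRs, or with zero all-gene frequency, have
    NaN enrichment.
    """
    genes = [g for g in annotation.genes if g in labels.index]
    # matrix of is-A indicators, aligned at the start codon, NaN beyond UTR
    mat = np.full((len(genes), max_depth), np.nan)
    for i, g in enumerate(genes):
        seq = annotation.utr5[g]
        _check_seq(g, seq)
        depth = min(len(seq), max_depth)
        for d in range(1, depth + 1):  # position -d is seq[-d]
            mat[i, d - 1] = 1.0 if seq[-d] == "A" else 0.0

    lab = labels.reindex(genes).to_numpy()
    with np.errstate(invalid="ignore"):
        f_all = np.nanmean(mat, axis=0)
    n_all = np.sum(~np.isnan(mat), axis=0)

    rows = []
    for cluster in sorted(pd.unique(labels)):
        sub = mat[lab == cluster]
        n_cov = np.sum(~np.isnan(sub), axis=0)
        f_cl = np.array([
            np.nanmean(sub[:, j]) if n_cov[j] > 0 else np.nan for j in range(max_depth)
        ])
        for j in range(max_depth):
            pos = -(j + 1)
            enr = np.nan
            if n_cov[j] >= min_coverage and n_all[j] >= min_coverage and f_all[j] > 0:
                enr = f_cl[j] / f_all[j]
            rows.append({
                "cluster": int(cluster), "position": pos,
                "f_cluster": float(f_cl[j]) if n_cov[j] > 0 else np.nan,
                "f_all": float(f_all[j]) if n_all[j] > 0 else np.nan,
                "enrichment": enr, "n_covered": int(n_cov[j]),
            })
    return pd.DataFrame(rows)
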
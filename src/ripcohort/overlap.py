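"""Gene-set overlap significance: exact hypergeometric tails for pairwise
overlaps, Monte-Carlo nulls for multi-way intersections, and term
over-representation for clusters against annotation/target lists.

The MC null draws every set uniformly without replacement from the universe
at its observed size and intersects them.  It is realized by chained
hypergeometric draws (given |A1 ∩ ... ∩ Aj| = m, the next intersection size
is Hypergeometric(N, m, |A_{j+1}|)), which is distributionally identical and
vectorizes to millions of draws.  The add-one estimator
p = (hits + 1)/(draws + 1) keeps p > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapResult:
    N: int
    K: int
    n: int
    x: int
    p: float
    enrichment_ratio: float
    method: str
    n_draws: int | None = None
    seed: int | None = None
    mc_se: float | None = None
    p_adj: float | None = None


def _check_subset(name, s, universe):
    extra = set(s) - set(universe)
    if extra:
        raise ValueError(f"{name} contains elements outside the universe: "
                         f"{sorted(extra)[:10]}")


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Upper tail P(X >= x) for overlap of a size-n draw with a size-K set."""
    if x <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(x - 1, N, K, n)))


def hypergeom_overlap(setA, setB, universe) -> OverlapResult:
    """Exact hypergeometric upper-tail significance of |A ∩ B|."""
    universe = list(universe)
    _check_subset("setA", setA, universe)
    _check_subset("setB", setB, universe)
    N, K, n = len(universe), len(set(setA)), len(set(setB))
    x = len(set(setA) & set(setB))
    ratio = (x / n) / (K / N) if n > 0 and K > 0 else np.nan
    return OverlapResult(N=N, K=K, n=n, x=x, p=hypergeom_tail(N, K, n, x),
                         enrichment_ratio=ratio, method="hypergeometric")


def mc_multiway_overlap(sets, universe, n_draws: int = 1_000_000,
                        seed: int = 0) -> OverlapResult:
    """Monte-Carlo significance of the full intersection of >= 2 sets.

    Each draw resamples every set uniformly at its observed size; the
    statistic is the size of the full intersection.
    """
    universe = list(universe)
    N = len(universe)
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    for i, s in enumerate(sets):
        _check_subset(f"set {i}", s, universe)
        if len(s) > N:
            raise ValueError(f"set {i} larger than the universe")
    sizes = [len(s) for s in sets]
    observed = len(set.intersection(*sets))

    rng = np.random.default_rng(seed)
    m = np.full(n_draws, sizes[0], dtype=np.int64)
    for sz in sizes[1:]:
        m = rng.hypergeometric(np.maximum(m, 0), N - np.maximum(m, 0), sz)
    hits = int(np.sum(m >= observed))
    p = (hits + 1) / (n_draws + 1)
    mc_se = float(np.sqrt(p * (1.0 - p) / n_draws))
    ratio = np.nan
    if all(sizes) and N > 0:
        expected = N * np.prod([s / N for s in sizes])
        ratio = observed / expected if expected > 0 else np.nan
    return OverlapResult(N=N, K=sizes[0], n=sizes[-1], x=observed, p=float(p),
                         enrichment_ratio=float(ratio), method="monte_carlo",
                         n_draws=n_draws, seed=seed, mc_se=mc_se)


def term_enrichment(
    query_sets: dict[str, set],
    term2gene: pd.DataFrame | dict[str, set],
    universe,
    min_size: int = 3,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in each query set.

    ``term2gene`` is either a mapping term -> genes or a two-column
    (term, gene) DataFrame.  Terms are restricted to the universe and
    filtered by size; BH adjustment is applied per query set.  The output
    carries the dot-plot quantities (enrichment_ratio, p_adj).
    """
    universe = list(universe)
    if len(universe) == 0:
        raise ValueError("empty universe")
    uni = set(universe)
    N = len(uni)
    if isinstance(term2gene, pd.DataFrame):
        t2g = {t: set(g) for t, g in term2gene.groupby(term2gene.columns[0])[
            term2gene.columns[1]]}
    else:
        t2g = {t: set(g) for t, g in term2gene.items()}
    terms = {}
    for t, genes in t2g.items():
        tg = genes & uni
        if min_size <= len(tg) <= max_size:
            terms[t] = tg

    rows = []
    for qname, qset in query_sets.items():
        _check_subset(f"query {qname!r}", qset, universe)
        q = set(qset)
        batch = []
        for t, tg in terms.items():
            x = len(q & tg)
            K, n = len(tg), len(q)
            ratio = (x / n) / (K / N) if n > 0 else np.nan
            batch.append({"query": qname, "term": t, "N": N, "K": K, "n": n,
                          "x": x, "p": hypergeom_tail(N, K, n, x),
                          "enrichment_ratio": ratio})
        if batch:
            df = pd.DataFrame(batch)
            _, p_adj, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
            df["p_adj"] = p_adj
            rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["query", "term", "N", "K", "n", "x", "p",
                                     "enrichment_ratio", "p_adj"])
    return pd.concat(rows, ignore_index=True)
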
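"""Interaction-profile integration and clustering.

Builds the gene x factor LFC matrix over the filtered universe, computes the
pairwise Pearson/R^2 similarity of experiments and the 1 - R dissimilarity,
orders experiments and cluster centers by UPGMA, and partitions genes into k
interaction-profile clusters with k-means (squared Euclidean on raw LFC
rows).  Cluster IDs 1..k follow the UPGMA leaf order of the centers under
correlation distance, so numbering is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


# ---------------------------------------------------------------------------
# LFC matrix assembly


def build_lfc_matrix(
    results_all_factors: dict[str, pd.DataFrame],
    universe: list[str],
    fill_untested: float = 0.0,
) -> pd.DataFrame:
    """Gene x factor LFC matrix over the filtered universe.

    Universe genes that were below the testing floor in some factor (LFC is
    NaN there) receive ``fill_untested`` (0 = no enrichment); a universe gene
    entirely absent from a factor's result table is an error.
    """
    cols = {}
    for factor, res in results_all_factors.items():
        missing = [g for g in universe if g not in res.index]
        if missing:
            raise KeyError(
                f"universe gene(s) missing from results for factor {factor!r}: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        cols[factor] = res["LFC"].reindex(universe).fillna(fill_untested)
    return pd.DataFrame(cols, index=pd.Index(universe, name="gene"))


# ---------------------------------------------------------------------------
# correlation / dissimilarity


@dataclass
class CorrelationMatrix:
    """Pairwise experiment similarity: Pearson R, R^2 and D = 1 - R."""

    R: pd.DataFrame
    R2: pd.DataFrame
    D: pd.DataFrame


def pairwise_r2(profile: pd.DataFrame) -> CorrelationMatrix:
    if profile.shape[0] < 3:
        raise ValueError("need at least 3 genes to correlate experiments")
    sd = profile.std(axis=0, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance factor column(s): {list(flat)}")
    R = profile.corr(method="pearson")
    np.fill_diagonal(R.to_numpy(), 1.0)
    return CorrelationMatrix(R=R, R2=R**2, D=1.0 - R)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Dendrogram:
    """UPGMA tree over labeled items (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        """Left-to-right leaves; at each node the subtree containing the
        smaller original index goes left."""
        n = len(self.labels)

        def leaves(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right = int(self.linkage_matrix[node - n, 0]), int(
                self.linkage_matrix[node - n, 1]
            )
            ll, rl = leaves(left), leaves(right)
            return ll + rl if min(ll) <= min(rl) else rl + ll

        return [self.labels[i] for i in leaves(2 * n - 2)] if n > 1 else list(self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cophenetic(self) -> pd.DataFrame:
        n = len(self.labels)
        if n == 1:
            return pd.DataFrame([[0.0]], index=self.labels, columns=self.labels)
        coph = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        """Newick with ultrametric branch lengths = (merge height)/2 per
        level, so leaf-to-leaf path lengths equal cophenetic distances."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}

        def node_str(node: int) -> str:
            if node < n:
                return self.labels[node]
            row = self.linkage_matrix[node - n]
            left, right, h = int(row[0]), int(row[1]), float(row[2])
            height[node] = h / 2.0
            if self._leaf_min(left) > self._leaf_min(right):
                left, right = right, left
            parts = []
            for child in (left, right):
                cs = node_str(child)
                parts.append(f"{cs}:{height[node] - height[child]:.10g}")
            return "(" + ",".join(parts) + ")"

        if n == 1:
            return f"{self.labels[0]};"
        return node_str(2 * n - 2) + ";"

    def clades(self) -> set[frozenset]:
        """Leaf-label sets of every internal node (topology fingerprint)."""
        n = len(self.labels)

        def leaves(node: int) -> list[int]:
            if node < n:
                return [node]
            row = self.linkage_matrix[node - n]
            return leaves(int(row[0])) + leaves(int(row[1]))

        return {frozenset(self.labels[i] for i in leaves(n + j))
                for j in range(max(n - 1, 0))}

    def _leaf_min(self, node: int) -> int:
        n = len(self.labels)
        if node < n:
            return node
        row = self.linkage_matrix[node - n]
        return min(self._leaf_min(int(row[0])), self._leaf_min(int(row[1])))


def upgma(D: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA (size-weighted average linkage) over a dissimilarity matrix."""
    if isinstance(D, pd.DataFrame):
        labels = labels or list(D.index)
        D = D.to_numpy()
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    labels = labels or [str(i) for i in range(D.shape[0])]
    if D.shape[0] == 1:
        return Dendrogram(np.empty((0, 4)), labels)
    Dz = D.copy()
    np.fill_diagonal(Dz, 0.0)
    Z = linkage(squareform(Dz, checks=False), method="average")
    return Dendrogram(Z, list(labels))


# ---------------------------------------------------------------------------
# k-means clustering


@dataclass
class ClusterModel:
    """A fitted k-means partition of interaction profiles.

    labels maps gene -> cluster id in 1..k (numbered by the UPGMA leaf order
    of the centers under 1 - Pearson distance); centers are the member-mean
    LFC profiles; cluster_tree is the center dendrogram.
    """

    k: int
    labels: pd.Series
    centers: pd.DataFrame
    inertia: float
    cluster_tree: Dendrogram | None
    seed: int
    n_starts: int
    profile: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        sizes = self.labels.value_counts().sort_index()
        lines = [
            f"k-means interaction-profile clustering (k={self.k}, "
            f"{self.n_starts} starts, seed={self.seed})",
            f"  genes: {len(self.labels)}  factors: {self.centers.shape[1]}  "
            f"inertia: {self.inertia:.4g}",
            "  cluster sizes: "
            + ", ".join(f"{c}: {sizes.get(c, 0)}" for c in range(1, self.k + 1)),
        ]
        if self.cluster_tree is not None:
            lines.append(f"  center tree: {self.cluster_tree.to_newick()}")
        return "\n".join(lines)


def _center_tree(centers: pd.DataFrame) -> Dendrogram | None:
    if centers.shape[0] < 2:
        return None
    C = centers.T.corr(method="pearson")
    D = 1.0 - C
    np.fill_diagonal(D.to_numpy(), 0.0)
    return upgma(D, labels=[str(c) for c in centers.index])


def kmeans_clusters(
    profile: pd.DataFrame,
    k: int = 7,
    n_starts: int = 50,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Partition genes into k profile clusters (Lloyd + k-means++, best of
    ``n_starts`` by inertia), with reproducible cluster numbering."""
    if k > profile.shape[0]:
        raise ValueError(f"k ({k}) may not exceed the number of genes ({profile.shape[0]})")
    X = profile.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_starts, max_iter=max_iter,
        random_state=seed, algorithm="lloyd",
    ).fit(X)
    raw = km.labels_

    # recompute centers as member means (guards the reconstruction invariant)
    centers = np.vstack([X[raw == c].mean(axis=0) for c in range(k)])

    if k == 1:
        order = [0]
        tree = None
    else:
        cdf = pd.DataFrame(centers, index=range(k), columns=profile.columns)
        # degenerate zero-variance centers make Pearson undefined; fall back
        # to Euclidean ordering in that corner case
        if np.any(cdf.std(axis=1).to_numpy() == 0):
            order = list(np.argsort(np.linalg.norm(centers, axis=1)))
            tree = None
        else:
            tree0 = _center_tree(cdf)
            order = [int(x) for x in tree0.leaf_order]
            tree = tree0
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=profile.index, name="cluster")
    centers_df = pd.DataFrame(
        centers[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=profile.columns,
    )
    if tree is not None:
        tree = _center_tree(centers_df)  # rebuilt so leaf labels match new ids
    return ClusterModel(
        k=k, labels=labels, centers=centers_df, inertia=float(km.inertia_),
        cluster_tree=tree, seed=seed, n_starts=n_starts, profile=profile,
    )


class ProfileClustering:
    """Model wrapper: ``ProfileClustering(profile, k=7).fit(seed=0)``."""

    def __init__(self, profile: pd.DataFrame, k: int = 7, n_starts: int = 50,
                 max_iter: int = 300):
        self.profile = profile
        self.k = k
        self.n_starts = n_starts
        self.max_iter = max_iter

    def fit(self, seed: int = 0) -> ClusterModel:
        return kmeans_clusters(
            self.profile, k=self.k, n_starts=self.n_starts,
            max_iter=self.max_iter, seed=seed,
        )


def choose_k_diagnostics(
    profile: pd.DataFrame,
    k_range=range(2, 11),
    n_starts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Inertia and mean silhouette per candidate k (no automatic choice)."""
    X = profile.to_numpy(dtype=float)
    rows = []
    for k in k_range:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValueError(f"k={k} outside [2, n_genes-1]")
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_starts,
                    random_state=seed, algorithm="lloyd").fit(X)
        sil = silhouette_score(X, km.labels_, metric="euclidean")
        rows.append({"k": k, "inertia": float(km.inertia_), "silhouette": float(sil)})
    return pd.DataFrame(rows)
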
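"""Sample classification: hierarchical clustering, PCA scores, topology checks.

Samples are clustered on log2 relative quantities (= −ΔΔCt), so Euclidean
distances carry cycle units.  Non-detects are handled by pairwise-complete
distances: for each sample pair the squared differences over jointly detected
assays are rescaled by (total assays / shared assays), keeping distances
comparable across pairs with different missingness (listwise deletion is
available behind a flag).  Linkage defaults to average (UPGMA).

Dendrogram read-offs that in print are done by eye — "group X clusters with
group Y, group Z is distinct" — are replaced by quantitative checks:
monophyly of a label set (does some subtree contain exactly those samples),
disjointness of smallest enclosing subtrees, and the adjusted Rand index of a
k-cut against the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .ct_io import RQMatrix
from .errors import ClusterInputError, ParameterError
from .results import SelectionResult
from .selection_stats import supervised_anova_select

__all__ = [
    "Dendrogram",
    "PcaScores",
    "pairwise_distances",
    "hierarchical_cluster",
    "supervised_cluster",
    "pca_scores",
    "topology_checks",
    "adjusted_rand",
    "group_silhouette",
]


@dataclass
class Dendrogram:
    """A binary merge tree over samples.

    ``linkage_matrix`` is the scipy linkage encoding; ``leaves`` gives the
    sample id of each leaf index.  Merge heights are non-decreasing for the
    monotone linkages used here (single/complete/average).
    """

    linkage_matrix: np.ndarray
    leaves: list[str]
    metric: str
    method: str
    selection: SelectionResult | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k flat clusters."""
        labels = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.leaves)

    def subtree_leafsets(self) -> list[frozenset[str]]:
        """Leaf set of every internal node (including the root)."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([s]) for i, s in enumerate(self.leaves)
        }
        out = []
        for row_idx, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + row_idx] = merged
            out.append(merged)
        return out

    def is_monophyletic(self, sample_set) -> bool:
        """True iff some subtree contains exactly ``sample_set``.

        A single sample is trivially monophyletic (it is its own leaf).
        """
        target = frozenset(sample_set)
        unknown = target - set(self.leaves)
        if unknown:
            raise ParameterError(f"samples not in dendrogram: {sorted(unknown)}")
        if len(target) <= 1:
            return True
        return target in set(self.subtree_leafsets())

    def smallest_enclosing(self, sample_set) -> frozenset[str]:
        """Leaf set of the smallest subtree containing all of ``sample_set``."""
        target = frozenset(sample_set)
        unknown = target - set(self.leaves)
        if unknown:
            raise ParameterError(f"samples not in dendrogram: {sorted(unknown)}")
        if len(target) == 1:
            return target
        best = frozenset(self.leaves)
        for ls in self.subtree_leafsets():
            if target <= ls and len(ls) < len(best):
                best = ls
        return best

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for row_idx, (a, b, h, _) in enumerate(self.linkage_matrix):
            node = n + row_idx
            heights[node] = float(h)
            children[node] = (int(a), int(b))
        root = n + len(self.linkage_matrix) - 1 if len(self.linkage_matrix) else 0

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.leaves[node]}:{bl:.10g}"
            a, b = children[node]
            inner = ",".join(render(c, heights[node]) for c in (a, b))
            return f"({inner}):{bl:.10g}"

        if not len(self.linkage_matrix):
            return f"{self.leaves[0]};"
        a, b = children[root]
        inner = ",".join(render(c, heights[root]) for c in (a, b))
        return f"({inner});"


@dataclass
class PcaScores:
    """Two leading principal-component scores per sample.

    ``explained_variance_ratio`` covers *all* components (fractions sum to 1,
    sorted descending); scores are mean-zero per component and component
    signs are fixed so the largest-magnitude gene loading is positive.
    """

    scores: pd.DataFrame  # samples x [PC1, PC2]
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x [PC1, PC2]


# ---------------------------------------------------------------------------


def pairwise_distances(
    matrix: pd.DataFrame, rescale_missing: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Condensed Euclidean distances over samples (columns of ``matrix``).

    With ``rescale_missing`` (default) each pair's squared distance over
    jointly detected assays is scaled by total/shared assay counts; with no
    missing cells this equals the plain Euclidean distance.  With
    ``rescale_missing=False``, rows with any missing value are dropped first
    (listwise deletion).  A pair sharing zero assays has no defined distance
    and is an error naming the pair.
    """
    samples = list(matrix.columns)
    if len(samples) < 2:
        raise ParameterError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if not rescale_missing:
        x = x[~np.isnan(x).any(axis=1)]
        if x.shape[0] == 0:
            raise ClusterInputError("no complete assay rows under listwise deletion")
    n_total = x.shape[0]
    present = ~np.isnan(x)
    out = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            shared = present[:, i] & present[:, j]
            n_sh = int(shared.sum())
            if n_sh == 0:
                raise ClusterInputError(
                    f"samples {samples[i]!r} and {samples[j]!r} share no detected assay"
                )
            diff = x[shared, i] - x[shared, j]
            d2 = float(np.dot(diff, diff)) * (n_total / n_sh)
            out.append(np.sqrt(d2))
    return np.asarray(out), samples


def hierarchical_cluster(
    matrix: pd.DataFrame,
    assays=None,
    metric: str = "euclidean",
    method: str = "average",
    rescale_missing: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of samples on (a subset of) log2 RQ rows.

    Samples are sorted lexicographically before distance computation so the
    tree is invariant to the input column order (scipy's tie-breaking is then
    deterministic).  ``metric`` is Euclidean — the distance the original
    heatmaps use; it is kept as an argument for the provenance record.
    """
    if metric != "euclidean":
        raise ParameterError("only the euclidean metric is supported")
    sub = matrix if assays is None else matrix.loc[list(assays)]
    sub = sub[sorted(sub.columns)]
    condensed, samples = pairwise_distances(sub, rescale_missing=rescale_missing)
    z = sch.linkage(condensed, method=method)
    return Dendrogram(linkage_matrix=z, leaves=samples, metric=metric, method=method)


def supervised_cluster(
    rq: RQMatrix,
    groups: pd.Series,
    alpha: float,
    method: str = "average",
    rescale_missing: bool = True,
) -> Dendrogram:
    """ANOVA feature selection followed by hierarchical clustering.

    Runs :func:`supervised_anova_select` at ``alpha`` on the annotated
    samples, then clusters *all* samples of ``rq`` on the retained assays.
    The selection record is attached to the returned dendrogram.  An empty
    selection is an error (raise ``alpha``).
    """
    sel = supervised_anova_select(rq, groups, alpha)
    if not sel.retained:
        raise ParameterError(
            f"ANOVA at alpha={alpha} retained no assay; increase alpha"
        )
    dend = hierarchical_cluster(
        rq.log2(), assays=sel.retained, method=method, rescale_missing=rescale_missing
    )
    dend.selection = sel
    return dend


def pca_scores(matrix: pd.DataFrame, assays=None) -> PcaScores:
    """Two-component PCA of samples from a gene × sample log2 RQ matrix.

    Genes are mean-centered across samples; missing cells are mean-imputed
    per gene before decomposition.  Requires >= 3 samples, >= 2 assays and a
    non-constant matrix.
    """
    sub = matrix if assays is None else matrix.loc[list(assays)]
    if sub.shape[1] < 3:
        raise ParameterError("need at least 3 samples")
    if sub.shape[0] < 2:
        raise ParameterError("need at least 2 assays")
    x = sub.to_numpy(dtype=float)
    if np.isnan(x).any():
        means = np.nanmean(x, axis=1, keepdims=True)
        x = np.where(np.isnan(x), means, x)
    centered = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ParameterError("constant matrix: no principal directions")
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)  # samples x genes
    evr = s**2 / np.sum(s**2)
    scores = u[:, :2] * s[:2]
    loads = vt[:2].T
    for j in range(2):
        lead = np.argmax(np.abs(loads[:, j]))
        if loads[lead, j] < 0:
            loads[:, j] = -loads[:, j]
            scores[:, j] = -scores[:, j]
    return PcaScores(
        scores=pd.DataFrame(scores, index=sub.columns, columns=["PC1", "PC2"]),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(loads, index=sub.index, columns=["PC1", "PC2"]),
    )


# ---------------------------------------------------------------------------
# quantitative topology read-offs


def adjusted_rand(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Adjusted Rand index between two labelings over the same samples."""
    common = [s for s in labels_a.index if s in labels_b.index]
    return float(adjusted_rand_score(labels_a.loc[common], labels_b.loc[common]))


def group_silhouette(scores: PcaScores, groups: pd.Series) -> float:
    """Mean silhouette of annotated groups in 2-component score space."""
    common = [s for s in scores.scores.index if s in groups.index]
    return float(
        silhouette_score(scores.scores.loc[common].to_numpy(), groups.loc[common])
    )


def topology_checks(
    dend: Dendrogram,
    groups: pd.Series,
    monophyly: list | None = None,
    disjoint: list[tuple] | None = None,
    ari_k: int | None = None,
) -> dict:
    """Quantitative dendrogram read-offs against an annotation.

    ``monophyly`` lists label sets — each entry a label or tuple of labels —
    to test for exact subtree containment.  ``disjoint`` lists label pairs
    whose smallest enclosing subtrees must not overlap.  ``ari_k`` requests
    the adjusted Rand index of the k-cut against the annotation labels.
    """
    missing = [s for s in dend.leaves if s not in groups.index]
    if missing:
        raise ParameterError(f"samples without annotation: {missing}")

    def members(labels) -> set[str]:
        labels = (labels,) if isinstance(labels, str) else tuple(labels)
        bad = set(labels) - set(groups.unique())
        if bad:
            raise ParameterError(f"labels absent from annotation: {sorted(bad)}")
        return {s for s in dend.leaves if groups[s] in labels}

    report: dict = {}
    if monophyly:
        report["monophyly"] = {
            str(lab): dend.is_monophyletic(members(lab)) for lab in monophyly
        }
    if disjoint:
        res = {}
        for la, lb in disjoint:
            ea = dend.smallest_enclosing(members(la))
            eb = dend.smallest_enclosing(members(lb))
            res[f"{la}|{lb}"] = ea.isdisjoint(eb)
        report["disjoint"] = res
    if ari_k is not None:
        cut = dend.cut(ari_k)
        report["ari"] = adjusted_rand(cut, groups.loc[dend.leaves])
        report["ari_k"] = ari_k
    return report
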
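"""Temporal-profile clustering of differential genes, sample ordination and
wave-activation scoring.

The differential genes of the wild-type time course fall into eight temporal
profiles.  Each gene is summarised by its standardized (z-scored) triple of
stage means over (roots, incipient nodules, nodules); genes are clustered
hierarchically with a correlation distance and the tree is cut at a fixed k.
Cluster ids are renumbered into a stable semantic order: profiles 1-3 are
repressed variants, 4 is the incipient-transient profile, 5-6 form the first
activation wave (induced already in incipient nodules) and 7-8 the second
wave (full induction only in mature nodules).  Wave activation of an
arbitrary sample is scored as the median log2 induction of a wave's gene set
over the root baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .arrays import ExpressionMatrix
from .de import STAGES, StageGrouping

#: Canonical stage-tier shapes (roots, incipient, nodules) on a 0..1 tier
#: scale, in the semantic profile order.  1-3: repressed variants; 4:
#: incipient-transient; 5-6: first wave; 7-8: second wave.
DEFAULT_PROFILE_SHAPES: dict[int, tuple[float, float, float]] = {
    1: (1.0, 0.0, 0.0),
    2: (1.0, 0.0, 1.0),
    3: (1.0, 1.0, 0.0),
    4: (0.0, 1.0, 0.0),
    5: (0.0, 1.0, 0.5),
    6: (0.0, 1.0, 1.0),
    7: (0.0, 0.5, 1.0),
    8: (0.0, 0.0, 1.0),
}

#: Profile ids defining the two transcriptome waves.
WAVE1_PROFILES = (5, 6)
WAVE2_PROFILES = (7, 8)


class ClusteringError(ValueError):
    pass


@dataclass
class ProfileAssignment:
    """gene -> profile id (1..k), per-profile mean standardized stage triple
    and the linkage tree the cut came from."""

    assignments: pd.Series
    templates: pd.DataFrame  # index: profile id; columns: STAGES (standardized)
    linkage: np.ndarray

    def genes_in(self, profile_ids: Sequence[int]) -> list[str]:
        wanted = set(profile_ids)
        return [g for g, p in self.assignments.items() if p in wanted]


@dataclass
class SampleClustering:
    coordinates: pd.DataFrame | None = None  # samples x PCs
    variance_fractions: np.ndarray | None = None
    labels: pd.Series | None = None
    linkage: np.ndarray | None = None
    newick: str | None = None


@dataclass
class WaveScore:
    """Median log2 induction of wave-1 and wave-2 gene sets over the root
    baseline, per sample, with activation booleans at ``threshold``."""

    scores: pd.DataFrame  # samples x [wave1_score, wave2_score]
    threshold: float

    @property
    def active(self) -> pd.DataFrame:
        out = self.scores >= self.threshold
        return out.rename(
            columns={"wave1_score": "wave1_active", "wave2_score": "wave2_active"}
        )


def stage_mean_matrix(expr: ExpressionMatrix, groups: StageGrouping) -> pd.DataFrame:
    """Genes x stages matrix of mean log2 ratios."""
    cols = {}
    for stage in STAGES:
        arrays = [a for a in groups.arrays_in(stage) if a in expr.values.columns]
        if not arrays:
            raise ClusteringError(f"no arrays for stage {stage!r}")
        cols[stage] = expr.values[arrays].mean(axis=1)
    return pd.DataFrame(cols)[list(STAGES)]


def standardize_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score; zero-variance rows map to all-zero rows."""
    centered = m.sub(m.mean(axis=1), axis=0)
    sd = m.std(axis=1, ddof=0)
    safe = sd.replace(0.0, 1.0)
    return centered.div(safe, axis=0)


def _standardized_shapes(
    shapes: Mapping[int, tuple[float, float, float]]
) -> pd.DataFrame:
    df = pd.DataFrame(shapes).T
    df.columns = list(STAGES)
    return standardize_rows(df)


def _semantic_renumbering(
    centroids: pd.DataFrame, shapes: Mapping[int, tuple[float, float, float]]
) -> dict[int, int]:
    """Map raw cluster labels to semantic ids by template-shape matching.

    When the cluster count equals the number of reference shapes the mapping
    is the correlation-maximising assignment; otherwise clusters are ordered
    by a repressed-to-activated key (nodules-roots, then incipient-roots
    contrast of the centroid).
    """
    refs = _standardized_shapes(shapes)
    raw_labels = list(centroids.index)
    if len(raw_labels) == len(refs):
        c = centroids.to_numpy()
        r = refs.to_numpy()
        # cost = 1 - Pearson correlation between centroid and reference shape
        cn = c - c.mean(axis=1, keepdims=True)
        rn = r - r.mean(axis=1, keepdims=True)
        cn /= np.where(np.linalg.norm(cn, axis=1, keepdims=True) == 0, 1, np.linalg.norm(cn, axis=1, keepdims=True))
        rn /= np.where(np.linalg.norm(rn, axis=1, keepdims=True) == 0, 1, np.linalg.norm(rn, axis=1, keepdims=True))
        cost = 1.0 - cn @ rn.T
        rows, cols = linear_sum_assignment(cost)
        ref_ids = list(refs.index)
        return {raw_labels[i]: int(ref_ids[j]) for i, j in zip(rows, cols)}
    key = centroids["nodules"] - centroids["roots"]
    tie = centroids["incipient"] - centroids["roots"]
    order = sorted(raw_labels, key=lambda l: (key[l], tie[l]))
    return {raw: i + 1 for i, raw in enumerate(order)}


def cluster_gene_profiles(
    expr: ExpressionMatrix,
    groups: StageGrouping,
    genes: Sequence[str],
    k: int = 8,
    shapes: Mapping[int, tuple[float, float, float]] = DEFAULT_PROFILE_SHAPES,
) -> ProfileAssignment:
    """Cluster genes into k temporal profiles.

    Each gene is its standardized stage-mean triple, so squared Euclidean
    distance between genes is proportional to 1 - Pearson correlation of
    their profiles.  Ward linkage on that geometry cuts into exactly k
    clusters, renumbered to the semantic profile order.  (Ward rather than
    average linkage: the raw-p differential selection feeding this step
    admits a few percent of flat false-positive genes whose random shapes
    form spurious average-linkage clusters; Ward absorbs them into the
    planted profiles.)
    """
    genes = list(genes)
    if len(genes) < k:
        raise ClusteringError(f"{len(genes)} genes cannot form {k} clusters")
    sm = stage_mean_matrix(expr, groups).loc[genes]
    z = standardize_rows(sm)
    if k == 1:
        assignments = pd.Series(1, index=z.index)
        linkage = hierarchy.linkage(z.to_numpy(), method="ward") if len(z) > 1 else np.empty((0, 4))
    else:
        linkage = hierarchy.linkage(z.to_numpy(), method="ward")
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if len(np.unique(raw)) < k:
            raise ClusteringError(f"tree cut produced fewer than {k} distinct clusters")
        assignments = pd.Series(raw, index=z.index)
    centroids = z.groupby(assignments).mean()
    mapping = _semantic_renumbering(centroids, shapes) if k > 1 else {1: 1}
    assignments = assignments.map(mapping)
    templates = z.groupby(assignments).mean().sort_index()
    return ProfileAssignment(assignments=assignments, templates=templates, linkage=linkage)


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def pca_samples(expr: ExpressionMatrix, n_components: int | None = None) -> SampleClustering:
    """PCA of the samples in gene space (genes mean-centered)."""
    if expr.values.shape[1] < 2:
        raise ClusteringError("PCA needs at least 2 samples")
    x = expr.values.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ClusteringError("constant matrix has no variance to decompose")
    n = n_components or min(x.shape)
    pca = PCA(n_components=min(n, min(x.shape)))
    coords = pca.fit_transform(x)
    coordinates = pd.DataFrame(
        coords,
        index=expr.values.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return SampleClustering(
        coordinates=coordinates, variance_fractions=pca.explained_variance_ratio_
    )


def cluster_samples(expr: ExpressionMatrix, k: int = 3) -> SampleClustering:
    """Hierarchical clustering of samples (1 - Pearson, average linkage), cut at k."""
    n = expr.values.shape[1]
    if k > n:
        raise ClusteringError(f"cannot cut {n} samples into {k} clusters")
    x = expr.values.to_numpy(dtype=float).T
    dist = np.clip(pdist(x, metric="correlation"), 0.0, None)
    linkage = hierarchy.linkage(dist, method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=expr.values.columns, name="cluster")
    return SampleClustering(
        labels=labels,
        linkage=linkage,
        newick=linkage_to_newick(linkage, list(expr.values.columns)),
    )


def wave_activation(
    expr: ExpressionMatrix,
    profiles: ProfileAssignment,
    root_baseline: pd.Series,
    threshold: float = 1.0,
    samples: Sequence[str] | None = None,
) -> WaveScore:
    """Score wave-1 (profiles 5-6) and wave-2 (profiles 7-8) activation.

    Per query sample, the score is the median over the wave's gene set of
    (log2 value - root baseline); a wave is active when its score reaches the
    threshold (default 1.0 log2 units, i.e. 2-fold).
    """
    wave_genes = {
        "wave1_score": profiles.genes_in(WAVE1_PROFILES),
        "wave2_score": profiles.genes_in(WAVE2_PROFILES),
    }
    for name, genes in wave_genes.items():
        if not genes:
            raise ClusteringError(f"no genes assigned to {name.split('_')[0]} profiles")
    cols = list(expr.values.columns) if samples is None else list(samples)
    rows = {}
    for name, genes in wave_genes.items():
        genes = [g for g in genes if g in root_baseline.index]
        if not genes:
            raise ClusteringError("root baseline does not cover the wave gene set")
        delta = expr.values.loc[genes, cols].sub(root_baseline.loc[genes], axis=0)
        rows[name] = delta.median(axis=0)
    scores = pd.DataFrame(rows)
    return WaveScore(scores=scores, threshold=threshold)


def root_baseline(expr: ExpressionMatrix, root_arrays: Sequence[str]) -> pd.Series:
    """Per-gene mean log2 ratio over the given root arrays."""
    root_arrays = [a for a in root_arrays if a in expr.values.columns]
    if not root_arrays:
        raise ClusteringError("no root arrays available for the baseline")
    return expr.values[root_arrays].mean(axis=1)
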
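"""Population-level analysis: z-scored clusterogram, tSNE embedding,
group-mean PCA + linkage, and per-feature group statistics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: the six firing statistics used for clustering / embedding
CLUSTER_FEATURES = [
    "frequency_hz",
    "frequency_mode_hz",
    "cv",
    "cv2",
    "pause_percent",
    "rhythmicity_index",
]


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Column z-scores (population SD); constant columns become all-zero."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    out = np.zeros_like(matrix, dtype=float)
    nonconst = sd > 0
    if not nonconst.all():
        logger.warning(
            "%d constant feature column(s) set to 0 in z-scoring",
            int((~nonconst).sum()),
        )
    out[:, nonconst] = (matrix[:, nonconst] - mean[nonconst]) / sd[nonconst]
    return out


@dataclass
class PopulationMatrix:
    cell_ids: list[str]
    group_labels: list[str]
    feature_matrix: np.ndarray  # cells x 6
    zscored_matrix: np.ndarray  # cells x 6


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # cells x 2
    seed: int
    perplexity: float


@dataclass
class GroupSummary:
    group_names: list[str]
    group_means: np.ndarray  # groups x 6
    pca_scores: np.ndarray | None = None  # groups x 2
    linkage_matrix: np.ndarray | None = None


def assemble_population(feature_table: pd.DataFrame) -> PopulationMatrix:
    """Build the cells x features matrix and z-score each feature column."""
    missing = set(CLUSTER_FEATURES) - set(feature_table.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    if len(feature_table) < 2:
        raise ValidationError("need >= 2 cells to assemble a population")
    matrix = feature_table[CLUSTER_FEATURES].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ValidationError("feature matrix contains missing values")
    return PopulationMatrix(
        cell_ids=[str(c) for c in feature_table["cell_id"]],
        group_labels=[str(g) for g in feature_table["group_label"]],
        feature_matrix=matrix,
        zscored_matrix=zscore_columns(matrix),
    )


@dataclass
class ClusterogramResult:
    linkage_matrix: np.ndarray
    leaf_order: list[int]
    reordered_matrix: np.ndarray
    method: str
    metric: str


def clusterogram(
    matrix: PopulationMatrix,
    linkage_method: str = "average",
    distance: str = "euclidean",
) -> ClusterogramResult:
    """Hierarchical clustering of cells on z-scored features.

    Labels play no role in the tree; they are attached downstream, after
    clustering, for display only.
    """
    n = matrix.zscored_matrix.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 cells: degenerate cluster tree")
    link = hierarchy.linkage(
        matrix.zscored_matrix, method=linkage_method, metric=distance
    )
    order = hierarchy.leaves_list(link).tolist()
    return ClusterogramResult(
        linkage_matrix=link,
        leaf_order=order,
        reordered_matrix=matrix.zscored_matrix[order],
        method=linkage_method,
        metric=distance,
    )


def tsne_pseudotimeline(
    matrix: PopulationMatrix, perplexity: float = 30.0, seed: int = 0
) -> EmbeddingResult:
    """2-D tSNE of the z-scored features with Euclidean distances."""
    n = matrix.zscored_matrix.shape[0]
    if perplexity >= n:
        raise ValidationError(
            f"perplexity ({perplexity}) must be < number of cells ({n})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        metric="euclidean",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(matrix.zscored_matrix)
    return EmbeddingResult(
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        perplexity=perplexity,
    )


def group_means(matrix: PopulationMatrix) -> GroupSummary:
    """Mean of each feature within each group, rows ordered by group name."""
    df = pd.DataFrame(matrix.feature_matrix, columns=CLUSTER_FEATURES)
    df["group"] = matrix.group_labels
    means = df.groupby("group", sort=True).mean()
    return GroupSummary(
        group_names=list(means.index), group_means=means.to_numpy()
    )


def group_linkage(
    summary: GroupSummary,
    linkage_method: str = "average",
    scale: bool = True,
) -> GroupSummary:
    """PCA (2 components) on z-scored group means, then hierarchical linkage.

    With ``scale=False`` the PCA runs on the raw (covariance-scaled)
    group-mean table instead.
    """
    n_groups = summary.group_means.shape[0]
    if n_groups < 3:
        raise ValidationError("group linkage needs >= 3 groups")
    table = (
        zscore_columns(summary.group_means) if scale else summary.group_means
    )
    scores = PCA(n_components=2).fit_transform(table)
    link = hierarchy.linkage(scores, method=linkage_method, metric="euclidean")
    return GroupSummary(
        group_names=summary.group_names,
        group_means=summary.group_means,
        pca_scores=scores,
        linkage_matrix=link,
    )


@dataclass
class GroupComparison:
    feature: str
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    excluded_groups: list[str] = field(default_factory=list)


@lru_cache(maxsize=64)
def _studentized_range_crit(alpha: float, n_groups: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, n_groups, df))


def compare_groups(
    feature_table: pd.DataFrame,
    feature_name: str,
    alpha: float = 0.05,
    include_pvalues: bool = True,
) -> GroupComparison:
    """One-way ANOVA plus all-pairs Tukey-Kramer on one feature.

    Groups with fewer than 2 cells are excluded with a warning; the
    Tukey-Kramer procedure supports unequal group sizes. Rejections are
    decided against a cached studentized-range critical value; adjusted
    p-values (an expensive numerical integral per pair) can be skipped with
    ``include_pvalues=False`` for simulation studies.
    """
    if feature_name not in feature_table.columns:
        raise ValidationError(f"unknown feature {feature_name!r}")
    grouped = feature_table.groupby("group_label")[feature_name]
    kept, excluded = {}, []
    for name, vals in grouped:
        if len(vals) >= 2:
            kept[str(name)] = vals.to_numpy(dtype=float)
        else:
            excluded.append(str(name))
    if excluded:
        warnings.warn(f"groups excluded (fewer than 2 cells): {excluded}")
    if len(kept) < 2:
        raise ValidationError("need >= 2 groups with >= 2 cells each")

    f_stat, p_val = stats.f_oneway(*kept.values())

    names = sorted(kept)
    k = len(names)
    ns = np.array([kept[g].size for g in names])
    means = np.array([kept[g].mean() for g in names])
    df_within = int(ns.sum() - k)
    mse = (
        sum(kept[g].var(ddof=1) * (kept[g].size - 1) for g in names)
        / df_within
    )
    i, j = np.triu_indices(k, k=1)
    meandiff = means[j] - means[i]
    # Tukey-Kramer standard error for unequal group sizes
    se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(meandiff) / se
    q_crit = _studentized_range_crit(alpha, k, df_within)
    reject = q > q_crit
    if include_pvalues:
        p_adj = stats.studentized_range.sf(q, k, df_within)
        p_adj = np.clip(np.nan_to_num(p_adj, nan=1.0), 0.0, 1.0)
    else:
        p_adj = np.full(q.shape, np.nan)
    tukey = pd.DataFrame(
        {
            "group1": np.array(names)[i],
            "group2": np.array(names)[j],
            "meandiff": meandiff,
            "p_adj": p_adj,
            "reject": reject,
        }
    )
    return GroupComparison(
        feature=feature_name,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
        excluded_groups=excluded,
    )


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
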
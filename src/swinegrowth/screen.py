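"""Carcass / meat-quality trait screening across body-weight groups.

Animals slaughtered over the post-inflection range are binned into 10-kg
weight groups; every trait is then tested for a weight-dependent trend with
a one-way ANOVA across groups (Tukey HSD pairwise follow-up; two groups fall
back to Student's t) and classified as up / down / unchanged by combining
the ANOVA gate at alpha with the sign of the Pearson correlation between
trait and body weight.  Companion views: trait correlation matrices,
hierarchical clustering of z-scored group means, and PCA of z-scored
animal-level traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SkPCA

from .errors import InsufficientDataError

__all__ = [
    "assign_weight_groups",
    "dressing_percentage",
    "GroupTestResult",
    "group_test",
    "TrendResult",
    "classify_trend",
    "correlation_matrix",
    "ClusterResult",
    "hierarchical_cluster",
    "PCAResult",
    "pca",
    "screen_traits",
]


def assign_weight_groups(
    bw, start_kg: float, bin_width: float = 10.0, n_groups: int = 8
) -> np.ndarray:
    """Map body weights to 1-based weight-group indices.

    Bins are half-open: group g covers [start + (g-1)*width, start + g*width).
    Weights outside the configured range get index -1 (unassigned) and a
    warning reports how many.
    """
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weights must be positive")
    idx = np.floor((bw - start_kg) / bin_width).astype(int) + 1
    out = np.where((idx >= 1) & (idx <= n_groups), idx, -1)
    n_unassigned = int(np.sum(out == -1))
    if n_unassigned:
        warnings.warn(
            f"{n_unassigned} animal(s) outside [{start_kg}, "
            f"{start_kg + n_groups * bin_width}) kg left unassigned",
            stacklevel=2,
        )
    return out


def dressing_percentage(cw, bw):
    """Dressing percentage = (carcass weight / live body weight) x 100.

    Requires 0 < cw < bw elementwise; result is in (0, 100).
    """
    cw = np.asarray(cw, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if np.any(cw <= 0) or np.any(bw <= 0):
        raise ValueError("weights must be positive")
    if np.any(cw >= bw):
        raise ValueError("carcass weight must be below live body weight")
    out = cw / bw * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupTestResult:
    """One-way ANOVA (or two-group t-test) across weight groups."""

    statistic: float
    p_value: float
    method: str  # "anova" or "t-test"
    tukey: pd.DataFrame | None
    n_groups_used: int
    excluded_groups: tuple = ()
    degenerate: bool = False  # zero within-group variance everywhere


def group_test(groups, tukey: bool = True) -> GroupTestResult:
    """Test a trait for differences across weight groups.

    ``groups`` is a mapping label -> values or a sequence of arrays.  Groups
    with fewer than 2 observations are excluded (warned); two usable groups
    fall back to Student's t-test; three or more use one-way ANOVA with an
    optional Tukey HSD pairwise table (columns group1, group2, meandiff,
    p_adj, reject).
    """
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = list(enumerate(groups))
    usable, excluded = [], []
    for label, values in items:
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            excluded.append(label)
        else:
            usable.append((label, arr))
    if excluded:
        warnings.warn(
            f"excluded group(s) with < 2 observations: {excluded}", stacklevel=2
        )
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 groups with >= 2 observations")

    arrays = [arr for _, arr in usable]
    degenerate = all(np.ptp(a) == 0 for a in arrays)
    if degenerate:
        means = [a.mean() for a in arrays]
        p = 1.0 if np.ptp(means) == 0 else 0.0
        return GroupTestResult(
            statistic=float("inf") if p == 0.0 else 0.0,
            p_value=p,
            method="anova" if len(arrays) > 2 else "t-test",
            tukey=None,
            n_groups_used=len(arrays),
            excluded_groups=tuple(excluded),
            degenerate=True,
        )

    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1])
        return GroupTestResult(
            statistic=float(t), p_value=float(p), method="t-test", tukey=None,
            n_groups_used=2, excluded_groups=tuple(excluded),
        )

    f, p = stats.f_oneway(*arrays)
    tukey_df = None
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate(
            [np.full(len(a), str(lbl)) for (lbl, _), a in zip(usable, arrays)]
        )
        res = pairwise_tukeyhsd(values, labels)
        tukey_df = pd.DataFrame(
            res.summary().data[1:],
            columns=[str(c) for c in res.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
    return GroupTestResult(
        statistic=float(f), p_value=float(p), method="anova", tukey=tukey_df,
        n_groups_used=len(arrays), excluded_groups=tuple(excluded),
    )


@dataclass(frozen=True)
class TrendResult:
    """Weight-trend classification of one trait within one breed."""

    trait: str
    breed: str
    direction: str  # "up" | "down" | "unchanged"
    anova_p: float
    bw_correlation: float
    group_means: dict = field(default_factory=dict)
    zero_variance: bool = False


def classify_trend(
    trait_values,
    bw,
    group,
    alpha: float = 0.05,
    trait: str = "",
    breed: str = "",
) -> TrendResult:
    """Classify a trait as up / down / unchanged along the weight axis.

    A trait is directional only when the across-group ANOVA rejects at
    ``alpha``; the direction is then the sign of the Pearson correlation
    between trait values and body weight.  Constant traits are returned as
    unchanged with ``zero_variance=True``.
    """
    y = np.asarray(trait_values, dtype=float)
    bw = np.asarray(bw, dtype=float)
    group = np.asarray(group)
    mask = np.isfinite(y) & np.isfinite(bw)
    y, bw, group = y[mask], bw[mask], group[mask]
    labels = [g for g in pd.unique(group) if g != -1]
    if len(labels) < 3:
        raise InsufficientDataError("need >= 3 weight groups for trend testing")
    group_means = {
        str(lbl): float(np.mean(y[group == lbl])) for lbl in sorted(labels)
    }
    if np.ptp(y) == 0:
        return TrendResult(trait, breed, "unchanged", 1.0, 0.0, group_means, True)
    res = group_test({lbl: y[group == lbl] for lbl in labels}, tukey=False)
    r = float(stats.pearsonr(y, bw)[0])
    if res.p_value <= alpha and r != 0:
        direction = "up" if r > 0 else "down"
    else:
        direction = "unchanged"
    return TrendResult(trait, breed, direction, res.p_value, r, group_means)


def correlation_matrix(
    table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Trait-by-trait correlation matrix with pairwise-complete observations.

    Constant columns produce NaN rows/columns and are reported in a warning
    rather than silently zeroed.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise InsufficientDataError("need >= 3 animals for correlations")
    constant = [c for c in numeric.columns if numeric[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) give undefined correlations: {constant}",
            stacklevel=2,
        )
    return numeric.corr(method=method, min_periods=2)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of items (rows)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: np.ndarray | None  # flat cluster ids when n_clusters given
    items: tuple


def hierarchical_cluster(
    data: pd.DataFrame,
    linkage_method: str = "average",
    metric: str = "euclidean",
    n_clusters: int | None = None,
    zscore: bool = False,
) -> ClusterResult:
    """Cluster rows of ``data`` (e.g. z-scored trait means per weight group).

    Euclidean distance + average linkage by default.  SciPy's merge order is
    deterministic for a fixed row order, which is the tie-break convention.
    """
    X = data.to_numpy(dtype=float)
    if len(X) < 2:
        raise InsufficientDataError("need >= 2 items to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in clustering input")
    if zscore:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(pdist(X, metric=metric), method=linkage_method)
    labels = (
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        if n_clusters
        else None
    )
    return ClusterResult(linkage=Z, labels=labels, items=tuple(data.index))


@dataclass(frozen=True)
class PCAResult:
    """PCA of the z-scored trait table."""

    scores: pd.DataFrame  # animals x components
    loadings: pd.DataFrame  # traits x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    imputed_columns: tuple = ()


def pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA on columns z-scored with the sample SD (ddof=1).

    Missing values are mean-imputed (reported via ``imputed_columns``).
    Component signs follow the convention that each component's largest-
    magnitude loading is positive.  With more traits than animals the rank
    is capped and a warning is emitted.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[0] < 2 or numeric.shape[1] < 2:
        raise InsufficientDataError("need >= 2 animals and >= 2 traits for PCA")
    imputed = tuple(c for c in numeric.columns if numeric[c].isna().any())
    X = numeric.fillna(numeric.mean()).to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    max_rank = min(Z.shape[0] - 1, Z.shape[1])
    if Z.shape[1] > Z.shape[0]:
        warnings.warn(
            f"more traits ({Z.shape[1]}) than animals ({Z.shape[0]}); "
            f"rank capped at {max_rank}",
            stacklevel=2,
        )
    k = max_rank if n_components is None else min(n_components, max_rank)
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Z)
    loadings = model.components_.T  # traits x components
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=numeric.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=numeric.columns, columns=comp_names),
        explained_variance=model.explained_variance_.copy(),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        imputed_columns=imputed,
    )


def screen_traits(
    table: pd.DataFrame,
    breed: str,
    start_kg: float,
    bin_width: float = 10.0,
    n_groups: int = 8,
    alpha: float = 0.05,
    bw_col: str = "bw",
    skip_cols: tuple = ("bw", "weight_group"),
) -> pd.DataFrame:
    """Run the full trend screen for one breed's trait table.

    Returns one row per trait: direction, ANOVA p, Pearson r with body
    weight.  ``table`` must carry body weight in ``bw_col``; non-numeric
    columns are ignored.
    """
    bw = table[bw_col].to_numpy(dtype=float)
    group = assign_weight_groups(bw, start_kg, bin_width, n_groups)
    rows = []
    for col in table.select_dtypes(include=[np.number]).columns:
        if col in skip_cols:
            continue
        res = classify_trend(
            table[col].to_numpy(dtype=float), bw, group, alpha=alpha,
            trait=col, breed=breed,
        )
        rows.append(
            {
                "trait": col,
                "breed": breed,
                "direction": res.direction,
                "anova_p": res.anova_p,
                "bw_correlation": res.bw_correlation,
                "zero_variance": res.zero_variance,
            }
        )
    return pd.DataFrame(rows)
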
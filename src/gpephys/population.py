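"""Population-level analysis: feature matrix, PCA, Ward clustering, statistics.

Builds the 15-feature electrophysiological matrix (rows with missing values
dropped, columns z-scored), runs correlation-matrix PCA with the
eigenvalue-greater-than-one retention rule, agglomerative Ward clustering on
squared Euclidean distances, and a normality-gated group-comparison
dispatcher (one-way ANOVA + Tukey when every group passes Shapiro-Wilk,
otherwise Kruskal-Wallis + Dunn with Bonferroni adjustment).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

#: the 15 passive and active membrane properties entering PCA/clustering
FEATURES_15 = [
    "ap_amplitude", "ap_duration", "ap_half_width", "ap_rise_time",
    "ap_fall_time", "ahp_time", "ap_rise_rate", "ap_fall_rate",
    "fahp_amplitude", "rectification_index", "threshold",
    "input_resistance", "rheobase", "max_discharge_freq", "fi_slope",
]

SHAPIRO_ALPHA = 0.05

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    """GraphPad-style stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    values: np.ndarray  # (cells x features), z-scored
    cell_ids: list
    groups: list
    feature_names: list
    dropped_ids: list = field(default_factory=list)
    excluded_features: list = field(default_factory=list)
    z_scored: bool = True

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "cell_id", self.cell_ids)
        df.insert(1, "group", self.groups)
        return df


def build_matrix(profiles, feature_list: list[str] | None = None) -> FeatureMatrix:
    """Assemble and z-score the feature matrix from per-cell profiles.

    ``profiles`` is a list of IntrinsicProfile objects or a DataFrame with
    the profile columns.  Rows with any missing feature are dropped (their
    ids recorded); constant columns cannot be z-scored and are excluded with
    a warning.  Fewer than 2 complete rows is an error.
    """
    feature_list = list(feature_list or FEATURES_15)
    if isinstance(profiles, pd.DataFrame):
        df = profiles.copy()
    else:
        df = pd.DataFrame([p.to_row() for p in profiles])
    missing_cols = [c for c in feature_list if c not in df.columns]
    if missing_cols:
        raise ValueError(f"profiles lack features {missing_cols}")
    complete = df[feature_list].notna().all(axis=1)
    dropped = df.loc[~complete, "cell_id"].astype(str).tolist()
    kept = df.loc[complete].reset_index(drop=True)
    if len(kept) < 2:
        raise ValueError(
            f"only {len(kept)} complete rows; at least 2 required "
            f"(dropped: {dropped})"
        )
    excluded = []
    usable = []
    for c in feature_list:
        col = kept[c].to_numpy(dtype=float)
        if np.std(col, ddof=1) == 0:
            excluded.append(c)
            warnings.warn(f"feature {c!r} is constant and was excluded from z-scoring",
                          stacklevel=2)
        else:
            usable.append(c)
    X = kept[usable].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return FeatureMatrix(
        values=Z,
        cell_ids=kept["cell_id"].astype(str).tolist(),
        groups=kept["group"].astype(str).tolist() if "group" in kept else [""] * len(kept),
        feature_names=usable,
        dropped_ids=dropped,
        excluded_features=excluded,
    )


# ---------------------------------------------------------------------------
# PCA (correlation matrix)
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending; sum = n_features
    explained: np.ndarray  # fractions, sum = 1
    loadings: np.ndarray  # features x components, orthonormal columns
    scores: np.ndarray  # cells x components
    n_retained: int  # eigenvalue > 1 rule
    elbow: int  # advisory: largest drop in consecutive eigenvalues
    feature_names: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def pca(matrix: FeatureMatrix) -> PcaResult:
    """Eigendecomposition of the correlation matrix of a z-scored matrix.

    Components are retained while their eigenvalue exceeds 1 (the operative
    rule); the scree-plot elbow (largest consecutive-eigenvalue drop) is
    reported as a diagnostic.  Numerically negative eigenvalues of
    rank-deficient data are zeroed and flagged.
    """
    Z = matrix.values
    n = Z.shape[0]
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    flags = []
    tiny = np.abs(evals) < 1e-10
    if np.any(evals < -1e-10):
        flags.append("negative_eigenvalues_zeroed")
    evals = np.where(tiny | (evals < 0), 0.0, evals)
    if np.any(tiny):
        flags.append("rank_deficient")
    explained = evals / evals.sum()
    scores = Z @ evecs
    drops = -np.diff(evals)
    elbow = int(np.argmax(drops)) + 1 if drops.size else 1
    return PcaResult(
        eigenvalues=evals, explained=explained, loadings=evecs,
        scores=scores, n_retained=int(np.sum(evals > 1.0)), elbow=elbow,
        feature_names=list(matrix.feature_names), flags=flags,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering (Ward / squared Euclidean)
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge heights monotone)
    labels: np.ndarray  # flat labels at k clusters (1..k)
    k: int
    purity: dict = field(default_factory=dict)  # true group -> majority fraction

    def purity_for(self, group: str) -> float:
        return self.purity.get(group, float("nan"))


def hier_cluster(matrix: FeatureMatrix, k: int, use_scores: bool = False,
                 n_components: int | None = None) -> ClusterResult:
    """Ward's-method agglomerative clustering on squared Euclidean distances.

    Operates on the z-scored features by default; ``use_scores`` switches to
    retained principal-component scores.  ``purity`` gives, per true group,
    the fraction of its cells assigned to that group's majority cluster.
    """
    X = matrix.values
    if use_scores:
        res = pca(matrix)
        nc = n_components or max(1, res.n_retained)
        X = res.scores[:, :nc]
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of rows ({n})")
    link = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    purity = {}
    groups = np.asarray(matrix.groups)
    for g in np.unique(groups):
        members = labels[groups == g]
        counts = np.bincount(members)
        purity[str(g)] = float(counts.max() / members.size)
    return ClusterResult(linkage=link, labels=labels, k=k, purity=purity)


# ---------------------------------------------------------------------------
# Normality-gated group comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    branch: str  # "anova_tukey" or "kruskal_dunn"
    omnibus_p: float
    omnibus_stat: float
    pairwise: pd.DataFrame  # group_a, group_b, p, stars
    normality_p: dict
    flags: list = field(default_factory=list)

    def stars(self, a: str, b: str) -> str:
        for _, row in self.pairwise.iterrows():
            if {row.group_a, row.group_b} == {a, b}:
                return row.stars
        raise KeyError(f"no pair ({a}, {b})")


def _dunn_posthoc(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test, Bonferroni adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = values_by_group[g].size
        mean_ranks[g] = float(np.mean(ranks[start:start + n]))
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_corr
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)  # Bonferroni
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p": p,
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def compare_groups(values_by_group: dict[str, np.ndarray]) -> ComparisonReport:
    """One-way comparison of a feature across groups, normality gated.

    Each group is tested with Shapiro-Wilk (alpha 0.05); if every group is
    normal the parametric branch runs (one-way ANOVA, Tukey post hoc),
    otherwise the non-parametric branch (Kruskal-Wallis, Dunn post hoc with
    Bonferroni adjustment).  A degenerate (constant) group forces the
    non-parametric branch.  Requires >= 2 groups of >= 3 values.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    flags = []
    normality_p = {}
    all_normal = True
    for g, v in groups.items():
        if np.ptp(v) == 0:
            normality_p[g] = 0.0
            all_normal = False
            flags.append(f"degenerate_group_{g}")
            continue
        p = float(stats.shapiro(v).pvalue)
        normality_p[g] = p
        if p < SHAPIRO_ALPHA:
            all_normal = False
    names = list(groups)
    samples = [groups[g] for g in names]
    if all_normal:
        stat, p = stats.f_oneway(*samples)
        res = stats.tukey_hsd(*samples)
        rows = []
        for i, j in itertools.combinations(range(len(names)), 2):
            pij = float(res.pvalue[i, j])
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(res.statistic[i, j]), "p": pij,
                         "stars": significance_stars(pij)})
        pairwise = pd.DataFrame(rows)
        branch = "anova_tukey"
    else:
        stat, p = stats.kruskal(*samples)
        pairwise = _dunn_posthoc(groups)
        branch = "kruskal_dunn"
    return ComparisonReport(branch=branch, omnibus_p=float(p),
                            omnibus_stat=float(stat), pairwise=pairwise,
                            normality_p=normality_p, flags=flags)
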
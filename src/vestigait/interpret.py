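"""Model interpretation: correlated-feature clusters, permutation importance,
and Welch t-tests with effect sizes.

To respect the heavy multi-collinearity among kinematic features, features
are grouped by Ward hierarchical clustering on the distance 1 - |Pearson r|
and importance is measured per *cluster*: all features of a cluster are
shuffled with one shared row permutation (preserving the intra-cluster
structure) and the drop in test AUROC is recorded over permutation repeats.
Directionality of the top cluster's features is examined with independent
Welch t-tests (controls minus vestibular), Welch-Satterthwaite degrees of
freedom and the effect size r = sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)


class InfiniteTError(ValueError):
    """Zero variance in both groups with distinct means."""


@dataclass
class FeatureClusterSet:
    """Ward linkage over features plus a flat cut at ``n_clusters``."""

    linkage: np.ndarray
    assignment: np.ndarray  # cluster id (1..n_clusters) per feature
    names: list[str]
    n_clusters: int

    def members(self, cluster_id: int) -> list[str]:
        return [n for n, c in zip(self.names, self.assignment) if c == cluster_id]

    def member_indices(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.tolist()))


def correlation_clusters(X, n_clusters: int = 3) -> FeatureClusterSet:
    """Cluster features by Ward linkage on the 1 - |Pearson r| distance.

    ``X`` is a samples x features matrix or DataFrame. Constant features
    have undefined correlations; these are set to 0 (distance 1) with a
    warning.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(arr.shape[1])]
    n_samples, n_features = arr.shape
    if n_features < 2 or n_samples < 3:
        raise ValueError("need at least 2 features and 3 rows")
    if n_clusters < 1 or n_clusters > n_features:
        raise ValueError("n_clusters must be in [1, n_features]")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    if np.any(~np.isfinite(corr)):
        constant = arr.std(axis=0) == 0
        log.warning("constant feature(s) %s: correlations set to 0",
                    [names[i] for i in np.flatnonzero(constant)])
        corr = np.where(np.isfinite(corr), corr, 0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    assignment = fcluster(z, t=n_clusters, criterion="maxclust")
    return FeatureClusterSet(linkage=z, assignment=assignment, names=names,
                             n_clusters=n_clusters)


@dataclass
class ClusterImportanceReport:
    """Mean AUROC drop per cluster with a percentile CI over repeats."""

    baseline_auroc: float
    drops: dict[int, np.ndarray]  # cluster id -> per-repeat drops
    mean_drop: dict[int, float]
    ci: dict[int, tuple[float, float]]
    ranking: list[int]  # cluster ids, largest mean drop first

    def to_frame(self, clusters: FeatureClusterSet | None = None) -> pd.DataFrame:
        rows = []
        for rank, cid in enumerate(self.ranking, start=1):
            row = {"cluster": cid, "rank": rank,
                   "mean_auroc_drop": self.mean_drop[cid],
                   "ci_low": self.ci[cid][0], "ci_high": self.ci[cid][1]}
            if clusters is not None:
                row["n_features"] = len(clusters.members(cid))
            rows.append(row)
        return pd.DataFrame(rows)


def cluster_permutation_importance(model, X_test: np.ndarray, y: np.ndarray,
                                   clusters: FeatureClusterSet,
                                   n_perm: int = 100, seed: int = 0,
                                   permutations=None) -> ClusterImportanceReport:
    """AUROC drop when each feature cluster is shuffled on the test matrix.

    All features of a cluster share one row permutation per repeat, so the
    within-cluster correlation structure is preserved while the cluster's
    relation to the labels (and to other clusters) is broken. Negative
    drops are reported as-is — they are noise, not clipped. An explicit
    ``permutations`` sequence overrides the random draws (useful for
    forcing the identity permutation, whose drop is exactly 0).
    """
    X_test = np.asarray(X_test, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    baseline = float(roc_auc_score(y, model.predict_proba(X_test)[:, 1]))
    rng = np.random.default_rng(seed)
    n = X_test.shape[0]
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_perm)]
    drops: dict[int, np.ndarray] = {}
    for cid in clusters.cluster_ids:
        cols = clusters.member_indices(cid)
        cluster_drops = []
        for perm in permutations:
            X_perm = X_test.copy()
            X_perm[:, cols] = X_test[np.asarray(perm)][:, cols]
            auc = roc_auc_score(y, model.predict_proba(X_perm)[:, 1])
            cluster_drops.append(baseline - auc)
        drops[cid] = np.asarray(cluster_drops)
    mean_drop = {cid: float(d.mean()) for cid, d in drops.items()}
    ci = {cid: (float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975)))
          for cid, d in drops.items()}
    ranking = sorted(mean_drop, key=lambda cid: -mean_drop[cid])
    return ClusterImportanceReport(baseline_auroc=baseline, drops=drops,
                                   mean_drop=mean_drop, ci=ci, ranking=ranking)


@dataclass
class WelchResult:
    """Two-sample Welch t-test summary; group A is listed first.

    By convention group A holds the controls, so the sign of t follows
    controls minus vestibular.
    """

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    r: float  # effect size, sqrt(t^2 / (t^2 + df))


def effect_size_r(t: float, df: float) -> float:
    """Effect size r = sqrt(t^2 / (t^2 + df)), in [0, 1]."""
    return float(np.sqrt(t * t / (t * t + df)))


def welch_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int) -> WelchResult:
    """Welch t-test from group summary statistics (M, SD, n).

    t = (M_A - M_B) / sqrt(SD_A^2/n_A + SD_B^2/n_B) with Welch-Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 samples per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            df = float(n_a + n_b - 2)
            return WelchResult(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                               t=0.0, df=df, p=1.0, r=0.0)
        raise InfiniteTError("zero variance in both groups with distinct means")
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                       t=float(t), df=float(df), p=p, r=effect_size_r(t, df))


def welch_t(samples_a, samples_b) -> WelchResult:
    """Welch t-test from raw samples (group A = controls first)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    return welch_t_from_summary(float(a.mean()), float(a.std(ddof=1)), a.size,
                                float(b.mean()), float(b.std(ddof=1)), b.size)


def welch_table(X: pd.DataFrame, y: np.ndarray, feature_names=None) -> pd.DataFrame:
    """Per-feature Welch results, controls (label 0) minus vestibular (1)."""
    names = list(feature_names) if feature_names is not None else list(X.columns)
    y = np.asarray(y)
    rows = []
    for name in names:
        res = welch_t(X.loc[y == 0, name], X.loc[y == 1, name])
        rows.append({
            "feature": name, "control_mean": res.mean_a, "control_sd": res.sd_a,
            "vestibular_mean": res.mean_b, "vestibular_sd": res.sd_b,
            "t": res.t, "df": res.df, "p": res.p, "r": res.r})
    return pd.DataFrame(rows)
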
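"""PCA-guided feature selection and fuzzy c-means severity grading.

Subjects are graded into ordered fat-infiltration severity groups from
their histogram features.  Features (mean intensity, mode intensity,
linewidth) are z-scored; PCA ranks them by summed absolute loading over the
components needed to explain 95 % of the variance and the top two are kept;
fuzzy c-means (FCM) then clusters subjects, with the cluster count chosen as
the largest candidate in {3, 4, 5} whose hard clusters are linearly
separable (separable solutions with more clusters also minimize the FCM
objective).  Clusters are named normal / mild / moderate / severe in
ascending order of their centroid mean-intensity coordinate.

FCM minimizes  J = sum_i sum_j u_ij^m ||x_i - v_j||^2  subject to row-
stochastic memberships, by alternating the closed-form updates

    v_j = sum_i u_ij^m x_i / sum_i u_ij^m
    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA

from .phantom import SEVERITY_CLASSES

__all__ = [
    "FeatureTable",
    "PCAFeatureSelector",
    "FuzzyCMeans",
    "SeverityLabels",
    "select_features",
    "fcm_cluster",
    "assess_separability",
    "choose_cluster_count",
    "assign_severity",
]

MFI_FEATURES = ("mean_intensity", "mode_intensity", "fwhm")


@dataclass
class FeatureTable:
    """Subject ids with raw and z-scored MFI feature matrices."""

    subject_ids: list
    features: pd.DataFrame
    zscored: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, columns=MFI_FEATURES) -> "FeatureTable":
        feats = df.loc[:, list(columns)].astype(float)
        if feats.isna().any().any():
            raise ValueError("missing values in feature columns")
        sds = feats.std(ddof=0)
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"constant feature column(s): {bad}")
        z = (feats - feats.mean()) / sds
        ids = list(df["subject_id"]) if "subject_id" in df else list(df.index)
        return cls(subject_ids=ids, features=feats, zscored=z)


class PCAFeatureSelector(BaseEstimator, TransformerMixin):
    """Rank features by PCA loading mass and keep the top ``n_keep``.

    Fitting z-scores the input, runs a full-rank PCA, keeps the smallest
    number of components whose cumulative explained-variance ratio reaches
    ``variance_threshold``, and scores each feature by the sum of absolute
    loadings over those components.  Loadings are sign-fixed (the
    largest-magnitude entry of each component is made positive) so the fit
    is deterministic.
    """

    def __init__(self, variance_threshold: float = 0.95, n_keep: int = 2):
        self.variance_threshold = variance_threshold
        self.n_keep = n_keep

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 rows")
        sds = X.std(axis=0)
        if np.any(sds == 0):
            raise ValueError("constant feature column")
        Z = (X - X.mean(axis=0)) / sds
        pca = PCA(svd_solver="full").fit(Z)
        loadings = pca.components_.T.copy()  # (n_features, n_components)
        for j in range(loadings.shape[1]):
            i = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[i, j] < 0:
                loadings[:, j] *= -1
        ratios = pca.explained_variance_ratio_
        k = int(np.searchsorted(np.cumsum(ratios), self.variance_threshold - 1e-12) + 1)
        importances = np.abs(loadings[:, :k]).sum(axis=1)
        order = np.argsort(-importances, kind="stable")
        self.loadings_ = loadings
        self.explained_variance_ratio_ = ratios
        self.k_ = k
        self.importances_ = importances
        self.ranking_ = order
        self.top_indices_ = order[: self.n_keep]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.top_indices_]


def select_features(table: FeatureTable) -> PCAFeatureSelector:
    """PCA feature selection on a z-scored feature table."""
    sel = PCAFeatureSelector().fit(table.features.to_numpy())
    sel.feature_names_ = list(table.features.columns)
    sel.top_features_ = [sel.feature_names_[i] for i in sel.top_indices_]
    return sel


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clustering with seeded multi-restart.

    Parameters follow the common defaults: fuzzifier ``m=2``, convergence on
    ``max |dU| < tol``, best of ``n_init`` random membership initializations
    by the final objective.

    Attributes (after fit): ``cluster_centers_``, ``membership_`` (n x c,
    row-stochastic), ``labels_`` (argmax membership), ``objective_``,
    ``objective_history_`` (non-increasing), ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 4, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 1000, n_init: int = 10, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _memberships(self, D2: np.ndarray) -> np.ndarray:
        # u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)), squared-distance form
        exponent = 1.0 / (self.m - 1.0)
        U = np.zeros_like(D2)
        zero_rows = (D2 <= 1e-300).any(axis=1)
        if zero_rows.any():  # coincident point/centroid: all mass there
            hits = D2[zero_rows] <= 1e-300
            U[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
        ok = ~zero_rows
        if ok.any():
            inv = D2[ok] ** -exponent
            U[ok] = inv / inv.sum(axis=1, keepdims=True)
        return U

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n = X.shape[0]
        U = rng.random((n, self.n_clusters))
        U /= U.sum(axis=1, keepdims=True)
        history = []
        for it in range(1, self.max_iter + 1):
            Um = U**self.m
            V = (Um.T @ X) / Um.sum(axis=0)[:, None]
            D2 = cdist(X, V, "sqeuclidean")
            U_new = self._memberships(D2)
            history.append(float((U_new**self.m * D2).sum()))
            if np.max(np.abs(U_new - U)) < self.tol:
                U = U_new
                break
            U = U_new
        return U, V, history, it

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        if not (n > self.n_clusters >= 2):
            raise ValueError("need n > n_clusters >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            U, V, history, iters = self._single_run(X, rng)
            if best is None or history[-1] < best[2][-1]:
                best = (U, V, history, iters)
        U, V, history, iters = best
        self.membership_ = U
        self.cluster_centers_ = V
        self.objective_history_ = np.asarray(history)
        self.objective_ = float(history[-1])
        self.n_iter_ = iters
        self.labels_ = U.argmax(axis=1)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        D2 = cdist(X, self.cluster_centers_, "sqeuclidean")
        return self._memberships(D2).argmax(axis=1)


def fcm_cluster(data, c: int, m: float = 2.0, tol: float = 1e-5,
                max_iter: int = 1000, n_init: int = 10, seed=None) -> FuzzyCMeans:
    """Functional wrapper: fitted :class:`FuzzyCMeans` on ``data``."""
    return FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                       n_init=n_init, random_state=seed).fit(data)


def _pair_separable(A: np.ndarray, B: np.ndarray) -> bool:
    """True iff a strictly separating hyperplane exists (LP feasibility)."""
    dim = A.shape[1]
    # variables: w (dim), b;  constraints: w.a + b >= 1, w.b + b <= -1
    A_ub = np.vstack(
        [np.hstack([-A, -np.ones((A.shape[0], 1))]),
         np.hstack([B, np.ones((B.shape[0], 1))])]
    )
    b_ub = -np.ones(A.shape[0] + B.shape[0])
    res = linprog(
        c=np.zeros(dim + 1), A_ub=A_ub, b_ub=b_ub,
        bounds=[(None, None)] * (dim + 1), method="highs",
    )
    return res.status == 0


def assess_separability(data, labels):
    """Pairwise linear-separability of hard clusters.

    Returns ``(pairwise, overall)``: a boolean DataFrame indexed by cluster
    label (diagonal True) and the all-pairs flag.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    table = pd.DataFrame(True, index=uniq, columns=uniq, dtype=bool)
    for i, gi in enumerate(uniq):
        for gj in uniq[i + 1:]:
            ok = _pair_separable(data[labels == gi], data[labels == gj])
            table.loc[gi, gj] = table.loc[gj, gi] = ok
    return table, bool(table.to_numpy().all())


def _fuzzy_solution_separable(data: np.ndarray, U: np.ndarray,
                              ambiguity: float = 0.5) -> bool:
    """Linear separability of a fuzzy solution, ambiguity-aware.

    A point belongs to the hull of every cluster whose membership is within
    ``ambiguity`` of its top membership (``u_ij >= ambiguity * max_j u_ij``).
    Hard nearest-centroid labels alone are Voronoi cells and therefore
    always separable; sharing ambiguously-assigned points between hulls is
    what lets an over-split solution (two centroids inside one tight group,
    memberships ~ 0.5/0.5) fail the test.
    """
    n, c = U.shape
    members = U >= ambiguity * U.max(axis=1, keepdims=True)
    for i in range(c):
        for j in range(i + 1, c):
            A, B = data[members[:, i]], data[members[:, j]]
            if A.size == 0 or B.size == 0:
                continue
            if not _pair_separable(A, B):
                return False
    return True


def choose_cluster_count(data, candidates=(3, 4, 5), m: float = 2.0,
                         seed=None, **fcm_kwargs):
    """Pick the largest candidate cluster count with linearly separable clusters.

    Among linearly separable solutions the one with more clusters also has
    the lower FCM objective, so this implements "separability plus minimal
    objective".  Separability of a candidate solution is assessed on its
    fuzzy memberships (see :func:`_fuzzy_solution_separable`): points whose
    membership is ambiguous between clusters join both hulls, so splitting
    a genuine group yields overlapping hulls and rejects the candidate.
    If no candidate is separable the smallest candidate is returned with a
    warning.

    Returns ``(c, diagnostics)`` with one diagnostics row per candidate
    (``c``, ``objective``, ``separable``).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    rows, separable_cs = [], []
    for c in sorted(candidates):
        fcm = fcm_cluster(data, c=c, m=m, seed=seed, **fcm_kwargs)
        sep = _fuzzy_solution_separable(data, fcm.membership_)
        rows.append({"c": c, "objective": fcm.objective_, "separable": sep})
        if sep:
            separable_cs.append(c)
    diagnostics = pd.DataFrame(rows)
    if separable_cs:
        return max(separable_cs), diagnostics
    warnings.warn("no candidate cluster count is linearly separable; "
                  "falling back to the smallest candidate", stacklevel=2)
    return min(sorted(candidates)), diagnostics


@dataclass
class SeverityLabels:
    """Ordered severity assignment plus per-group average profiles."""

    labels: list  # per-subject class name
    class_names: list  # ascending severity order
    cluster_order: np.ndarray  # cluster index -> ascending-severity rank
    group_profiles: dict  # class name -> HistogramProfile | None


def _average_profiles(profiles):
    from .histogram import HistogramProfile

    lo = min(p.x[0] for p in profiles)
    hi = max(p.x[-1] for p in profiles)
    width = min(p.bin_width for p in profiles)
    grid = np.arange(lo, hi + width / 2, width)
    y = np.mean([np.interp(grid, p.x, p.y, left=0.0, right=0.0) for p in profiles],
                axis=0)
    y *= 100.0 / np.trapezoid(y, grid)
    return HistogramProfile(x=grid, y=y, bin_width=width,
                            provenance={"population_average": len(profiles)})


def assign_severity(fcm: FuzzyCMeans, mean_col: int = 0, mode_col: int | None = 1,
                    profiles=None) -> SeverityLabels:
    """Name clusters by ascending centroid mean-intensity coordinate.

    ``mean_col``/``mode_col`` index the mean- and mode-intensity coordinates
    of the fitted feature space (mode breaks centroid ties).  With four
    clusters the names are normal/mild/moderate/severe; otherwise
    ``level_1..level_c``.  ``profiles``, if given, is a per-subject sequence
    of :class:`~calfmfi.histogram.HistogramProfile` used to compute the
    population-average profile of each group.
    """
    V = fcm.cluster_centers_
    c = V.shape[0]
    key = V[:, mean_col]
    if mode_col is not None and V.shape[1] > mode_col:
        order = np.lexsort((V[:, mode_col], key))
    else:
        order = np.argsort(key, kind="stable")
    rank_of_cluster = np.empty(c, dtype=int)
    rank_of_cluster[order] = np.arange(c)
    names = (list(SEVERITY_CLASSES) if c == 4
             else [f"level_{i + 1}" for i in range(c)])
    labels = [names[rank_of_cluster[j]] for j in fcm.labels_]

    group_profiles: dict = {}
    if profiles is not None:
        for rank, name in enumerate(names):
            members = [p for p, lab in zip(profiles, labels) if lab == name]
            if members:
                group_profiles[name] = _average_profiles(members)
            else:
                warnings.warn(f"severity group {name!r} is empty", stacklevel=2)
                group_profiles[name] = None
    return SeverityLabels(labels=labels, class_names=names,
                          cluster_order=rank_of_cluster,
                          group_profiles=group_profiles)
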
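"""Lost-track reject strategies.

Three ways to decide, from the filter's own outputs, that a track has left
its accuracy tolerance σ = (d, a):

* **Chow threshold** — reject when the maximum image log-likelihood falls
  below a per-σ threshold τ, optimized over a fixed candidate grid.
* **Per-σ binary classification** — a linear max-margin model or random
  forest on the 11-D window features, with SMOTE rebalancing of the
  training split; each scorer exposes a continuous score whose decision
  threshold φ can be shifted, letting one classifier *cover* neighbouring
  tolerances.  A minimum set of classifiers whose coverage ranges span all
  20 σ forms the sparse ensemble.
* **Regression** — predict the window-maximum (δ, α) directly and compare
  against any σ, so a single model serves every tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVC

from .datasets import ThresholdPair

__all__ = [
    "ChowModel",
    "ClassifierModel",
    "SparseEnsemble",
    "RegressorModel",
    "UncoverableError",
    "smote_resample",
    "fit_chow_threshold",
    "fit_sigma_classifier",
    "classifier_range",
    "build_sparse_ensemble",
    "fit_regressor",
    "regression_decision",
]

TAU_GRID = np.linspace(-200.0, 200.0, 401)  # candidate Chow thresholds (step 1)


class UncoverableError(ValueError):
    """No candidate classifier covers some tolerance pairs at the goals."""

    def __init__(self, orphans: Sequence[int]):
        self.orphans = list(orphans)
        super().__init__(f"no candidate covers sigma indices {self.orphans}")


# ---------------------------------------------------------------------------
# SMOTE

def smote_resample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                   rng: Optional[np.random.Generator] = None) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: balance a binary training set.

    New minority samples are linear interpolations between a minority sample
    and one of its k nearest minority neighbours, drawn uniformly.  Applied
    to training partitions only — never to evaluation data.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() == counts.max():
        return X, y
    minority = classes[np.argmin(counts)]
    Xm = X[y == minority]
    n_new = int(counts.max() - counts.min())
    k = min(k_neighbors, len(Xm) - 1)
    if k < 1:
        # a single minority sample: replicate it
        synth = np.repeat(Xm, n_new, axis=0)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        base = rng.integers(0, len(Xm), n_new)
        pick = idx[base, rng.integers(1, k + 1, n_new)]
        gap = rng.random((n_new, 1))
        synth = Xm[base] + gap * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Chow threshold baseline

@dataclass(frozen=True)
class ChowModel:
    """Reject rule ``ll_max < tau``; one threshold per tolerance pair."""

    tau: float
    sigma_index: Optional[int] = None

    def predict(self, ll_max: np.ndarray) -> np.ndarray:
        return (np.asarray(ll_max) < self.tau).astype(int)


def _precision_recall_counts(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    p = tp / (tp + fp) if tp + fp else np.nan
    r = tp / (tp + fn) if tp + fn else np.nan
    return p, r


def fit_chow_threshold(ll_max_values: np.ndarray, labels_sigma: np.ndarray,
                       sigma_index: Optional[int] = None) -> ChowModel:
    """Pick the τ on the candidate grid maximizing training F1 of ``ll < τ``.

    Ties resolve to the smallest τ.  Raises on single-class training labels.
    """
    ll = np.asarray(ll_max_values, dtype=float)
    y = np.asarray(labels_sigma).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("Chow threshold fitting needs both classes in training data")
    # vectorized F1 over the whole grid
    pred = ll[None, :] < TAU_GRID[:, None]            # (401, n)
    tp = (pred & (y == 1)).sum(axis=1).astype(float)
    fp = (pred & (y == 0)).sum(axis=1).astype(float)
    fn = ((~pred) & (y == 1)).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = 2 * tp / (2 * tp + fp + fn)
    f1 = np.nan_to_num(f1, nan=-1.0)
    best = int(np.argmax(f1))  # first maximum = smallest tau
    return ChowModel(tau=float(TAU_GRID[best]), sigma_index=sigma_index)


# ---------------------------------------------------------------------------
# Per-sigma classification

@dataclass
class ClassifierModel:
    """A fitted per-σ scorer with a shiftable decision threshold φ.

    ``score(X)`` is the signed margin for the linear model and the fraction
    of trees voting "lost" for the forest; the prediction is 1 iff
    ``score >= phi``.
    """

    kind: str
    estimator: object
    sigma_index: int
    phi: float  # native boundary: 0.0 (margin) or 0.5 (vote fraction)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "linear":
            return self.estimator.decision_function(X)
        votes = np.stack([t.predict(X) for t in self.estimator.estimators_])
        return votes.mean(axis=0)

    def predict(self, X: np.ndarray, phi: Optional[float] = None) -> np.ndarray:
        phi = self.phi if phi is None else phi
        return (self.score(X) >= phi).astype(int)


def fit_sigma_classifier(features: np.ndarray, labels_sigma: np.ndarray, kind: str = "forest",
                         smote: bool = True, seed: int = 0,
                         sigma_index: int = 0) -> ClassifierModel:
    """Fit one lost-track classifier for a single tolerance pair.

    ``kind`` is ``"linear"`` (max-margin linear model on standardized
    features) or ``"forest"`` (100 trees).  SMOTE balances the training data
    first when requested.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels_sigma).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("classifier training needs both classes")
    if smote:
        X, y = smote_resample(X, y, rng=np.random.default_rng(seed))
    if kind == "linear":
        est = make_pipeline(StandardScaler(), LinearSVC(dual=False, random_state=seed))
        phi = 0.0
    elif kind == "forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        phi = 0.5
    else:
        raise ValueError(f"unknown classifier kind: {kind}")
    est.fit(X, y)
    return ClassifierModel(kind=kind, estimator=est, sigma_index=sigma_index, phi=phi)


def _sweep_operating_points(scores: np.ndarray, y: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision/recall of ``score >= phi`` at every distinct cutpoint.

    Candidate φ are the sorted unique scores plus +inf (predict nothing).
    Returns (phis, precision, recall); undefined precision is NaN.
    """
    phis = np.concatenate([np.unique(scores), [np.inf]])
    pred = scores[None, :] >= phis[:, None]
    tp = (pred & (y == 1)).sum(axis=1).astype(float)
    fp = (pred & (y == 0)).sum(axis=1).astype(float)
    fn = ((~pred) & (y == 1)).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        rec = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
    return phis, prec, rec


def classifier_range(model: ClassifierModel, features: np.ndarray,
                     labels_by_sigma: np.ndarray, sigmas: Sequence[ThresholdPair],
                     goal_p: float, goal_r: float) -> dict[int, tuple[float, float, float]]:
    """Which tolerances this classifier can serve by shifting its threshold.

    For every σᵢ the decision threshold φ is swept over the training scores;
    σᵢ joins the range iff some φ reaches precision ≥ goal_p and recall ≥
    goal_r against σᵢ's labels.  Returns ``{sigma index: (phi, p, r)}`` with
    the φ maximizing precision+recall.
    """
    if not (0 < goal_p <= 1 and 0 < goal_r <= 1):
        raise ValueError("goals must lie in (0, 1]")
    scores = model.score(np.asarray(features, dtype=float))
    out: dict[int, tuple[float, float, float]] = {}
    for col, sig in enumerate(sigmas):
        y = np.asarray(labels_by_sigma)[:, col].astype(int)
        if y.sum() == 0:  # no lost windows: recall undefined, cannot certify
            continue
        phis, prec, rec = _sweep_operating_points(scores, y)
        ok = (prec >= goal_p) & (rec >= goal_r)
        if not np.any(ok):
            continue
        combined = np.where(ok, prec + rec, -np.inf)
        best = int(np.argmax(combined))
        out[sig.index] = (float(phis[best]), float(prec[best]), float(rec[best]))
    return out


@dataclass
class SparseEnsemble:
    """A minimum set of classifiers jointly covering all tolerance pairs.

    ``assignment`` maps each σ index to (member position, φ, training
    precision, training recall); predictions for a σ depend only on its
    assigned member and φ.
    """

    members: list[ClassifierModel]
    assignment: dict[int, tuple[int, float, float, float]]

    @property
    def size(self) -> int:
        return len(self.members)

    def predict(self, X: np.ndarray, sigma_index: int) -> np.ndarray:
        m_idx, phi, _, _ = self.assignment[sigma_index]
        return self.members[m_idx].predict(X, phi=phi)


def _min_cover(range_sets: list[set[int]], universe: set[int]) -> Optional[list[int]]:
    """Exhaustive minimum set cover by increasing cardinality."""
    n = len(range_sets)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            if set().union(*(range_sets[i] for i in combo)) >= universe:
                return list(combo)
    return None


def _greedy_cover(range_sets: list[set[int]], universe: set[int]) -> Optional[list[int]]:
    uncovered = set(universe)
    chosen: list[int] = []
    while uncovered:
        gains = [len(rs & uncovered) for rs in range_sets]
        best = int(np.argmax(gains))
        if gains[best] == 0:
            return None
        chosen.append(best)
        uncovered -= range_sets[best]
    return chosen


def build_sparse_ensemble(candidates: Sequence[ClassifierModel], features: np.ndarray,
                          labels_by_sigma: np.ndarray, sigmas: Sequence[ThresholdPair],
                          goal_p: float, goal_r: float,
                          ranges: Optional[list[dict]] = None) -> SparseEnsemble:
    """Select the fewest classifiers whose ranges cover every tolerance pair.

    Exact search over subsets (by increasing cardinality) when there are at
    most 20 candidates, greedy otherwise.  A σ covered by several selected
    members is assigned to the one with the highest training precision +
    recall.  Raises :class:`UncoverableError` listing any σ no candidate can
    serve.
    """
    if ranges is None:
        ranges = [classifier_range(m, features, labels_by_sigma, sigmas, goal_p, goal_r)
                  for m in candidates]
    universe = {s.index for s in sigmas}
    range_sets = [set(r.keys()) for r in ranges]
    covered = set().union(*range_sets) if range_sets else set()
    orphans = sorted(universe - covered)
    if orphans:
        raise UncoverableError(orphans)
    if len(candidates) <= 20:
        chosen = _min_cover(range_sets, universe)
    else:
        chosen = _greedy_cover(range_sets, universe)
    assert chosen is not None
    # tie-break equal-cardinality covers by total precision+recall of assignment
    members = [candidates[i] for i in chosen]
    assignment: dict[int, tuple[int, float, float, float]] = {}
    for s in sigmas:
        best_pos, best_val = None, -np.inf
        for pos, i in enumerate(chosen):
            if s.index in ranges[i]:
                phi, p, r = ranges[i][s.index]
                if p + r > best_val:
                    best_pos, best_val = pos, p + r
                    assignment[s.index] = (pos, phi, p, r)
    return SparseEnsemble(members=members, assignment=assignment)


# ---------------------------------------------------------------------------
# Regression

@dataclass
class RegressorModel:
    """Two fitted predictors for the window-maximum (δ, α) errors.

    A single regressor pair serves every tolerance: the reject decision for
    σ = (d, a) compares the clamped predictions against the tolerances.
    """

    kind: str
    est_d: object
    est_a: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = np.clip(self.est_d.predict(X), 0.0, None)
        a = np.clip(self.est_a.predict(X), 0.0, None)
        return np.stack([d, a], axis=1)


_REGRESSORS = {
    "linear": lambda seed: LinearRegression(),
    "kernel": lambda seed: make_pipeline(StandardScaler(), SVR(kernel="rbf")),
    "forest": lambda seed: RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1),
    "gp": lambda seed: make_pipeline(StandardScaler(), GaussianProcessRegressor(random_state=seed)),
}


def fit_regressor(features: np.ndarray, targets: np.ndarray, kind: str = "forest",
                  seed: int = 0) -> RegressorModel:
    """Fit the (δ_max, α_max) regressor pair.

    ``kind``: linear, kernel (RBF support-vector), forest, or gp.  No SMOTE
    is involved — rebalancing applies to the classification strategy only.
    """
    X = np.asarray(features, dtype=float)
    t = np.asarray(targets, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("regression needs at least two samples")
    if kind not in _REGRESSORS:
        raise ValueError(f"unknown regressor kind: {kind}")
    est_d = _REGRESSORS[kind](seed)
    est_a = _REGRESSORS[kind](seed + 1)
    est_d.fit(X, t[:, 0])
    est_a.fit(X, t[:, 1])
    return RegressorModel(kind=kind, est_d=est_d, est_a=est_a)


def regression_decision(pred: np.ndarray, sigma: ThresholdPair) -> np.ndarray:
    """Reject (1) iff a clamped prediction exceeds its tolerance.

    The track is kept (0) when predicted d ≤ dᵢ and predicted a ≤ aᵢ —
    boundary values keep the track, mirroring the strict exceedance used in
    the labels.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    pred = np.clip(pred, 0.0, None)
    lost = (pred[:, 0] > sigma.d) | (pred[:, 1] > sigma.a)
    return lost.astype(int)
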
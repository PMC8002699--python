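"""Walk-forward cross-validation of the reject strategies.

The windowed dataset is kept in its (sequence, config, window-start) time
order, split into 11 consecutive blocks, and evaluated over 10 folds: fold
k trains on blocks 1..k and tests on block k+1, so training data always
precede test data and every sample is tested at most once.  Precision and
recall treat "lost" (label 1) as the positive class; undefined metrics
(no positive predictions / no positives present) are excluded from averages
rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import FEATURE_COLUMNS, ThresholdPair, threshold_pairs
from . import reject as rj

__all__ = [
    "CVSplit",
    "MetricsReport",
    "time_series_folds",
    "precision_recall",
    "ChowStrategy",
    "ClassificationStrategy",
    "RegressionStrategy",
    "EnsembleStrategy",
    "evaluate_strategy",
    "compare_strategies",
]

N_BLOCKS = 11


@dataclass(frozen=True)
class CVSplit:
    fold: int  # 1..10
    train: np.ndarray  # contiguous prefix of sample indices
    test: np.ndarray   # the following contiguous block


def time_series_folds(n: int) -> list[CVSplit]:
    """10 walk-forward folds over ``n`` time-ordered samples.

    The samples are cut into 11 consecutive blocks of near-equal size (any
    remainder goes to the earliest blocks); fold k tests on block k+1 and
    trains on everything before it.
    """
    if n < N_BLOCKS:
        raise ValueError(f"need at least {N_BLOCKS} samples, got {n}")
    base, rem = divmod(n, N_BLOCKS)
    sizes = [base + (1 if b < rem else 0) for b in range(N_BLOCKS)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    folds = []
    for k in range(1, N_BLOCKS):
        folds.append(CVSplit(
            fold=k,
            train=np.arange(0, bounds[k]),
            test=np.arange(bounds[k], bounds[k + 1]),
        ))
    return folds


def precision_recall(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(precision, recall) with lost=1 positive; undefined values are NaN."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, recall


# ---------------------------------------------------------------------------
# Strategy adapters: fit(train_df) then predict(test_df, sigma)

class ChowStrategy:
    """Per-σ likelihood threshold on the window-mean maximum log-likelihood."""

    name = "chow"

    def __init__(self) -> None:
        self.models: dict[int, rj.ChowModel] = {}

    def fit(self, train: pd.DataFrame, sigmas: Sequence[ThresholdPair], seed: int = 0) -> "ChowStrategy":
        self.models = {}
        ll = train["ll_max_mean"].to_numpy()
        for s in sigmas:
            y = train[f"lost_{s.index}"].to_numpy()
            if len(np.unique(y)) < 2:
                continue  # degenerate: no threshold can be optimized
            self.models[s.index] = rj.fit_chow_threshold(ll, y, sigma_index=s.index)
        return self

    def predict(self, test: pd.DataFrame, sigma: ThresholdPair) -> Optional[np.ndarray]:
        model = self.models.get(sigma.index)
        if model is None:
            return None
        return model.predict(test["ll_max_mean"].to_numpy())


class ClassificationStrategy:
    """One SMOTE-balanced classifier per σ (linear margin or random forest)."""

    def __init__(self, kind: str = "forest", smote: bool = True) -> None:
        self.kind = kind
        self.smote = smote
        self.name = f"{kind}_classification"
        self.models: dict[int, rj.ClassifierModel] = {}

    def fit(self, train: pd.DataFrame, sigmas: Sequence[ThresholdPair], seed: int = 0):
        self.models = {}
        X = train[FEATURE_COLUMNS].to_numpy()
        for s in sigmas:
            y = train[f"lost_{s.index}"].to_numpy()
            if len(np.unique(y)) < 2:
                continue
            self.models[s.index] = rj.fit_sigma_classifier(
                X, y, kind=self.kind, smote=self.smote, seed=seed, sigma_index=s.index)
        return self

    def predict(self, test: pd.DataFrame, sigma: ThresholdPair) -> Optional[np.ndarray]:
        model = self.models.get(sigma.index)
        if model is None:
            return None
        return model.predict(test[FEATURE_COLUMNS].to_numpy())


class RegressionStrategy:
    """One (δ, α) regressor pair serving every σ through the decision rule."""

    def __init__(self, kind: str = "forest") -> None:
        self.kind = kind
        self.name = f"{kind}_regression"
        self.model: Optional[rj.RegressorModel] = None

    def fit(self, train: pd.DataFrame, sigmas: Sequence[ThresholdPair], seed: int = 0):
        X = train[FEATURE_COLUMNS].to_numpy()
        t = train[["max_delta", "max_alpha"]].to_numpy()
        self.model = rj.fit_regressor(X, t, kind=self.kind, seed=seed)
        return self

    def predict(self, test: pd.DataFrame, sigma: ThresholdPair) -> Optional[np.ndarray]:
        if self.model is None:
            return None
        pred = self.model.predict(test[FEATURE_COLUMNS].to_numpy())
        return rj.regression_decision(pred, sigma)


class EnsembleStrategy:
    """Sparse classifier ensemble covering all σ at target precision/recall."""

    def __init__(self, kind: str = "forest", goal_p: float = 0.9, goal_r: float = 0.9,
                 smote: bool = True) -> None:
        self.kind = kind
        self.goal_p = goal_p
        self.goal_r = goal_r
        self.smote = smote
        self.name = f"{kind}_ensemble_{goal_p:g}_{goal_r:g}"
        self.ensemble: Optional[rj.SparseEnsemble] = None

    def fit(self, train: pd.DataFrame, sigmas: Sequence[ThresholdPair], seed: int = 0):
        X = train[FEATURE_COLUMNS].to_numpy()
        labels = train[[f"lost_{s.index}" for s in sigmas]].to_numpy()
        candidates = []
        for col, s in enumerate(sigmas):
            y = labels[:, col]
            if len(np.unique(y)) < 2:
                continue
            candidates.append(rj.fit_sigma_classifier(
                X, y, kind=self.kind, smote=self.smote, seed=seed, sigma_index=s.index))
        self.ensemble = rj.build_sparse_ensemble(
            candidates, X, labels, sigmas, self.goal_p, self.goal_r)
        return self

    def predict(self, test: pd.DataFrame, sigma: ThresholdPair) -> Optional[np.ndarray]:
        if self.ensemble is None or sigma.index not in self.ensemble.assignment:
            return None
        return self.ensemble.predict(test[FEATURE_COLUMNS].to_numpy(), sigma.index)


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class MetricsReport:
    """Per-(fold, σ) precision/recall for one strategy, with aggregates."""

    name: str
    per_fold: pd.DataFrame  # columns: fold, sigma, precision, recall
    skipped: list[str] = field(default_factory=list)

    @property
    def mean_precision(self) -> float:
        return float(np.nanmean(self.per_fold["precision"]))

    @property
    def mean_recall(self) -> float:
        return float(np.nanmean(self.per_fold["recall"]))

    @property
    def std_precision(self) -> float:
        return float(np.nanstd(self.per_fold["precision"]))

    @property
    def std_recall(self) -> float:
        return float(np.nanstd(self.per_fold["recall"]))

    def per_sigma(self) -> pd.DataFrame:
        return (self.per_fold.groupby("sigma")[["precision", "recall"]]
                .mean().reset_index())

    def summary_row(self) -> dict:
        return {
            "model": self.name,
            "avg_precision": self.mean_precision, "std_precision": self.std_precision,
            "avg_recall": self.mean_recall, "std_recall": self.std_recall,
        }

    def summary(self) -> str:
        r = self.summary_row()
        return (f"{self.name}: precision {r['avg_precision']:.4f}±{r['std_precision']:.4f}  "
                f"recall {r['avg_recall']:.4f}±{r['std_recall']:.4f}")


def evaluate_strategy(strategy, dataset: pd.DataFrame,
                      sigmas: Optional[Sequence[ThresholdPair]] = None,
                      seed: int = 0, log: Optional[Callable[[str], None]] = None,
                      ) -> MetricsReport:
    """Walk-forward evaluation of one strategy over the windowed dataset.

    The dataset must already be in (sequence, config, window-start) order.
    Each fold refits the strategy on its training prefix (any resampling
    such as SMOTE happens inside ``fit`` and therefore only ever sees
    training rows) and scores the following test block per σ.  Folds whose
    training data are single-class for a σ are skipped and logged.
    """
    if sigmas is None:
        sigmas = threshold_pairs()
    if {"config", "sequence", "window_start"} <= set(dataset.columns):
        # pool runs in (config, sequence) order, time-ordered within each run,
        # so every training prefix spans both disruption types
        dataset = dataset.sort_values(["config", "sequence", "window_start"],
                                      kind="stable").reset_index(drop=True)
    folds = time_series_folds(len(dataset))
    rows = []
    skipped: list[str] = []
    for split in folds:
        train = dataset.iloc[split.train]
        test = dataset.iloc[split.test]
        try:
            strategy.fit(train, sigmas, seed=seed)
        except (ValueError, rj.UncoverableError) as exc:
            msg = f"fold {split.fold}: fit failed ({exc})"
            skipped.append(msg)
            if log:
                log(msg)
            continue
        for s in sigmas:
            pred = strategy.predict(test, s)
            if pred is None:
                msg = f"fold {split.fold} sigma {s.index}: degenerate training labels"
                skipped.append(msg)
                if log:
                    log(msg)
                continue
            p, r = precision_recall(pred, test[f"lost_{s.index}"].to_numpy())
            rows.append({"fold": split.fold, "sigma": s.index,
                         "precision": p, "recall": r})
    return MetricsReport(name=strategy.name,
                         per_fold=pd.DataFrame(rows, columns=["fold", "sigma", "precision", "recall"]),
                         skipped=skipped)


def compare_strategies(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Side-by-side mean ± std table, flagging the best by each metric."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    df = pd.DataFrame([r.summary_row() for r in reports])
    best_p = df["avg_precision"].max()
    best_r = df["avg_recall"].max()
    df["best_precision"] = df["avg_precision"] == best_p
    df["best_recall"] = df["avg_recall"] == best_r
    return df
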
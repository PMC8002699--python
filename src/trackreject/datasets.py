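"""Windowed feature/label tables for the lost-track prediction task.

Tracking traces from many filter configurations are cut into 20-frame
windows with 10-frame overlap.  Each window yields an 11-dimensional
feature vector — the 7 configuration values plus the window mean of the
4 filter diagnostics — a pair of regression targets (window-maximum
position and angle error), and 20 binary lost-track labels, one per
accuracy-tolerance pair σᵢ = (dᵢ, aᵢ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import FilterConfig, TrackingTrace, track_sequence
from .scene import CameraIntrinsics, SequenceRecord

__all__ = [
    "N_SIGMA",
    "ThresholdPair",
    "ConfigGrid",
    "TABLE_RANGES",
    "FEATURE_COLUMNS",
    "threshold_pairs",
    "sample_config_grid",
    "window_features",
    "window_label",
    "build_dataset",
    "sigma_label_columns",
    "save_dataset",
    "load_dataset",
]

#: number of accuracy-tolerance pairs
N_SIGMA = 20

#: feature column order: the 7 config values then the 4 window-mean diagnostics
FEATURE_COLUMNS = [
    "n_trans", "n_rot", "vf", "w_exp", "w_gaus", "w_uni", "K",
    "ll_max_mean", "ess_mean", "w_mean_mean", "w_var_mean",
]

#: sampling lattice per tracker parameter: (low, high, step)
TABLE_RANGES = {
    "n_trans": (0.0005, 0.01, 0.0005),
    "n_rot": (0.005, 0.1, 0.005),
    "vf": (0.8, 0.99, 0.01),
    "w_exp": (0.2, 0.39, 0.01),
    "w_gaus": (0.5, 0.69, 0.01),
    "w_uni": (0.01, 0.2, 0.01),
    "K": (100, 2000, 100),
}


@dataclass(frozen=True)
class ThresholdPair:
    """One accuracy tolerance σᵢ: distance d (m) and angle a (rad)."""

    d: float
    a: float
    index: int  # 1-based, strict (1) to tolerant (20)


def threshold_pairs() -> list[ThresholdPair]:
    """The 20 equidistant (d, a) tolerance pairs.

    d runs from 0.05 to 0.2 m and a from 0.13 to 0.26 rad, both linearly;
    σ1 = (0.05, 0.13) is the strictest, σ20 = (0.2, 0.26) the most tolerant.
    """
    ds = np.linspace(0.05, 0.2, N_SIGMA)
    as_ = np.linspace(0.13, 0.26, N_SIGMA)
    return [ThresholdPair(float(d), float(a), i + 1) for i, (d, a) in enumerate(zip(ds, as_))]


def sigma_label_columns() -> list[str]:
    return [f"lost_{i}" for i in range(1, N_SIGMA + 1)]


@dataclass
class ConfigGrid:
    configs: list[FilterConfig]
    seed: int

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)


def _lattice(low: float, high: float, step: float) -> np.ndarray:
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def sample_config_grid(n: int, seed: int, dt: float = 1.0 / 30.0, lam: float = 1.0,
                       k_max: Optional[int] = None) -> ConfigGrid:
    """Sample ``n`` filter configurations uniformly from the parameter lattice.

    Each parameter is drawn independently from its range in its printed step
    size.  ``k_max`` optionally caps the particle-count lattice (desk-scale
    runs use k_max=300).  Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one configuration")
    rng = np.random.default_rng(seed)
    lattices = {k: _lattice(*v) for k, v in TABLE_RANGES.items()}
    if k_max is not None:
        lattices["K"] = lattices["K"][lattices["K"] <= k_max]
    configs = []
    for _ in range(n):
        draw = {k: rng.choice(lat) for k, lat in lattices.items()}
        configs.append(FilterConfig(
            n_trans=float(draw["n_trans"]), n_rot=float(draw["n_rot"]),
            vf=float(draw["vf"]), w_exp=float(draw["w_exp"]),
            w_gaus=float(draw["w_gaus"]), w_uni=float(draw["w_uni"]),
            K=int(draw["K"]), dt=dt, lam=lam,
        ))
    return ConfigGrid(configs, seed)


def window_features(trace: TrackingTrace, cfg: FilterConfig,
                    window: int = 20, stride: int = 10) -> list[tuple[np.ndarray, int]]:
    """Slide a window over a trace and emit 11-vectors (config ‖ mean diagnostics).

    Windows cover frames ``[t, t+window)`` advancing by ``stride``; a trace
    shorter than one window yields an empty list.
    """
    T = len(trace)
    if T < window:
        return []
    xconf = cfg.x_conf()
    xout = trace.x_out()
    out = []
    for start in range(0, T - window + 1, stride):
        mean_out = xout[start:start + window].mean(axis=0)
        out.append((np.concatenate([xconf, mean_out]), start))
    return out


def window_label(deltas: np.ndarray, alphas: np.ndarray, sigma: ThresholdPair) -> int:
    """1 iff the track leaves tolerance anywhere in the window (strict >)."""
    deltas = np.asarray(deltas)
    alphas = np.asarray(alphas)
    if deltas.size == 0 or deltas.shape != alphas.shape:
        raise ValueError("delta/alpha windows must be non-empty and equal length")
    return int(np.any(deltas > sigma.d) or np.any(alphas > sigma.a))


def build_dataset(sequences: Sequence[SequenceRecord], grid: ConfigGrid,
                  intr: CameraIntrinsics, target_shape,
                  window: int = 20, stride: int = 10,
                  log=None) -> pd.DataFrame:
    """Track every (sequence, config) pair and window the traces into a table.

    Row order is (sequence, config, window start) — the time order later
    respected by the walk-forward evaluation.  Tracking failures are logged
    and skipped, never silently dropped.  Deterministic given ``grid.seed``.
    """
    sigmas = threshold_pairs()
    rows = []
    ss = np.random.SeedSequence(grid.seed)
    run_seeds = ss.generate_state(max(len(sequences) * len(grid), 1))
    run = 0
    for s_idx, seq in enumerate(sequences):
        for c_idx, cfg in enumerate(grid):
            rng = np.random.default_rng(int(run_seeds[run]))
            run += 1
            try:
                trace = track_sequence(seq, cfg, intr, target_shape, rng=rng)
            except Exception as exc:  # pragma: no cover - defensive
                if log is not None:
                    log(f"tracking failed for sequence {s_idx} config {c_idx}: {exc}")
                continue
            for feats, start in window_features(trace, cfg, window, stride):
                d_win = trace.delta[start:start + window]
                a_win = trace.alpha[start:start + window]
                row = {
                    "sequence": s_idx, "config": c_idx, "window_start": start,
                    **dict(zip(FEATURE_COLUMNS, feats)),
                    "max_delta": float(d_win.max()), "max_alpha": float(a_win.max()),
                }
                for sig in sigmas:
                    row[f"lost_{sig.index}"] = window_label(d_win, a_win, sig)
                rows.append(row)
    cols = (["sequence", "config", "window_start"] + FEATURE_COLUMNS
            + ["max_delta", "max_alpha"] + sigma_label_columns())
    return pd.DataFrame(rows, columns=cols)


def save_dataset(df: pd.DataFrame, path: str | Path, meta: Optional[dict] = None) -> None:
    """Write the dataset CSV plus a JSON schema sidecar (columns, units, σ table)."""
    path = Path(path)
    df.to_csv(path, index=False)
    schema = {
        "columns": list(df.columns),
        "feature_columns": FEATURE_COLUMNS,
        "label_columns": sigma_label_columns(),
        "units": {"max_delta": "m", "max_alpha": "rad"},
        "sigmas": [{"index": s.index, "d": s.d, "a": s.a} for s in threshold_pairs()],
    }
    if meta:
        schema["meta"] = meta
    path.with_suffix(".json").write_text(json.dumps(schema, indent=2))


def load_dataset(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        schema = json.loads(sidecar.read_text())
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            raise ValueError(f"dataset does not match schema; missing columns: {missing}")
    return df
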
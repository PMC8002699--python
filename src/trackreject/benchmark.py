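"""The packaged synthetic tracking benchmark.

Two surgical-style scenarios mirror the disruptions a depth-camera tracker
faces in the operating room: one sequence with a partial occlusion event
(tissue or a person moving in front of the target) and one with a sudden
displacement (the body being repositioned).  The tracker is rerun over the
pair with many sampled configurations and the traces are windowed into the
feature/label table the reject strategies train on.

Desk-scale defaults: 64×48 depth images at 30 Hz, a sphere target of radius
6 cm about 0.6 m from the camera over a background plane at 0.85 m,
RealSense-class sensor noise (variance 4e-6·x² + 4e-6, 2% dropout), 150
frames per sequence and particle counts capped at 300.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datasets import ConfigGrid, build_dataset, sample_config_grid
from .scene import (CameraIntrinsics, DisplacementEvent, MotionModel, NoiseModel,
                    OcclusionEvent, ScenarioConfig, SequenceRecord, Sphere,
                    simulate_sequence)

__all__ = [
    "default_intrinsics",
    "default_noise",
    "default_target",
    "occlusion_scenario",
    "displacement_scenario",
    "benchmark_sequences",
    "make_benchmark",
    "DT",
]

DT = 1.0 / 30.0


def default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=55.0, fy=55.0, cx=31.5, cy=23.5,
                            width=64, height=48, d_min=0.3, d_max=3.0,
                            df=4e-6, bn=4e-6)


def default_noise() -> NoiseModel:
    return NoiseModel(df=4e-6, bn=4e-6, dropout_p=0.02)


def default_target() -> Sphere:
    return Sphere(0.06)


def benchmark_motion() -> MotionModel:
    """Ground-truth drift of an operating-table target being handled.

    The AR(1) velocity walk settles well under a millimetre per frame, so
    nominal tracking error stays clearly inside the strictest tolerance.
    """
    return MotionModel(trans_diffusion=0.002, rot_diffusion=0.01, decay=0.97)


#: trajectory seeds of the two packaged sequences — fixed study constants,
#: the stand-ins for the two recorded surgical sequences
SCENARIO_SEEDS = (7, 8)


def occlusion_scenario(seed: int, n_frames: int = 150) -> ScenarioConfig:
    """The target is fully hidden for one second late in the sequence.

    While the view is blocked the target is also nudged by 7 cm and 6°
    (the surgeon adjusting it while standing in front of the camera), so
    when the view clears the track is off by more than the strict
    tolerances; how quickly — and whether — it re-locks depends on the
    filter configuration.
    """
    event = (5 * n_frames) // 8
    ang = np.deg2rad(6.0)
    rot = (float(np.cos(ang / 2)), 0.0, 0.0, float(np.sin(ang / 2)))
    return ScenarioConfig(
        n_frames=n_frames,
        target_shape=default_target(),
        initial_position=(0.0, 0.0, 0.6),
        motion=benchmark_motion(),
        occlusion_event=OcclusionEvent(start=event, duration=30, coverage=1.0),
        displacement_event=DisplacementEvent(frame=event + 15,
                                             translation=(0.05, 0.05, 0.0), rotation=rot),
        noise=default_noise(),
        background_depth=0.85,
        seed=seed,
    )


def displacement_scenario(seed: int, n_frames: int = 150,
                          jump: tuple[float, float, float] = (0.13, 0.0, -0.125)) -> ScenarioConfig:
    """The target jumps 18 cm (with a depth component) late in the sequence."""
    ang = np.deg2rad(10.0)
    rot = (float(np.cos(ang / 2)), 0.0, 0.0, float(np.sin(ang / 2)))
    return ScenarioConfig(
        n_frames=n_frames,
        target_shape=default_target(),
        initial_position=(0.0, 0.0, 0.6),
        motion=benchmark_motion(),
        displacement_event=DisplacementEvent(frame=(5 * n_frames) // 8, translation=jump, rotation=rot),
        noise=default_noise(),
        background_depth=0.85,
        seed=seed,
    )


def benchmark_sequences(n_frames: int = 150) -> list[SequenceRecord]:
    """The two packaged sequences (fixed trajectories, occlusion + jump)."""
    intr = default_intrinsics()
    occ = simulate_sequence(occlusion_scenario(SCENARIO_SEEDS[0], n_frames), intr, DT)
    disp = simulate_sequence(displacement_scenario(SCENARIO_SEEDS[1], n_frames), intr, DT)
    return [occ, disp]


def make_benchmark(seed: int, n_configs: int = 60, n_frames: int = 150,
                   k_max: int = 300, log=None) -> tuple[pd.DataFrame, ConfigGrid]:
    """Build the full windowed benchmark table.

    The two sequences are fixed study inputs; ``seed`` drives the sampled
    configuration grid and all tracking randomness (and, downstream, SMOTE
    and the forests).
    """
    intr = default_intrinsics()
    seqs = benchmark_sequences(n_frames)
    grid = sample_config_grid(n_configs, seed=seed, dt=DT, k_max=k_max)
    df = build_dataset(seqs, grid, intr, default_target(), log=log)
    return df, grid
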
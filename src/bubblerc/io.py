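"""File formats and run configuration.

Three on-disk artifacts tie the pipeline together:

* **trial logs** — one CSV per simulated session, one row per trial, carrying
  the bubble parameters (``sigma`` plus a semicolon-separated ``centers``
  field, ``x:y`` pairs for spatial sessions) so every reveal profile can be
  regenerated bit-exactly from the log;
* **classification arrays** — per-participant ``.npz`` (raw, z, degenerate
  mask, coverage) with a JSON metadata sidecar (counts, seed, permutations);
* **run configs / manifests** — a YAML config fully echoed into a JSON
  manifest next to each run's outputs, so a run is reproducible from the
  manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationArray
from .masks import DEFAULT_N_BUBBLES, DEFAULT_SIGMA, StimulusGeometry
from .observer import LOG_COLUMNS, ObserverModel, window_kernel

__all__ = [
    "RunConfig",
    "write_trial_log",
    "read_trial_log",
    "save_classification",
    "load_classification",
    "make_observers",
]


@dataclass
class RunConfig:
    """Configuration of one simulate→classify→infer run.

    Defaults reproduce the study design: 384 trials per participant, 8
    temporal bubbles of sigma 3 frames (20 spatial bubbles of sigma 12
    pixels), 2,000 within-participant and 10,000 group permutations, and a
    chance-exclusion threshold of 55% correct. ``kernel_frame_window`` /
    ``kernel_pixel_box`` place the simulated observers' information; leaving
    both unset simulates pure guessers. ``p_max`` is a scalar ceiling shared
    by all observers or a [low, high] range sampled uniformly per observer.
    """

    session_type: str = "temporal"
    n_observers: int = 27
    n_trials: int = 384
    n_bubbles: int | None = None
    sigma: float | None = None
    n_frames: int = 96
    frame_rate: float = 120.0
    width: int = 600
    height: int = 400
    kernel_frame_window: list | None = None
    kernel_pixel_box: list | None = None
    p_max: object = 0.75
    psychometric: str = "linear"
    balanced_labels: bool = False
    contact_jitter: float = 0.0
    n_permutations_within: int = 2000
    n_permutations_group: int = 10000
    accuracy_threshold: float = 0.55
    cluster_metric: str = "mass"
    cluster_forming_threshold: float | None = None
    connectivity: int = 1
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.session_type not in ("temporal", "spatial"):
            raise ValueError(f"unknown session_type {self.session_type!r}")
        if self.n_bubbles is None:
            self.n_bubbles = DEFAULT_N_BUBBLES[self.session_type]
        if self.sigma is None:
            self.sigma = DEFAULT_SIGMA[self.session_type]

    @property
    def geometry(self) -> StimulusGeometry:
        return StimulusGeometry(
            n_frames=self.n_frames,
            frame_rate=self.frame_rate,
            width=self.width,
            height=self.height,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def write_trial_log(log: pd.DataFrame, path) -> None:
    """Write a trial log CSV (lossless round trip with :func:`read_trial_log`)."""
    log[LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read a trial log CSV, validating structure and reporting bad rows."""
    df = pd.read_csv(path, dtype={"centers": str, "participant_id": str})
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, val in enumerate(df["centers"]):
        if not isinstance(val, str) or not val:
            raise ValueError(f"{path}: line {i + 2}: empty or malformed centers field")
    df["correct"] = df["correct"].astype(bool)
    return df


def save_classification(arr: ClassificationArray, base) -> None:
    """Write one participant's arrays as ``<base>.npz`` + ``<base>.json``."""
    base = Path(base)
    arrays = {
        "raw": arr.raw,
        "z": arr.z,
        "degenerate": arr.degenerate,
        "coverage": arr.coverage,
    }
    if arr.perm_mean is not None:
        arrays["perm_mean"] = arr.perm_mean
        arrays["perm_sd"] = arr.perm_sd
    np.savez(base.with_suffix(".npz"), **arrays)
    meta = {
        "participant_id": arr.participant_id,
        "n_correct": arr.n_correct,
        "n_incorrect": arr.n_incorrect,
        "n_permutations": arr.n_permutations,
        "seed": arr.seed,
        "n_degenerate": int(arr.degenerate.sum()),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_classification(base) -> ClassificationArray:
    base = Path(base)
    with np.load(base.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(base.with_suffix(".json").read_text())
    return ClassificationArray(
        raw=arrays["raw"],
        z=arrays["z"],
        degenerate=arrays["degenerate"].astype(bool),
        coverage=arrays["coverage"],
        perm_mean=arrays.get("perm_mean"),
        perm_sd=arrays.get("perm_sd"),
        n_correct=int(meta["n_correct"]),
        n_incorrect=int(meta["n_incorrect"]),
        n_permutations=int(meta["n_permutations"]),
        seed=meta["seed"],
        participant_id=meta["participant_id"],
    )


def make_observers(config: RunConfig) -> list[ObserverModel]:
    """Build the simulated cohort a config describes.

    The kernel is an indicator on the configured frame window / pixel box
    (all observers share it); per-observer p_max values are drawn uniformly
    from a [low, high] range, or shared when scalar. Deterministic in
    ``master_seed`` (a stream independent of the trial streams).
    """
    geometry = config.geometry
    if config.kernel_frame_window is not None:
        kernel = window_kernel(
            geometry, frame_window=tuple(config.kernel_frame_window)
        )
    elif config.kernel_pixel_box is not None:
        kernel = window_kernel(geometry, pixel_box=tuple(config.kernel_pixel_box))
    else:
        shape = (
            geometry.spatial_shape
            if config.session_type == "spatial"
            else geometry.n_frames
        )
        kernel = np.zeros(shape)

    # stream independent of the per-participant trial streams
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(999,))
    )
    if np.ndim(config.p_max) == 0:
        p_maxes = np.full(config.n_observers, float(config.p_max))
    else:
        lo, hi = config.p_max
        p_maxes = rng.uniform(lo, hi, config.n_observers)
    return [
        ObserverModel(
            kernel=kernel,
            p_max=float(p),
            participant_id=f"sim{i + 1:02d}",
            psychometric=config.psychometric,
        )
        for i, p in enumerate(p_maxes)
    ]
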
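"""Replicate-level simulation studies: calibration and parameter recovery.

Convenience layer over observer + classify + inference for running many
replicate experiments quickly (temporal domain, in memory, no file IO):
each replicate simulates a cohort, z-scores every participant's
classification array against its within-participant permutation null, and
runs the group permutation test. Used for type-I-error calibration (zero
kernels) and for parameter recovery (kernel on a known frame window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import permutation_zscore
from .inference import ClusterResult, StatConfig, cluster_permutation_test
from .masks import StimulusGeometry, temporal_profiles
from .observer import ObserverModel, window_kernel

__all__ = ["CohortResult", "simulate_temporal_cohort", "run_group_test"]


@dataclass
class CohortResult:
    """In-memory equivalent of one session's classified cohort."""

    z: np.ndarray  # (n_observers, n_frames)
    raw: np.ndarray
    accuracy: np.ndarray  # (n_observers,)
    degenerate: np.ndarray  # any-participant degenerate mask


def simulate_temporal_cohort(
    n_observers: int = 27,
    frame_window: tuple[int, int] | None = (86, 96),
    p_max=0.75,
    n_trials: int = 384,
    n_bubbles: int = 8,
    sigma: float = 3.0,
    geometry: StimulusGeometry | None = None,
    n_permutations_within: int = 2000,
    seed: int = 0,
) -> CohortResult:
    """Simulate and classify one temporal cohort.

    ``frame_window`` places an indicator information kernel ([a, b], 1-based,
    inclusive); ``None`` simulates pure guessers. ``p_max`` is a scalar shared
    ceiling or a (low, high) range sampled uniformly per observer. Fully
    deterministic in ``seed``.
    """
    if geometry is None:
        geometry = StimulusGeometry()
    kernel = (
        np.zeros(geometry.n_frames)
        if frame_window is None
        else window_kernel(geometry, frame_window=frame_window)
    )
    ksum = kernel.sum()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_observers + 1)
    pm_rng = np.random.default_rng(children[-1])
    if np.ndim(p_max) == 0:
        p_maxes = np.full(n_observers, float(p_max))
    else:
        p_maxes = pm_rng.uniform(p_max[0], p_max[1], n_observers)

    z = np.empty((n_observers, geometry.n_frames))
    raw = np.empty_like(z)
    accuracy = np.empty(n_observers)
    degenerate = np.zeros(geometry.n_frames, dtype=bool)
    for i, child in enumerate(children[:-1]):
        rng = np.random.default_rng(child)
        obs = ObserverModel(kernel=kernel, p_max=float(p_maxes[i]))
        centers = rng.uniform(0.5, geometry.n_frames + 0.5, (n_trials, n_bubbles))
        profiles = temporal_profiles(centers, sigma, geometry)
        info = np.zeros(n_trials) if ksum == 0 else profiles @ kernel / ksum
        correct = rng.random(n_trials) < np.asarray(obs.p_correct(info))
        # degenerate only if a participant answers everything (in)correctly;
        # resample once with a guaranteed split rather than failing the study
        if correct.all() or not correct.any():
            correct[rng.integers(n_trials)] ^= True
        arr = permutation_zscore(
            profiles, correct, n_permutations=n_permutations_within, rng=rng
        )
        z[i] = arr.z
        raw[i] = arr.raw
        accuracy[i] = correct.mean()
        degenerate |= arr.degenerate
    return CohortResult(z=z, raw=raw, accuracy=accuracy, degenerate=degenerate)


def run_group_test(
    cohort: CohortResult,
    statistic: str = "t",
    n_permutations: int = 10000,
    seed: int = 0,
    **config_kwargs,
) -> ClusterResult:
    """Group cluster/max-statistic test on a simulated cohort."""
    config = StatConfig(
        statistic=statistic,
        n_permutations=n_permutations,
        seed=seed,
        **config_kwargs,
    )
    performance = cohort.accuracy if statistic == "r" else None
    return cluster_permutation_test(
        cohort.z, config, performance=performance, exclude=cohort.degenerate
    )
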
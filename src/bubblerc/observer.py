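"""Simulated observers for the bubbles discrimination task.

Each synthetic participant carries a latent *information kernel* — a
nonnegative array over the stimulus domain marking where the discriminative
information lives — and a performance ceiling ``p_max``. On each trial the
revealed fraction of that information is

    I = sum(profile * kernel) / sum(kernel)            (0 if kernel is zero)

and correctness is Bernoulli with, under the default linear psychometric map,

    p(correct) = 0.5 + (p_max - 0.5) * I

so a fully revealed stimulus is discriminated at p_max and a fully masked one
at chance. Linearity makes the expected classification array proportional to
the kernel, which is what downstream parameter-recovery checks exploit;
logistic and hard-threshold psychometric maps are available as options. A
zero kernel yields a pure guesser (p = 0.5 on every trial) regardless of the
mask. The study design this emulates: 384 two-alternative trials per
participant, 8 temporal / 20 spatial bubbles, observers spanning chance to
~75% correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .masks import (
    DEFAULT_N_BUBBLES,
    DEFAULT_SIGMA,
    BubbleSpec,
    StimulusGeometry,
    make_profile,
    sample_bubble_centers,
    temporal_profiles,
)

__all__ = [
    "ObserverModel",
    "TrialRecord",
    "overlap_information",
    "simulate_trial",
    "simulate_experiment",
    "window_kernel",
    "LOG_COLUMNS",
]

#: trial-log CSV column order (the on-disk dialect; see io.py)
LOG_COLUMNS = [
    "participant_id",
    "session_type",
    "trial_index",
    "video_id",
    "stimulus_label",
    "response",
    "correct",
    "n_bubbles",
    "sigma",
    "centers",
    "contact_x",
    "contact_y",
    "seed",
]


@dataclass
class ObserverModel:
    """A synthetic participant: information kernel + performance ceiling.

    ``kernel`` is nonnegative over the stimulus domain (all-zero = pure
    guesser); ``p_max`` in [0.5, 1] is the proportion correct reached when the
    kernel region is fully revealed. ``psychometric`` selects the map from
    revealed information I to p(correct): "linear" (default), "logistic"
    (slope 10 around I = 0.5, rescaled to hit 0.5 at I=0 and p_max at I=1), or
    "threshold" (p_max once I >= 0.5, else chance).
    """

    kernel: np.ndarray
    p_max: float = 0.75
    participant_id: str = "obs"
    psychometric: str = "linear"
    logistic_slope: float = 10.0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if np.any(self.kernel < 0):
            raise ValueError("kernel values must be >= 0")
        if not 0.5 <= self.p_max <= 1.0:
            raise ValueError(f"p_max must be in [0.5, 1], got {self.p_max}")
        if self.psychometric not in ("linear", "logistic", "threshold"):
            raise ValueError(f"unknown psychometric {self.psychometric!r}")

    def p_correct(self, information):
        """Probability of a correct response given revealed information I."""
        info = np.asarray(information, dtype=float)
        gain = self.p_max - 0.5
        if self.psychometric == "linear":
            p = 0.5 + gain * info
        elif self.psychometric == "logistic":
            lo = expit(-self.logistic_slope / 2.0)
            hi = expit(self.logistic_slope / 2.0)
            scaled = (expit(self.logistic_slope * (info - 0.5)) - lo) / (hi - lo)
            p = 0.5 + gain * scaled
        else:  # threshold
            p = np.where(info >= 0.5, self.p_max, 0.5)
        return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class TrialRecord:
    """One trial: what was shown, what was answered, and the bubble layout."""

    participant_id: str
    session_type: str
    trial_index: int
    video_id: int
    stimulus_label: int
    response: int
    correct: bool
    bubble_spec: BubbleSpec
    contact_point: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.correct != (self.response == self.stimulus_label):
            raise ValueError("correct flag inconsistent with response/label")

    @property
    def n_bubbles(self) -> int:
        return self.bubble_spec.n_bubbles


def overlap_information(profile: np.ndarray, kernel: np.ndarray) -> float:
    """Fraction of kernel-weighted information the profile reveals, in [0, 1]."""
    profile = np.asarray(profile, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if profile.shape != kernel.shape:
        raise ValueError(
            f"profile shape {profile.shape} != kernel shape {kernel.shape}"
        )
    if np.any(kernel < 0):
        raise ValueError("kernel values must be >= 0")
    total = kernel.sum()
    if total == 0:
        return 0.0
    return float(np.sum(profile * kernel) / total)


def simulate_trial(
    observer: ObserverModel,
    spec: BubbleSpec,
    geometry: StimulusGeometry,
    rng: np.random.Generator,
    trial_index: int = 0,
    session_type: str = "temporal",
    video_id: int = 0,
    contact_point: tuple[float, float] | None = None,
    seed: int = 0,
) -> TrialRecord:
    """Simulate one trial under the observer's psychometric model.

    The stimulus label is Bernoulli(0.5); correctness is Bernoulli with
    p = observer.p_correct(I) where I is the revealed-information overlap of
    the combined bubble profile with the kernel; the response is derived so
    that ``correct == (response == stimulus_label)``.
    """
    profile = make_profile(spec, geometry)
    info = overlap_information(profile, observer.kernel)
    p = observer.p_correct(info)
    label = int(rng.random() < 0.5)
    correct = bool(rng.random() < p)
    response = label if correct else 1 - label
    if contact_point is None:
        contact_point = geometry.contact_point
    return TrialRecord(
        participant_id=observer.participant_id,
        session_type=session_type,
        trial_index=trial_index,
        video_id=video_id,
        stimulus_label=label,
        response=response,
        correct=correct,
        bubble_spec=spec,
        contact_point=contact_point,
        seed=seed,
    )


def window_kernel(
    geometry: StimulusGeometry,
    frame_window: tuple[int, int] | None = None,
    pixel_box: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Indicator kernel on a frame window [a, b] (1-based, inclusive) or a
    pixel box (x0, x1, y0, y1); exactly one must be given."""
    if (frame_window is None) == (pixel_box is None):
        raise ValueError("give exactly one of frame_window or pixel_box")
    if frame_window is not None:
        a, b = frame_window
        if not (1 <= a <= b <= geometry.n_frames):
            raise ValueError(f"frame window {frame_window} outside stimulus")
        k = np.zeros(geometry.n_frames)
        k[a - 1 : b] = 1.0
        return k
    x0, x1, y0, y1 = pixel_box
    k = np.zeros(geometry.spatial_shape)
    xs = np.arange(geometry.width)
    ys = np.arange(geometry.height)
    k[np.ix_((ys >= y0) & (ys <= y1), (xs >= x0) & (xs <= x1))] = 1.0
    return k


def _format_centers(centers, spatial: bool) -> str:
    if spatial:
        return ";".join(f"{x:.17g}:{y:.17g}" for x, y in centers)
    return ";".join(f"{c:.17g}" for c in centers)


def simulate_experiment(
    observers,
    n_trials: int = 384,
    n_bubbles: int | None = None,
    sigma: float | None = None,
    geometry: StimulusGeometry | None = None,
    session_type: str = "temporal",
    master_seed: int = 0,
    balanced_labels: bool = False,
    n_videos: int = 24,
    contact_jitter: float = 0.0,
) -> pd.DataFrame:
    """Simulate a full bubbles block for each observer; returns a trial log.

    Per observer, ``n_trials`` independent trials with freshly sampled uniform
    bubble centers; one RNG stream per participant is spawned from
    ``master_seed`` so logs are reproducible and participants uncoupled.
    Defaults follow the study design: 384 trials, 8 bubbles of sigma 3 frames
    (temporal) or 20 bubbles of sigma 12 pixels (spatial). Stimulus labels are
    Bernoulli(0.5) by default; ``balanced_labels`` forces an exact 50/50 split
    per block. Trials cycle through ``n_videos`` synthetic videos whose
    contact points sit at the geometry's contact point, optionally jittered
    uniformly by up to ``contact_jitter`` pixels per axis (spatial sessions).

    The returned DataFrame uses the trial-log CSV dialect (:data:`LOG_COLUMNS`);
    bubble profiles regenerate bit-exactly from its centers/sigma fields.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if session_type not in ("temporal", "spatial"):
        raise ValueError(f"unknown session_type {session_type!r}")
    if geometry is None:
        geometry = StimulusGeometry()
    if n_bubbles is None:
        n_bubbles = DEFAULT_N_BUBBLES[session_type]
    if sigma is None:
        sigma = DEFAULT_SIGMA[session_type]
    spatial = session_type == "spatial"

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(observers) + 1)
    video_rng = np.random.default_rng(children[-1])
    cx0, cy0 = geometry.contact_point
    if spatial and contact_jitter > 0:
        vx = cx0 + video_rng.uniform(-contact_jitter, contact_jitter, n_videos)
        vy = cy0 + video_rng.uniform(-contact_jitter, contact_jitter, n_videos)
    else:
        vx = np.full(n_videos, cx0)
        vy = np.full(n_videos, cy0)

    rows = []
    for obs, child in zip(observers, children[:-1]):
        seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        rng = np.random.default_rng(seed)
        ksum = obs.kernel.sum()

        if spatial:
            centers = np.stack(
                [
                    rng.uniform(0, geometry.width, (n_trials, n_bubbles)),
                    rng.uniform(0, geometry.height, (n_trials, n_bubbles)),
                ],
                axis=-1,
            )  # (n_trials, B, 2)
            info = np.empty(n_trials)
            from .masks import spatial_profile

            for t in range(n_trials):
                prof = spatial_profile(centers[t], sigma, geometry)
                info[t] = 0.0 if ksum == 0 else np.sum(prof * obs.kernel) / ksum
        else:
            centers = rng.uniform(
                0.5, geometry.n_frames + 0.5, (n_trials, n_bubbles)
            )
            profs = temporal_profiles(centers, sigma, geometry)
            info = (
                np.zeros(n_trials) if ksum == 0 else profs @ obs.kernel.ravel() / ksum
            )

        p = np.asarray(obs.p_correct(info))
        if balanced_labels:
            labels = np.zeros(n_trials, dtype=int)
            labels[: n_trials // 2] = 1
            rng.shuffle(labels)
        else:
            labels = (rng.random(n_trials) < 0.5).astype(int)
        correct = rng.random(n_trials) < p
        responses = np.where(correct, labels, 1 - labels)
        videos = np.arange(n_trials) % n_videos

        for t in range(n_trials):
            ctrs = centers[t]
            rows.append(
                {
                    "participant_id": obs.participant_id,
                    "session_type": session_type,
                    "trial_index": t + 1,
                    "video_id": int(videos[t]),
                    "stimulus_label": int(labels[t]),
                    "response": int(responses[t]),
                    "correct": bool(correct[t]),
                    "n_bubbles": n_bubbles,
                    "sigma": sigma,
                    "centers": _format_centers(ctrs, spatial),
                    "contact_x": float(vx[videos[t]]),
                    "contact_y": float(vy[videos[t]]),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)
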
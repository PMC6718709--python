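"""Per-participant classification arrays from bubbles trial logs.

The raw classification array (RCA) weights each trial's reveal profile by
response correctness,

    RCA = sum_c Bubbles_c  -  sum_i Bubbles_i

summing profiles from correct trials positively and incorrect trials
negatively; points revealing task-relevant information accumulate positive
weight. To put participants on a common, interpretable scale, the RCA is
z-scored against its own permutation null: correct/incorrect labels are
reassigned without replacement (preserving the observed counts) over many
iterations, and the per-point permutation mean and SD standardize the
observed array. Spatial profiles are first translated into a common
coordinate frame centered on the racket-ball contact point.

Participants whose bubbles-block accuracy is consistent with guessing are
excluded before group analysis, since reverse correlation is uninformative at
chance performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .masks import StimulusGeometry, spatial_profile, temporal_profiles

__all__ = [
    "ClassificationArray",
    "RecenterFrame",
    "raw_classification_array",
    "permutation_zscore",
    "exclude_guesser",
    "build_recenter_frame",
    "recenter_profile",
    "profiles_from_log",
    "classify_participant",
]

# cap on elements per permutation chunk (keeps W @ P workspaces ~tens of MB)
_CHUNK_ELEMENTS = 20_000_000


@dataclass
class ClassificationArray:
    """Raw and permutation-z-scored classification arrays for one participant.

    ``degenerate`` flags points where the permutation SD is zero (all trial
    profiles share one value there); z is set to 0 at those points rather than
    NaN so group statistics stay computable, and the flag propagates.
    ``coverage`` is the pointwise sum of all trial profiles (a diagnostic of
    how much each point was sampled).
    """

    raw: np.ndarray
    z: np.ndarray
    degenerate: np.ndarray
    coverage: np.ndarray
    n_correct: int
    n_incorrect: int
    n_permutations: int
    seed: int | None = None
    participant_id: str = ""
    perm_mean: np.ndarray | None = None
    perm_sd: np.ndarray | None = None


@dataclass(frozen=True)
class RecenterFrame:
    """Common canvas for spatial profiles, centered on the contact point.

    ``canvas_shape`` is (height, width); ``origin`` is the (x, y) canvas
    coordinate at which every video's contact point lands after translation.
    """

    canvas_shape: tuple[int, int]
    origin: tuple[int, int]


def raw_classification_array(profiles, correct) -> np.ndarray:
    """Sum of correct-trial profiles minus sum of incorrect-trial profiles."""
    profiles = np.asarray(profiles, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if len(profiles) != len(correct):
        raise ValueError(
            f"{len(profiles)} profiles but {len(correct)} correctness flags"
        )
    if len(profiles) == 0:
        raise ValueError("need at least one trial")
    w = np.where(correct, 1.0, -1.0)
    flat = profiles.reshape(len(profiles), -1)
    return (w @ flat).reshape(profiles.shape[1:])


def permutation_zscore(
    profiles,
    correct,
    n_permutations: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "",
) -> ClassificationArray:
    """Z-score the raw classification array against its permutation null.

    For each iteration the correctness labels are shuffled without replacement
    (one shared shuffled label vector applied to all points, preserving the
    correct/incorrect counts) and the RCA recomputed; the observed array is
    standardized by the per-point permutation mean and SD. Points with zero
    permutation SD are flagged degenerate and get z = 0.
    """
    profiles = np.asarray(profiles, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    n = len(profiles)
    if n != len(correct):
        raise ValueError(
            f"{len(profiles)} profiles but {len(correct)} correctness flags"
        )
    n_correct = int(correct.sum())
    n_incorrect = n - n_correct
    if n_correct == 0 or n_incorrect == 0:
        raise ValueError(
            "permutation z-score undefined: all trials share one correctness label"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    shape = profiles.shape[1:]
    flat = profiles.reshape(n, -1)
    m = flat.shape[1]
    w = np.where(correct, 1.0, -1.0)
    raw = w @ flat

    # accumulate permutation moments in chunks to bound the W @ P workspace
    chunk = max(1, min(n_permutations, _CHUNK_ELEMENTS // max(m, n)))
    s1 = np.zeros(m)
    s2 = np.zeros(m)
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        W = rng.permuted(np.tile(w, (k, 1)), axis=1)
        perm = W @ flat
        s1 += perm.sum(axis=0)
        s2 += np.einsum("ij,ij->j", perm, perm)
        done += k
    mean = s1 / n_permutations
    var = np.maximum(s2 / n_permutations - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = np.isclose(sd, 0.0, atol=1e-12 * max(1.0, np.abs(flat).max()))
    z = np.zeros(m)
    ok = ~degenerate
    z[ok] = (raw[ok] - mean[ok]) / sd[ok]
    return ClassificationArray(
        raw=raw.reshape(shape),
        z=z.reshape(shape),
        degenerate=degenerate.reshape(shape),
        coverage=flat.sum(axis=0).reshape(shape),
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_permutations=n_permutations,
        seed=seed,
        participant_id=participant_id,
        perm_mean=mean.reshape(shape),
        perm_sd=sd.reshape(shape),
    )


def exclude_guesser(
    n_correct: int, n_trials: int, accuracy_threshold: float = 0.55
) -> tuple[bool, float]:
    """Chance-level exclusion: accuracy below the threshold means excluded.

    Returns ``(excluded, p)`` where p is the exact one-sided binomial tail
    P(X >= n_correct | p = 0.5), reported for context; the operational
    criterion is the accuracy threshold itself (default 55%).
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError(f"n_correct {n_correct} outside [0, {n_trials}]")
    excluded = n_correct / n_trials < accuracy_threshold
    p = float(stats.binom.sf(n_correct - 1, n_trials, 0.5))
    return excluded, p


def build_recenter_frame(
    contact_points, geometry: StimulusGeometry
) -> RecenterFrame:
    """Canvas sized so every video's region fits after translating its contact
    point to the canvas center (the common origin)."""
    pts = np.atleast_2d(np.asarray(contact_points, dtype=float))
    cx = np.rint(pts[:, 0]).astype(int)
    cy = np.rint(pts[:, 1]).astype(int)
    half_w = int(max(cx.max(), geometry.width - 1 - cx.min()))
    half_h = int(max(cy.max(), geometry.height - 1 - cy.min()))
    return RecenterFrame(
        canvas_shape=(2 * half_h + 1, 2 * half_w + 1),
        origin=(half_w, half_h),
    )


def recenter_profile(
    profile: np.ndarray,
    contact_point,
    frame: RecenterFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Translate a spatial profile so its contact point lands on the origin.

    Profiles live on the pixel grid, so the translation is the integer offset
    nearest ``origin - contact_point``. Returns ``(recentered, covered)``:
    canvas cells outside the translated source region are 0 in the profile and
    False in the coverage mask.
    """
    profile = np.asarray(profile, dtype=float)
    h, w = profile.shape
    ch, cw = frame.canvas_shape
    ox, oy = frame.origin
    cx, cy = (int(np.rint(c)) for c in contact_point)
    x0 = ox - cx
    y0 = oy - cy
    if x0 < 0 or y0 < 0 or x0 + w > cw or y0 + h > ch:
        raise ValueError(
            "translated profile exceeds the canvas; rebuild the RecenterFrame "
            "from the full set of contact points"
        )
    out = np.zeros((ch, cw))
    covered = np.zeros((ch, cw), dtype=bool)
    out[y0 : y0 + h, x0 : x0 + w] = profile
    covered[y0 : y0 + h, x0 : x0 + w] = True
    return out, covered


def _parse_centers(s: str, spatial: bool):
    if spatial:
        return [tuple(float(v) for v in pair.split(":")) for pair in s.split(";")]
    return [float(v) for v in s.split(";")]


def profiles_from_log(
    log: pd.DataFrame,
    geometry: StimulusGeometry,
    recenter: RecenterFrame | None = None,
) -> np.ndarray:
    """Regenerate each trial's combined profile from a trial log.

    Temporal logs give an (n_trials, n_frames) array. Spatial logs give
    (n_trials, H, W) in video coordinates, or in recentered canvas
    coordinates when a :class:`RecenterFrame` is supplied.
    """
    session = log["session_type"].iloc[0]
    spatial = session == "spatial"
    if not spatial:
        out = []
        for sigma, grp in log.groupby("sigma", sort=False):
            centers = np.array(
                [_parse_centers(s, False) for s in grp["centers"]], dtype=float
            )
            out.append((grp.index, temporal_profiles(centers, sigma, geometry)))
        profiles = np.empty((len(log), geometry.n_frames))
        for idx, block in out:
            profiles[log.index.get_indexer(idx)] = block
        return profiles

    shape = recenter.canvas_shape if recenter is not None else geometry.spatial_shape
    profiles = np.empty((len(log), *shape))
    for i, row in enumerate(log.itertuples(index=False)):
        prof = spatial_profile(
            _parse_centers(row.centers, True), row.sigma, geometry
        )
        if recenter is not None:
            prof, _ = recenter_profile(
                prof, (row.contact_x, row.contact_y), recenter
            )
        profiles[i] = prof
    return profiles


def classify_participant(
    log: pd.DataFrame,
    geometry: StimulusGeometry,
    n_permutations: int = 2000,
    seed: int | None = None,
    recenter: RecenterFrame | None = None,
) -> ClassificationArray:
    """Full per-participant pipeline: profiles from the log (re-centering
    spatial profiles first), RCA, then permutation z-scoring."""
    session = log["session_type"].iloc[0]
    if session == "spatial" and recenter is None:
        recenter = build_recenter_frame(
            log[["contact_x", "contact_y"]].to_numpy(), geometry
        )
    profiles = profiles_from_log(log, geometry, recenter=recenter)
    return permutation_zscore(
        profiles,
        log["correct"].to_numpy(dtype=bool),
        n_permutations=n_permutations,
        seed=seed,
        participant_id=str(log["participant_id"].iloc[0]),
    )
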
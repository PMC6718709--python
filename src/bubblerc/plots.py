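"""Publication-style figures for group results.

1-D (temporal) results are drawn as a sequence over time before contact with
a 95% confidence band and significant clusters shaded; 2-D (spatial) results
as the threshold-normalized map with significant clusters outlined.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .inference import ClusterResult, transformed_r_ci
from .masks import StimulusGeometry, frame_to_time

__all__ = ["plot_sequence", "plot_map"]


def plot_sequence(
    z_arrays,
    result: ClusterResult,
    geometry: StimulusGeometry,
    path,
    n_for_ci: int | None = None,
) -> None:
    """Temporal result: mean z (t analysis) or Fisher-z r (r analysis) vs
    time before contact, with 95% CI band and shaded significant clusters."""
    frames = np.arange(1, geometry.n_frames + 1)
    times = -frame_to_time(frames, geometry)  # negative = before contact

    fig, ax = plt.subplots(figsize=(7, 3.2))
    if result.config.statistic == "t" and z_arrays is not None:
        n = z_arrays.shape[0]
        mean = z_arrays.mean(axis=0)
        sem = z_arrays.std(axis=0, ddof=1) / np.sqrt(n)
        from scipy import stats

        hw = stats.t.ppf(0.975, n - 1) * sem
        ax.set_ylabel("mean z-scored classification")
    else:
        mean, hw, _ = transformed_r_ci(result.stat_map, n_for_ci)
        ax.set_ylabel("Fisher-z correlation")
    ax.fill_between(times, mean - hw, mean + hw, alpha=0.3, lw=0)
    ax.plot(times, mean, lw=1.5)
    ax.axhline(0.0, color="k", lw=0.5)
    for c in result.significant_clusters():
        (lo, hi), = [(int(m.min()), int(m.max())) for m in [np.nonzero(c.members)[0]]]
        ax.axvspan(times[lo], times[hi], color="tab:red", alpha=0.2)
    ax.set_xlabel("time relative to racket-ball contact (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_map(result: ClusterResult, path) -> None:
    """Spatial result: threshold-normalized map plus significant clusters."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    vmax = max(1.0, np.abs(result.normalized_map).max())
    im = axes[0].imshow(
        result.normalized_map, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="lower"
    )
    axes[0].set_title("statistic / cluster threshold")
    fig.colorbar(im, ax=axes[0], shrink=0.8)

    sig = np.zeros(result.stat_map.shape)
    for c in result.clusters:
        sig[c.members] = 2.0 if c.p <= result.config.alpha else 1.0
    axes[1].imshow(sig, cmap="Reds", vmin=0, vmax=2, origin="lower")
    axes[1].set_title("clusters (dark = significant)")
    for ax in axes:
        ax.set_xlabel("x (px, contact-centered)")
        ax.set_ylabel("y (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
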
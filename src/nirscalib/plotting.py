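"""Optional matplotlib views of SAD profiles and box statistics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sad import SADProfile

__all__ = ["plot_sad_curves", "plot_sad_boxes", "plot_fluence_slices"]


def plot_sad_curves(mean_profiles: dict[float, SADProfile], stagger: float = 2.0, ax=None):
    """Mean SAD vs depth, one curve per SDS, vertically staggered.

    Each successive curve is shifted up by ``stagger`` percent to avoid
    overlap; subtract the shift to read absolute values.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    reds = plt.get_cmap("Reds")
    sds_sorted = sorted(mean_profiles)
    for i, sds in enumerate(sds_sorted):
        p = mean_profiles[sds]
        ax.plot(
            p.depths,
            p.sad + i * stagger,
            color=reds(0.3 + 0.7 * i / max(1, len(sds_sorted) - 1)),
            label=f"SDS {sds:g} mm",
        )
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel(f"SAD (%) + {stagger:g}% stagger per curve")
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_sad_boxes(sad_by_sds: dict[float, np.ndarray], depth: float, ax=None):
    """Box plots of across-head SAD at one depth, one box per SDS."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sds_sorted = sorted(sad_by_sds)
    ax.boxplot(
        [np.asarray(sad_by_sds[s]) for s in sds_sorted],
        tick_labels=[f"{s:g}" for s in sds_sorted],
        whis=1.5,
    )
    ax.set_xlabel("SDS (mm)")
    ax.set_ylabel(f"SAD (%) at {depth:g} mm depth")
    return ax


def plot_fluence_slices(volume, log_floor: float = 1e-12):
    """Top and front log-scale views of a fluence volume."""
    vals = np.maximum(volume.values, log_floor)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    top = np.log10(vals[:, :, 0:3].sum(axis=2)).T
    front = np.log10(vals[:, vals.shape[1] // 2, :]).T
    for ax, img, title in ((axes[0], top, "top view"), (axes[1], front, "front view")):
        ax.imshow(img, cmap="Reds", origin="lower")
        ax.set_title(title)
    return fig
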
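"""Depth-sensitivity (SAD) profiles and summary statistics.

Sensitivity at depth is the percentage of a volume's total signal that
falls, at each 1 mm depth layer, inside a circular in-plane region of
interest (default radius 10 mm) centred on the source-detector midpoint:

    SAD(z) = 100 * sum_{(x,y) in ROI} Phi(x, y, z) / denominator

With ``normalization="volume"`` (default) the denominator is the sum over
the entire volume; with ``normalization="roi"`` it is the sum over the ROI
cylinder only, so the profile reads as the share of in-ROI signal located
at each depth and sums to exactly 100.  ROI membership is decided by
voxel-centre distance.  Depth layer ``z`` covers [z, z+1) mm from the outer
scalp surface.  SAD is invariant to global rescaling of the volume, and
under volume normalization sums to at most 100.

For probe calibration the relevant field is not the raw source fluence
(which only ever decays away from the source) but the sensitivity of the
*detected* signal to a local absorption change - the banana-shaped
source-detector path envelope.  :func:`sensitivity_volume` builds it as the
voxelwise product of the source fluence and the detector (adjoint)
fluence; in a laterally homogeneous slab the adjoint field is, by optical
reciprocity, the source field mirrored through the channel midplane, so a
single transport run suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import DetectedPhotons, FluenceVolume

__all__ = [
    "SADProfile",
    "BoxStats",
    "PathLengthHistogram",
    "compute_sad_profile",
    "sensitivity_volume",
    "mean_sad_across_heads",
    "sad_box_stats",
    "pathlength_histogram",
]


@dataclass
class SADProfile:
    """SAD percentages per 1 mm depth layer for one (head, SDS) pair."""

    head_id: str | int | None
    sds: float
    sad: np.ndarray  # (nz,) percent, indexed by integer depth in mm

    @property
    def depths(self) -> np.ndarray:
        return np.arange(self.sad.shape[0], dtype=float)

    def peak_depth(self) -> float:
        """Depth (mm) of the maximum SAD value."""
        return float(np.argmax(self.sad))


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot statistics (linear-interpolation quantiles)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class PathLengthHistogram:
    """Mean detected packet weight per path-length bin."""

    bin_edges: np.ndarray  # (n_bins + 1,) mm
    mean_weight: np.ndarray  # (n_bins,)
    counts: np.ndarray  # (n_bins,)

    def mean_path_length(self) -> float:
        """Weight-weighted mean path length over all detected packets."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        tot = (self.mean_weight * self.counts).sum()
        if tot <= 0:
            return float("nan")
        return float((centers * self.mean_weight * self.counts).sum() / tot)


def roi_mask(shape_xy: tuple[int, int], voxel_size: float, center_xy: tuple[float, float], radius: float) -> np.ndarray:
    """In-plane ROI membership by voxel-centre Euclidean distance."""
    nx, ny = shape_xy
    xc = (np.arange(nx) + 0.5) * voxel_size
    yc = (np.arange(ny) + 0.5) * voxel_size
    dx = xc[:, None] - center_xy[0]
    dy = yc[None, :] - center_xy[1]
    return dx * dx + dy * dy <= radius * radius


def sensitivity_volume(fluence: FluenceVolume) -> FluenceVolume:
    """Measurement-sensitivity (banana) field of a source-detector channel.

    Voxelwise product of the source fluence with the detector's adjoint
    fluence.  The channel midplane must be the x-centre of the domain (the
    standard symmetric placement), so the adjoint field is the source field
    mirrored in x by reciprocity.
    """
    mirrored = np.flip(fluence.values, axis=0)
    meta = dict(fluence.meta)
    meta["field"] = "sensitivity"
    return FluenceVolume(values=fluence.values * mirrored, voxel_size=fluence.voxel_size, meta=meta)


def compute_sad_profile(
    fluence: FluenceVolume,
    midpoint_xy: tuple[float, float] | None = None,
    roi_radius: float = 10.0,
    head_id=None,
    sds: float | None = None,
    normalization: str = "volume",
) -> SADProfile:
    """SAD(z) for one fluence or sensitivity volume.

    ``midpoint_xy`` defaults to the source-detector midpoint recorded in the
    volume's metadata, falling back to the plane centre.  ``normalization``
    selects the denominator: the whole volume (``"volume"``) or the ROI
    cylinder (``"roi"``).
    """
    if normalization not in ("volume", "roi"):
        raise ValueError(f"unknown normalization {normalization!r}; use 'volume' or 'roi'")
    vals = fluence.values
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("all-zero fluence volume: SAD ratio undefined")
    if midpoint_xy is None:
        meta = fluence.meta
        if "source_xy_mm" in meta and "detector_xy_mm" in meta:
            sx, sy = meta["source_xy_mm"]
            dx, dy = meta["detector_xy_mm"]
            midpoint_xy = ((sx + dx) / 2.0, (sy + dy) / 2.0)
        else:
            midpoint_xy = (
                vals.shape[0] * fluence.voxel_size / 2.0,
                vals.shape[1] * fluence.voxel_size / 2.0,
            )
    mask = roi_mask(vals.shape[:2], fluence.voxel_size, midpoint_xy, roi_radius)
    roi_sums = np.einsum("xyz,xy->z", vals, mask.astype(vals.dtype))
    denom = float(roi_sums.sum()) if normalization == "roi" else total
    if denom <= 0:
        raise ValueError("no signal inside the ROI cylinder: SAD ratio undefined")
    sad = 100.0 * roi_sums / denom
    if head_id is None:
        head_id = fluence.meta.get("head_id")
    if sds is None:
        sds = fluence.meta.get("sds_mm", float("nan"))
    return SADProfile(head_id=head_id, sds=float(sds), sad=sad)


def mean_sad_across_heads(profiles: list[SADProfile]) -> SADProfile:
    """Unweighted per-depth mean of SAD profiles sharing one SDS."""
    if not profiles:
        raise ValueError("need at least one profile")
    sds_vals = {p.sds for p in profiles}
    if len(sds_vals) != 1:
        raise ValueError(f"profiles mix several SDS values: {sorted(sds_vals)}")
    sad = np.mean([p.sad for p in profiles], axis=0)
    return SADProfile(head_id="mean", sds=profiles[0].sds, sad=sad)


def sad_box_stats(values, sds: float | None = None) -> BoxStats:
    """Box-plot statistics of SAD values across heads at a fixed depth.

    Quartiles use the linear-interpolation convention; whiskers extend to
    the most extreme data within 1.5 IQR of the quartiles, anything beyond
    is flagged as an outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 values for box statistics, got {v.size}")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def pathlength_histogram(detected: DetectedPhotons, n_bins: int = 20) -> PathLengthHistogram:
    """Histogram of mean detected packet weight vs path length.

    Uniform bins spanning [min, max] path length; each bin reports the mean
    weight of the packets it contains (weighted-packet analogue of a photon
    count vs path length histogram).
    """
    if len(detected) < 1:
        raise ValueError("no detected photons to histogram")
    L = detected.path_length
    w = detected.weight
    lo, hi = float(L.min()), float(L.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, L, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    wsum = np.bincount(idx, weights=w, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(counts > 0, wsum / np.maximum(counts, 1), 0.0)
    return PathLengthHistogram(bin_edges=edges, mean_weight=mean_w, counts=counts)
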
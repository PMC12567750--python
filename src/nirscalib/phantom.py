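"""Layered head phantoms for slab-geometry photon transport.

A phantom is an ordered stack of planar tissue slabs (scalp-muscle, cranium,
cerebrospinal fluid, brain) along the depth axis +z, with z = 0 at the outer
scalp surface.  Layer boundaries are kept *continuous* in millimetres: two of
the packaged cadaveric geometries have sub-voxel CSF layers (0.68 and 0.6 mm)
that a 1 mm label grid would destroy, and slab transport physics needs no
label volume.  The voxel grid exists only as the fluence tally raster.

The packaged eight-head thickness table (scalp-muscle, cranium, CSF measured
from cadaveric MRI; brain filling the remaining 64 mm domain) ships as a CSV
fixture and is loaded by :func:`packaged_heads`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import TISSUE_ORDER, OpticalProperties, default_optical_properties

__all__ = [
    "TissueLayer",
    "HeadPhantom",
    "build_phantom",
    "layer_at_depth",
    "thickness_summary",
    "packaged_heads",
    "load_thickness_table",
]

DEFAULT_SHAPE = (64, 64, 64)
DEFAULT_VOXEL_MM = 1.0


@dataclass(frozen=True)
class TissueLayer:
    name: str
    thickness: float  # mm, continuous (may be sub-voxel)
    props: OpticalProperties

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class HeadPhantom:
    """Planar slab stack plus the voxel raster used for fluence tallies."""

    layers: tuple[TissueLayer, ...]
    domain_shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size: float = DEFAULT_VOXEL_MM
    head_id: str | int | None = None
    z_boundaries: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        bounds = np.cumsum([lay.thickness for lay in self.layers])
        extent = self.domain_shape[2] * self.voxel_size
        if not np.isclose(bounds[-1], extent):
            raise ValueError(
                f"layer thicknesses sum to {bounds[-1]:g} mm but the domain extends {extent:g} mm"
            )
        if np.any(np.diff(bounds) <= 0):
            raise ValueError("z boundaries must be strictly increasing")
        object.__setattr__(self, "z_boundaries", tuple(float(b) for b in bounds))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size for s in self.domain_shape)

    def layer_names(self) -> tuple[str, ...]:
        return tuple(lay.name for lay in self.layers)

    def label_volume(self) -> np.ndarray:
        """Voxel label grid (value = layer index, nearest layer at voxel centers).

        Lossy for sub-voxel layers; intended only for export / visualisation.
        """
        nz = self.domain_shape[2]
        zc = (np.arange(nz) + 0.5) * self.voxel_size
        labels_z = np.searchsorted(self.z_boundaries, zc, side="right")
        labels_z = np.clip(labels_z, 0, len(self.layers) - 1)
        vol = np.broadcast_to(
            labels_z[np.newaxis, np.newaxis, :], self.domain_shape
        )
        return np.ascontiguousarray(vol, dtype=np.int16)


def build_phantom(
    scalp_mm: float,
    cranium_mm: float,
    csf_mm: float,
    domain_shape: Sequence[int] = DEFAULT_SHAPE,
    voxel_size: float = DEFAULT_VOXEL_MM,
    properties: dict[str, OpticalProperties] | None = None,
    head_id: str | int | None = None,
) -> HeadPhantom:
    """Build a four-layer head phantom; brain fills the remaining depth.

    Raises
    ------
    ValueError
        If any thickness is non-positive or the non-brain layers fill (or
        exceed) the z-extent of the domain.
    """
    props = properties if properties is not None else default_optical_properties()
    thick = {"scalp_muscle": scalp_mm, "cranium": cranium_mm, "csf": csf_mm}
    for name, t in thick.items():
        if t <= 0:
            raise ValueError(f"{name} thickness must be > 0, got {t}")
    extent = domain_shape[2] * voxel_size
    brain_mm = extent - (scalp_mm + cranium_mm + csf_mm)
    if brain_mm <= 0:
        raise ValueError(
            f"scalp+cranium+CSF = {scalp_mm + cranium_mm + csf_mm:g} mm leaves no room "
            f"for brain in a {extent:g} mm domain"
        )
    thick["brain"] = brain_mm
    layers = tuple(TissueLayer(name, thick[name], props[name]) for name in TISSUE_ORDER)
    return HeadPhantom(
        layers=layers,
        domain_shape=tuple(int(s) for s in domain_shape),
        voxel_size=float(voxel_size),
        head_id=head_id,
    )


def layer_at_depth(phantom: HeadPhantom, z_mm: float) -> str:
    """Name of the layer containing depth ``z_mm``.

    Layers occupy half-open intervals [lower, upper): a point exactly on a
    boundary belongs to the deeper layer.
    """
    extent = phantom.extent_mm[2]
    if not 0 <= z_mm < extent:
        raise ValueError(f"depth {z_mm} mm outside domain [0, {extent:g}) mm")
    idx = int(np.searchsorted(phantom.z_boundaries, z_mm, side="right"))
    idx = min(idx, len(phantom.layers) - 1)
    return phantom.layers[idx].name


def load_thickness_table(path) -> pd.DataFrame:
    """Read a head-thickness CSV (`head,scalp_muscle_mm,cranium_mm,csf_mm`)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed thickness table {path}: {exc}") from exc
    required = {"head", "scalp_muscle_mm", "cranium_mm", "csf_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"thickness table {path} missing columns: {sorted(missing)}")
    return df


def packaged_heads() -> pd.DataFrame:
    """The eight packaged cadaveric head geometries, brain column included.

    Brain thickness is derived as 64 mm minus the measured layers, so every
    row sums exactly to the 64 mm domain extent.
    """
    with resources.files("nirscalib.data").joinpath("head_thicknesses.csv").open() as fh:
        df = pd.read_csv(fh)
    df["brain_mm"] = 64.0 - df[["scalp_muscle_mm", "cranium_mm", "csf_mm"]].sum(axis=1)
    return df


def build_packaged_phantom(head: int, **kwargs) -> HeadPhantom:
    """Build the phantom for packaged head ``head`` (1-based id)."""
    table = packaged_heads().set_index("head")
    if head not in table.index:
        raise KeyError(f"no packaged head {head!r}; available: {list(table.index)}")
    row = table.loc[head]
    return build_phantom(
        row["scalp_muscle_mm"], row["cranium_mm"], row["csf_mm"], head_id=head, **kwargs
    )


def thickness_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-layer mean and sample (n-1) standard deviation, rounded to 2 dp.

    Accepts the thickness table (with or without a brain column; the brain
    column is derived if absent) and returns a DataFrame indexed by layer
    with ``mean`` and ``std`` columns.
    """
    if len(table) < 2:
        raise ValueError(f"need >= 2 heads to summarise, got {len(table)}")
    df = table.copy()
    if "brain_mm" not in df.columns:
        df["brain_mm"] = 64.0 - df[["scalp_muscle_mm", "cranium_mm", "csf_mm"]].sum(axis=1)
    cols = ["scalp_muscle_mm", "cranium_mm", "csf_mm", "brain_mm"]
    out = pd.DataFrame(
        {
            "mean": df[cols].mean().round(2),
            "std": df[cols].std(ddof=1).round(2),
        }
    )
    out.index = [c.removesuffix("_mm") for c in cols]
    out.index.name = "layer"
    return out


def to_nifti(phantom: HeadPhantom):
    """Export the phantom label volume as a NIfTI-1 image (voxel = layer index)."""
    import nibabel as nib

    affine = np.diag([phantom.voxel_size] * 3 + [1.0])
    return nib.Nifti1Image(phantom.label_volume().astype(np.int16), affine)
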
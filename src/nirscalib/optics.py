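"""Tissue optical properties for near-infrared photon transport.

Each head layer is described by four wavelength-specific constants: the
absorption coefficient ``mu_a`` (mm^-1), the scattering coefficient ``mu_s``
(mm^-1), the Henyey-Greenstein anisotropy factor ``g`` (mean cosine of the
single-scattering angle) and the refractive index ``n``.  The packaged
default set is a literature compilation at 735 nm for the four tissue
layers of a layered head model plus the exterior void.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

__all__ = ["OpticalProperties", "default_optical_properties", "load_optical_properties"]

#: canonical layer order along +z (depth into the head)
TISSUE_ORDER = ("scalp_muscle", "cranium", "csf", "brain")


@dataclass(frozen=True)
class OpticalProperties:
    """Optical constants of one homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient in mm^-1, >= 0.
    mu_s : float
        Scattering coefficient in mm^-1, >= 0.
    g : float
        Scattering anisotropy factor, -1 < g < 1; g = 0 is isotropic.
    n : float
        Refractive index; 1 for void, >= 1 for tissue.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1 < self.g < 1:
            raise ValueError(f"anisotropy g must satisfy -1 < g < 1, got {self.g}")
        if self.n < 1:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / mu_t (0 for a void medium)."""
        mt = self.mu_t
        return self.mu_s / mt if mt > 0 else 0.0


def _parse_table(raw: Mapping) -> dict[str, OpticalProperties]:
    layers = raw["layers"] if "layers" in raw else raw
    return {name: OpticalProperties(**vals) for name, vals in layers.items()}


def default_optical_properties() -> dict[str, OpticalProperties]:
    """Return the packaged 735 nm optical-property set.

    Covers ``void``, ``scalp_muscle``, ``cranium``, ``csf`` and ``brain``.
    """
    text = resources.files("nirscalib.data").joinpath("optical_properties.json").read_text()
    return _parse_table(json.loads(text))


def load_optical_properties(path) -> dict[str, OpticalProperties]:
    """Load a layer -> optical-property map from a JSON file.

    The file holds either a bare ``{layer: {mu_a, mu_s, g, n}}`` map or an
    object with a ``layers`` key in the same shape as the packaged default.
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed optical-property JSON {path}: {exc}") from exc
    return _parse_table(raw)
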
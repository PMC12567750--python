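"""Bidirectional probe calibration from a fitted depth-sensitivity surrogate.

Two query modes mirror how an experimenter plans an fNIRS montage:

* ``sds_for_depth`` — given a target cortical depth, recommend the
  source-detector separation achieving each requested sensitivity level
  (percent SAD).  The predicted SAD(SDS) curve at that depth is scanned on
  a 0.1 mm grid over the supported separation range; the first crossing of
  each level is refined by bisection to 0.01 mm and reported at 0.1 mm
  precision.  When a curve crosses a level more than once the smallest
  separation is reported (it favours signal strength, since larger
  separations cost source power).
* ``depth_for_sds`` — given a separation, report the deepest depth still
  achieving each level, so sensitivity at the target depth is guaranteed.

A level is infeasible when the predicted SAD never reaches it anywhere on
the scanned grid; feasible levels always form a downward-closed set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surrogate import DEPTH_RANGE, SDS_RANGE

__all__ = [
    "CalibrationQuery",
    "LevelResult",
    "CalibrationReport",
    "sds_for_depth",
    "depth_for_sds",
    "feasibility",
]

DEFAULT_LEVELS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
_GRID_STEP = 0.1  # mm scan resolution
_BISECT_TOL = 0.01  # mm refinement tolerance


@dataclass(frozen=True)
class CalibrationQuery:
    mode: str  # "sds_from_depth" | "depth_from_sds"
    value: float  # mm
    levels: tuple[float, ...] = DEFAULT_LEVELS


@dataclass(frozen=True)
class LevelResult:
    level: float  # % SAD
    feasible: bool
    recommended_mm: float | None  # 0.1 mm precision; None if infeasible
    predicted_sad: float | None = None
    sad_std: float | None = None  # advisory GPR posterior std, if available


@dataclass
class CalibrationReport:
    query: CalibrationQuery
    results: list[LevelResult]
    model_kind: str
    provenance: dict = field(default_factory=dict)

    def feasible_levels(self) -> list[float]:
        return [r.level for r in self.results if r.feasible]

    def max_feasible_level(self) -> float | None:
        feas = self.feasible_levels()
        return max(feas) if feas else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_pct": [r.level for r in self.results],
                "recommended_mm": [r.recommended_mm for r in self.results],
                "feasible": [r.feasible for r in self.results],
            }
        )

    def __str__(self) -> str:
        unit = "SDS" if self.query.mode == "sds_from_depth" else "depth"
        hdr = f"{self.query.mode} @ {self.query.value:g} mm ({self.model_kind.upper()} surrogate)"
        lines = [hdr, f"{'SAD level (%)':>14} {unit + ' (mm)':>12}"]
        for r in sorted(self.results, key=lambda r: -r.level):
            val = f"{r.recommended_mm:.1f}" if r.feasible else "-"
            lines.append(f"{r.level:>14g} {val:>12}")
        return "\n".join(lines)


def _check_levels(levels, level_bounds):
    if levels is None:
        levels = DEFAULT_LEVELS
    lo, hi = level_bounds
    for lv in levels:
        if not lo <= lv <= hi:
            raise ValueError(f"SAD level {lv}% outside the allowed range [{lo:g}, {hi:g}]%")
    return tuple(float(lv) for lv in levels)


def _predict_curve(results, var_grid, fixed, axis):
    if axis == "sds":
        return results.predict(var_grid, np.full_like(var_grid, fixed))
    return results.predict(np.full_like(var_grid, fixed), var_grid)


def _bisect_crossing(predict, lo, hi, level, increasing: bool) -> float:
    """Refine the point where the prediction crosses ``level`` in (lo, hi)."""
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        above = predict(mid) >= level
        if above == increasing:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def sds_for_depth(
    results,
    depth: float,
    levels=None,
    sds_range=SDS_RANGE,
    depth_range=DEPTH_RANGE,
    level_bounds=(1.0, 6.0),
) -> CalibrationReport:
    """Recommend separations reaching each SAD level at a target depth."""
    lo_d, hi_d = depth_range
    if not lo_d <= depth <= hi_d:
        raise ValueError(f"depth {depth} mm outside supported range [{lo_d:g}, {hi_d:g}] mm")
    levels = _check_levels(levels, level_bounds)
    lo, hi = sds_range
    grid = np.round(np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP), 6)
    curve = _predict_curve(results, grid, depth, "sds")
    out = []
    for lv in levels:
        if curve.max() < lv:
            out.append(LevelResult(level=lv, feasible=False, recommended_mm=None))
            continue
        idx = int(np.argmax(curve >= lv))  # smallest grid point at/above the level
        if idx == 0:
            sds_star = grid[0]
        else:
            sds_star = _bisect_crossing(
                lambda s: results.predict(s, depth), grid[idx - 1], grid[idx], lv, increasing=True
            )
        sds_star = round(sds_star, 1)
        if hasattr(results, "kind") and results.kind == "gpr":
            mu, sd = results.predict(sds_star, depth, return_std=True)
        else:
            mu, sd = results.predict(sds_star, depth), None
        out.append(
            LevelResult(level=lv, feasible=True, recommended_mm=sds_star, predicted_sad=mu, sad_std=sd)
        )
    return CalibrationReport(
        query=CalibrationQuery("sds_from_depth", float(depth), levels),
        results=out,
        model_kind=getattr(results, "kind", "unknown"),
    )


def depth_for_sds(
    results,
    sds: float,
    levels=None,
    sds_range=SDS_RANGE,
    depth_range=DEPTH_RANGE,
    level_bounds=(1.0, 6.0),
) -> CalibrationReport:
    """Deepest depth still achieving each SAD level at a given separation."""
    lo_s, hi_s = sds_range
    if not lo_s <= sds <= hi_s:
        raise ValueError(f"sds {sds} mm outside supported range [{lo_s:g}, {hi_s:g}] mm")
    levels = _check_levels(levels, level_bounds)
    lo, hi = depth_range
    grid = np.round(np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP), 6)
    curve = _predict_curve(results, grid, sds, "depth")
    out = []
    for lv in levels:
        qualifying = np.nonzero(curve >= lv)[0]
        if qualifying.size == 0:
            out.append(LevelResult(level=lv, feasible=False, recommended_mm=None))
            continue
        idx = int(qualifying[-1])  # deepest grid point still achieving the level
        if idx == len(grid) - 1:
            depth_star = grid[-1]
        else:
            # SAD decreases past the deepest qualifying point; refine the drop
            depth_star = _bisect_crossing(
                lambda d: results.predict(sds, d), grid[idx], grid[idx + 1], lv, increasing=False
            )
        depth_star = round(depth_star, 1)
        if hasattr(results, "kind") and results.kind == "gpr":
            mu, sd = results.predict(sds, depth_star, return_std=True)
        else:
            mu, sd = results.predict(sds, depth_star), None
        out.append(
            LevelResult(level=lv, feasible=True, recommended_mm=depth_star, predicted_sad=mu, sad_std=sd)
        )
    return CalibrationReport(
        query=CalibrationQuery("depth_from_sds", float(sds), levels),
        results=out,
        model_kind=getattr(results, "kind", "unknown"),
    )


def prediction_surface(
    results,
    sds_step: float = 0.5,
    depth_step: float = 0.5,
    sds_range=SDS_RANGE,
    depth_range=DEPTH_RANGE,
) -> pd.DataFrame:
    """Gridded (sds, depth, predicted SAD) surface for plotting/export."""
    sds = np.round(np.arange(sds_range[0], sds_range[1] + sds_step / 2, sds_step), 6)
    depth = np.round(np.arange(depth_range[0], depth_range[1] + depth_step / 2, depth_step), 6)
    S, D = np.meshgrid(sds, depth, indexing="ij")
    pred = results.predict(S.ravel(), D.ravel())
    return pd.DataFrame({"sds_mm": S.ravel(), "depth_mm": D.ravel(), "sad_pct": pred})


def feasibility(
    results,
    depth: float,
    level: float,
    sds_range=SDS_RANGE,
    depth_range=DEPTH_RANGE,
) -> bool:
    """True iff the predicted SAD reaches ``level`` for some separation."""
    lo_d, hi_d = depth_range
    if not lo_d <= depth <= hi_d:
        raise ValueError(f"depth {depth} mm outside supported range [{lo_d:g}, {hi_d:g}] mm")
    lo, hi = sds_range
    grid = np.round(np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP), 6)
    curve = _predict_curve(results, grid, depth, "sds")
    return bool(curve.max() >= level)
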
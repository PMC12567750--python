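"""File formats: SAD tables, fluence volumes, detected-photon records.

Formats are deliberately plain: CSV for tabular data, NIfTI-1 plus a JSON
sidecar for fluence volumes, JSON Lines for per-photon detector records.
All round-trips are lossless to the declared precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sad import SADProfile
from .transport import DetectedPhotons, FluenceVolume

__all__ = [
    "write_sad_table",
    "read_sad_table",
    "profiles_to_table",
    "write_fluence_nifti",
    "read_fluence_nifti",
    "write_detected_jsonl",
    "read_detected_jsonl",
]

SAD_COLUMNS = ["head", "sds_mm", "depth_mm", "sad_pct"]


def profiles_to_table(profiles: list[SADProfile]) -> pd.DataFrame:
    """Stack SAD profiles into a long-format `head,sds_mm,depth_mm,sad_pct` table."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "head": p.head_id,
                    "sds_mm": p.sds,
                    "depth_mm": p.depths.astype(int),
                    "sad_pct": p.sad,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_sad_table(profiles_or_df, path) -> None:
    df = profiles_or_df if isinstance(profiles_or_df, pd.DataFrame) else profiles_to_table(profiles_or_df)
    df.to_csv(path, index=False, float_format="%.10g")


def read_sad_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed SAD table {path}: {exc}") from exc
    missing = set(SAD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SAD table {path} missing columns: {sorted(missing)}")
    return df


def table_to_profiles(df: pd.DataFrame) -> list[SADProfile]:
    """Inverse of :func:`profiles_to_table`."""
    out = []
    for (head, sds), grp in df.groupby(["head", "sds_mm"], sort=True):
        grp = grp.sort_values("depth_mm")
        out.append(SADProfile(head_id=head, sds=float(sds), sad=grp["sad_pct"].to_numpy()))
    return out


def write_fluence_nifti(vol: FluenceVolume, path) -> None:
    """Write a fluence volume as NIfTI-1 with a JSON config sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.values, affine), path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(vol.meta, fh, indent=1, default=lambda o: o.item() if hasattr(o, "item") else str(o))


def read_fluence_nifti(path) -> FluenceVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    voxel = float(img.affine[0, 0])
    return FluenceVolume(values=np.asarray(img.dataobj, dtype=np.float64), voxel_size=voxel, meta=meta)


def write_detected_jsonl(detected: DetectedPhotons, path) -> None:
    """One JSON object per detected photon packet."""
    with open(path, "w") as fh:
        for i in range(len(detected)):
            rec = {
                "weight": float(detected.weight[i]),
                "path_length_mm": float(detected.path_length[i]),
                "exit_x_mm": float(detected.exit_x[i]),
                "exit_y_mm": float(detected.exit_y[i]),
            }
            fh.write(json.dumps(rec) + "\n")


def read_detected_jsonl(path) -> DetectedPhotons:
    w, L, xs, ys = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                w.append(rec["weight"])
                L.append(rec["path_length_mm"])
                xs.append(rec["exit_x_mm"])
                ys.append(rec["exit_y_mm"])
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"malformed detected-photon record at {path}:{lineno}: {exc}") from exc
    return DetectedPhotons(w, L, xs, ys)
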
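"""Reading and writing the pipeline's on-disk formats.

Cine series and field-map volumes travel as NIfTI-1 (spacing and frame
period in the header pixdims); motion traces and landmark tables as CSV;
configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import PLANE_AXES, CineSeries, FieldMapVolume, LandmarkTrack, MotionTrace


def save_cine(cine: CineSeries, path) -> None:
    """Write a cine as a (H, W, T) NIfTI-1 with pixdim = (px, px, dt_ms)."""
    data = np.moveaxis(cine.frames, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), affine=np.diag(
        [cine.pixel_mm[0], cine.pixel_mm[1], 1.0, 1.0]))
    img.header["pixdim"][1:4] = [cine.pixel_mm[0], cine.pixel_mm[1], cine.dt_ms]
    img.header["descrip"] = f"{cine.orientation};t0={cine.t0_ms};slice={cine.slice_mm}".encode()
    nib.save(img, str(path))


def load_cine(path, orientation: str = "coronal") -> CineSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    px = (float(img.header["pixdim"][1]), float(img.header["pixdim"][2]))
    dt = float(img.header["pixdim"][3])
    desc = bytes(img.header["descrip"]).decode(errors="ignore")
    t0, slice_mm = 0.0, 10.0
    for token in desc.strip("\x00").split(";"):
        if token.startswith("t0="):
            t0 = float(token[3:])
        elif token.startswith("slice="):
            slice_mm = float(token[6:])
        elif token in PLANE_AXES:
            orientation = token
    return CineSeries(
        frames=np.moveaxis(data, -1, 0), pixel_mm=px, slice_mm=slice_mm,
        dt_ms=dt if dt > 0 else 1.0, orientation=orientation,
        axes=PLANE_AXES[orientation], t0_ms=t0,
    )


def save_fieldmap(fm: FieldMapVolume, path_prefix) -> None:
    """Write magnitude/phase volumes as ``<prefix>_{mag,ph1,ph2}.nii``."""
    prefix = Path(path_prefix)
    affine = np.diag([*fm.voxel_mm, 1.0])
    for suffix, vol in (("mag", fm.magnitude), ("ph1", fm.phase_te1),
                        ("ph2", fm.phase_te2)):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 str(prefix) + f"_{suffix}.nii")


def save_field(field, path) -> None:
    """Write a deformation field as a 2-channel (H, W, 1, 2) NIfTI-1,
    displacements in mm."""
    data = np.moveaxis(field.u_mm(), 0, -1)[:, :, None, :]
    affine = np.diag([field.spacing_mm[0], field.spacing_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_field(path):
    from .containers import DeformationField
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)[:, :, 0, :]
    spacing = (float(img.affine[0, 0]), float(img.affine[1, 1]))
    u_px = np.moveaxis(data, -1, 0) / np.asarray(spacing)[:, None, None]
    return DeformationField(u_px, spacing)


def save_trace(trace: MotionTrace, path) -> None:
    """Trace as CSV: frame, t_ms, one ``<axis>_mm`` column per axis, valid."""
    df = pd.DataFrame({"frame": np.arange(len(trace)), "t_ms": trace.t_ms})
    for i, ax in enumerate(trace.axes):
        df[f"{ax}_mm"] = trace.pos_mm[:, i]
    df["valid"] = trace.valid.astype(int)
    df.to_csv(path, index=False)


def load_trace(path, source: str = "image_derived") -> MotionTrace:
    df = pd.read_csv(path)
    axes = tuple(c[:-3] for c in df.columns if c.endswith("_mm"))
    pos = df[[f"{ax}_mm" for ax in axes]].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool) if "valid" in df else None
    return MotionTrace(df["t_ms"].to_numpy(dtype=float), pos, axes, source, valid)


def save_landmarks(tracks: list, path) -> None:
    """Landmark tracks as CSV: frame, name, row_mm, col_mm, valid."""
    rows = []
    for lm in tracks:
        for k in range(lm.t_ms.size):
            rows.append({
                "frame": k, "name": lm.name, "t_ms": lm.t_ms[k],
                "row_mm": lm.pos_mm[k, 0], "col_mm": lm.pos_mm[k, 1],
                "valid": int(lm.valid[k]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_landmarks(path, axes=("HF", "RL")) -> list:
    df = pd.read_csv(path)
    tracks = []
    for name, grp in df.groupby("name", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(LandmarkTrack(
            name=str(name), t_ms=grp["t_ms"].to_numpy(dtype=float),
            pos_mm=grp[["row_mm", "col_mm"]].to_numpy(dtype=float),
            axes=tuple(axes), valid=grp["valid"].to_numpy(dtype=bool),
        ))
    return tracks


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
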
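"""File formats: NIfTI volumes and masks, CSV measurement tables, JSON models.

This is the only module that touches the filesystem. Volumes are stored as
signed 16-bit NIfTI with unit scaling (HU are integers on disk, clamped to
the valid CT range), masks as uint8 {0, 1}; measurement tables are CSV;
fitted models, series manifests and FFD transforms are JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTVolume, Measurement, QCFlag
from .errors import PmctseqError
from .pmi import LinearFit
from .register import FFDTransform

_TIME_RE = re.compile(r"_t(\d+(?:\.\d+)?)(?:h)?\.nii(?:\.gz)?$")


@dataclass
class SeriesManifest:
    """Order and location of the acquisitions of one case."""

    case_id: str
    entries: list[tuple[float, str, str | None]]  # (time_h, image_path, mask_path)

    def __post_init__(self) -> None:
        times = [e[0] for e in self.entries]
        if sorted(set(times)) != times:
            raise ValueError("manifest entries must be sorted by unique time_h")


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(vol: CTVolume, path) -> None:
    """Write a CTVolume as int16 NIfTI (HU, unit slope, clamped to CT range)."""
    data = np.clip(np.rint(vol.voxels), -1024, 3071).astype(np.int16)
    img = nib.Nifti1Image(data, _affine(vol.spacing_mm))
    img.header.set_zooms(vol.spacing_mm)
    img.header["descrip"] = f"time_h={vol.time_h:g}".encode()
    nib.save(img, str(path))


def read_volume(path, time_h: float | None = None) -> CTVolume:
    """Read a 3D NIfTI into a CTVolume.

    The acquisition time is taken from the argument when given, else parsed
    from a ``_t<hours>`` filename token or the header description, else 0.
    """
    path = Path(path)
    if not path.exists():
        raise PmctseqError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise PmctseqError(f"cannot read {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise PmctseqError(f"expected a 3D image, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise PmctseqError(f"missing or invalid voxel spacing in {path}")
    if time_h is None:
        m = _TIME_RE.search(path.name)
        if m:
            time_h = float(m.group(1))
        else:
            d = re.search(rb"time_h=([\d.]+)", bytes(img.header["descrip"]))
            time_h = float(d.group(1)) if d else 0.0
    return CTVolume(np.asarray(data, dtype=np.float32), tuple(float(z) for z in zooms), time_h)


def write_mask(mask: np.ndarray, spacing_mm, path) -> None:
    """Write a binary (or small-label) mask as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise PmctseqError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise PmctseqError(f"expected a 3D mask, got {data.ndim}D in {path}")
    return data.astype(np.uint8), tuple(float(z) for z in img.header.get_zooms()[:3])


_MEAS_COLUMNS = ["time_h", "volume_ml", "mean_hu", "voxel_count", "qc_flag"]


def write_measurements(rows, path) -> None:
    df = pd.DataFrame(
        [
            {
                "time_h": m.time_h,
                "volume_ml": m.volume_ml,
                "mean_hu": m.mean_hu,
                "voxel_count": m.voxel_count,
                "qc_flag": m.qc_flag.value,
            }
            for m in rows
        ],
        columns=_MEAS_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_measurements(path) -> list[Measurement]:
    df = pd.read_csv(path)
    missing = set(_MEAS_COLUMNS) - set(df.columns)
    if missing:
        raise PmctseqError(f"measurement table missing columns: {sorted(missing)}")
    return [
        Measurement(
            float(r.time_h),
            float(r.volume_ml),
            float(r.mean_hu),
            int(r.voxel_count),
            QCFlag(r.qc_flag),
        )
        for r in df.itertuples()
    ]


def write_manifest(manifest: SeriesManifest, path) -> None:
    payload = {
        "case_id": manifest.case_id,
        "entries": [
            {"time_h": t, "image": img, "mask": msk} for t, img, msk in manifest.entries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path) -> SeriesManifest:
    payload = json.loads(Path(path).read_text())
    entries = [
        (float(e["time_h"]), e["image"], e.get("mask")) for e in payload["entries"]
    ]
    return SeriesManifest(case_id=payload["case_id"], entries=entries)


def write_model(fits, path, notes: str | None = None) -> None:
    """Serialize one or more LinearFits keyed by quantity."""
    if isinstance(fits, LinearFit):
        fits = [fits]
    payload = {
        f.quantity: {
            "slope": f.slope,
            "intercept": f.intercept,
            "slope_se": f.slope_se,
            "r2": f.r2,
            "n": f.n,
        }
        for f in fits
    }
    if notes:
        payload["notes"] = notes
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> dict[str, LinearFit]:
    payload = json.loads(Path(path).read_text())
    return {
        q: LinearFit(d["slope"], d["intercept"], d["slope_se"], d["r2"], d["n"], q)
        for q, d in payload.items()
        if q in ("volume", "hu")
    }


def write_transform(transform: FFDTransform, path) -> None:
    payload = {
        "control_grid_spacing_mm": list(transform.control_grid_spacing_mm),
        "displacements": np.asarray(transform.displacements).tolist(),
        "image_shape": list(transform.image_shape),
        "image_spacing_mm": list(transform.image_spacing_mm),
    }
    Path(path).write_text(json.dumps(payload))


def read_transform(path) -> FFDTransform:
    d = json.loads(Path(path).read_text())
    return FFDTransform(
        control_grid_spacing_mm=tuple(d["control_grid_spacing_mm"]),
        displacements=np.asarray(d["displacements"], dtype=float),
        image_shape=tuple(int(n) for n in d["image_shape"]),
        image_spacing_mm=tuple(d["image_spacing_mm"]),
    )
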
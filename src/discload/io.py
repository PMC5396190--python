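"""File formats: accelerometer CSV, echo-stack NIfTI + manifest, tidy tables.

Accelerometer traces travel as CSV with an ISO-8601 ``timestamp`` column
and ``x,y,z`` columns in g; readers insist on strictly uniform sampling
(any gap is an error naming the first bad line).  Echo stacks are written
as one NIfTI file per echo plus a label-mask NIfTI and a JSON manifest
carrying echo times, pixel geometry, seed and, for phantoms, the ground
truth.  Every CSV writer/reader pair round-trips losslessly to float
precision.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .actigraphy import AccelRecording, MADHistogram
from .relaxometry import EchoStack, T2Map

__all__ = [
    "write_accel_csv",
    "read_accel_csv",
    "write_echo_stack",
    "read_echo_stack",
    "write_t2_map",
    "write_histogram_csv",
    "read_histogram_csv",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


def write_accel_csv(rec: AccelRecording, path) -> Path:
    """Write a recording as timestamp,x,y,z rows (g units in the header)."""
    path = Path(path)
    t = pd.to_datetime(rec.start) + pd.to_timedelta(
        np.arange(rec.n_samples) / rec.fs_hz, unit="s"
    )
    df = pd.DataFrame(
        {
            "timestamp": t.strftime(_TS_FORMAT),
            "x_g": rec.xyz[:, 0],
            "y_g": rec.xyz[:, 1],
            "z_g": rec.xyz[:, 2],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_accel_csv(path, fs_hz: float | None = None) -> AccelRecording:
    """Read a triaxial CSV back into an :class:`AccelRecording`.

    Accepts either the package's ``timestamp,x_g,y_g,z_g`` schema or plain
    ``x,y,z`` columns with an explicit ``fs_hz``.  Non-monotone or gappy
    timestamps raise with the first offending line number (1-based,
    counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "timestamp" in cols:
        ts = pd.to_datetime(df[cols["timestamp"]])
        dt = ts.diff().dt.total_seconds().to_numpy()[1:]
        if np.any(dt <= 0):
            line = int(np.nonzero(dt <= 0)[0][0]) + 3  # +1 header +1 diff +1 base
            raise ValueError(f"{path}: non-monotone timestamp at line {line}")
        step = np.median(dt)
        bad = np.nonzero(np.abs(dt - step) > 0.01 * step)[0]
        if bad.size:
            raise ValueError(
                f"{path}: timestamp gap at line {int(bad[0]) + 3} "
                f"(expected {step:.6f} s steps)"
            )
        fs = 1.0 / step
        start = ts.iloc[0].to_pydatetime()
    else:
        if fs_hz is None:
            raise ValueError("plain x,y,z CSV needs an explicit sampling rate")
        fs = fs_hz
        start = datetime(2020, 1, 6, 6, 0, 0)
    try:
        xyz = np.column_stack(
            [
                df[cols.get("x_g", cols.get("x"))].to_numpy(dtype=float),
                df[cols.get("y_g", cols.get("y"))].to_numpy(dtype=float),
                df[cols.get("z_g", cols.get("z"))].to_numpy(dtype=float),
            ]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing axis columns (need x,y,z)") from exc
    if not np.all(np.isfinite(xyz)):
        line = int(np.nonzero(~np.isfinite(xyz).all(axis=1))[0][0]) + 2
        raise ValueError(f"{path}: non-finite sample at line {line}")
    return AccelRecording(start=start, fs_hz=fs, xyz=xyz)


def _nifti_affine(pixel_size_mm: float, slice_spacing_mm: float) -> np.ndarray:
    return np.diag([slice_spacing_mm, pixel_size_mm, pixel_size_mm, 1.0])


def write_echo_stack(
    stack: EchoStack,
    outdir,
    label_map: np.ndarray | None = None,
    ground_truth: list[dict] | None = None,
    seed: int | None = None,
) -> Path:
    """Write one NIfTI per echo (+ optional label mask) and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = _nifti_affine(stack.pixel_size_mm, stack.slice_spacing_mm)
    echo_files = []
    for i, te in enumerate(stack.echo_times_ms):
        fname = f"echo_{i:02d}.nii.gz"
        nib.save(nib.Nifti1Image(stack.images[i].astype(np.float32), affine), outdir / fname)
        echo_files.append(fname)
    manifest = {
        "echo_files": echo_files,
        "echo_times_ms": [float(t) for t in stack.echo_times_ms],
        "pixel_size_mm": stack.pixel_size_mm,
        "slice_spacing_mm": stack.slice_spacing_mm,
    }
    if label_map is not None:
        nib.save(
            nib.Nifti1Image(label_map.astype(np.int16), affine), outdir / "labels.nii.gz"
        )
        manifest["label_file"] = "labels.nii.gz"
    if ground_truth is not None:
        manifest["ground_truth"] = ground_truth
    if seed is not None:
        manifest["seed"] = seed
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_echo_stack(manifest_path) -> tuple[EchoStack, np.ndarray | None, dict]:
    """Load a stack from its manifest: (stack, label map or None, manifest)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    missing = [f for f in manifest["echo_files"] if not (root / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"echo stack at {root} is missing echo files: {', '.join(missing)}"
        )
    images = np.stack(
        [np.asarray(nib.load(root / f).dataobj, dtype=float) for f in manifest["echo_files"]]
    )
    stack = EchoStack(
        images=images,
        echo_times_ms=np.asarray(manifest["echo_times_ms"], dtype=float),
        pixel_size_mm=manifest["pixel_size_mm"],
        slice_spacing_mm=manifest["slice_spacing_mm"],
    )
    labels = None
    if manifest.get("label_file"):
        labels = np.asarray(nib.load(root / manifest["label_file"]).dataobj, dtype=int)
    return stack, labels, manifest


def write_t2_map(t2map: T2Map, stack: EchoStack, path) -> Path:
    """T2 map (ms; NaN outside the mask / invalid fits) in stack geometry."""
    path = Path(path)
    affine = _nifti_affine(stack.pixel_size_mm, stack.slice_spacing_mm)
    nib.save(nib.Nifti1Image(t2map.t2_ms.astype(np.float32), affine), path)
    return path


def write_histogram_csv(hist: MADHistogram, path) -> Path:
    """98-row histogram table: bin_low_g, bin_high_g, mean_epochs_per_day."""
    path = Path(path)
    pd.DataFrame(
        {
            "bin_low_g": hist.bin_edges_g[:-1],
            "bin_high_g": hist.bin_edges_g[1:],
            "mean_epochs_per_day": hist.mean_epochs_per_day,
            "total_epochs": hist.total_counts,
        }
    ).to_csv(path, index=False)
    return path


def read_histogram_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
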
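"""TIFF stack and measurement-table I/O.

Stacks are stored one channel per file as multi-page TIFF z-stacks,
16-bit unsigned preferred. Voxel sizes travel in ImageJ-style metadata
(XResolution/YResolution tags for the lateral spacing, the ImageJ
``spacing`` field for the axial step, both in micrometres); an explicit
:class:`~telofish.stacks.VoxelSize` passed by the caller always wins over
embedded metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

from .stacks import ImageStack, VoxelSize

__all__ = [
    "read_stack",
    "write_stack",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

#: Column schema of the measurements table, one row per accepted telomere.
MEASUREMENT_COLUMNS = [
    "sample_id",
    "nucleus_id",
    "spot_id",
    "x_nm",
    "y_nm",
    "z_nm",
    "z_plane",
    "amplitude_counts",
    "r_squared",
    "fit_axis",
    "accepted",
]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to an ImageJ-flavoured TIFF with voxel-size metadata."""
    vs = stack.voxel_size
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1e3 / vs.dx_nm, 1e3 / vs.dy_nm),
        metadata={"spacing": vs.dz_nm / 1e3, "unit": "um", "axes": "ZYX"},
    )


def _voxel_size_from_tiff(tf: tifffile.TiffFile) -> Optional[VoxelSize]:
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    meta = tf.imagej_metadata or {}
    spacing_um = meta.get("spacing")
    if xres is None or yres is None or spacing_um is None:
        return None
    # resolution tags are rationals in pixels per unit (here, per micrometre)
    xr = xres.value[0] / xres.value[1]
    yr = yres.value[0] / yres.value[1]
    if xr <= 0 or yr <= 0 or spacing_um <= 0:
        return None
    return VoxelSize(dx_nm=1e3 / xr, dy_nm=1e3 / yr, dz_nm=float(spacing_um) * 1e3)


def read_stack(
    path: str | Path,
    channel_name: str = "telomere",
    voxel_size: Optional[VoxelSize] = None,
) -> ImageStack:
    """Read a TIFF z-stack into an :class:`ImageStack`.

    Integer pixel types are preserved losslessly. The voxel size is taken
    from ``voxel_size`` if given, otherwise from embedded ImageJ metadata;
    if neither is available an explicit error is raised rather than a
    silent default being applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        embedded = _voxel_size_from_tiff(tf)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {data.shape}")
    vs = voxel_size or embedded
    if vs is None:
        raise ValueError(
            f"{path}: voxel size missing — no XResolution/YResolution/spacing metadata "
            "in the TIFF and no voxel_size override was supplied"
        )
    return ImageStack(voxels=data, voxel_size=vs, channel_name=channel_name)


def measurements_to_frame(measurements: Iterable, sample_id: str = "") -> pd.DataFrame:
    """Flatten :class:`~telofish.detect.TelomereMeasurement` objects to a table."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "sample_id": getattr(m, "sample_id", "") or sample_id,
                "nucleus_id": m.spot.nucleus_label,
                "spot_id": m.spot_id,
                "x_nm": m.spot.center_of_mass_nm[2],
                "y_nm": m.spot.center_of_mass_nm[1],
                "z_nm": m.spot.center_of_mass_nm[0],
                "z_plane": m.z_plane,
                "amplitude_counts": m.brightness_counts,
                "r_squared": m.best_fit.r_squared,
                "fit_axis": m.best_fit.axis,
                "accepted": m.accepted,
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(measurements: Iterable, path: str | Path, sample_id: str = "") -> pd.DataFrame:
    """Write accepted-and-rejected telomere measurements to CSV.

    An empty input produces a header-only file. Returns the frame written.
    """
    frame = measurements_to_frame(measurements, sample_id=sample_id)
    frame.to_csv(path, index=False, float_format="%.10g")
    return frame


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurements CSV back into a DataFrame with the standard schema."""
    frame = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: measurement table missing columns {missing}")
    return frame
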
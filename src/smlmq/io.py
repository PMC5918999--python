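"""Reading and writing localization tables (CSV) and camera frame stacks (TIFF).

The native CSV dialect uses headers ``frame, x_nm, y_nm, z_nm, sigma_nm,
photons, background, precision_nm`` with acquisition metadata in leading
``# key: value`` comment lines.  A reader shim additionally accepts the
widely used bracketed-unit convention (``x [nm]``, ``intensity [photon]``,
``uncertainty [nm]``); columns flagged ``[px]`` are converted to nm using the
camera pixel size.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError
from .table import MANDATORY_COLUMNS, LocalizationTable

logger = logging.getLogger(__name__)

_METADATA_FIELDS = ("camera_pixel_nm", "field_width_nm", "field_height_nm", "frames_total")

# bracketed-header base names -> native column names
_SHIM_NAMES = {
    "frame": "frame",
    "x": "x_nm",
    "y": "y_nm",
    "z": "z_nm",
    "sigma": "sigma_nm",
    "intensity": "photons",
    "photons": "photons",
    "uncertainty": "precision_nm",
    "precision": "precision_nm",
    "offset": "background",
    "background": "background",
}


def _parse_shim_header(name: str) -> tuple[str, str | None]:
    """Split ``"x [nm]"`` into (native name, unit); unknown names pass through."""
    name = name.strip()
    unit = None
    if "[" in name and name.endswith("]"):
        base, bracket = name.split("[", 1)
        base = base.strip()
        unit = bracket[:-1].strip().lower()
    else:
        base = name
    native = _SHIM_NAMES.get(base.lower(), base)
    return native, unit


def read_localizations(
    path, dialect: str = "native", camera_pixel_nm: float = 100.0
) -> LocalizationTable:
    """Read a localization table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row. With ``dialect="native"``, metadata is
        recovered from leading ``#`` comment lines.
    dialect
        ``"native"`` or ``"thunderstorm-like"`` (bracketed units; ``[px]``
        columns are scaled by ``camera_pixel_nm``).
    camera_pixel_nm
        Pixel size used to convert ``[px]`` columns and recorded in metadata
        when the file does not carry one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("native", "thunderstorm-like"):
        raise ParameterError(f"unknown dialect {dialect!r}")

    text = path.read_text()
    metadata: dict[str, float] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                key = key.strip()
                if key in _METADATA_FIELDS:
                    metadata[key] = float(value)
            continue
        body_lines.append(line)
    body = "\n".join(body_lines).strip()
    if not body:
        raise FormatError(f"{path}: empty file (no header row)")

    try:
        df = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if len(df.columns) < 2:
        raise FormatError(f"{path}: not a localization CSV (single column)")

    pixel_nm = metadata.get("camera_pixel_nm", camera_pixel_nm)
    if dialect == "thunderstorm-like":
        renames, scale_cols = {}, []
        for col in df.columns:
            native, unit = _parse_shim_header(col)
            renames[col] = native
            if unit == "px" and native != "frame":
                scale_cols.append(native)
        df = df.rename(columns=renames)
        for col in scale_cols:
            df[col] = df[col] * pixel_nm

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        df = df.astype({c: float for c in df.columns if c != "frame"})
    for col in df.columns:
        if col == "frame" or len(df) == 0:
            continue
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise FormatError(f"{path}: non-numeric value in column {col!r}, row {row}")
    df["frame"] = df["frame"].astype(int)

    table = LocalizationTable(
        df,
        camera_pixel_nm=pixel_nm,
        field_width_nm=metadata.get("field_width_nm", 0.0),
        field_height_nm=metadata.get("field_height_nm", 0.0),
        frames_total=int(metadata.get("frames_total", 0)),
    )
    table.validate()
    logger.info("read %d localizations from %s", len(table), path)
    return table


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table as native CSV; ``read_localizations`` round-trips it."""
    path = Path(path)
    lines = [
        f"# {key}: {getattr(table, key)}" for key in _METADATA_FIELDS
    ]
    df = table.df
    # keep native column order first, extras after
    native = [c for c in ("frame", "x_nm", "y_nm", "z_nm", "sigma_nm",
                          "photons", "background", "precision_nm") if c in df.columns]
    extras = [c for c in df.columns if c not in native]
    csv = df[native + extras].to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + csv)
    logger.info("wrote %d localizations to %s", len(table), path)


def read_frame_stack(path, pixel_nm: float = 100.0):
    """Read a multi-page TIFF as a :class:`~smlmq.simulate.CameraFrameStack`."""
    from .simulate import CameraFrameStack

    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a 2D/3D image stack, got shape {frames.shape}")
    logger.info("read %d frames of %dx%d px from %s",
                len(frames), frames.shape[1], frames.shape[2], path)
    return CameraFrameStack(frames=frames, pixel_nm=pixel_nm)


def write_frame_stack(stack, path) -> None:
    """Write a frame stack as multi-page float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(stack.frames, dtype=np.float32))
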
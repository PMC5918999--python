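"""The localization table: the central record passed between pipeline stages.

Coordinates are continuous nanometres with the origin at the top-left corner
of the field, x increasing rightward and y downward. Frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Mandatory columns of the native table layout.
MANDATORY_COLUMNS = ("frame", "x_nm", "y_nm", "sigma_nm", "photons", "precision_nm")

#: Optional columns filled with defaults when absent.
OPTIONAL_COLUMNS = {"z_nm": 0.0, "background": 0.0}


@dataclass
class LocalizationTable:
    """Per-event localizations plus acquisition metadata.

    Parameters
    ----------
    df
        One row per localization event. Mandatory columns: ``frame`` (0-based
        integer), ``x_nm``, ``y_nm``, ``sigma_nm`` (fitted Gaussian width),
        ``photons`` (integrated detected photons), ``precision_nm``
        (localization precision, FWHM/sqrt(photons)). Optional: ``z_nm``
        (0 for 2D data), ``background`` (photons/pixel). Unknown columns are
        preserved as opaque extras.
    camera_pixel_nm
        Physical size of one camera pixel.
    field_width_nm, field_height_nm
        Extent of the imaged field; all coordinates must lie inside it.
    frames_total
        Number of frames in the acquisition; frame indices lie in
        ``[0, frames_total)``.
    """

    df: pd.DataFrame
    camera_pixel_nm: float = 100.0
    field_width_nm: float = 0.0
    field_height_nm: float = 0.0
    frames_total: int = 0
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in OPTIONAL_COLUMNS.items():
            if col not in df.columns:
                df[col] = default
        self.df = df
        if len(df):
            if self.field_width_nm <= 0:
                self.field_width_nm = float(np.ceil(df["x_nm"].max()))
            if self.field_height_nm <= 0:
                self.field_height_nm = float(np.ceil(df["y_nm"].max()))
            if self.frames_total <= 0:
                self.frames_total = int(df["frame"].max()) + 1

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> "LocalizationTable":
        """Check table invariants, raising :class:`ParameterError` on violation."""
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise ParameterError(f"missing mandatory column {col!r}")
        if len(df) == 0:
            return self
        for col, lo, hi in (
            ("x_nm", 0.0, self.field_width_nm),
            ("y_nm", 0.0, self.field_height_nm),
        ):
            vals = df[col].to_numpy(float)
            if np.any(vals < lo) or np.any(vals > hi):
                raise ParameterError(f"{col} outside [0, field extent]")
        for col in ("photons", "sigma_nm", "precision_nm"):
            if np.any(df[col].to_numpy(float) <= 0):
                raise ParameterError(f"{col} must be strictly positive")
        frames = df["frame"].to_numpy()
        if np.any(frames < 0) or np.any(frames >= self.frames_total):
            raise ParameterError("frame index outside [0, frames_total)")
        return self

    @property
    def has_z(self) -> bool:
        return bool(np.any(self.df["z_nm"].to_numpy(float) != 0.0))

    def xy(self) -> np.ndarray:
        """(n, 2) array of x, y coordinates in nm."""
        return self.df[["x_nm", "y_nm"]].to_numpy(float)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(
            self.df.copy(),
            camera_pixel_nm=self.camera_pixel_nm,
            field_width_nm=self.field_width_nm,
            field_height_nm=self.field_height_nm,
            frames_total=self.frames_total,
            extra_metadata=dict(self.extra_metadata),
        )


def empty_table(**metadata) -> LocalizationTable:
    """A zero-row table with the native column layout."""
    cols = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df, **metadata)
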
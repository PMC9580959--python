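"""Core containers and file I/O shared by every analysis stage.

Conventions
-----------
* Pixel indices are 0-based and integer coordinates denote pixel centers;
  sub-pixel positions are continuous.
* Coordinates are stored in pixels of the owning channel.  Conversion to
  nanometres is always explicit through ``pixel_size_nm``.
* Localization tables are written as plain CSV with a fixed header; frames
  are exported 0-based.  Optional fields that are unset are written as empty
  cells, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "ImageStack",
    "LocalizationRecord",
    "LocalizationTable",
    "CSV_COLUMNS",
    "read_image_stack",
    "write_image_stack",
    "read_localizations",
    "write_localizations",
]

#: Fixed CSV column order for localization tables.
CSV_COLUMNS = [
    "frame",
    "x",
    "y",
    "sigma_x",
    "sigma_y",
    "photons",
    "background",
    "goodness",
    "z",
    "wavelength",
    "pair_distance",
    "track_id",
    "species",
]

#: Columns that must be present in any readable localization CSV.
MANDATORY_COLUMNS = ["frame", "x", "y", "sigma_x", "sigma_y", "photons"]

#: Default physical pixel sizes (16 um camera pixels at x100 / x90 magnification).
SPATIAL_PIXEL_NM = 160.0
SPECTRAL_PIXEL_NM = 178.0


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected format."""


@dataclass
class ImageStack:
    """A single-channel acquisition: frames of camera counts plus metadata.

    Parameters
    ----------
    frames
        3-D array of counts, indexed ``(frame, row, col)``; 16-bit unsigned
        semantics (all counts non-negative).
    pixel_size_nm
        Physical size of one pixel in sample space, in nm.
    channel_label
        ``"spatial"`` (direct path) or ``"spectral"`` (prism path).
    frame_interval_s
        Acquisition period in seconds.
    """

    frames: np.ndarray
    pixel_size_nm: float
    channel_label: str = "spatial"
    frame_interval_s: float = 0.05

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frame, row, col), got ndim={self.frames.ndim}")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("image counts must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class LocalizationRecord:
    """One fitted emitter in one frame.

    ``x``/``y`` are sub-pixel coordinates in pixels of the owning channel;
    ``sigma_x``/``sigma_y`` the fitted elliptical-Gaussian widths (pixels);
    ``photons`` the integrated signal above background; ``goodness`` a
    goodness-of-fit in [0, 1].  ``z`` (nm), ``wavelength`` (nm),
    ``pair_distance`` (spectral-channel pixels), ``track_id`` and ``species``
    are optional and stay ``None`` until the corresponding stage assigns them.
    """

    frame: int
    x: float
    y: float
    sigma_x: float
    sigma_y: float
    photons: float
    background: float = 0.0
    goodness: float = 1.0
    z: float | None = None
    wavelength: float | None = None
    pair_distance: float | None = None
    track_id: int | None = None
    species: str | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if self.sigma_x <= 0 or self.sigma_y <= 0:
                raise ValueError("sigma_x and sigma_y must be positive")
            if self.photons < 0:
                raise ValueError("photons must be non-negative")
            if not (0.0 <= self.goodness <= 1.0):
                raise ValueError("goodness must lie in [0, 1]")


class LocalizationTable:
    """Ordered collection of :class:`LocalizationRecord` backed by a DataFrame.

    Records are kept sorted by ``(frame, detection order)``.  ``metadata``
    is a free-form provenance map (source file, parameters, seed).
    """

    def __init__(
        self,
        records: Iterable[LocalizationRecord] | pd.DataFrame | None = None,
        channel_label: str = "spatial",
        metadata: dict | None = None,
    ) -> None:
        self.channel_label = channel_label
        self.metadata: dict = dict(metadata or {})
        if isinstance(records, pd.DataFrame):
            df = records.copy()
            for col in CSV_COLUMNS:
                if col not in df.columns:
                    df[col] = np.nan
            self._df = df[CSV_COLUMNS].reset_index(drop=True)
        else:
            rows = []
            for rec in records or []:
                rows.append(
                    {
                        "frame": rec.frame,
                        "x": rec.x,
                        "y": rec.y,
                        "sigma_x": rec.sigma_x,
                        "sigma_y": rec.sigma_y,
                        "photons": rec.photons,
                        "background": rec.background,
                        "goodness": rec.goodness,
                        "z": np.nan if rec.z is None else rec.z,
                        "wavelength": np.nan if rec.wavelength is None else rec.wavelength,
                        "pair_distance": np.nan if rec.pair_distance is None else rec.pair_distance,
                        "track_id": np.nan if rec.track_id is None else rec.track_id,
                        "species": rec.species,
                    }
                )
            self._df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        if len(self._df):
            if (self._df["frame"] < 0).any():
                raise ValueError("frame indices must be non-negative")
            # stable sort preserves within-frame detection order
            self._df = self._df.sort_values("frame", kind="stable").reset_index(drop=True)
        self._df["frame"] = self._df["frame"].astype(np.int64) if len(self._df) else self._df["frame"]

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        return iter(self.records)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (fixed column order, one row per record)."""
        return self._df

    @property
    def records(self) -> list[LocalizationRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            out.append(
                LocalizationRecord(
                    frame=int(row.frame),
                    x=float(row.x),
                    y=float(row.y),
                    sigma_x=float(row.sigma_x),
                    sigma_y=float(row.sigma_y),
                    photons=float(row.photons),
                    background=float(row.background) if pd.notna(row.background) else 0.0,
                    goodness=float(row.goodness) if pd.notna(row.goodness) else 1.0,
                    z=None if pd.isna(row.z) else float(row.z),
                    wavelength=None if pd.isna(row.wavelength) else float(row.wavelength),
                    pair_distance=None if pd.isna(row.pair_distance) else float(row.pair_distance),
                    track_id=None if pd.isna(row.track_id) else int(row.track_id),
                    species=None if (row.species is None or (isinstance(row.species, float) and np.isnan(row.species))) else str(row.species),
                )
            )
        return out

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self._df.copy(), channel_label=self.channel_label, metadata=dict(self.metadata))

    def frames_present(self) -> np.ndarray:
        return np.unique(self._df["frame"].to_numpy()) if len(self._df) else np.array([], dtype=np.int64)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def read_image_stack(
    path: str | Path,
    pixel_size_nm: float = SPATIAL_PIXEL_NM,
    frame_interval_s: float = 0.05,
    channel_label: str = "spatial",
) -> ImageStack:
    """Load a multi-page grayscale TIFF as an :class:`ImageStack`.

    Frames are returned in acquisition (page) order.  A TIFF whose pages do
    not share one frame size raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(f"non-uniform frame dimensions in {path.name}: {sorted(shapes)}")
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile error classes vary
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.ndim != 3:
        raise FormatError(f"expected grayscale pages, got array of shape {frames.shape}")
    return ImageStack(
        frames=frames,
        pixel_size_nm=pixel_size_nm,
        channel_label=channel_label,
        frame_interval_s=frame_interval_s,
    )


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to a 16-bit multi-page TIFF."""
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a localization table to CSV.

    The file carries a header with the fixed column names and one row per
    record; unset optional fields serialize as empty cells.  Numbers use the
    period as decimal separator regardless of locale.
    """
    df = table.df.copy()
    # track_id as nullable integer so missing ids stay empty, set ids print without ".0"
    df["track_id"] = df["track_id"].astype("Int64")
    df["frame"] = df["frame"].astype("Int64")
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def read_localizations(path: str | Path, channel_label: str = "spatial") -> LocalizationTable:
    """Read a localization CSV written by :func:`write_localizations`.

    Mandatory columns are ``frame, x, y, sigma_x, sigma_y, photons``; their
    absence raises :class:`FormatError`.  Unknown columns trigger a warning
    and are preserved in ``table.metadata["extra_columns"]`` rather than
    silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s) {missing} in {path.name}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    metadata: dict = {"source": str(path)}
    if extra:
        warnings.warn(f"ignoring unknown column(s) {extra} in {path.name}", stacklevel=2)
        metadata["extra_columns"] = {c: df[c].tolist() for c in extra}
    return LocalizationTable(df, channel_label=channel_label, metadata=metadata)
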
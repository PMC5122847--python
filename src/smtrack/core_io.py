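"""Movie input, result-table data model, and bundle persistence.

The pipeline's tabular outputs (candidates, localizations, tracks) are stored
as flat column tables, one column per output parameter, wrapped in
:class:`ResultTable`.  A complete analysis -- all three tables plus the exact
plugin/parameter provenance needed to re-run it -- is bundled into a
:class:`ResultBundle` and persisted to a single HDF5 file (with optional CSV
export per table).

Conventions used throughout the package:

* pixel coordinates are 0-based; a point at the center of pixel ``(row i,
  col j)`` has ``x = j``, ``y = i``; sub-pixel positions are floats in pixel
  units and ``x_nm = x * pixel_size_nm``.
* frame indices are 0-based integers in ``[0, T)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "ResultTable",
    "ResultBundle",
    "MANDATORY_COLUMNS",
    "read_movie",
    "write_movie",
    "save_bundle",
    "load_bundle",
    "export_csv",
]

#: Mandatory leading columns for each pipeline stage.
MANDATORY_COLUMNS = {
    "detection": ("frame", "x", "y"),
    "refinement": ("frame", "x", "y", "n_photons", "background", "sigma_x"),
    "tracking": ("track_id", "frame", "x", "y"),
}


class FormatError(ValueError):
    """Raised for malformed movie or bundle files."""


@dataclass
class MovieStack:
    """A T x H x W image sequence with physical metadata.

    Parameters
    ----------
    data
        Intensity array, shape ``(T, H, W)``.  Camera counts before photon
        conversion, photons after.
    pixel_size_nm
        Physical edge length of one camera pixel in nanometres.
    frame_time_s
        Acquisition time per frame in seconds (optional; needed only for
        diffusion analysis).
    unit_flag
        ``"counts"`` or ``"photons"``.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_time_s: Optional[float] = None
    unit_flag: str = "counts"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise FormatError(
                f"movie must be T x H x W, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise FormatError("movie dimensions must all be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("movie contains non-finite intensities")
        if self.unit_flag not in ("counts", "photons"):
            raise ValueError(f"unknown unit_flag {self.unit_flag!r}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ResultTable:
    """One pipeline stage's output as a column table.

    Wraps a :class:`pandas.DataFrame` whose leading columns are fixed by the
    stage (see :data:`MANDATORY_COLUMNS`); plugins may append any number of
    additional columns.  Rows are complete (no missing values).
    """

    df: pd.DataFrame
    stage_tag: str

    def __post_init__(self) -> None:
        if self.stage_tag not in MANDATORY_COLUMNS:
            raise ValueError(f"unknown stage_tag {self.stage_tag!r}")
        mandatory = MANDATORY_COLUMNS[self.stage_tag]
        cols = list(self.df.columns)
        if tuple(cols[: len(mandatory)]) != mandatory:
            raise ValueError(
                f"{self.stage_tag} table must start with columns {mandatory}, "
                f"got {cols[:len(mandatory)]}"
            )
        if len(self.df) and self.df.isna().any().any():
            raise ValueError("result table has missing values (ragged rows)")
        if len(self.df):
            frames = self.df["frame"].to_numpy()
            if not np.allclose(frames, np.round(frames)) or frames.min() < 0:
                raise ValueError("frame indices must be non-negative integers")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, stage_tag: str, extra_columns: tuple = ()) -> "ResultTable":
        cols = list(MANDATORY_COLUMNS[stage_tag]) + list(extra_columns)
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cols}), stage_tag)


@dataclass
class ResultBundle:
    """Full analysis output: stage tables + provenance + movie metadata.

    ``provenance`` maps stage name to ``{"plugin": name, "params": {...}}``
    and is sufficient to re-run the identical analysis.
    """

    candidates: Optional[ResultTable] = None
    localizations: Optional[ResultTable] = None
    tracks: Optional[ResultTable] = None
    provenance: dict = field(default_factory=dict)
    movie_meta: dict = field(default_factory=dict)


def read_movie(path, pixel_size_nm: float, frame_time_s: Optional[float] = None) -> MovieStack:
    """Read a single- or multi-page grayscale TIFF into a :class:`MovieStack`.

    Integer pixel data is preserved losslessly.  Raises ``FileNotFoundError``
    for a missing file and :class:`FormatError` for non-grayscale input or
    pages of inconsistent shape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            if tif.pages[0].samplesperpixel != 1:
                raise FormatError(f"{path}: movie must be grayscale")
            data = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # inconsistent page shapes etc.
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype == object:
        raise FormatError(f"{path}: pages have inconsistent shapes")
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale movie, got array of shape {data.shape}"
        )
    return MovieStack(data, pixel_size_nm=pixel_size_nm, frame_time_s=frame_time_s)


def write_movie(path, movie: MovieStack) -> None:
    """Write a :class:`MovieStack` as a multi-page TIFF."""
    tifffile.imwrite(str(path), movie.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# bundle persistence (HDF5 container)
# ---------------------------------------------------------------------------

_TABLE_KEYS = ("candidates", "localizations", "tracks")


def _write_table(group: h5py.Group, table: ResultTable) -> None:
    group.attrs["stage_tag"] = table.stage_tag
    group.attrs["columns"] = json.dumps(list(table.df.columns))
    for col in table.df.columns:
        values = table.df[col].to_numpy()
        if values.dtype == object:  # string columns
            group.create_dataset(col, data=np.array(values, dtype=h5py.string_dtype()))
        else:
            group.create_dataset(col, data=values)


def _read_table(group: h5py.Group) -> ResultTable:
    columns = json.loads(group.attrs["columns"])
    data = {}
    for col in columns:
        values = group[col][()]
        if values.dtype.kind in ("S", "O"):
            values = np.array([v.decode() if isinstance(v, bytes) else v for v in values])
        data[col] = values
    df = pd.DataFrame(data, columns=columns)
    return ResultTable(df, stage_tag=group.attrs["stage_tag"])


def save_bundle(bundle: ResultBundle, path) -> None:
    """Persist a :class:`ResultBundle` to a single HDF5 file."""
    with h5py.File(str(path), "w") as fh:
        for key in _TABLE_KEYS:
            table = getattr(bundle, key)
            if table is not None:
                _write_table(fh.create_group(key), table)
        fh.create_dataset("provenance", data=json.dumps(bundle.provenance))
        fh.create_dataset("movie_meta", data=json.dumps(bundle.movie_meta))


def load_bundle(path) -> ResultBundle:
    """Load a bundle saved by :func:`save_bundle`.

    Raises :class:`FormatError` naming the missing section if the file is
    corrupt or incomplete.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bundle = ResultBundle()
    with h5py.File(str(path), "r") as fh:
        for section in ("provenance", "movie_meta"):
            if section not in fh:
                raise FormatError(f"bundle {path} is missing section '{section}'")
        for key in _TABLE_KEYS:
            if key in fh:
                setattr(bundle, key, _read_table(fh[key]))
        raw = fh["provenance"][()]
        bundle.provenance = json.loads(raw.decode() if isinstance(raw, bytes) else raw)
        raw = fh["movie_meta"][()]
        bundle.movie_meta = json.loads(raw.decode() if isinstance(raw, bytes) else raw)
    return bundle


def export_csv(bundle: ResultBundle, directory) -> list:
    """Write one CSV per non-empty table; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for key in _TABLE_KEYS:
        table = getattr(bundle, key)
        if table is not None:
            out = directory / f"{key}.csv"
            table.df.to_csv(out, index=False)
            written.append(out)
    return written
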
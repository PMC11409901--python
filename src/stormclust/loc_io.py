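"""Reading, validating and writing localization tables and cohort manifests.

A *localization* is one fitted single-molecule position produced upstream by
the microscope software: 3D coordinates, a photon count (PC, the detected
intensity of the blink event) and a per-axis localization precision.  This
module owns the unit and coordinate conventions of the whole toolkit:

* every coordinate and precision is stored in **nanometres**; ingestion is
  the only place where units are converted (``Dialect.coordinate_unit``);
* coordinates live in an image-local frame; channels of the same image are
  assumed pre-registered by the microscope;
* missing ``sigma_y``/``sigma_z`` default to ``sigma_x`` (quality gates act
  on the x precision only), missing ``channel`` defaults to ``"default"``,
  missing ``frame`` to 0.

Native on-disk format is delimited text with a named-column header
(comma- or tab-separated, autodetected from the file extension); a
:class:`Dialect` maps arbitrary vendor column names onto the canonical
schema so common SMLM exports (ThunderSTORM-like CSVs and similar) can be
read without bespoke parsers.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TableValidationError",
    "Dialect",
    "LocalizationTable",
    "CohortManifest",
    "read_localizations",
    "write_localizations",
    "read_manifest",
    "write_manifest",
]

#: canonical column order of the on-disk format
REQUIRED_COLUMNS = ("x", "y", "z", "photon_count", "sigma_x")
OPTIONAL_COLUMNS = ("sigma_y", "sigma_z", "frame", "channel")
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0}
_LENGTH_COLUMNS = ("x", "y", "z", "sigma_x", "sigma_y", "sigma_z")


class FormatError(ValueError):
    """The file does not conform to the localization-table schema."""


class TableValidationError(ValueError):
    """In-memory data violates a table invariant."""


@dataclass(frozen=True)
class Dialect:
    """Column-mapping specification for ingesting foreign table layouts.

    Parameters
    ----------
    column_map:
        Mapping from canonical column name (``x``, ``photon_count``, ...) to
        the column name used in the file.  Canonical names absent from the
        map are looked up verbatim.
    coordinate_unit:
        Unit of all length-valued columns in the file (``"nm"`` or
        ``"um"``); values are converted to nm on read.
    """

    column_map: Mapping[str, str] = field(default_factory=dict)
    coordinate_unit: str = "nm"

    def __post_init__(self) -> None:
        if self.coordinate_unit not in _UNIT_TO_NM:
            raise FormatError(
                f"unknown coordinate unit {self.coordinate_unit!r}; "
                f"expected one of {sorted(_UNIT_TO_NM)}"
            )

    def file_column(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)

    @property
    def nm_per_unit(self) -> float:
        return _UNIT_TO_NM[self.coordinate_unit]


def _validate_frame(df: pd.DataFrame) -> None:
    for col in ("x", "y", "z"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise TableValidationError(f"non-finite values in coordinate column {col!r}")
    pc = df["photon_count"].to_numpy(dtype=float)
    if not (np.isfinite(pc).all() and (pc > 0).all()):
        raise TableValidationError("photon_count must be finite and > 0")
    for col in ("sigma_x", "sigma_y", "sigma_z"):
        s = df[col].to_numpy(dtype=float)
        if not (np.isfinite(s).all() and (s > 0).all()):
            raise TableValidationError(f"{col} must be finite and > 0")
    frames = df["frame"].to_numpy()
    if (frames < 0).any():
        raise TableValidationError("frame indices must be non-negative")


@dataclass
class LocalizationTable:
    """One dSTORM image's localizations plus image-level metadata.

    ``data`` holds one row per localization with the canonical columns
    (see module docstring); row order is meaningful and preserved by every
    operation in the toolkit.  ``roi_bounds``, when given, is an
    axis-aligned box ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in nm.
    """

    data: pd.DataFrame
    image_id: str
    roi_bounds: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.image_id:
            raise TableValidationError("image_id must be non-empty")
        df = self.data.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise TableValidationError(f"missing required column {col!r}")
        if "sigma_y" not in df.columns:
            df["sigma_y"] = df["sigma_x"]
        if "sigma_z" not in df.columns:
            df["sigma_z"] = df["sigma_x"]
        if "frame" not in df.columns:
            df["frame"] = 0
        if "channel" not in df.columns:
            df["channel"] = "default"
        df = df.loc[:, list(ALL_COLUMNS)].reset_index(drop=True)
        for col in ALL_COLUMNS[:-1]:
            df[col] = pd.to_numeric(df[col])
        df["frame"] = df["frame"].astype(np.int64)
        df["channel"] = df["channel"].astype(str)
        if len(df):
            _validate_frame(df)
        if self.roi_bounds is not None:
            bounds = tuple((float(lo), float(hi)) for lo, hi in self.roi_bounds)
            if len(bounds) != 3 or any(hi <= lo for lo, hi in bounds):
                raise TableValidationError("roi_bounds must be 3 (lo, hi) pairs with hi > lo")
            self.roi_bounds = bounds
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of x, y, z in nm."""
        return self.data[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def photon_count(self) -> np.ndarray:
        return self.data["photon_count"].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "LocalizationTable":
        """New table with the same metadata and different rows."""
        return LocalizationTable(
            data=data.reset_index(drop=True),
            image_id=self.image_id,
            roi_bounds=self.roi_bounds,
        )

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Row subset by boolean mask; order preserved, input untouched."""
        return self.with_data(self.data.loc[np.asarray(mask, dtype=bool)])


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_localizations(
    path: str | Path,
    dialect: Dialect | None = None,
    image_id: str | None = None,
    roi_bounds: tuple | None = None,
) -> LocalizationTable:
    """Read a delimited-text localization table.

    Raises :class:`FormatError` naming the column when a required column is
    missing, and a parse error with the 1-based data row number when a
    numeric field cannot be parsed.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, skipinitialspace=True)

    frame = pd.DataFrame(index=raw.index)
    for canonical in ALL_COLUMNS:
        col = dialect.file_column(canonical)
        if col in raw.columns:
            frame[canonical] = raw[col]
        elif canonical in REQUIRED_COLUMNS:
            raise FormatError(
                f"missing required column {canonical!r} "
                f"(looked for {col!r} in {path.name})"
            )

    for canonical in frame.columns:
        if canonical == "channel":
            continue
        parsed = pd.to_numeric(frame[canonical], errors="coerce")
        bad = parsed.isna() & frame[canonical].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(
                f"non-numeric value {frame[canonical][bad].iloc[0]!r} in column "
                f"{canonical!r} at data row {row} of {path.name}"
            )
        frame[canonical] = parsed

    if dialect.nm_per_unit != 1.0:
        for col in _LENGTH_COLUMNS:
            if col in frame.columns:
                frame[col] = frame[col] * dialect.nm_per_unit

    return LocalizationTable(
        data=frame, image_id=image_id or path.stem, roi_bounds=roi_bounds
    )


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table in the native format; ``read(write(t))`` reproduces all
    numeric fields exactly (floats serialized at full round-trip precision)."""
    path = Path(path)
    df = table.data.copy()
    # repr-precision serialization so the round trip is bit exact
    float_cols = [c for c in ALL_COLUMNS if c not in ("frame", "channel")]
    for col in float_cols:
        df[col] = df[col].map(repr)
    df.to_csv(path, sep=_sep_for(path), index=False)


@dataclass
class CohortManifest:
    """Mapping of images to subjects, groups and channels.

    One row per (image, channel); an image may appear once per channel but a
    given ``image_id`` always belongs to a single subject, and a subject to a
    single group.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("image_id", "subject_id", "group", "channel"):
            if col not in df.columns:
                raise TableValidationError(f"manifest missing column {col!r}")
            df[col] = df[col].astype(str)
        df = df.reset_index(drop=True)
        dup = df.duplicated(subset=["image_id", "channel"])
        if dup.any():
            raise TableValidationError(
                f"duplicate image_id/channel entries: "
                f"{sorted(df.loc[dup, 'image_id'].unique())}"
            )
        img_subjects = df.groupby("image_id")["subject_id"].nunique()
        if (img_subjects > 1).any():
            raise TableValidationError(
                f"image assigned to multiple subjects: "
                f"{sorted(img_subjects[img_subjects > 1].index)}"
            )
        per_subject = df.groupby("subject_id")["group"].nunique()
        if (per_subject > 1).any():
            raise TableValidationError(
                f"subject(s) appear in more than one group: "
                f"{sorted(per_subject[per_subject > 1].index)}"
            )
        self.data = df

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def image_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["image_id"]))

    def subjects(self, group: str | None = None) -> list[str]:
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        return sorted(df["subject_id"].unique())

    def images_of(self, subject_id: str) -> list[str]:
        df = self.data[self.data["subject_id"] == subject_id]
        return list(dict.fromkeys(df["image_id"]))

    def subject_of(self, image_id: str) -> str:
        rows = self.data[self.data["image_id"] == image_id]
        if rows.empty:
            raise KeyError(f"image_id {image_id!r} not in manifest")
        return rows["subject_id"].iloc[0]

    def group_of_subject(self, subject_id: str) -> str:
        rows = self.data[self.data["subject_id"] == subject_id]
        if rows.empty:
            raise KeyError(f"subject_id {subject_id!r} not in manifest")
        return rows["group"].iloc[0]

    def channels_of(self, image_id: str) -> list[str]:
        df = self.data[self.data["image_id"] == image_id]
        return list(dict.fromkeys(df["channel"]))


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    return CohortManifest(pd.read_csv(path, sep=_sep_for(path), dtype=str))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    manifest.data.to_csv(path, sep=_sep_for(path), index=False)
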
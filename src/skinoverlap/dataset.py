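"""Reading, validating and filtering skin-colour measurement tables.

The archive schema is one row per measurement: a subject id, a
self-identified ethnic-group code, gender, optional age, a body site
from a controlled vocabulary, and the colour — given directly as
CIELAB, as XYZ tristimulus values, or as a reflectance spectrum spread
over wavelength columns.  Everything downstream consumes the in-memory
:class:`SkinDataset`, which is a validated pandas DataFrame plus
provenance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import colorimetry as cm

__all__ = [
    "GROUPS",
    "SITES",
    "ANALYSIS_SITES",
    "DEFAULT_EXCLUDED_SITES",
    "SkinDataset",
    "read_dataset",
    "filter_sites",
    "write_outputs",
]

#: Ethnic-group codes, in the canonical row/column order used by all outputs.
GROUPS: tuple[str, ...] = ("CA", "CN", "JP", "SA", "AF", "IQ", "TH", "AB")

#: Controlled body-site vocabulary (all names the archive uses).
SITES: tuple[str, ...] = (
    "back of hand",
    "cheek",
    "cheekbone",
    "chin",
    "ear lobe",
    "forehead",
    "inner arm",
    "neck",
    "nose tip",
    "palm",
    "ring finger",
    "inner forearm",
    "outer forearm",
)

#: Sites dropped by default: ear lobe and ring finger have incomplete
#: coverage across collection sites, so analyses use the remaining ones.
DEFAULT_EXCLUDED_SITES: tuple[str, ...] = ("ear lobe", "ring finger")

#: Sites retained under the default exclusion, used by the generator.
ANALYSIS_SITES: tuple[str, ...] = tuple(s for s in SITES if s not in DEFAULT_EXCLUDED_SITES)[:10]

GENDERS: tuple[str, ...] = ("female", "male")

_META_COLUMNS = ["subject_id", "group", "gender", "age", "body_site"]
_LAB_COLUMNS = ["L", "a", "b"]


@dataclass
class SkinDataset:
    """A validated measurement table with one CIELAB triple per row."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _META_COLUMNS + _LAB_COLUMNS if c not in df.columns and c != "age"]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if "age" not in df.columns:
            df = df.assign(age=np.nan)
        if len(df) == 0:
            raise ValueError("dataset is empty")
        _check_vocab(df, "group", GROUPS)
        _check_vocab(df, "body_site", SITES)
        _check_vocab(df, "gender", GENDERS)
        lab = df[_LAB_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(lab)):
            bad = np.flatnonzero(~np.isfinite(lab).all(axis=1))
            raise ValueError(f"non-finite colour values at rows {bad[:10].tolist()}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> tuple[str, ...]:
        """Groups present, in canonical order."""
        present = set(self.frame["group"])
        return tuple(g for g in GROUPS if g in present)

    def group_counts(self) -> pd.Series:
        return self.frame["group"].value_counts().reindex(list(self.groups))

    def subject_counts(self) -> pd.Series:
        return self.frame.groupby("group", sort=False)["subject_id"].nunique().reindex(
            list(self.groups)
        )

    def lab(self, group: str | None = None) -> np.ndarray:
        """CIELAB triples as an (n, 3) array, optionally for one group."""
        df = self.frame if group is None else self.frame[self.frame["group"] == group]
        return df[_LAB_COLUMNS].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")


def _check_vocab(df: pd.DataFrame, column: str, vocab: Iterable[str]) -> None:
    bad = df.loc[~df[column].isin(tuple(vocab)), column]
    if len(bad):
        rows = bad.index[:10].tolist()
        vals = sorted(set(bad))
        raise ValueError(f"unknown {column} value(s) {vals} at row(s) {rows}")


def read_dataset(
    path,
    format: str = "lab_csv",
    illuminant: str = "D65",
    observer: str = "1964_10deg",
    white: cm.WhitePoint | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SkinDataset:
    """Read a measurement CSV and convert every record to CIELAB.

    format
        ``lab_csv`` (columns L, a, b), ``xyz_csv`` (columns X, Y, Z,
        converted with the given white point), or ``spectra_csv``
        (wavelength-named columns, integrated under the given
        illuminant/observer; a long table with ``wavelength`` /
        ``reflectance`` columns and a ``measurement_id`` is pivoted
        first).
    column_map
        Optional mapping from foreign header names to the schema names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if len(df) == 0:
        raise ValueError(f"{path} contains no records")

    if format == "lab_csv":
        _require(df, _LAB_COLUMNS, path)
    elif format == "xyz_csv":
        _require(df, ["X", "Y", "Z"], path)
        w = white or cm.white_point(illuminant, observer)
        lab = cm.xyz_to_lab(df[["X", "Y", "Z"]].to_numpy(dtype=float), white=w)
        df[_LAB_COLUMNS] = lab
    elif format == "spectra_csv":
        df = _spectra_to_lab(df, illuminant, observer)
    else:
        raise ValueError(f"unknown format {format!r}")

    keep = [c for c in _META_COLUMNS if c in df.columns] + _LAB_COLUMNS
    ds = SkinDataset(df[keep].copy(), provenance={"source": str(path), "format": format,
                                                  "illuminant": illuminant,
                                                  "observer": observer})
    return ds


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _spectra_to_lab(df: pd.DataFrame, illuminant: str, observer: str) -> pd.DataFrame:
    if "wavelength" in df.columns and "reflectance" in df.columns:
        # long layout → wide on measurement_id
        idx = [c for c in _META_COLUMNS + ["measurement_id"] if c in df.columns]
        wide = df.pivot_table(index=idx, columns="wavelength", values="reflectance")
        wide.columns = [str(c) for c in wide.columns]
        df = wide.reset_index()
    wl_cols = [c for c in df.columns if _is_number(c)]
    if not wl_cols:
        raise ValueError("spectra_csv: no wavelength columns found")
    wl_cols = sorted(wl_cols, key=float)
    grid = np.array([float(c) for c in wl_cols])
    spectra = df[wl_cols].to_numpy(dtype=float)
    white = cm.white_point(illuminant, observer)
    xyz = np.array(
        [
            cm.spectrum_to_xyz(cm.ReflectanceSpectrum(grid, row), illuminant, observer)
            for row in spectra
        ]
    )
    df = df.drop(columns=wl_cols)
    df[_LAB_COLUMNS] = cm.xyz_to_lab(xyz, white=white)
    return df


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def filter_sites(
    dataset: SkinDataset,
    excluded: Iterable[str] = DEFAULT_EXCLUDED_SITES,
    log: list[str] | None = None,
) -> SkinDataset:
    """Drop measurements at the excluded body sites (default: ear lobe,
    ring finger).  Retained records are untouched.  Excluding a site
    absent from the data is a no-op."""
    excluded = tuple(excluded)
    unknown = [s for s in excluded if s not in SITES]
    if unknown:
        raise ValueError(f"unknown site name(s) in exclusion list: {unknown}")
    mask = ~dataset.frame["body_site"].isin(excluded)
    removed = int((~mask).sum())
    if log is not None:
        log.append(f"filter_sites: removed {removed} of {len(dataset)} measurements "
                   f"(excluded sites: {list(excluded)})")
    if removed == 0:
        return SkinDataset(dataset.frame.copy(), dict(dataset.provenance))
    prov = dict(dataset.provenance)
    prov["excluded_sites"] = list(excluded)
    return SkinDataset(dataset.frame[mask].copy(), prov)


def write_outputs(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write result tables as deterministic CSVs (6 significant digits).

    ``tables`` maps file stems to DataFrames.  Returns the paths written,
    sorted, so repeated runs produce byte-identical file sets.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for stem in sorted(tables):
        p = out / f"{stem}.csv"
        buf = io.StringIO()
        tables[stem].to_csv(buf, float_format="%.6g", lineterminator="\n")
        p.write_text(buf.getvalue())
        paths.append(p)
    return paths
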
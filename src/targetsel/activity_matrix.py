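"""Compound × target bioactivity matrices.

The data model shared by every other module: an ordered set of compounds C,
an ordered set of targets T, a |C|×|T| grid of pK_d values and a boolean
mask marking which cells were actually measured.  pK_d = −log10(K_d in molar)
is the canonical internal scale — larger means stronger binding; pK_d = 5
(K_d = 10 µM) is the customary "no activity" baseline of kinase primary
screens and is a real measurement, never missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "BioactivityMatrix",
    "ActivityVector",
    "kd_to_pkd",
    "read_matrix",
    "write_matrix",
]

Layout = Literal["wide", "long"]
Orientation = Literal["compounds-as-rows", "targets-as-rows"]
ValueKind = Literal["kd_nM", "kd_uM", "kd_M", "pkd"]

#: Multiplier taking a K_d in the stated unit to molar.
_UNIT_TO_MOLAR = {"kd_nM": 1e-9, "kd_uM": 1e-6, "kd_M": 1.0}


def kd_to_pkd(value, unit: ValueKind = "kd_M"):
    """Convert a dissociation constant to pK_d = −log10(K_d in molar).

    Parameters
    ----------
    value : float or array-like
        K_d in the unit named by ``unit``; must be strictly positive.
    unit : {"kd_nM", "kd_uM", "kd_M", "pkd"}
        Unit of ``value``.  ``"pkd"`` passes the value through unchanged.

    Returns
    -------
    float or ndarray
        pK_d, e.g. 10 µM → 5.0 and 1 nM → 9.0.
    """
    arr = np.asarray(value, dtype=float)
    if unit == "pkd":
        return arr if arr.ndim else float(arr)
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown value_kind: {unit!r}")
    if np.any(arr <= 0):
        raise ValueError("K_d must be strictly positive to take -log10")
    out = -np.log10(arr * _UNIT_TO_MOLAR[unit])
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ActivityVector:
    """One row (a compound's bioactivity spectrum B_c) or one column (a
    target's activity profile P_t), restricted to measured cells."""

    axis_label: str
    entries: dict[str, float]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def values(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=float, count=len(self.entries))


def _check_ids(ids: Iterable[str], what: str) -> list[str]:
    out = [str(i).strip() for i in ids]
    if any(not i for i in out):
        raise ValueError(f"empty {what} identifier")
    if len(set(out)) != len(out):
        dupes = sorted({i for i in out if out.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return out


@dataclass
class BioactivityMatrix:
    """pK_d values for |C| compounds × |T| targets with a measured-cell mask.

    Attributes
    ----------
    compounds, targets : list of str
        Unique, non-empty, whitespace-trimmed identifiers (case-sensitive).
    values : ndarray, shape (|C|, |T|)
        pK_d.  Cells where ``mask`` is False are undefined and never read.
    mask : ndarray of bool, shape (|C|, |T|)
        True where the cell was measured.
    """

    compounds: list[str]
    targets: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.compounds = _check_ids(self.compounds, "compound")
        self.targets = _check_ids(self.targets, "target")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compounds), len(self.targets)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compounds)} compounds × {len(self.targets)} targets"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            bad = np.argwhere(self.mask & ~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite pK_d at measured cell "
                f"({self.compounds[bad[0]]}, {self.targets[bad[1]]})"
            )
        self._c_index = {c: i for i, c in enumerate(self.compounds)}
        self._t_index = {t: j for j, t in enumerate(self.targets)}

    # -- basic introspection -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pairs(self) -> int:
        """Number of measured compound–target pairs."""
        return int(self.mask.sum())

    def compound_index(self, compound: str) -> int:
        try:
            return self._c_index[compound]
        except KeyError:
            raise KeyError(f"unknown compound: {compound!r}") from None

    def target_index(self, target: str) -> int:
        try:
            return self._t_index[target]
        except KeyError:
            raise KeyError(f"unknown target: {target!r}") from None

    # -- slicing -------------------------------------------------------------

    def compound_spectrum(self, compound: str) -> ActivityVector:
        """Measured entries of one row: B_c = {K_{c,t} : t measured}."""
        i = self.compound_index(compound)
        row = self.values[i]
        m = self.mask[i]
        entries = {t: float(row[j]) for j, t in enumerate(self.targets) if m[j]}
        return ActivityVector(axis_label=compound, entries=entries)

    def target_profile(self, target: str) -> ActivityVector:
        """Measured entries of one column: P_t = {K_{c,t} : c measured}."""
        j = self.target_index(target)
        col = self.values[:, j]
        m = self.mask[:, j]
        entries = {c: float(col[i]) for i, c in enumerate(self.compounds) if m[i]}
        return ActivityVector(axis_label=target, entries=entries)

    def subset(self, compounds: list[str] | None = None,
               targets: list[str] | None = None) -> "BioactivityMatrix":
        """Return a submatrix restricted to the given identifiers (order kept)."""
        cs = self.compounds if compounds is None else list(compounds)
        ts = self.targets if targets is None else list(targets)
        ci = [self.compound_index(c) for c in cs]
        tj = [self.target_index(t) for t in ts]
        return BioactivityMatrix(
            compounds=cs,
            targets=ts,
            values=self.values[np.ix_(ci, tj)].copy(),
            mask=self.mask[np.ix_(ci, tj)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame of pK_d (NaN where unmeasured)."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.compounds, columns=self.targets)

    def to_long(self) -> pd.DataFrame:
        """Long DataFrame of measured pairs: compound, target, pkd."""
        ci, tj = np.nonzero(self.mask)
        return pd.DataFrame(
            {
                "compound": [self.compounds[i] for i in ci],
                "target": [self.targets[j] for j in tj],
                "pkd": self.values[ci, tj],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BioactivityMatrix":
        """Build from a wide DataFrame (index = compounds, columns = targets,
        NaN = missing)."""
        vals = frame.to_numpy(dtype=float)
        return cls(
            compounds=[str(c) for c in frame.index],
            targets=[str(t) for t in frame.columns],
            values=np.where(np.isfinite(vals), vals, 0.0),
            mask=np.isfinite(vals),
        )


class MatrixParseError(ValueError):
    """Raised when an input file cannot be parsed into a matrix."""


class DuplicateRecordError(MatrixParseError):
    """Raised when the same (compound, target) pair appears more than once."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_matrix(
    path,
    layout: Layout = "wide",
    orientation: Orientation = "compounds-as-rows",
    value_kind: ValueKind = "pkd",
    sheet: int | str = 0,
    usecols=None,
) -> BioactivityMatrix:
    """Read a bioactivity matrix from CSV/TSV (wide or long) or Excel (wide).

    Parameters
    ----------
    path : path-like
        Input file.  ``.xls``/``.xlsx`` are read with pandas' excel engines;
        anything else is delimited text (tab for ``.tsv``, comma otherwise).
    layout : {"wide", "long"}
        Wide: header row of identifiers, first column of identifiers, one
        value per cell, empty = missing.  Long: three columns
        (compound, target, value).
    orientation : {"compounds-as-rows", "targets-as-rows"}
        How a wide table is oriented.  Some public exports of kinase panels
        ship with kinases as rows; there is no sniffing, the caller declares.
    value_kind : {"kd_nM", "kd_uM", "kd_M", "pkd"}
        Unit of the stored values; K_d is converted to pK_d on load.
    sheet : int or str
        Sheet to read when the file is an Excel workbook.
    usecols :
        Optional column selection forwarded to pandas, for files that carry
        ancillary annotation columns next to the value grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_excel = path.suffix.lower() in {".xls", ".xlsx"}

    if layout == "long":
        if is_excel:
            df = pd.read_excel(path, sheet_name=sheet, usecols=usecols)
        else:
            df = pd.read_csv(path, sep=_sep_for(path), usecols=usecols,
                             float_precision="round_trip")
        if df.shape[1] < 3:
            raise MatrixParseError(
                f"{path}: long layout needs 3 columns (compound, target, value), "
                f"found {df.shape[1]}"
            )
        df = df.iloc[:, :3]
        df.columns = ["compound", "target", "value"]
        df["compound"] = df["compound"].astype(str).str.strip()
        df["target"] = df["target"].astype(str).str.strip()
        dup = df.duplicated(subset=["compound", "target"], keep=False)
        if dup.any():
            first = df.loc[dup].iloc[0]
            raise DuplicateRecordError(
                f"{path}: duplicate record for pair "
                f"({first['compound']}, {first['target']})"
            )
        vals = pd.to_numeric(df["value"], errors="coerce")
        bad = vals.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise MatrixParseError(
                f"{path}: non-numeric value {row['value']!r} at pair "
                f"({row['compound']}, {row['target']})"
            )
        df["value"] = vals
        df = df.dropna(subset=["value"])
        wide = df.pivot(index="compound", columns="target", values="value")
    else:
        try:
            if is_excel:
                wide = pd.read_excel(path, sheet_name=sheet, index_col=0, usecols=usecols)
            else:
                wide = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                                   usecols=usecols, float_precision="round_trip")
        except Exception as exc:  # surface the offending file, keep the cause
            raise MatrixParseError(f"{path}: could not parse wide table: {exc}") from exc
        wide.index = wide.index.astype(str).str.strip()
        wide.columns = wide.columns.astype(str).str.strip()
        if wide.index.has_duplicates:
            d = wide.index[wide.index.duplicated()][0]
            raise DuplicateRecordError(f"{path}: duplicate row identifier {d!r}")
        if wide.columns.has_duplicates:
            d = wide.columns[wide.columns.duplicated()][0]
            raise DuplicateRecordError(f"{path}: duplicate column identifier {d!r}")
        for col in wide.columns:
            coerced = pd.to_numeric(wide[col], errors="coerce")
            bad = coerced.isna() & wide[col].notna() & (
                wide[col].astype(str).str.strip() != ""
            )
            if bad.any():
                row = wide.index[bad][0]
                raise MatrixParseError(
                    f"{path}: non-numeric value {wide.loc[row, col]!r} "
                    f"at cell ({row}, {col})"
                )
            wide[col] = coerced
        if orientation == "targets-as-rows":
            wide = wide.T

    vals = wide.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    if value_kind != "pkd":
        converted = np.full_like(vals, np.nan)
        measured = vals[mask]
        if np.any(measured <= 0):
            i, j = [a[0] for a in np.nonzero(mask & (vals <= 0))]
            raise MatrixParseError(
                f"{path}: non-positive K_d at cell ({wide.index[i]}, {wide.columns[j]})"
            )
        converted[mask] = kd_to_pkd(measured, value_kind)
        vals = converted
    return BioactivityMatrix(
        compounds=[str(c) for c in wide.index],
        targets=[str(t) for t in wide.columns],
        values=np.where(mask, vals, 0.0),
        mask=mask,
    )


def write_matrix(m: BioactivityMatrix, path, layout: Layout = "wide") -> None:
    """Write pK_d values to CSV/TSV; missing cells become empty fields."""
    path = Path(path)
    sep = _sep_for(path)
    if layout == "long":
        m.to_long().to_csv(path, sep=sep, index=False)
    else:
        m.to_frame().to_csv(path, sep=sep)
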
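"""Osteometric table data model and CSV input/output.

The unit of data is a rectangular table of innominate (hip bone)
measurements: one row per individual, one column per measurement, values in
millimetres. The eight measurements follow the DSP 2 nomenclature:

==========  ====================================
symbol      measurement
==========  ====================================
PUM         acetabulo-symphyseal pubic length
SPU         cotylo-pubic width
DCOX        innominate height
IIMT        greater sciatic notch height
ISMM        post-acetabular ischium length
SCOX        iliac breadth
SS          spino-sciatic length
SA          spino-auricular length
==========  ====================================

Missing values are first-class citizens: downstream analyses are strictly
complete-case (no imputation anywhere), so the table preserves missingness
and exposes per-trait summaries of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical measurement names, in the conventional DSP 2 order.
CANONICAL_TRAITS: tuple[str, ...] = (
    "PUM", "SPU", "DCOX", "IIMT", "ISMM", "SCOX", "SS", "SA",
)

#: Recognised sex labels.
SEX_LABELS: tuple[str, ...] = ("F", "M", "unknown")

_SEX_ALIASES = {
    "f": "F", "female": "F",
    "m": "M", "male": "M",
}


class OsteometricFormatError(ValueError):
    """A CSV file does not conform to the expected osteometric layout."""


class TableValidationError(ValueError):
    """A table (or an operation on one) violates a data-model invariant."""


def _normalise_sex(raw: object) -> str:
    if raw is None:
        return "unknown"
    token = str(raw).strip().lower()
    return _SEX_ALIASES.get(token, "unknown")


@dataclass(frozen=True)
class OsteometricTable:
    """Individuals x eight innominate measurements, with optional sex labels.

    Wraps a :class:`pandas.DataFrame` with columns ``id`` (unique string),
    ``sex`` (``F``/``M``/``unknown``) and the eight canonical traits as
    floats, ``NaN`` marking a missing measurement.

    Invariants (enforced at construction): all present values strictly
    positive and finite; exactly the canonical trait columns; unique ids.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [t for t in CANONICAL_TRAITS if t not in df.columns]
        if missing_cols:
            raise OsteometricFormatError(
                f"missing required trait column(s): {', '.join(missing_cols)}"
            )
        extra = [
            c for c in df.columns
            if c not in CANONICAL_TRAITS and c not in ("id", "sex")
        ]
        if extra:
            raise TableValidationError(
                f"unexpected column(s): {', '.join(extra)}"
            )
        df = df.copy()
        if "id" not in df.columns:
            df["id"] = [str(i + 1) for i in range(len(df))]
        df["id"] = df["id"].astype(str)
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        df["sex"] = df["sex"].map(
            lambda s: s if s in SEX_LABELS else _normalise_sex(s)
        )
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].unique()
            raise TableValidationError(
                f"duplicate individual id(s): {', '.join(map(str, dupes[:5]))}"
            )
        for t in CANONICAL_TRAITS:
            df[t] = pd.to_numeric(df[t], errors="raise").astype(float)
            vals = df[t].to_numpy()
            present = ~np.isnan(vals)
            if np.any(~np.isfinite(vals[present])) or np.any(vals[present] <= 0):
                raise TableValidationError(
                    f"trait {t} has non-positive or non-finite value(s)"
                )
        # canonical column order; positional index
        df = df[["id", "sex", *CANONICAL_TRAITS]].reset_index(drop=True)
        object.__setattr__(self, "data", df)

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    @property
    def sex(self) -> pd.Series:
        return self.data["sex"]

    def values(self, traits: Iterable[str] | None = None) -> np.ndarray:
        """Measurement matrix (n x len(traits)), NaN for missing cells."""
        traits = list(traits) if traits is not None else list(CANONICAL_TRAITS)
        _check_traits(traits)
        return self.data[traits].to_numpy(dtype=float)

    def equals(self, other: "OsteometricTable") -> bool:
        return self.data.equals(other.data)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write in the canonical dialect: header id,sex,PUM,...,SA; empty
        cells mark missing values."""
        self.data.to_csv(path, index=False, na_rep="")


def _check_traits(traits: Iterable[str]) -> list[str]:
    traits = list(traits)
    if not traits:
        raise TableValidationError("trait set must be non-empty")
    bad = [t for t in traits if t not in CANONICAL_TRAITS]
    if bad:
        raise TableValidationError(f"unknown trait(s): {', '.join(bad)}")
    if len(set(traits)) != len(traits):
        raise TableValidationError("duplicate traits in subset")
    return traits


def read_osteometric_csv(path, missing_token: str = "NA") -> OsteometricTable:
    """Read an osteometric CSV into an :class:`OsteometricTable`.

    The header must contain the eight canonical trait names
    (case-insensitive) and may contain ``id`` and ``sex`` columns. Cells
    equal to *missing_token* or empty are treated as missing. Sex values are
    mapped case-insensitively from {F, female} / {M, male}; anything else
    becomes ``unknown``.

    Raises
    ------
    OsteometricFormatError
        If a required trait column is absent (the message names it).
    TableValidationError
        For a non-numeric non-missing cell (row and column named) or
        duplicate ids.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    colmap = {c.strip().lower(): c for c in raw.columns}
    for t in CANONICAL_TRAITS:
        if t.lower() not in colmap:
            raise OsteometricFormatError(f"missing required trait column: {t}")

    out: dict[str, object] = {}
    if "id" in colmap:
        out["id"] = raw[colmap["id"]].astype(str)
    if "sex" in colmap:
        out["sex"] = raw[colmap["sex"]].map(_normalise_sex)

    for t in CANONICAL_TRAITS:
        col = raw[colmap[t.lower()]].astype(str).str.strip()
        blank = (col == "") | (col == missing_token)
        parsed = pd.to_numeric(col.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableValidationError(
                f"non-numeric value {col.iloc[row]!r} at row {row + 1}, "
                f"column {t}"
            )
        out[t] = parsed
    return OsteometricTable(pd.DataFrame(out))


def complete_cases(table: OsteometricTable, traits: Iterable[str]) -> OsteometricTable:
    """Records with no missing value among *traits* (order preserved).

    Missingness in traits outside the requested subset is ignored, so
    different subsets generally retain different sample sizes.
    """
    traits = _check_traits(traits)
    keep = ~table.data[traits].isna().any(axis=1)
    return OsteometricTable(table.data.loc[keep].reset_index(drop=True))


def missingness_summary(table: OsteometricTable) -> dict[str, int]:
    """Count of missing cells per trait (all eight, zero included)."""
    return {t: int(table.data[t].isna().sum()) for t in CANONICAL_TRAITS}
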
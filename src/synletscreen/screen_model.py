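"""Data model and I/O for plate-based combination viability screens.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
with one row per well (see :data:`REQUIRED_COLUMNS`); :class:`PlateRecord`
is the corresponding single-row dataclass for callers that prefer objects.
A screen is a collection of 6x6 dose matrices — vehicle control plus five
concentrations per agent, so 25 true combination wells per matrix — and
:func:`assemble_matrices` pivots the long table into
:class:`CombinationMatrix` grids.

Raw luminescence reads are normalized to the mean of the vehicle wells of
their own (cell line, compound pair, replicate) group; values above 1
(growth stimulation) are retained at this stage.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from synletscreen.errors import (
    DuplicateWellError,
    IncompleteGridError,
    NormalizationError,
    ParseError,
    SchemaError,
)

#: Columns every long-format screen table must carry.
REQUIRED_COLUMNS = (
    "cell_line",
    "genotype",
    "compound_a",
    "compound_b",
    "conc_a",
    "conc_b",
    "replicate",
    "value",
)

#: Keys identifying one dose matrix (one plate's worth of wells).
GROUP_KEYS = ("cell_line", "compound_a", "compound_b", "replicate")

#: Well-level uniqueness key.
WELL_KEYS = GROUP_KEYS + ("conc_a", "conc_b")

GENOTYPES = ("deficient", "proficient")

#: multiplicative factors to micromolar
_UNIT_FACTORS = {"uM": 1.0, "µM": 1.0, "um": 1.0, "nM": 1e-3, "nm": 1e-3, "mM": 1e3, "mm": 1e3, "M": 1e6}


@dataclass(frozen=True)
class PlateRecord:
    """One well of a combination screen plate.

    Concentrations are in micromolar; ``conc == 0`` denotes the vehicle
    (DMSO) axis.  ``value`` is either a raw luminescence read or a
    normalized viability fraction, disambiguated by ``value_kind``.
    """

    cell_line: str
    genotype: str
    compound_a: str
    compound_b: str
    conc_a: float
    conc_b: float
    replicate: int
    value: float
    value_kind: str = "normalized"


@dataclass
class CombinationMatrix:
    """A 6x6 (or ``n x m``) dose grid for one cell line / compound pair / replicate.

    ``viability[i, j]`` is the normalized viability at ``conc_a[i]`` of
    compound A and ``conc_b[j]`` of compound B; index 0 on each axis is the
    vehicle, so ``viability[0, 0]`` is the vehicle control (~1 after
    normalization), row ``[:, 0]`` is the compound-A single-agent response
    and column ``[0, :]`` the compound-B one.  ``effect`` is the inhibition
    fraction 1 - viability, filled by :func:`effect_matrix`.
    """

    conc_a: np.ndarray
    conc_b: np.ndarray
    viability: np.ndarray
    cell_line: str
    genotype: str
    compound_a: str
    compound_b: str
    replicate: int
    effect: np.ndarray | None = None
    effect_clipped: bool | None = None

    def __post_init__(self) -> None:
        self.conc_a = np.asarray(self.conc_a, dtype=float)
        self.conc_b = np.asarray(self.conc_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (self.conc_a.size, self.conc_b.size):
            raise IncompleteGridError(
                f"viability grid shape {self.viability.shape} does not match "
                f"concentration axes ({self.conc_a.size}, {self.conc_b.size})"
            )
        for name, axis in (("conc_a", self.conc_a), ("conc_b", self.conc_b)):
            if axis[0] != 0:
                raise IncompleteGridError(f"{name} must start at 0 (vehicle), got {axis[0]}")
            if np.any(np.diff(axis) <= 0):
                raise IncompleteGridError(f"{name} must be strictly ascending")

    @property
    def shape(self) -> tuple[int, int]:
        return self.viability.shape

    def metadata(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "genotype": self.genotype,
            "compound_a": self.compound_a,
            "compound_b": self.compound_b,
            "replicate": self.replicate,
        }


def records_to_frame(records: Iterable[PlateRecord]) -> pd.DataFrame:
    """Convert an iterable of :class:`PlateRecord` to the canonical DataFrame."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return validate_records(df)


def frame_to_records(df: pd.DataFrame) -> list[PlateRecord]:
    cols = list(REQUIRED_COLUMNS) + ["value_kind"]
    return [PlateRecord(**row) for row in df[cols].to_dict("records")]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-table schema, value ranges, and well uniqueness."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "value_kind" not in df.columns:
        df = df.assign(value_kind="normalized")
    bad_kind = set(df["value_kind"].unique()) - {"raw", "normalized"}
    if bad_kind:
        raise SchemaError(f"value_kind must be 'raw' or 'normalized', got {sorted(bad_kind)}")
    for col in ("conc_a", "conc_b", "value"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric {col!r} value {df[col].iloc[row]!r} in row {row}")
        df = df.assign(**{col: vals.astype(float)})
        if col != "value" and (vals < 0).any():
            raise SchemaError(f"negative concentration in column {col!r}")
    if (df["value"] < 0).any():
        raise SchemaError("negative well value")
    df = df.assign(replicate=pd.to_numeric(df["replicate"], errors="raise").astype(int))
    dup = df.duplicated(subset=list(WELL_KEYS), keep=False)
    if dup.any():
        keys = df.loc[dup, list(WELL_KEYS)].drop_duplicates().to_records(index=False)
        raise DuplicateWellError(f"duplicate well key(s): {list(keys)[:5]}")
    return df


def parse_screen_table(
    path: str | os.PathLike | io.IOBase,
    *,
    unit: str = "uM",
    value_kind: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format screen table (CSV or TSV) into the canonical DataFrame.

    Parameters
    ----------
    path:
        File path or open text buffer.  ``.tsv`` files default to tab
        separation; otherwise comma.
    unit:
        Concentration unit used in the file; converted to micromolar.
    value_kind:
        Force 'raw' or 'normalized'.  If None, a ``value_kind`` column in
        the file is honored, else 'normalized' is assumed.
    """
    if unit not in _UNIT_FACTORS:
        raise SchemaError(f"unknown concentration unit {unit!r}")
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "\t" if str(name).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    if value_kind is not None:
        if value_kind not in ("raw", "normalized"):
            raise SchemaError(f"value_kind must be 'raw' or 'normalized', got {value_kind!r}")
        df["value_kind"] = value_kind
    df = validate_records(df)
    factor = _UNIT_FACTORS[unit]
    if factor != 1.0:
        df = df.assign(conc_a=df["conc_a"] * factor, conc_b=df["conc_b"] * factor)
    return df


def write_screen_table(df: pd.DataFrame, path: str | os.PathLike, *, sep: str | None = None) -> None:
    """Write the canonical long table back to CSV/TSV (micromolar, full precision)."""
    if sep is None:
        sep = "\t" if str(path).endswith(".tsv") else ","
    cols = [c for c in list(REQUIRED_COLUMNS) + ["value_kind"] if c in df.columns]
    df[cols].to_csv(path, sep=sep, index=False)


def normalize_viability(
    df: pd.DataFrame, *, return_factors: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize raw reads to the mean vehicle-well intensity of each group.

    Each (cell line, compound pair, replicate) group must contain at least
    one vehicle well (``conc_a == conc_b == 0``); every value in the group
    is divided by the arithmetic mean of its vehicle wells, so vehicle
    wells average to 1 and growth stimulation (> 1) is retained.  Already
    normalized groups pass through unchanged up to the same division, which
    makes the operation idempotent.

    With ``return_factors=True`` also returns the per-group normalization
    factors as a DataFrame (one row per group).
    """
    df = validate_records(df.copy())
    keys = list(GROUP_KEYS)
    vehicle = (df["conc_a"] == 0) & (df["conc_b"] == 0)
    factors = (
        df[vehicle].groupby(keys, sort=False)["value"].mean().rename("vehicle_mean").reset_index()
    )
    merged = df.merge(factors, on=keys, how="left")
    if merged["vehicle_mean"].isna().any():
        grp = merged.loc[merged["vehicle_mean"].isna(), keys].drop_duplicates().iloc[0]
        raise NormalizationError(
            "group without a vehicle (conc_a = conc_b = 0) well: "
            + ", ".join(f"{k}={grp[k]!r}" for k in keys)
        )
    if (merged["vehicle_mean"] == 0).any():
        grp = merged.loc[merged["vehicle_mean"] == 0, keys].drop_duplicates().iloc[0]
        raise NormalizationError(
            "degenerate vehicle control (mean 0) in group: "
            + ", ".join(f"{k}={grp[k]!r}" for k in keys)
        )
    out = df.assign(value=merged["value"].to_numpy() / merged["vehicle_mean"].to_numpy(),
                    value_kind="normalized")
    if return_factors:
        return out, factors
    return out


def assemble_matrices(
    df: pd.DataFrame, *, expected_shape: tuple[int, int] | None = (6, 6)
) -> list[CombinationMatrix]:
    """Pivot a normalized long table into one :class:`CombinationMatrix` per group.

    Raises :class:`IncompleteGridError` when a group is missing cells or
    (with ``expected_shape``) does not form a full grid of that size.  Pass
    ``expected_shape=None`` to admit other matrix sizes.
    """
    df = validate_records(df)
    if (df["value_kind"] == "raw").any():
        raise SchemaError("assemble_matrices expects normalized records; run normalize_viability first")
    out: list[CombinationMatrix] = []
    for key, grp in df.groupby(list(GROUP_KEYS), sort=False):
        cell_line, compound_a, compound_b, replicate = key
        pivot = grp.pivot(index="conc_a", columns="conc_b", values="value")
        if expected_shape is not None and pivot.shape != expected_shape:
            raise IncompleteGridError(
                f"incomplete grid for {key}: shape {pivot.shape}, expected {expected_shape}"
            )
        if pivot.isna().any().any():
            raise IncompleteGridError(f"incomplete grid for {key}: missing cells")
        genotypes = grp["genotype"].unique()
        if len(genotypes) != 1:
            raise SchemaError(f"conflicting genotype labels for {key}: {genotypes}")
        out.append(
            CombinationMatrix(
                conc_a=pivot.index.to_numpy(dtype=float),
                conc_b=pivot.columns.to_numpy(dtype=float),
                viability=pivot.to_numpy(dtype=float),
                cell_line=cell_line,
                genotype=str(genotypes[0]),
                compound_a=compound_a,
                compound_b=compound_b,
                replicate=int(replicate),
            )
        )
    return out


def effect_matrix(m: CombinationMatrix, clip: bool = True) -> CombinationMatrix:
    """Fill the inhibition-effect grid ``effect = 1 - viability``.

    With ``clip`` (the default) effects are bounded to [0, 1] so the Bliss
    model composes probabilities; without clipping, effect + viability = 1
    exactly and growth stimulation shows up as negative effect.  Returns a
    new matrix; the input is not modified.
    """
    if not np.all(np.isfinite(m.viability)):
        raise IncompleteGridError("viability grid contains non-finite values")
    effect = 1.0 - m.viability
    if clip:
        effect = np.clip(effect, 0.0, 1.0)
    return dataclasses.replace(m, effect=effect, effect_clipped=clip)
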
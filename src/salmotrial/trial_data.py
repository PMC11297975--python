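"""Pen-level trial tables: data model, validation, CSV I/O, and packaged fixtures.

The experimental unit throughout is the sea pen.  The reference design is an
unreplicated 2 x 6 factorial: two fish size classes (0 = small, autumn smolt;
1 = large, spring smolt) crossed with six dietary rapeseed-oil inclusion
levels (0, 5, 9, 14, 19, 24 % of diet), one pen per cell, twelve pens total.
Each pen carries one or more named response variables (organosomatic indices,
tissue lipid concentrations, digestible fatty-acid content, ...).

Packaged fixtures hold the trial's published summary tables as plain CSV:

``feed_composition``
    Ingredient and analyzed nutrient composition of the six feeds
    (including the analyzed choline level, mg/kg).
``feed_fatty_acids``
    Fatty-acid composition of the six feeds, % of diet.
``digestibility_means`` / ``digestibility_stats``
    Apparent digestibility (%) per nutrient, averaged over the two sizes,
    with the published model-selection statistics.
``organ_lipid`` / ``organ_lipid_stats``
    Per-pen organ indices and tissue lipid concentrations (eight response
    variables) with the published model-selection statistics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PenRecord",
    "PenTable",
    "SchemaError",
    "ParseError",
    "FixtureLookupError",
    "load_pen_table",
    "save_pen_table",
    "fixture",
    "available_fixtures",
    "organ_lipid_table",
    "TABLE5_VARIABLES",
    "TABLE5_UNITS",
    "OIL_LEVELS",
    "SIZE_CLASSES",
]

#: Nominal dietary rapeseed-oil inclusion levels, % of diet.
OIL_LEVELS: tuple[float, ...] = (0.0, 5.0, 9.0, 14.0, 19.0, 24.0)

#: Size-class coding: 0 = small (autumn smolt), 1 = large (spring smolt).
SIZE_CLASSES: tuple[int, int] = (0, 1)

#: Response variables of the per-pen organ/lipid fixture, in table order.
TABLE5_VARIABLES: tuple[str, ...] = (
    "sum_dig_FA", "OSIPI", "PI_lipid", "OSIDI",
    "OSIMes", "Mes_lipid", "OSILI", "LI_lipid",
)

TABLE5_UNITS: dict[str, str] = {
    "sum_dig_FA": "g/kg feed",
    "OSIPI": "% of body weight",
    "PI_lipid": "g/kg tissue",
    "OSIDI": "% of body weight",
    "OSIMes": "% of body weight",
    "Mes_lipid": "g/kg tissue",
    "OSILI": "% of body weight",
    "LI_lipid": "g/kg tissue",
}


class SchemaError(ValueError):
    """A required column is missing or mis-named in an input table."""


class ParseError(ValueError):
    """A cell that should be numeric could not be parsed."""


class FixtureLookupError(KeyError):
    """Requested packaged fixture does not exist."""


@dataclass(frozen=True)
class PenRecord:
    """One pen: design coordinates plus named response values.

    ``size`` is coded 0 (small) / 1 (large); ``rapeseed_oil`` is the dietary
    inclusion level in % of diet.  ``responses`` maps variable name to value;
    ``units`` carries the unit string per variable (metadata only).
    """

    pen_id: str
    size: int
    rapeseed_oil: float
    responses: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size not in (0, 1):
            raise ValueError(f"size must be 0 or 1, got {self.size!r}")
        if not 0.0 <= self.rapeseed_oil <= 100.0:
            raise ValueError(
                f"rapeseed_oil must be within [0, 100] %, got {self.rapeseed_oil!r}"
            )
        for name, value in self.responses.items():
            if not math.isfinite(value):
                raise ValueError(f"response {name!r} is not finite: {value!r}")


@dataclass
class PenTable:
    """Ordered collection of :class:`PenRecord` with design metadata."""

    records: list[PenRecord]

    def __post_init__(self) -> None:
        ids = [r.pen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pen_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PenTable):
            return NotImplemented
        return self.to_frame().equals(other.to_frame())

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for name in rec.responses:
                seen.setdefault(name, None)
        return tuple(seen)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted({r.size for r in self.records}))

    @property
    def oil_levels(self) -> tuple[float, ...]:
        return tuple(sorted({r.rapeseed_oil for r in self.records}))

    def design_warnings(self) -> list[str]:
        """Flag deviations from the reference 2 x 6 single-pen design.

        Deviations are reported, never rejected: the statistics run on any
        layout with a valid design matrix.
        """
        notes: list[str] = []
        if len(self.records) != 12:
            notes.append(f"expected 12 pens, found {len(self.records)}")
        cells = {(r.size, r.rapeseed_oil) for r in self.records}
        if len(cells) != len(self.records):
            notes.append("replicated (size, rapeseed_oil) cells present")
        reference = {(s, o) for s in SIZE_CLASSES for o in OIL_LEVELS}
        missing = reference - cells
        if missing and len(self.records) == 12:
            notes.append(f"cells absent from the reference design: {sorted(missing)}")
        return notes

    def response_vector(self, variable: str) -> np.ndarray:
        try:
            return np.array([r.responses[variable] for r in self.records], dtype=float)
        except KeyError:
            raise KeyError(
                f"variable {variable!r} missing from at least one pen; "
                f"available: {list(self.variables)}"
            ) from None

    def covariates(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (size, rapeseed_oil) arrays in record order."""
        size = np.array([r.size for r in self.records], dtype=float)
        oil = np.array([r.rapeseed_oil for r in self.records], dtype=float)
        return size, oil

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "pen_id": rec.pen_id,
                "size": rec.size,
                "rapeseed_oil": rec.rapeseed_oil,
            }
            row.update(rec.responses)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, units: Mapping[str, str] | None = None
    ) -> "PenTable":
        units = dict(units or {})
        response_cols = [
            c for c in frame.columns if c not in ("pen_id", "size", "rapeseed_oil")
        ]
        records = []
        for i, row in frame.reset_index(drop=True).iterrows():
            pen_id = str(row["pen_id"]) if "pen_id" in frame.columns else f"pen{i}"
            responses = {}
            for col in response_cols:
                try:
                    responses[col] = float(row[col])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric value {row[col]!r} for {col!r} in row {i}"
                    ) from None
            records.append(
                PenRecord(
                    pen_id=pen_id,
                    size=int(row["size"]),
                    rapeseed_oil=float(row["rapeseed_oil"]),
                    responses=responses,
                    units={k: units[k] for k in responses if k in units},
                )
            )
        return cls(records)


def load_pen_table(
    path: str | Path,
    schema: Sequence[str] | Mapping[str, str],
) -> PenTable:
    """Read a pen table from CSV (comma, UTF-8, dot decimals, header row).

    ``schema`` lists the expected response-variable names, or maps them to
    unit strings.  Header matching is case-insensitive; the stored names are
    the schema's.  Raises :class:`SchemaError` for a missing column and
    :class:`ParseError` (with row index) for non-numeric responses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    folded = {c.casefold(): c for c in frame.columns}
    if isinstance(schema, Mapping):
        variables, units = list(schema), dict(schema)
    else:
        variables, units = list(schema), {}

    for required in ["size", "rapeseed_oil", *variables]:
        if required.casefold() not in folded:
            raise SchemaError(f"missing required column {required!r} in {path}")

    out = pd.DataFrame()
    if "pen_id".casefold() in folded:
        out["pen_id"] = frame[folded["pen_id"]]
    for name in ("size", "rapeseed_oil", *variables):
        col = frame[folded[name.casefold()]]
        try:
            out[name] = pd.to_numeric(col)
        except (TypeError, ValueError):
            bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
            row = int(bad.index[0]) if len(bad) else -1
            raise ParseError(
                f"non-numeric value for column {name!r} at row {row} in {path}"
            ) from None
    if "pen_id" not in out.columns:
        out.insert(0, "pen_id", [f"pen{i}" for i in range(len(out))])
    return PenTable.from_frame(out, units=units)


def save_pen_table(table: PenTable, path: str | Path) -> None:
    """Write a pen table to CSV in the same dialect :func:`load_pen_table` reads."""
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged fixtures

_FIXTURE_FILES = {
    "feed_composition": "feed_composition.csv",
    "feed_fatty_acids": "feed_fatty_acids.csv",
    "digestibility_means": "digestibility_means.csv",
    "digestibility_stats": "digestibility_stats.csv",
    "organ_lipid": "organ_lipid.csv",
    "organ_lipid_stats": "organ_lipid_stats.csv",
}

_fixture_cache: dict[str, pd.DataFrame] = {}

# Plausibility ranges for the per-pen organ/lipid table, used to guard
# against transcription errors when the fixture is (re)generated.
_ORGAN_LIPID_RANGES = {
    "PI_lipid": (62.0, 129.0),
    "Mes_lipid": (589.0, 830.0),
    "LI_lipid": (27.0, 55.0),
}


def available_fixtures() -> tuple[str, ...]:
    return tuple(_FIXTURE_FILES)


def fixture(name: str) -> pd.DataFrame:
    """Return a packaged read-only table by name, as a fresh DataFrame copy.

    Repeated calls compare equal; mutating the returned frame does not alter
    the catalog.  Unknown names raise :class:`FixtureLookupError` listing the
    available fixtures.
    """
    if name not in _FIXTURE_FILES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    if name not in _fixture_cache:
        text = (
            resources.files("salmotrial.fixtures")
            .joinpath(_FIXTURE_FILES[name])
            .read_text(encoding="utf-8")
        )
        frame = pd.read_csv(io.StringIO(text))
        if name == "organ_lipid":
            _check_organ_lipid(frame)
        _fixture_cache[name] = frame
    return _fixture_cache[name].copy(deep=True)


def _check_organ_lipid(frame: pd.DataFrame) -> None:
    if len(frame) != 12:
        raise ValueError(f"organ_lipid fixture must have 12 rows, found {len(frame)}")
    for col, (lo, hi) in _ORGAN_LIPID_RANGES.items():
        vals = frame[col].astype(float)
        if not ((vals >= lo) & (vals <= hi)).all():
            raise ValueError(
                f"organ_lipid column {col!r} outside plausible range [{lo}, {hi}]"
            )


def organ_lipid_table() -> PenTable:
    """The per-pen organ/lipid fixture as a :class:`PenTable` with units."""
    return PenTable.from_frame(fixture("organ_lipid"), units=TABLE5_UNITS)
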
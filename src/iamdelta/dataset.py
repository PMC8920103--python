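"""Compound property tables: data model, validation and delimited-text I/O.

A compound is a row of physico-chemical properties — no structures are
handled here.  The central quantities are the two in-silico
phospholipophilicity values (``clogkw_mg``, ``clogkw_dd2``: retention
factors, extrapolated to 100 % aqueous eluent, on the IAM.PC.MG and
IAM.PC.DD2 immobilized-artificial-membrane phases), the octanol/water
lipophilicity columns (experimental log P of the neutral species plus two
calculated estimates, and log D at pH 7.4 for acids), and the experimental
blood-brain distribution ``logbb`` = log10(C_brain / C_blood).

Missing numeric values are ``None`` in memory and empty cells on disk;
zero is a legal value and never means "missing".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "IONIZATION_CLASSES",
    "COMPOUND_COLUMNS",
    "CompoundRecord",
    "CompoundTable",
    "SchemaError",
    "ValidationError",
    "load_table",
    "write_table",
    "filter_subset",
    "load_reference_table",
    "load_reference_deltas",
]

logger = logging.getLogger(__name__)

#: Legal ionization classes: acid, monobasic, bibasic, neutral.
IONIZATION_CLASSES = ("A", "B", "BB", "N")

#: Canonical CSV schema (header names, in order).
COMPOUND_COLUMNS = (
    "name",
    "ionization_class",
    "clogkw_mg",
    "clogkw_dd2",
    "explogp",
    "clogp_alogps",
    "clogp_marvin",
    "clogd74",
    "logbb",
)

_MANDATORY = ("name", "ionization_class", "clogkw_mg", "clogkw_dd2")
_REFERENCE_FIXTURE = "table1_table2_merged.csv"


class SchemaError(ValueError):
    """A delimited file does not match the documented compound schema."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


@dataclass
class CompoundRecord:
    """One compound: identity, ionization class and property values.

    Optional fields are ``None`` when the source table leaves the cell
    empty.  Class-A (acidic) records must carry ``clogd74``, because the
    excess descriptor for acids is computed against the pH 7.4
    distribution coefficient rather than the neutral-species log P.
    """

    name: str
    ionization_class: str
    clogkw_mg: float
    clogkw_dd2: float
    explogp: float | None = None
    clogp_alogps: float | None = None
    clogp_marvin: float | None = None
    clogd74: float | None = None
    logbb: float | None = None

    def validate(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("record has an empty name")
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ValidationError(
                f"{self.name!r}: ionization_class {self.ionization_class!r} "
                f"not in {IONIZATION_CLASSES}"
            )
        for attr in ("clogkw_mg", "clogkw_dd2"):
            v = getattr(self, attr)
            if v is None or not math.isfinite(v):
                raise ValidationError(f"{self.name!r}: {attr} must be a finite number")
        if self.ionization_class == "A" and self.clogd74 is None:
            raise ValidationError(
                f"{self.name!r}: acidic (class A) record lacks clogd74"
            )
        if self.ionization_class != "A" and self.explogp is None and self.clogp_marvin is None:
            raise ValidationError(
                f"{self.name!r}: non-acid record needs explogp or clogp_marvin"
            )

    def clogkw(self, phase: str) -> float:
        """Phospholipophilicity on the requested IAM phase ('MG' or 'DD2')."""
        phase = phase.upper()
        if phase == "MG":
            return self.clogkw_mg
        if phase == "DD2":
            return self.clogkw_dd2
        raise ValueError(f"unknown phase {phase!r}; expected 'MG' or 'DD2'")


@dataclass
class CompoundTable:
    """An ordered collection of unique-named :class:`CompoundRecord`."""

    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.records]

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.name in seen:
                raise ValidationError(f"duplicate compound name {rec.name!r}")
            seen.add(rec.name)

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame with the canonical columns."""
        rows = [
            {f.name: getattr(rec, f.name) for f in fields(CompoundRecord)}
            for rec in self.records
        ]
        return pd.DataFrame(rows, columns=list(COMPOUND_COLUMNS))


def _cell(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def load_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    provenance: str | None = None,
) -> CompoundTable:
    """Read and validate a compound table from delimited text.

    Extra columns beyond the canonical schema are ignored (the packaged
    reference table carries the printed delta columns for regression
    testing).  Empty cells become ``None``, never zero.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"name": str, "ionization_class": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}"
        )
    records = []
    for row in df.to_dict("records"):
        kwargs = {}
        for col in COMPOUND_COLUMNS:
            if col not in df.columns:
                continue
            raw = row[col]
            if col == "name":
                kwargs[col] = str(raw).strip()
            elif col == "ionization_class":
                kwargs[col] = str(raw).strip().upper()
            else:
                kwargs[col] = _cell(raw)
        records.append(CompoundRecord(**kwargs))
    table = CompoundTable(records, provenance=provenance or str(path))
    table.validate()
    return table


def write_table(table: CompoundTable, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a validated table as delimited text readable by :func:`load_table`.

    Absent values are serialized as empty cells; names containing the
    delimiter are quoted by the CSV writer.
    """
    table.validate()
    df = table.to_frame()
    df.to_csv(Path(path), sep=delimiter, index=False)


def filter_subset(
    table: CompoundTable,
    logbb_max: float | None = None,
    exclude_names: Sequence[str] | Iterable[str] = (),
) -> CompoundTable:
    """Select records with log BB strictly below a threshold, minus exclusions.

    Records lacking a log BB value are never selected when a threshold is
    given.  Exclusion names absent from the table are logged as warnings,
    not errors.  Order is preserved.
    """
    exclude = list(exclude_names)
    present = set(table.names)
    for name in exclude:
        if name not in present:
            logger.warning("exclusion %r not found in table", name)
    excluded = set(exclude)
    out = []
    for rec in table.records:
        if rec.name in excluded:
            continue
        if logbb_max is not None:
            if rec.logbb is None or not rec.logbb < logbb_max:
                continue
        out.append(replace(rec))
    tag = f"{table.provenance} | subset(logbb<{logbb_max}, exclude={exclude})"
    return CompoundTable(out, provenance=tag)


def _reference_path() -> Path:
    return Path(str(resources.files("iamdelta") / "data" / _REFERENCE_FIXTURE))


def load_reference_table() -> CompoundTable:
    """The packaged 56-compound reference table (properties + log BB)."""
    return load_table(_reference_path(), provenance="packaged reference table (56 compounds)")


def load_reference_deltas() -> pd.DataFrame:
    """Published excess-descriptor values shipped with the reference table.

    Returns a DataFrame indexed by compound name with columns
    ``printed_delta_mg`` and ``printed_delta_dd2`` — the cΔ/Δ'log kw values
    as published, used to recover the calibration lines and as regression
    inputs.
    """
    df = pd.read_csv(_reference_path(), dtype={"name": str})
    return df.set_index("name")[["printed_delta_mg", "printed_delta_dd2"]]
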
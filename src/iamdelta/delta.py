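"""The phospholipophilicity-excess descriptor cΔ/Δ'log kw^IAM.

For structurally unrelated *neutral* compounds, IAM retention is an affine
function of octanol/water lipophilicity::

    log kw^IAM  =  slope * log P  +  intercept        (per phase)

The excess descriptor is the deviation of a compound's (here: in-silico)
phospholipophilicity from that isolipophilic-neutral expectation:

    delta = clog kw^IAM  -  (slope * lip + intercept)

where ``lip`` is the experimental log P of the neutral species when
available, a calculated log P otherwise — except for acids (class A),
which always use the calculated log D at pH 7.4; their values carry the
primed name (Δ') to mark the convention.  A positive delta signals
polar/electrostatic membrane interactions in excess of what plain
lipophilicity explains; large excess is associated with poor blood-brain
barrier passage.

The calibration lines' coefficients are not free parameters: they are
pinned by the published per-compound deltas and can be re-derived from any
table that carries them (:func:`recover_calibration`).  The shipped
defaults below were obtained exactly that way from the packaged
56-compound reference table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CompoundRecord, CompoundTable

__all__ = [
    "Phase",
    "Policy",
    "PhaseCalibration",
    "DeltaResult",
    "DeltaReport",
    "LipophilicityError",
    "CALIBRATION_LOGP_RANGE",
    "SHIPPED_CALIBRATIONS",
    "select_lipophilicity",
    "expected_logkw",
    "compute_delta",
    "compute_delta_table",
    "recover_calibration",
    "recover_both_calibrations",
]

Phase = Literal["MG", "DD2"]
Policy = Literal["default", "exp-only", "calc-alogps", "calc-marvin"]

#: log P interval over which the isolipophilic-neutral lines were
#: established.  Outside it the expectation is an extrapolation; results
#: are flagged, not rejected.
CALIBRATION_LOGP_RANGE = (1.0, 4.8)


class LipophilicityError(ValueError):
    """No usable lipophilicity value for a compound under a given policy."""


@dataclass(frozen=True)
class PhaseCalibration:
    """Isolipophilic-neutral line for one IAM phase: logkw = slope*lip + intercept."""

    phase: str
    slope: float
    intercept: float
    provenance: str = ""
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("MG", "DD2"):
            raise ValueError(f"phase must be 'MG' or 'DD2', got {self.phase!r}")
        if not self.slope > 0:
            raise ValueError(
                f"calibration slope must be positive (retention increases with "
                f"lipophilicity); got {self.slope}"
            )


#: Default calibrations, re-derivable via recover_calibration on the
#: packaged reference table (least squares pins them to 3 decimals).
SHIPPED_CALIBRATIONS: Mapping[str, PhaseCalibration] = {
    "MG": PhaseCalibration("MG", 0.792, -0.732, "recovered from packaged reference table"),
    "DD2": PhaseCalibration("DD2", 0.934, -0.883, "recovered from packaged reference table"),
}


@dataclass(frozen=True)
class DeltaResult:
    """One computed excess value with its provenance."""

    name: str
    phase: str
    lipophilicity_used: float
    lipophilicity_source: str  # experimental_logP | calculated_logP | calculated_logD74
    expected_logkw: float
    delta: float
    is_prime: bool
    out_of_calibration_range: bool = False


@dataclass
class DeltaReport:
    """Per-table delta computation outcome; failures are reported, not dropped."""

    results: list[DeltaResult] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (name, message)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def deltas(self) -> "pd.Series":
        return pd.Series(
            {r.name: r.delta for r in self.results}, name="delta", dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "phase": r.phase,
                    "lipophilicity_used": r.lipophilicity_used,
                    "lipophilicity_source": r.lipophilicity_source,
                    "expected_logkw": r.expected_logkw,
                    "delta": r.delta,
                    "is_prime": r.is_prime,
                    "out_of_calibration_range": r.out_of_calibration_range,
                }
                for r in self.results
            ]
        )


def select_lipophilicity(
    record: CompoundRecord, policy: Policy = "default"
) -> tuple[float, str]:
    """Pick the lipophilicity input for one compound under a source policy.

    Acids (class A) always use the calculated log D^7.4 — ionization at
    physiological pH makes the neutral-species log P the wrong reference —
    regardless of policy.  For the other classes:

    - ``default``: experimental log P if present, else the calculated
      clog P^N(2) column (the one the published deltas back-solve to);
    - ``exp-only``: experimental log P or an error (no silent fallback);
    - ``calc-alogps`` / ``calc-marvin``: force the respective calculated
      column (the all-calculated variant analyses).
    """
    if record.ionization_class == "A":
        if record.clogd74 is None:
            raise LipophilicityError(f"{record.name!r}: class A but no clogd74")
        return record.clogd74, "calculated_logD74"
    if policy == "default":
        if record.explogp is not None:
            return record.explogp, "experimental_logP"
        if record.clogp_marvin is not None:
            return record.clogp_marvin, "calculated_logP"
    elif policy == "exp-only":
        if record.explogp is not None:
            return record.explogp, "experimental_logP"
    elif policy == "calc-alogps":
        if record.clogp_alogps is not None:
            return record.clogp_alogps, "calculated_logP"
    elif policy == "calc-marvin":
        if record.clogp_marvin is not None:
            return record.clogp_marvin, "calculated_logP"
    else:
        raise ValueError(f"unknown lipophilicity policy {policy!r}")
    raise LipophilicityError(
        f"{record.name!r}: no usable lipophilicity under policy {policy!r}"
    )


def expected_logkw(lipophilicity: float, calibration: PhaseCalibration) -> float:
    """Retention expected for a neutral compound of the given lipophilicity."""
    return calibration.slope * lipophilicity + calibration.intercept


def compute_delta(
    record: CompoundRecord,
    calibration: PhaseCalibration,
    policy: Policy = "default",
) -> DeltaResult:
    """Excess phospholipophilicity of one compound on one IAM phase."""
    lip, source = select_lipophilicity(record, policy)
    exp_kw = expected_logkw(lip, calibration)
    lo, hi = CALIBRATION_LOGP_RANGE
    return DeltaResult(
        name=record.name,
        phase=calibration.phase,
        lipophilicity_used=lip,
        lipophilicity_source=source,
        expected_logkw=exp_kw,
        delta=record.clogkw(calibration.phase) - exp_kw,
        is_prime=source == "calculated_logD74",
        out_of_calibration_range=not (lo <= lip <= hi),
    )


def compute_delta_table(
    table: CompoundTable,
    calibration: PhaseCalibration,
    policy: Policy = "default",
) -> DeltaReport:
    """Compute deltas for every record; per-record failures are collected."""
    report = DeltaReport()
    for rec in table:
        try:
            report.results.append(compute_delta(rec, calibration, policy))
        except (LipophilicityError, ValueError) as exc:
            report.errors.append((rec.name, str(exc)))
    return report


def recover_calibration(
    table: CompoundTable,
    printed_deltas: Mapping[str, float] | "pd.Series",
    phase: Phase,
    policy: Policy = "default",
    *,
    min_r2: float = 0.999,
) -> PhaseCalibration:
    """Invert published deltas to the isolipophilic-neutral line.

    For every compound with a published delta, ``clogkw - delta`` is the
    expected retention of the isolipophilic neutral; regressing it on the
    policy-selected lipophilicity recovers the line's slope and intercept.
    On a consistent table the fit is essentially exact; r² below
    ``min_r2`` means the deltas and the property columns disagree and the
    recovery is refused as degenerate.
    """
    lips, exps = [], []
    for rec in table:
        if rec.name not in printed_deltas:
            continue
        d = printed_deltas[rec.name]
        if d is None or (isinstance(d, float) and np.isnan(d)):
            continue
        lip, _ = select_lipophilicity(rec, policy)
        lips.append(lip)
        exps.append(rec.clogkw(phase) - float(d))
    if len(lips) < 2:
        raise ValueError(
            f"calibration recovery needs >= 2 compounds with deltas; got {len(lips)}"
        )
    x = np.asarray(lips)
    y = np.asarray(exps)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate lipophilicity spread; cannot fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - pred) ** 2).sum()) / sst if sst > 0 else 1.0
    if r2 < min_r2:
        raise ValueError(
            f"degenerate calibration recovery on phase {phase}: r2={r2:.6f} < {min_r2}; "
            "published deltas are inconsistent with the property columns"
        )
    return PhaseCalibration(
        phase=phase,
        slope=float(slope),
        intercept=float(intercept),
        provenance=f"recovered by least squares from {table.provenance or 'table'} (n={len(x)})",
        r2=r2,
    )


def recover_both_calibrations(
    table: CompoundTable,
    printed_deltas: "pd.DataFrame",
    policy: Policy = "default",
) -> dict[str, PhaseCalibration]:
    """Convenience: recover MG and DD2 lines from a printed-delta frame."""
    return {
        "MG": recover_calibration(table, printed_deltas["printed_delta_mg"], "MG", policy),
        "DD2": recover_calibration(table, printed_deltas["printed_delta_dd2"], "DD2", policy),
    }
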
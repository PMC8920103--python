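"""High-level analysis runs: the end-to-end reproduction of the published study.

These functions tie the modules together the way the study uses them:
recover the two calibration lines from the packaged table, recompute both
delta columns, regress log BB on them over the full set and over the
low-permeation subset (log BB < −0.20, the flagged outlier valproic acid
excluded), and run the all-calculated lipophilicity variant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .dataset import CompoundTable, load_reference_deltas, load_reference_table
from .delta import (
    PhaseCalibration,
    compute_delta_table,
    recover_both_calibrations,
)
from .regress import RegressionSummary, fit_logbb_simple

__all__ = ["reference_calibrations", "reproduce_report"]

SUBSET_THRESHOLD = -0.20
SUBSET_EXCLUDE = ("valproic acid",)


def reference_calibrations() -> dict[str, PhaseCalibration]:
    """Recover both phase calibrations from the packaged reference table."""
    table = load_reference_table()
    return recover_both_calibrations(table, load_reference_deltas())


def reproduce_report(
    table: CompoundTable | None = None,
    printed_deltas: pd.DataFrame | None = None,
    *,
    subset_threshold: float = SUBSET_THRESHOLD,
    exclude: Sequence[str] = SUBSET_EXCLUDE,
) -> dict:
    """Recompute the study's headline regressions from a compound table.

    Returns a dict with the recovered calibrations, the recomputed delta
    frames per phase, and :class:`~iamdelta.regress.RegressionSummary`
    panels for the full-set and subset simple regressions on each phase
    plus the all-calculated (ALOGPS clog P) DD2 subset variant.
    """
    if table is None:
        table = load_reference_table()
    if printed_deltas is None:
        printed_deltas = load_reference_deltas()
    cals = recover_both_calibrations(table, printed_deltas)

    deltas = {ph: compute_delta_table(table, cals[ph]) for ph in ("MG", "DD2")}
    full: dict[str, RegressionSummary] = {}
    subset: dict[str, RegressionSummary] = {}
    for ph in ("MG", "DD2"):
        full[ph] = fit_logbb_simple(table, deltas[ph])
        subset[ph] = fit_logbb_simple(
            table, deltas[ph], subset_threshold=subset_threshold, exclude=list(exclude)
        )
    calc_dd2 = compute_delta_table(table, cals["DD2"], policy="calc-alogps")
    subset_calc = fit_logbb_simple(
        table, calc_dd2, subset_threshold=subset_threshold, exclude=list(exclude)
    )
    return {
        "calibrations": cals,
        "deltas": deltas,
        "full": full,
        "subset": subset,
        "subset_all_calculated_dd2": subset_calc,
    }
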
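"""Seeded generators for compound tables and descriptor matrices.

The generators emit data with the statistical structure the analysis
assumes, so every pipeline stage can be exercised — and its parameter
recovery checked against known truths — without any external download.

``gen_compound_table`` draws lipophilicities, builds phospholipophilicity
as ``calibration(lipophilicity) + class-dependent polar excess + noise``
on both IAM phases, gives acids a pH 7.4 log D strictly below their
neutral log P (ionization always reduces the apparent lipophilicity), and
attaches a log BB generated as a linear function of the DD2 excess plus
noise.  ``gen_descriptor_matrix`` emits a wide descriptor table with a
planted linear response model, one strongly collinear descriptor pair and
pure-noise decoys.

A single integer seed drives everything; each generator stream is derived
from it via ``numpy.random.SeedSequence(seed, spawn_key=(stream,))``, so
adding a new generator never perturbs existing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import CompoundRecord, CompoundTable
from .delta import PhaseCalibration
from .stepwise import DescriptorMatrix

__all__ = ["SyntheticConfig", "gen_compound_table", "gen_descriptor_matrix"]

_STREAMS = {"compound": 1, "descriptor": 2}

#: Class mix of the reference dataset (41 N, 8 B, 2 BB, 5 A of 56).
_DEFAULT_PROPORTIONS = {"N": 41 / 56, "B": 8 / 56, "BB": 2 / 56, "A": 5 / 56}

#: Per-class polar-excess mean/sd in log units, spanning the range the
#: reference deltas occupy (-1 .. +2).
_DEFAULT_EXCESS = {
    "N": (0.1, 0.45),
    "B": (0.0, 0.35),
    "BB": (0.4, 0.45),
    "A": (1.0, 0.45),
}


@dataclass
class SyntheticConfig:
    """Knobs for both generators; defaults mimic the reference dataset."""

    seed: int = 0
    n_compounds: int = 56
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    calibration_true: Mapping[str, PhaseCalibration] = field(
        default_factory=lambda: {
            "MG": PhaseCalibration("MG", 0.792, -0.732, "synthetic truth"),
            "DD2": PhaseCalibration("DD2", 0.934, -0.883, "synthetic truth"),
        }
    )
    polar_excess: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_EXCESS)
    )
    lip_range: tuple[float, float] = (-1.5, 6.0)
    retention_noise_sd: float = 0.0
    #: log BB ~ intercept + slope * delta_dd2 + N(0, sd)
    logbb_model: tuple[float, float, float] = (0.25, -0.55, 0.40)
    # descriptor-matrix settings
    n_descriptors: int = 15
    planted: Mapping[str, float] = field(
        default_factory=lambda: {"d01": 0.8, "d02": -0.5, "d03": 0.3}
    )
    planted_intercept: float = 0.1
    collinear_pair: tuple[str, str] = ("d04", "d05")
    collinear_rho: float = 0.95
    descriptor_noise_sd: float = 0.1

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def validate(self) -> None:
        props = dict(self.class_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9 or any(p < 0 for p in props.values()):
            raise ValueError("class_proportions must be non-negative and sum to 1")
        if self.retention_noise_sd < 0 or self.descriptor_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if self.logbb_model[2] < 0:
            raise ValueError("logbb noise sd must be non-negative")
        missing = [k for k in self.planted if not k.startswith("d")]
        if len(self.planted) > self.n_descriptors:
            raise ValueError("planted subset larger than n_descriptors")
        del missing


def gen_compound_table(
    config: SyntheticConfig,
) -> tuple[CompoundTable, dict]:
    """Generate a compound table plus its generating truths.

    Returns ``(table, truths)`` where ``truths`` holds the true
    calibrations, the per-compound true excess on each phase, and the
    log BB model used.  Acids receive ``clogd74 = explogp − shift`` with
    shift drawn in (0.5, 2.5), so the ionization invariant
    ``clogd74 < explogp`` always holds; the acid's retention and log BB
    are generated from the log D (the quantity the Δ' convention uses).
    """
    config.validate()
    rng = config.rng("compound")
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes], dtype=float)
    drawn = rng.choice(classes, size=config.n_compounds, p=probs / probs.sum())
    lo, hi = config.lip_range
    logp = rng.uniform(lo, hi, size=config.n_compounds)

    b0, b1, bsd = config.logbb_model
    records, true_mg, true_dd2 = [], {}, {}
    for i, (cls, lp) in enumerate(zip(drawn, logp)):
        name = f"synth-{i:03d}"
        mu, sd = config.polar_excess[cls]
        # one common polar excess per compound, phase noise on top
        excess = rng.normal(mu, sd)
        lip_eff = lp
        clogd74 = None
        if cls == "A":
            clogd74 = lp - rng.uniform(0.5, 2.5)
            lip_eff = clogd74
        kw = {}
        for phase in ("MG", "DD2"):
            cal = config.calibration_true[phase]
            noise = rng.normal(0.0, config.retention_noise_sd) if config.retention_noise_sd else 0.0
            kw[phase] = cal.slope * lip_eff + cal.intercept + excess + noise
            # the truth is the structural excess; measurement noise stays
            # in the retention value, so recovery tests see real residuals
            (true_mg if phase == "MG" else true_dd2)[name] = excess
        logbb = b0 + b1 * true_dd2[name] + (rng.normal(0.0, bsd) if bsd else 0.0)
        records.append(
            CompoundRecord(
                name=name,
                ionization_class=str(cls),
                clogkw_mg=kw["MG"],
                clogkw_dd2=kw["DD2"],
                explogp=float(lp),
                clogp_alogps=float(lp),
                clogp_marvin=float(lp),
                clogd74=clogd74,
                logbb=float(logbb),
            )
        )
    table = CompoundTable(records, provenance=f"synthetic(seed={config.seed})")
    table.validate()
    truths = {
        "calibration": dict(config.calibration_true),
        "true_delta_mg": true_mg,
        "true_delta_dd2": true_dd2,
        "logbb_model": config.logbb_model,
    }
    return table, truths


def gen_descriptor_matrix(
    config: SyntheticConfig,
) -> tuple[DescriptorMatrix, np.ndarray, dict]:
    """Generate a descriptor matrix with a planted linear response model.

    Descriptors are standard-normal columns named ``d01..dNN``; the
    configured pair is made collinear at the requested correlation; the
    response is ``intercept + Σ planted coefficient·column + N(0, sd)``.
    Returns ``(matrix, response, truths)``.
    """
    config.validate()
    rng = config.rng("descriptor")
    n = config.n_compounds
    p = config.n_descriptors
    names = [f"d{i + 1:02d}" for i in range(p)]
    X = rng.standard_normal((n, p))
    a, b = config.collinear_pair
    if a in names and b in names:
        rho = config.collinear_rho
        ia, ib = names.index(a), names.index(b)
        X[:, ib] = rho * X[:, ia] + np.sqrt(1.0 - rho**2) * X[:, ib]
    y = np.full(n, config.planted_intercept)
    for name, coef in config.planted.items():
        if name not in names:
            raise ValueError(f"planted descriptor {name!r} not among generated columns")
        y = y + coef * X[:, names.index(name)]
    if config.descriptor_noise_sd:
        y = y + rng.normal(0.0, config.descriptor_noise_sd, size=n)
    matrix = DescriptorMatrix(
        compound_names=[f"synth-{i:03d}" for i in range(n)],
        descriptor_names=names,
        values=X,
    )
    truths = {
        "planted": dict(config.planted),
        "intercept": config.planted_intercept,
        "collinear_pair": config.collinear_pair,
        "collinear_rho": config.collinear_rho,
        "noise_sd": config.descriptor_noise_sd,
    }
    return matrix, y, truths
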
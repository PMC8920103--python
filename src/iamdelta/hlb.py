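"""Hydrophilic–lipophilic balance (HLB) calculators and linear QSPR evaluation.

Three HLB variants are provided: Griffin's mass-fraction formula
(20·Mh/M, bounded 0–20), Davies' group-contribution formula
(7 + Σ hydrophilic group numbers − 0.475 per lipophilic group), and a
surface-based variant scale·PSA/Surface that folds in steric effects via
the polar fraction of the molecular surface (scale defaults to 20 so the
three variants share a range).  ``hlb_mean`` averages the three into the
consensus HLB_M used as a QSPR descriptor.

``LinearQSPR`` evaluates user-supplied linear retention models
(intercept + Σ coefficient·descriptor), e.g. the published
phospholipophilicity models whose inputs include miLogP and HLB_M; the
coefficients live in external YAML model files, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "HLBProfile",
    "LinearQSPR",
    "hlb_griffin",
    "hlb_davies",
    "hlb_psa",
    "hlb_mean",
    "predict_logkw",
    "DAVIES_GROUP_NUMBERS",
]

#: Standard Davies hydrophilic group numbers (group-contribution method);
#: editable — pass your own mapping to build inputs for :func:`hlb_davies`.
DAVIES_GROUP_NUMBERS: Mapping[str, float] = {
    "-SO4Na": 38.7,
    "-COOK": 21.1,
    "-COONa": 19.1,
    "-SO3Na": 11.0,
    "-N(tertiary amine)": 9.4,
    "ester(sorbitan ring)": 6.8,
    "ester(free)": 2.4,
    "-COOH": 2.1,
    "-OH(free)": 1.9,
    "-O-": 1.3,
    "-OH(sorbitan ring)": 0.5,
}

#: Decrement per lipophilic group (CH, CH2, CH3, =CH-) in Davies' formula.
DAVIES_LIPOPHILIC_DECREMENT = 0.475


def hlb_griffin(hydrophilic_mass: float, molar_mass: float) -> float:
    """Griffin HLB: 20 × (hydrophilic mass fraction); bounded in [0, 20]."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    if not 0 <= hydrophilic_mass <= molar_mass:
        raise ValueError("hydrophilic_mass must lie in [0, molar_mass]")
    return 20.0 * hydrophilic_mass / molar_mass


def hlb_davies(
    hydrophilic_group_numbers: Sequence[float],
    n_lipophilic_groups: int,
) -> float:
    """Davies HLB: 7 + Σ group numbers − 0.475 × number of lipophilic groups."""
    if n_lipophilic_groups < 0:
        raise ValueError("n_lipophilic_groups must be non-negative")
    return 7.0 + float(sum(hydrophilic_group_numbers)) - DAVIES_LIPOPHILIC_DECREMENT * n_lipophilic_groups


def hlb_psa(psa: float, total_surface: float, scale: float = 20.0) -> float:
    """Surface-based HLB: scale × PSA / total surface.

    PSA is the polar surface area; with the default scale of 20 the value
    shares the Griffin range, 0 (fully apolar surface) to 20 (fully
    polar).
    """
    if total_surface <= 0:
        raise ValueError(f"total_surface must be positive, got {total_surface}")
    if not 0 <= psa <= total_surface:
        raise ValueError("psa must lie in [0, total_surface]")
    return scale * psa / total_surface


@dataclass(frozen=True)
class HLBProfile:
    """The three HLB variants and their arithmetic mean (HLB_M)."""

    hlb_griffin: float
    hlb_davies: float
    hlb_psa: float

    @property
    def hlb_mean(self) -> float:
        return (self.hlb_griffin + self.hlb_davies + self.hlb_psa) / 3.0


def hlb_mean(
    griffin: float | None, davies: float | None, psa_based: float | None
) -> HLBProfile:
    """Assemble an :class:`HLBProfile`; all three components are required."""
    missing = [name for name, v in
               [("griffin", griffin), ("davies", davies), ("psa", psa_based)]
               if v is None]
    if missing:
        raise ValueError(f"missing HLB component(s): {', '.join(missing)}")
    return HLBProfile(float(griffin), float(davies), float(psa_based))


@dataclass(frozen=True)
class LinearQSPR:
    """A linear retention model: logkw = intercept + Σ coefficient·descriptor.

    ``metadata`` may carry the published fit statistics (n, r2, se, f, p,
    pc); they are informational only.
    """

    phase: str
    terms: tuple[tuple[str, float], ...]
    intercept: float
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate descriptor names in QSPR terms")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LinearQSPR":
        """Load a model file: phase, intercept, terms: [{descriptor, coefficient}]."""
        spec = yaml.safe_load(Path(path).read_text())
        terms = tuple(
            (t["descriptor"], float(t["coefficient"])) for t in spec.get("terms", [])
        )
        return cls(
            phase=spec["phase"],
            terms=terms,
            intercept=float(spec["intercept"]),
            metadata=dict(spec.get("statistics", {})),
        )


def predict_logkw(descriptors: Mapping[str, float], model: LinearQSPR) -> float:
    """Evaluate a linear QSPR on a named descriptor map."""
    value = model.intercept
    for name, coef in model.terms:
        if name not in descriptors:
            raise KeyError(f"descriptor {name!r} required by the model is missing")
        value += coef * float(descriptors[name])
    return value
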
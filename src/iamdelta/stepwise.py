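"""Automatic multiple-linear-regression model building.

The procedure mirrors common QSPR practice for wide descriptor tables:

1. **Univariate screen** — each descriptor is regressed alone against the
   response; descriptors with r² below a floor (default 0.1) are dropped,
   the survivors ranked (this reproduces the single-descriptor league
   table).
2. **Collinearity filter** — variance inflation factors
   (VIF_j = 1/(1 − R²_j), descriptor j regressed on the other
   candidates) are computed and the worst offender removed, iteratively,
   until all VIFs sit below a threshold (default 5).  Exact duplicates
   are resolved by dropping the later-listed column.
3. **Subset search** — all variable subsets of size 1..max_vars (default
   5) are fitted exhaustively when the candidate count allows
   (≤ ``exhaustive_limit``), otherwise greedy forward selection; models
   are ranked by leave-one-out q² (ties: smaller SE, then fewer
   variables).
4. Optionally, an **exclusion search** refits each top model n times with
   one compound left out and reports the single exclusion that most
   improves the objective.

The search is fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .regress import RegressionSummary, fit_ols

__all__ = [
    "DescriptorMatrix",
    "StepwiseModel",
    "ScreenedDescriptor",
    "univariate_screen",
    "vif_filter",
    "search_models",
    "run_stepwise",
]

logger = logging.getLogger(__name__)


@dataclass
class DescriptorMatrix:
    """Named per-compound descriptor columns feeding the model search."""

    compound_names: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # shape (n_compounds, n_descriptors)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_names), len(self.descriptor_names)):
            raise ValueError("values shape does not match name axes")
        if len(set(self.compound_names)) != len(self.compound_names):
            raise ValueError("duplicate compound names")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("duplicate descriptor names")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorMatrix":
        return cls(
            compound_names=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        """Read a matrix CSV: first column ``name``, one column per descriptor."""
        frame = pd.read_csv(path).set_index("name")
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_names, columns=self.descriptor_names
        ).rename_axis("name")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def subset(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.descriptor_names.index(n) for n in names]
        return self.values[:, idx]


@dataclass
class ScreenedDescriptor:
    name: str
    summary: RegressionSummary


@dataclass
class StepwiseModel:
    """One candidate multiple-regression model from the subset search."""

    selected: list[str]
    summary: RegressionSummary
    vif: dict[str, float] = field(default_factory=dict)
    excluded_compound: str | None = None

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "vif": dict(self.vif),
            "excluded_compound": self.excluded_compound,
            **self.summary.to_dict(),
        }


def univariate_screen(
    matrix: DescriptorMatrix,
    response: Sequence[float],
    r2_min: float = 0.1,
) -> list[ScreenedDescriptor]:
    """Rank descriptors by single-variable r²; drop those below ``r2_min``.

    Constant columns cannot be regressed and are skipped with a warning.
    Returns the survivors sorted by descending r².
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(matrix.compound_names):
        raise ValueError("response length does not match matrix rows")
    kept = []
    for name in matrix.descriptor_names:
        x = matrix.column(name)
        if np.ptp(x) < 1e-14:
            logger.warning("descriptor %r is constant; skipped", name)
            continue
        summary = fit_ols(x, y, [name], compute_q2=len(y) >= 4)
        if summary.r2 >= r2_min:
            kept.append(ScreenedDescriptor(name, summary))
    kept.sort(key=lambda s: -s.summary.r2)
    return kept


def _vifs(X: np.ndarray) -> np.ndarray:
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.array(
        [variance_inflation_factor(Xc, j + 1) for j in range(X.shape[1])]
    )


def vif_filter(
    matrix: DescriptorMatrix,
    candidates: Sequence[str] | None = None,
    threshold: float = 5.0,
) -> tuple[list[str], dict[str, float], list[str]]:
    """Iteratively remove the highest-VIF descriptor until all sit below threshold.

    Exactly duplicated columns (infinite VIF) are resolved by removing the
    later-listed one — a deterministic tie-break.  Returns
    ``(kept_names, final_vifs, removal_log)``.
    """
    names = list(candidates) if candidates is not None else list(matrix.descriptor_names)
    if len(names) < 2:
        vif = {n: 1.0 for n in names}
        return names, vif, []
    removed: list[str] = []
    while len(names) > 1:
        X = matrix.subset(names)
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = _vifs(X)
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        worst = float(np.max(vifs))
        if worst < threshold:
            break
        # ties (e.g. exact duplicates -> both infinite): drop later-listed
        ties = np.flatnonzero(vifs == worst)
        drop = names[int(ties[-1])]
        names.remove(drop)
        removed.append(drop)
        logger.info("VIF filter removed %r (VIF=%.3g)", drop, worst)
    final = dict(zip(names, _vifs(matrix.subset(names)))) if len(names) > 1 else {n: 1.0 for n in names}
    return names, {k: float(v) for k, v in final.items()}, removed


def _objective_key(model: StepwiseModel) -> tuple:
    # rank by q2 desc, ties by SE asc then fewer variables
    return (-model.summary.q2_loo, model.summary.se, len(model.selected))


def _fit_subset(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    names: Sequence[str],
    mask: np.ndarray | None = None,
    excluded_compound: str | None = None,
) -> StepwiseModel | None:
    X = matrix.subset(names)
    if mask is not None:
        X, yy = X[mask], y[mask]
    else:
        yy = y
    try:
        summary = fit_ols(X, yy, list(names),
                          excluded=[excluded_compound] if excluded_compound else [])
    except (ValueError, np.linalg.LinAlgError):
        return None
    vif = {}
    if len(names) > 1:
        vals = _vifs(X)
        vif = {n: float(v) for n, v in zip(names, vals)}
    else:
        vif = {names[0]: 1.0}
    return StepwiseModel(list(names), summary, vif, excluded_compound)


def search_models(
    matrix: DescriptorMatrix,
    response: Sequence[float],
    max_vars: int = 5,
    *,
    exclusion_search: bool = False,
    exhaustive_limit: int = 20,
    top: int = 10,
) -> list[StepwiseModel]:
    """Enumerate variable subsets and rank fitted models by LOO q².

    With ≤ ``exhaustive_limit`` candidates every subset of size
    1..max_vars is fitted; beyond that, greedy forward selection explores
    one path per size.  With ``exclusion_search`` each of the top models
    is additionally refitted n times leaving one compound out, and the
    best single exclusion (by the objective) is attached as a variant.
    """
    y = np.asarray(response, dtype=float)
    names = matrix.descriptor_names
    if not names:
        raise ValueError("empty candidate descriptor set")
    max_vars = min(max_vars, len(names), max(1, len(y) - 3))

    models: list[StepwiseModel] = []
    if len(names) <= exhaustive_limit:
        for size in range(1, max_vars + 1):
            for combo in itertools.combinations(names, size):
                m = _fit_subset(matrix, y, combo)
                if m is not None:
                    models.append(m)
    else:  # greedy forward
        current: list[str] = []
        remaining = list(names)
        while len(current) < max_vars and remaining:
            best = None
            for cand in remaining:
                m = _fit_subset(matrix, y, current + [cand])
                if m is not None and (best is None or _objective_key(m) < _objective_key(best)):
                    best = m
            if best is None:
                break
            models.append(best)
            current = list(best.selected)
            remaining = [n for n in remaining if n not in current]

    models.sort(key=_objective_key)
    models = models[:top]

    if exclusion_search:
        augmented = []
        for m in models:
            best_variant = m
            for i, comp in enumerate(matrix.compound_names):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                v = _fit_subset(matrix, y, m.selected, mask, excluded_compound=comp)
                if v is not None and _objective_key(v) < _objective_key(best_variant):
                    best_variant = v
            augmented.append(best_variant)
        models = sorted(augmented, key=_objective_key)
    return models


def run_stepwise(
    matrix: DescriptorMatrix,
    response: Sequence[float],
    *,
    r2_min: float = 0.1,
    vif_threshold: float = 5.0,
    max_vars: int = 5,
    exclusion_search: bool = False,
    top: int = 10,
) -> dict:
    """Full pipeline: screen → VIF filter → subset search.

    Returns a report dict with the ranked univariate table, the VIF
    removal log, and the ranked models.
    """
    screened = univariate_screen(matrix, response, r2_min)
    screened_names = [s.name for s in screened]
    if not screened_names:
        raise ValueError(f"no descriptor passed the univariate screen (r2 >= {r2_min})")
    kept, vifs, removed = vif_filter(matrix, screened_names, vif_threshold)
    sub = DescriptorMatrix(
        compound_names=list(matrix.compound_names),
        descriptor_names=kept,
        values=matrix.subset(kept),
    )
    models = search_models(
        sub, response, max_vars, exclusion_search=exclusion_search, top=top
    )
    return {
        "screen": screened,
        "screen_table": pd.DataFrame(
            [
                {
                    "descriptor": s.name,
                    "r2": s.summary.r2,
                    "q2": s.summary.q2_loo,
                    "se": s.summary.se,
                    "f": s.summary.f_stat,
                    "p": s.summary.p_value,
                    "pc_sse_like": s.summary.pc_sse_like,
                }
                for s in screened
            ]
        ),
        "vif": vifs,
        "vif_removed": removed,
        "models": models,
    }
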
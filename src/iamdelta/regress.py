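"""Ordinary least squares with the QSPR statistics panel.

Every fit reports n, k, coefficients, r², leave-one-out q², the standard
error of the estimate, the Fisher F with its upper-tail p, and the
Amemiya prediction criterion.  Conventions:

- r² = 1 − SSE/SST, SE = sqrt(SSE/(n−k−1)), F = (r²/k)/((1−r²)/(n−k−1)).
- q² (LOO) = 1 − PRESS/SST with SST about the *full-sample* mean, the
  common QSAR convention; PRESS uses the exact hat-matrix identity
  e_(−i) = e_i / (1 − h_ii), algebraically equal to refitting n times.
- The Amemiya criterion is exposed in two variants: ``standard``
  ((SSE/(n−k−1))·(1+(k+1)/n)) and ``sse_like`` (the raw SSE, which is the
  scale some QSPR software prints under the PC label).

The coefficient estimation itself is delegated to :mod:`statsmodels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import CompoundTable, filter_subset
from .delta import DeltaReport, DeltaResult

__all__ = [
    "RegressionSummary",
    "fit_ols",
    "loo_q2",
    "amemiya_pc",
    "fit_logbb_simple",
]

PC_VARIANTS = ("standard", "sse_like")


@dataclass
class RegressionSummary:
    """Full statistics panel for one OLS model."""

    n: int
    k: int
    coefficients: dict[str, float]
    intercept: float
    r2: float
    q2_loo: float
    se: float
    f_stat: float
    p_value: float
    sse: float
    pc_standard: float
    pc_sse_like: float
    pc_variant: str = "standard"
    excluded: list[str] = field(default_factory=list)

    @property
    def pc_amemiya(self) -> float:
        return self.pc_standard if self.pc_variant == "standard" else self.pc_sse_like

    def predict(self, x: Mapping[str, float] | np.ndarray) -> float:
        if isinstance(x, Mapping):
            return self.intercept + sum(c * x[name] for name, c in self.coefficients.items())
        return self.intercept + float(np.dot(list(self.coefficients.values()), x))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "r2": self.r2,
            "q2_loo": self.q2_loo,
            "se": self.se,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "pc_standard": self.pc_standard,
            "pc_sse_like": self.pc_sse_like,
            "excluded": list(self.excluded),
        }


def _as_matrix(predictors, variable_names=None):
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if variable_names is None:
        variable_names = [f"x{i + 1}" for i in range(X.shape[1])]
    if len(variable_names) != X.shape[1]:
        raise ValueError("variable_names length does not match predictor columns")
    return X, list(variable_names)


def amemiya_pc(sse: float, n: int, k: int, variant: str = "standard") -> float:
    """Amemiya prediction criterion of a fitted model.

    ``standard`` is (SSE/(n−k−1))·(1+(k+1)/n); ``sse_like`` returns SSE
    itself (the quantity some legacy QSPR software labels PC).
    """
    if variant not in PC_VARIANTS:
        raise ValueError(f"unknown PC variant {variant!r}; expected one of {PC_VARIANTS}")
    if not n > k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if variant == "sse_like":
        return float(sse)
    return float(sse / (n - k - 1) * (1.0 + (k + 1) / n))


def loo_q2(predictors, response, variable_names=None) -> float:
    """Leave-one-out cross-validated q² = 1 − PRESS/SST.

    Uses the exact hat-matrix identity for the deleted residuals; an
    observation with leverage 1 makes the corresponding leave-one-out fit
    rank-deficient and raises.
    """
    X, _ = _as_matrix(predictors, variable_names)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"LOO needs n >= k + 3 (n={n}, k={k})")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.OLS(y, Xc).fit()
    h = model.get_influence().hat_matrix_diag
    if np.any(h > 1.0 - 1e-10):
        raise ValueError("leave-one-out fit is rank-deficient (leverage 1 observation)")
    press = float(np.sum((model.resid / (1.0 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant response; q2 undefined")
    return 1.0 - press / sst


def fit_ols(
    predictors,
    response,
    variable_names: Sequence[str] | None = None,
    *,
    compute_q2: bool = True,
    pc_variant: str = "standard",
    excluded: Sequence[str] = (),
) -> RegressionSummary:
    """Fit an OLS model with intercept and assemble the statistics panel."""
    X, names = _as_matrix(predictors, variable_names)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("absent values in predictors or response")
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 observations (n={n}, k={k})")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = []
        if k > 1:
            for i in range(k):
                for j in range(i + 1, k):
                    if abs(corr[i, j]) > 1 - 1e-10:
                        pairs.append(f"{names[i]}~{names[j]}")
        raise ValueError(
            "rank-deficient predictor matrix"
            + (f" (collinear: {', '.join(pairs)})" if pairs else "")
        )
    model = sm.OLS(y, Xc).fit()
    sse = float(model.ssr)
    return RegressionSummary(
        n=n,
        k=k,
        coefficients=dict(zip(names, map(float, model.params[1:]))),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        q2_loo=loo_q2(X, y) if compute_q2 and n >= k + 3 else float("nan"),
        se=float(np.sqrt(sse / (n - k - 1))),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        sse=sse,
        pc_standard=amemiya_pc(sse, n, k, "standard"),
        pc_sse_like=amemiya_pc(sse, n, k, "sse_like"),
        pc_variant=pc_variant,
        excluded=list(excluded),
    )


def fit_logbb_simple(
    table: CompoundTable,
    deltas: DeltaReport | Sequence[DeltaResult] | Mapping[str, float] | pd.Series,
    *,
    subset_threshold: float | None = None,
    exclude: Sequence[str] = (),
    variable_name: str = "delta",
) -> RegressionSummary:
    """Simple regression of log BB on the excess descriptor.

    ``deltas`` may be a :class:`~iamdelta.delta.DeltaReport`, a sequence of
    results, or a name→delta mapping (e.g. the published column).  The
    optional threshold restricts to the low-permeation range
    (log BB strictly below it) and ``exclude`` drops flagged outliers;
    both are recorded in the summary, never applied silently.
    """
    if isinstance(deltas, DeltaReport):
        dmap = {r.name: r.delta for r in deltas.results}
    elif isinstance(deltas, (pd.Series, Mapping)):
        dmap = dict(pd.Series(deltas).dropna())
    else:
        dmap = {r.name: r.delta for r in deltas}
    sub = filter_subset(table, subset_threshold, exclude)
    rows = [(rec.name, dmap[rec.name], rec.logbb) for rec in sub
            if rec.name in dmap and rec.logbb is not None]
    if len(rows) < 4:
        raise ValueError(f"subset too small for regression (n={len(rows)} < 4)")
    x = [r[1] for r in rows]
    y = [r[2] for r in rows]
    return fit_ols(x, y, [variable_name], excluded=list(exclude))
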
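"""Random-intercept mixed models and multiple-testing helpers.

The metric comparison fits ``value ~ time + (1 | mouse_id)`` by REML and
reports the fixed time effect as beta, SE, Wald z, normal-based 95% CI and
p-value.  Time is coded Before = 0 (reference), After = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

TIME_LEVELS = ("Before", "After")


@dataclass
class EffectEstimate:
    """Fixed-effect estimate for the Before -> After contrast."""

    beta: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    n_obs: int
    method: str = "lmm_reml"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"mouse_id", "time", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit a model")
    levels = set(table["time"].unique())
    if not levels <= set(TIME_LEVELS):
        raise ValueError(
            f"time must take values in {TIME_LEVELS}, got {sorted(levels)}"
        )
    if len(levels) != 2:
        raise ValueError("time must have exactly two observed levels")
    if np.ptp(table["value"].to_numpy(dtype=float)) == 0:
        raise ValueError("metric is constant: effect is unidentifiable")
    return table


def fit_lmm(table: pd.DataFrame, reml: bool = True) -> EffectEstimate:
    """REML fit of ``value ~ time + (1 | mouse_id)``; time effect estimate.

    With a single mouse the random intercept is unidentifiable, so the fit
    degrades to ordinary least squares with a logged warning.
    """
    table = _validate_table(table).copy()
    table["time"] = pd.Categorical(
        table["time"], categories=list(TIME_LEVELS), ordered=False
    )

    single_group = table["mouse_id"].nunique() < 2
    if single_group:
        logger.warning(
            "single mouse: random intercept unidentifiable, falling back to OLS"
        )
        model = smf.ols("value ~ C(time, Treatment('Before'))", data=table)
        fit = model.fit()
        method = "ols_fallback"
    else:
        model = smf.mixedlm(
            "value ~ C(time, Treatment('Before'))",
            data=table,
            groups=table["mouse_id"],
        )
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with _warnings.catch_warnings(), np.errstate(all="ignore"):
            # with few groups the intercept variance often sits on the
            # boundary; the fixed-effect estimate is still well defined
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _warnings.simplefilter("ignore", RuntimeWarning)
            _warnings.simplefilter("ignore", UserWarning)
            fit = model.fit(reml=reml, method="lbfgs")
        method = "lmm_reml" if reml else "lmm_ml"

    term = [t for t in fit.params.index if "time" in t][0]
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    z = beta / se if se > 0 else np.inf
    p = float(fit.pvalues[term])
    ci = (beta - 1.96 * se, beta + 1.96 * se)
    return EffectEstimate(
        beta=beta, se=se, z=z, p=min(max(p, 0.0), 1.0), ci95=ci,
        n_obs=len(table), method=method,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted p(k) = min over i >= k of m * p(i) / i on the sorted vector,
    capped at 1; monotone non-decreasing in the sorted order and never
    smaller than the raw value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
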
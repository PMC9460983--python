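"""Model performance metrics.

Overall skill is judged by a zero-intercept linear regression of observed on
modelled transpiration (slope near 1 and high R2 mean the model is unbiased
and explains the variance), computed on the full data and on the shallow
water-table subset where the waterlogging branch is active.  Per-tree skill
uses the RMSE normalized by the mean observation (NRMSE, %).  The residuals
can additionally be correlated with water table temperature to probe
missing cold-soil processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    r2: float
    n: int
    p_value: float
    subset: str = "full"


@dataclass(frozen=True)
class TreeError:
    tree_id: str | int
    rmse: float
    nrmse: float  # percent


def zero_intercept_fit(e_obs, e_model, subset: str = "full",
                       centered_r2: bool = True) -> RegressionReport:
    """Least-squares fit of ``y = b x`` of observed on modelled rates.

    The slope has the closed form ``b = sum(xy)/sum(x^2)``; its two-sided
    p-value comes from the usual t statistic with n-1 degrees of freedom.
    R2 defaults to the centered convention ``1 - SS_res / sum((y-ybar)^2)``
    (comparable with ordinary regression R2); ``centered_r2=False`` gives
    the uncentered ``1 - SS_res / sum(y^2)``.
    NaN pairs are dropped.
    """
    x = np.asarray(e_model, dtype=float).ravel()
    y = np.asarray(e_obs, dtype=float).ravel()
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all modelled values are zero")
    b = float(np.sum(x * y)) / sxx
    resid = y - b * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2)) if centered_r2 else float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    # t-test on the slope of the through-origin regression
    dof = n - 1
    se = np.sqrt(ss_res / dof / sxx)
    t = b / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), dof)
    return RegressionReport(slope=b, r2=r2, n=n, p_value=float(p), subset=subset)


def nrmse(e_obs, e_model, tree_id="all") -> TreeError:
    """Root-mean-square error and its percentage of the mean observation."""
    x = np.asarray(e_model, dtype=float).ravel()
    y = np.asarray(e_obs, dtype=float).ravel()
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if y.size == 0:
        raise ValueError("no paired points")
    mean_obs = float(y.mean())
    if mean_obs <= 0:
        raise ValueError("mean observation must be positive for NRMSE")
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return TreeError(tree_id=tree_id, rmse=rmse, nrmse=100.0 * rmse / mean_obs)


def residual_wtt_correlation(eps, wtt, masks: dict | None = None) -> dict:
    """Pearson correlation of model residuals with water table temperature.

    ``masks`` maps a label to a boolean array selecting a subset (e.g. cold
    water, shallow WTD); the full data is always reported under ``"full"``.
    Subsets with fewer than 3 paired points yield NaN.  Returns
    ``{label: (r, p)}``.
    """
    eps = np.asarray(eps, dtype=float).ravel()
    wtt = np.asarray(wtt, dtype=float).ravel()
    base = np.isfinite(eps) & np.isfinite(wtt)
    out = {}
    all_masks = {"full": np.ones_like(base)}
    all_masks.update(masks or {})
    for label, m in all_masks.items():
        sel = base & np.asarray(m, dtype=bool).ravel()
        if sel.sum() < 3:
            out[label] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(eps[sel], wtt[sel])
        out[label] = (float(r), float(p))
    return out


def shallow_mask(delta, delta_star: float):
    """Boolean mask of the waterlogging-branch range: WTD < delta* - 10 cm."""
    return np.asarray(delta, dtype=float) < (delta_star - 10.0)
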
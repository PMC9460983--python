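"""Optimal-stomata canopy model with delayed temperature acclimation.

Stomata maximize carbon gain minus the water cost lambda*E, which at steady
state gives transpiration as a closed-form function of vapour pressure
deficit, irradiance, leaf temperature and the marginal water-use efficiency.
The light response saturates at gamma and its initial slope is gated by the
"S" state — a first-order low-pass filter of leaf temperature that encodes
the slow spring recovery and autumn shutdown of photosynthetic capacity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CanopyConfig

__all__ = ["CanopyParams", "respiration", "update_acclimation",
           "acclimation_series", "light_response", "transpiration"]

#: Light-response denominators below this are treated as fully closed stomata.
F_GUARD = 1e-12


@dataclass(frozen=True)
class CanopyParams:
    """Canopy constants for one tree.

    ``c`` (m3 mol-1 degC-1, estimated per tree) scales the acclimation state
    into the initial slope of the light response; ``gamma`` (m s-1,
    estimated, shared) is its saturation.  ``r0``/``q10`` set respiration,
    ``s0``/``tau`` the acclimation threshold (degC) and time constant
    (days), ``ca`` atmospheric CO2 (mol m-3).
    """

    c: float
    gamma: float
    r0: float = 1.0e-6
    q10: float = 2.0
    s0: float = 5.0
    tau: float = 7.0
    ca: float = 0.0167

    def __post_init__(self):
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")
        if self.q10 <= 1 or self.tau < 1 or self.ca <= 0 or self.r0 < 0:
            raise ValueError("invalid canopy constants")

    @classmethod
    def from_config(cls, c: float, gamma: float, cc: CanopyConfig) -> "CanopyParams":
        return cls(c=c, gamma=gamma, r0=cc.r0, q10=cc.q10, s0=cc.s0,
                   tau=cc.tau, ca=cc.ca)


def respiration(t_l, cp: CanopyParams):
    """Respiration (mol CO2 m-2 s-1): ``max(R0 Q10^(T_l/10), 0)``."""
    t_l = np.asarray(t_l, dtype=float)
    out = np.maximum(cp.r0 * cp.q10 ** (t_l / 10.0), 0.0)
    return out if out.ndim else float(out)


def update_acclimation(s_prev: float, t_l: float, tau: float) -> float:
    """One forward-Euler day of the acclimation ODE dS/dt = (T_l - S)/tau.

    The update lands between the previous state and today's leaf
    temperature; tau = 1 tracks T_l exactly.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 day")
    return s_prev + (t_l - s_prev) / tau


def acclimation_series(t_l, tau: float, season_starts=None, s_init=None,
                       spinup_days: int = 0):
    """Daily acclimation state for a leaf-temperature series.

    ``season_starts`` are indices where a new season begins; the state is
    re-initialized there to that day's T_l (or ``s_init``), optionally after
    ``spinup_days`` repeats of the first day to settle the filter.
    """
    t_l = np.asarray(t_l, dtype=float)
    n = t_l.size
    starts = sorted(set([0] + list(season_starts or [])))
    s = np.empty(n)
    for k, start in enumerate(starts):
        end = starts[k + 1] if k + 1 < len(starts) else n
        state = float(t_l[start]) if s_init is None else float(s_init)
        for _ in range(spinup_days):
            state = update_acclimation(state, t_l[start], tau)
        for j in range(start, end):
            state = update_acclimation(state, t_l[j], tau)
            s[j] = state
    return s


def light_response(i, s, cp: CanopyParams):
    """Saturating light response f(I) (m s-1): ``iota gamma I/(iota I + gamma)``
    with initial slope ``iota = max(c (S - S0), 0)``.

    Below the acclimation threshold (S <= S0) the canopy is dormant and
    f(I) = 0 for all I; for large I, f saturates at gamma.
    """
    i = np.asarray(i, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(i < 0):
        raise ValueError("PPFD must be non-negative")
    iota = np.maximum(cp.c * (s - cp.s0), 0.0)
    denom = iota * i + cp.gamma
    out = np.where(denom > 0, iota * cp.gamma * i / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def transpiration(d, i, t_l, lam, cp: CanopyParams, s=None):
    """Optimal-stomata stomatal conductance and transpiration.

    ``g_sigma = max[(sqrt(max(Ca - R/f(I), 0) / (1.6 lambda D)) - 1) f(I), 0]``
    and ``E = 1.6 D g_sigma`` (mol H2O m-2 leaf s-1).  The square root is
    the optimality condition balancing the marginal carbon gain of opening
    against the water cost lambda; stomata close completely (E = 0) when the
    respiration burden exhausts the CO2 gradient or the water price
    ``1.6 lambda D`` exceeds it.

    ``s`` defaults to ``t_l`` (fully acclimated canopy).  Returns
    ``(g_sigma, E)``.
    """
    d = np.asarray(d, dtype=float)
    i = np.asarray(i, dtype=float)
    t_l = np.asarray(t_l, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    if np.any(d < 0):
        raise ValueError("D must be non-negative")
    s = t_l if s is None else np.asarray(s, dtype=float)

    f = light_response(i, s, cp)
    r = respiration(t_l, cp)
    open_canopy = f > F_GUARD
    # inner CO2 budget: what is left of the gradient after respiration
    inner = np.where(open_canopy, cp.ca - r / np.where(open_canopy, f, 1.0), -np.inf)
    inner = np.maximum(inner, 0.0)
    cost = 1.6 * lam * d
    with np.errstate(divide="ignore", invalid="ignore"):
        root = np.sqrt(np.where(cost > 0, inner / np.where(cost > 0, cost, 1.0), 0.0))
    g_sigma = np.maximum((root - 1.0) * f, 0.0)
    g_sigma = np.where(open_canopy & (d > 0), g_sigma, 0.0)
    e = 1.6 * d * g_sigma
    if g_sigma.ndim:
        return g_sigma, e
    return float(g_sigma), float(e)
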
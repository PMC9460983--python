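"""Soil water retention, the segmented soil-to-root conductance, the
soil-to-leaf conductance chain and the marginal-water-use-efficiency bridge.

The central object is a non-monotonic soil-to-root conductance k_sr(delta):
a power law of relative soil water content rising with wetness on the dry
side (water limitation), a mirrored power law falling with wetness on the
wet side (hypoxia under waterlogging: soil air displaced by water throttles
root oxygen supply), and a plateau between them around the optimal water
table depth delta*.  The realized conductance is the pointwise minimum of
the three branches.  In series with a constant root-to-leaf conductance it
gives the soil-to-leaf conductance k_sl, and the marginal water-use
efficiency lambda — the stomatal shadow price of water — is a log-log-linear
declining function of k_sl.  Waterlogging therefore *raises* lambda just as
drought does, producing the U-shaped lambda(delta) that closes stomata at
both ends of the water-table range.

All conductances are per unit leaf area (mol H2O m-2 leaf s-1 Pa-1) once the
soil-root multipliers have been scaled by ``leaf_area_conversion`` at
parameter-decode time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import SoilConfig

__all__ = [
    "RetentionParams", "SoilRootParams", "TreeHydraulics", "MwueParams",
    "theta_of_wtd", "ksr_plus", "ksr_minus", "ksr_star", "ksr", "ksl",
    "mwue", "decline_onset", "curve_table",
]


@dataclass(frozen=True)
class RetentionParams:
    """van Genuchten retention constants mapping WTD (cm) to SWC (m3 m-3)."""

    theta_sat: float
    theta_res: float
    a_vg: float = 0.072
    n_vg: float = 1.371

    def __post_init__(self):
        if not (0 <= self.theta_res < self.theta_sat <= 1):
            raise ValueError("need 0 <= theta_res < theta_sat <= 1")
        if self.a_vg <= 0 or self.n_vg <= 1:
            raise ValueError("need a_vg > 0 and n_vg > 1")

    @classmethod
    def from_config(cls, sc: SoilConfig) -> "RetentionParams":
        return cls(sc.theta_sat, sc.theta_res, sc.a_vg, sc.n_vg)


@dataclass(frozen=True)
class SoilRootParams:
    """Per-tree segmented soil-to-root conductance parameters.

    ``xi_m``/``xi_p`` govern the rising (drought) branch, ``eta_m``/``eta_p``
    the falling (hypoxia) branch, ``delta_star`` (cm) the optimal water table
    depth at the centre of the plateau.  The multipliers are stored already
    on the per-leaf-area scale (i.e. after the one-off
    ``leaf_area_conversion``).
    """

    xi_m: float
    xi_p: float
    eta_m: float
    eta_p: float
    delta_star: float

    def __post_init__(self):
        if min(self.xi_m, self.xi_p, self.eta_m, self.eta_p, self.delta_star) <= 0:
            raise ValueError("all soil-root parameters must be positive")


@dataclass(frozen=True)
class TreeHydraulics:
    """Whole-tree hydraulic constants.

    ``j_max`` is the maximum observed sap flow density
    (mol H2O m-2 sapwood s-1); with the leaf-to-sapwood area ratio ``rho``
    and the isohydric minimum leaf water potential ``psi_lmin`` (Pa, < 0) it
    fixes the constant root-to-leaf conductance
    ``k_rl = j_max / (rho |psi_lmin|)``.
    """

    tree_id: str | int
    j_max: float
    rho: float = 2500.0
    psi_lmin: float = -2.0e6

    def __post_init__(self):
        if self.j_max <= 0 or self.rho <= 0:
            raise ValueError("j_max and rho must be positive")
        if self.psi_lmin >= 0:
            raise ValueError("psi_lmin must be negative")

    @property
    def k_rl(self) -> float:
        return self.j_max / (self.rho * abs(self.psi_lmin))


@dataclass(frozen=True)
class MwueParams:
    """Log-log-linear bridge from soil-to-leaf conductance to marginal
    water-use efficiency: ``log10 lambda = z0 + z1 log10(k_sl / k0)``."""

    z0: float
    z1: float
    k0: float

    def __post_init__(self):
        if self.z1 >= 0:
            raise ValueError("z1 must be negative (lambda declines with k_sl)")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")


def theta_of_wtd(delta, rp: RetentionParams):
    """Soil water content (m3 m-3) from water table depth (cm, >= 0).

    van Genuchten retention with WTD as the matric head proxy:
    ``theta = theta_res + (theta_sat - theta_res) /
    [1 + (a delta)^n]^(1 - 1/n)``; strictly decreasing in delta, equal to
    theta_sat at the surface and approaching theta_res at depth.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("WTD must be non-negative")
    m = 1.0 - 1.0 / rp.n_vg
    s = (1.0 + (rp.a_vg * delta) ** rp.n_vg) ** (-m)
    out = rp.theta_res + (rp.theta_sat - rp.theta_res) * s
    return out if out.ndim else float(out)


def ksr_plus(theta, p: SoilRootParams, rp: RetentionParams):
    """Rising branch: ``xi_m (theta/theta_sat)^xi_p`` — water-limited
    conductance increasing with soil water content."""
    theta = np.asarray(theta, dtype=float)
    out = p.xi_m * (theta / rp.theta_sat) ** p.xi_p
    return out if out.ndim else float(out)


def ksr_minus(theta, p: SoilRootParams, rp: RetentionParams):
    """Falling branch: ``eta_m ((2 theta* - theta)/theta_sat)^eta_p`` —
    hypoxia-limited conductance decreasing with soil water content.

    ``theta* = theta(delta*)`` is recomputed from ``delta_star`` on every
    call so it can never go stale.  The base is clamped at zero (with a
    warning) for theta >= 2 theta*, which keeps non-integer powers real.
    """
    theta = np.asarray(theta, dtype=float)
    theta_star = theta_of_wtd(p.delta_star, rp)
    base = (2.0 * theta_star - theta) / rp.theta_sat
    if np.any(base < 0):
        warnings.warn("theta >= 2 theta*: hypoxia branch clamped to 0",
                      RuntimeWarning, stacklevel=2)
        base = np.maximum(base, 0.0)
    out = p.eta_m * base ** p.eta_p
    return out if out.ndim else float(out)


def ksr_star(p: SoilRootParams, rp: RetentionParams) -> float:
    """Plateau conductance: the mean of the rising branch 10 cm below and
    the falling branch 10 cm above the optimal WTD, held constant over the
    20 cm band around delta*."""
    if p.delta_star < 10:
        raise ValueError("delta_star must be >= 10 cm for the plateau band")
    up = ksr_plus(theta_of_wtd(p.delta_star + 10.0, rp), p, rp)
    down = ksr_minus(theta_of_wtd(p.delta_star - 10.0, rp), p, rp)
    return 0.5 * (float(up) + float(down))


def ksr(delta, p: SoilRootParams, rp: RetentionParams):
    """Realized soil-to-root conductance: the pointwise minimum of the
    rising, falling and plateau branches evaluated at theta(delta)."""
    theta = theta_of_wtd(delta, rp)
    out = np.minimum(np.minimum(ksr_plus(theta, p, rp), ksr_minus(theta, p, rp)),
                     ksr_star(p, rp))
    return out if np.ndim(out) else float(out)


def ksl(k_sr, k_rl):
    """Series (harmonic) composition of soil-to-root and root-to-leaf
    conductance: ``1/k_sl = 1/k_sr + 1/k_rl``; zero if either leg is zero."""
    k_sr = np.asarray(k_sr, dtype=float)
    k_rl = np.asarray(k_rl, dtype=float)
    if np.any(k_sr < 0) or np.any(k_rl < 0):
        raise ValueError("conductances must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where((k_sr > 0) & (k_rl > 0),
                       1.0 / (1.0 / np.maximum(k_sr, 1e-300)
                              + 1.0 / np.maximum(k_rl, 1e-300)),
                       0.0)
    return out if out.ndim else float(out)


def mwue(k_sl, mp: MwueParams):
    """Marginal water-use efficiency lambda (mol CO2 mol-1 H2O) from
    soil-to-leaf conductance; strictly decreasing in k_sl since z1 < 0."""
    k_sl = np.asarray(k_sl, dtype=float)
    if np.any(k_sl <= 0):
        raise ValueError("k_sl must be positive")
    out = 10.0 ** (mp.z0 + mp.z1 * np.log10(k_sl / mp.k0))
    return out if out.ndim else float(out)


def decline_onset(p: SoilRootParams, rp: RetentionParams) -> float:
    """WTD (cm) at which the hypoxia branch drops below the plateau, i.e.
    the onset of the waterlogging-driven conductance decline as the water
    table rises.  Solved by bracketing root finding on
    ``ksr_minus(theta(delta)) = ksr_star``."""
    plateau = ksr_star(p, rp)

    def f(d):
        return ksr_minus(theta_of_wtd(d, rp), p, rp) - plateau

    lo = 1e-6
    if f(lo) >= 0:  # plateau never undercut within the physical range
        return 0.0
    return float(brentq(f, lo, p.delta_star))


def curve_table(p: SoilRootParams, th: TreeHydraulics, mp: MwueParams,
                rp: RetentionParams, delta_grid=None):
    """Evaluate theta, k_sr, k_sl and lambda on a WTD grid (default 0-200 cm
    at 1 mm).  Returns a dict of equal-length arrays, ready for CSV export."""
    if delta_grid is None:
        delta_grid = np.arange(0.0, 200.0 + 1e-9, 0.1)
    delta_grid = np.asarray(delta_grid, dtype=float)
    theta = theta_of_wtd(delta_grid, rp)
    k_sr = ksr(delta_grid, p, rp)
    k_sl = ksl(k_sr, th.k_rl)
    lam = mwue(k_sl, mp)
    return {"delta": delta_grid, "theta": theta, "ksr": k_sr,
            "ksl": k_sl, "lambda": lam}
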
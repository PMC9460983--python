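"""Forward simulation: drivers -> soil hydraulics -> canopy -> daily E.

``Dataset`` bundles the aligned daily driver arrays, the per-tree observed
transpiration matrix and everything that can be precomputed once per
dataset (soil water content, respiration, the acclimation state — none of
which depend on estimated parameters).  ``simulate`` runs one parameter
vector through the chain for the full model (FM) or either reference model:

* FM   — lambda follows the soil-to-leaf conductance with the segmented,
         non-monotonic soil-to-root branch (waterlogging cut included);
* RM1  — no belowground hydraulics, one constant lambda per tree;
* RM2  — as FM but with the monotonic rising branch only (no hypoxic cut).

The hot loop is plain vectorized numpy over (n_trees, n_days); its
equivalence to the per-point soil/canopy functions is pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canopy import acclimation_series, respiration, CanopyParams
from .config import RunConfig
from .params import DecodedParams, DEFAULT_W1_TREES
from .soil import RetentionParams, theta_of_wtd

#: Light-response guard, mirrors canopy.F_GUARD.
_F_GUARD = 1e-12


@dataclass
class Dataset:
    """Aligned daily drivers and per-tree observations for one site."""

    dates: np.ndarray                 # datetime64[D], (n_days,)
    d: np.ndarray                     # VPD, mol H2O m-3
    i: np.ndarray                     # PPFD, mol m-2 s-1
    t: np.ndarray                     # air temperature, degC
    t_l: np.ndarray                   # leaf temperature, degC
    delta: np.ndarray                 # water table depth, cm
    tree_ids: list
    j_max: np.ndarray                 # (n_trees,) max sap flow density
    w1: np.ndarray                    # (n_trees,) bool, semi-log error group
    e_obs: np.ndarray | None = None   # (n_trees, n_days), NaN = missing
    config: RunConfig = field(default_factory=RunConfig)

    def __post_init__(self):
        n = len(self.dates)
        for name in ("d", "i", "t", "t_l", "delta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"driver {name!r} misaligned with dates")
            setattr(self, name, arr)
        self.j_max = np.asarray(self.j_max, dtype=float)
        self.w1 = np.asarray(self.w1, dtype=bool)
        if self.e_obs is not None:
            self.e_obs = np.asarray(self.e_obs, dtype=float)
            if self.e_obs.shape != (self.n_trees, n):
                raise ValueError("e_obs must be (n_trees, n_days)")
        rp = RetentionParams.from_config(self.config.soil)
        tc = self.config.tree
        cc = self.config.canopy
        # parameter-independent precomputations
        self.theta = theta_of_wtd(self.delta, rp)
        self.log_theta_rel = np.log(self.theta / rp.theta_sat)
        self.k_rl = self.j_max / (tc.rho * abs(tc.psi_lmin))
        cp = CanopyParams.from_config(c=0.05, gamma=2e-3, cc=cc)  # R only
        self.r = respiration(self.t_l, cp)
        self.s = acclimation_series(self.t_l, cc.tau,
                                    season_starts=self.season_starts(),
                                    spinup_days=cc.spinup_days)
        self.retention = rp

    @property
    def n_trees(self) -> int:
        return len(self.tree_ids)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def season_starts(self) -> list[int]:
        """Indices where a new season begins: the first day, and any gap of
        more than 30 days (the frozen off-season)."""
        gaps = np.diff(self.dates).astype("timedelta64[D]").astype(int)
        return [0] + [k + 1 for k in np.nonzero(gaps > 30)[0]]

    @classmethod
    def from_frames(cls, drivers: pd.DataFrame, eobs: pd.DataFrame | None = None,
                    trees: pd.DataFrame | None = None,
                    config: RunConfig | None = None) -> "Dataset":
        """Assemble from the standard tables.

        ``drivers``: date,D,I,T,T_l,delta.  ``eobs``: date,tree_id,E_obs.
        ``trees`` (optional): tree_id,j_max[,group] — when absent, j_max is
        recovered from the observations as rho * max(E_obs) and the error
        groups default to trees 4 and 6 (1-based) forming the semi-log
        group W1.
        """
        config = config or RunConfig()
        drv = drivers.sort_values("date").reset_index(drop=True)
        dates = pd.to_datetime(drv["date"]).to_numpy().astype("datetime64[D]")
        e_mat = None
        if eobs is not None:
            eo = eobs.copy()
            eo["date"] = pd.to_datetime(eo["date"]).dt.strftime("%Y-%m-%d")
            piv = eo.pivot_table(index="tree_id", columns="date",
                                 values="E_obs", aggfunc="first")
            tree_ids = list(piv.index)
            cols = pd.to_datetime(drv["date"]).dt.strftime("%Y-%m-%d")
            e_mat = piv.reindex(columns=cols).to_numpy(dtype=float)
        else:
            tree_ids = list(trees["tree_id"]) if trees is not None else []
        if trees is not None:
            trees = trees.set_index("tree_id")
            if eobs is None:
                tree_ids = list(trees.index)
            j_max = trees.loc[tree_ids, "j_max"].to_numpy(dtype=float)
            if "group" in trees.columns:
                w1 = (trees.loc[tree_ids, "group"].astype(str) == "W1").to_numpy()
            else:
                w1 = _default_w1(len(tree_ids))
        else:
            if e_mat is None:
                raise ValueError("need eobs and/or trees to define the tree set")
            j_max = config.tree.rho * np.nanmax(e_mat, axis=1)
            w1 = _default_w1(len(tree_ids))
        return cls(dates=dates, d=drv["D"], i=drv["I"], t=drv["T"],
                   t_l=drv["T_l"], delta=drv["delta"], tree_ids=tree_ids,
                   j_max=j_max, w1=w1, e_obs=e_mat, config=config)


def _default_w1(n_trees: int) -> np.ndarray:
    w1 = np.zeros(n_trees, dtype=bool)
    for k in DEFAULT_W1_TREES:
        if k <= n_trees:
            w1[k - 1] = True
    return w1


@dataclass
class SimulationResult:
    """Per-tree daily simulation with hydraulic diagnostics."""

    dates: np.ndarray
    tree_ids: list
    e_model: np.ndarray               # (n_trees, n_days)
    k_sr: np.ndarray                  # (n_trees, n_days); NaN for RM1
    k_sl: np.ndarray
    lam: np.ndarray
    s: np.ndarray                     # (n_days,) acclimation state

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, tid in enumerate(self.tree_ids):
            rows.append(pd.DataFrame({
                "date": self.dates, "tree_id": tid,
                "E_model": self.e_model[k], "k_sr": self.k_sr[k],
                "k_sl": self.k_sl[k], "lambda": self.lam[k], "S": self.s,
            }))
        return pd.concat(rows, ignore_index=True)


def simulate(ds: Dataset, dp: DecodedParams, variant: str | None = None,
             rm2_cap: str = "none") -> SimulationResult:
    """Run one decoded parameter vector through the forward chain.

    ``rm2_cap='ksr_star'`` makes RM2 retain the plateau cap (requires the
    plateau parameters, i.e. a vector decoded from the FM layout); the
    default RM2 is the uncapped rising branch, the minimal monotonic change
    from FM.
    """
    variant = variant or dp.variant
    for arr in (ds.d, ds.i, ds.t_l, ds.delta):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite driver input")
    n, m = ds.n_trees, ds.n_days
    rp = ds.retention

    if variant == "RM1":
        if dp.lambda_const is None:
            raise ValueError("RM1 requires per-tree constant lambda")
        lam = np.broadcast_to(dp.lambda_const[:, None], (n, m)).copy()
        k_sr = np.full((n, m), np.nan)
        k_sl = np.full((n, m), np.nan)
    else:
        plus_shape = np.exp(dp.xi_p * ds.log_theta_rel)          # (m,)
        k_plus = dp.xi_m[:, None] * plus_shape[None, :]          # (n, m)
        if variant == "FM" or rm2_cap == "ksr_star":
            if dp.eta_m is None:
                raise ValueError("plateau parameters required for this variant")
            theta_star = theta_of_wtd(dp.delta_star, rp)
            base = np.maximum((2.0 * theta_star - ds.theta) / rp.theta_sat, 0.0)
            k_minus = dp.eta_m * base ** dp.eta_p                # (m,)
            th_up = theta_of_wtd(dp.delta_star + 10.0, rp)
            th_dn = theta_of_wtd(dp.delta_star - 10.0, rp)
            plus_at_up = np.exp(dp.xi_p * np.log(th_up / rp.theta_sat))
            minus_at_dn = dp.eta_m * ((2.0 * theta_star - th_dn) / rp.theta_sat) ** dp.eta_p
            k_star = 0.5 * (dp.xi_m * plus_at_up + minus_at_dn)  # (n,)
            if variant == "FM":
                k_sr = np.minimum(np.minimum(k_plus, k_minus[None, :]),
                                  k_star[:, None])
            else:
                k_sr = np.minimum(k_plus, k_star[:, None])
        else:
            k_sr = k_plus
        k_sl = 1.0 / (1.0 / k_sr + 1.0 / ds.k_rl[:, None])
        lam = 10.0 ** (dp.z0 + dp.z1 * np.log10(k_sl / ds.config.soil.k0))

    # canopy, vectorized over (n_trees, n_days)
    cc = ds.config.canopy
    iota = np.maximum(dp.c[:, None] * (ds.s[None, :] - cc.s0), 0.0)
    denom = iota * ds.i[None, :] + dp.gamma
    f = np.where(denom > 0, iota * dp.gamma * ds.i[None, :]
                 / np.where(denom > 0, denom, 1.0), 0.0)
    open_canopy = f > _F_GUARD
    inner = np.maximum(np.where(open_canopy,
                                cc.ca - ds.r[None, :] / np.where(open_canopy, f, 1.0),
                                0.0), 0.0)
    cost = 1.6 * lam * ds.d[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        root = np.sqrt(np.where(cost > 0, inner / np.where(cost > 0, cost, 1.0), 0.0))
    g_sigma = np.where(open_canopy & (ds.d[None, :] > 0),
                       np.maximum((root - 1.0) * f, 0.0), 0.0)
    e_model = 1.6 * ds.d[None, :] * g_sigma
    return SimulationResult(dates=ds.dates, tree_ids=ds.tree_ids,
                            e_model=e_model, k_sr=k_sr, k_sl=k_sl,
                            lam=lam, s=ds.s)
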
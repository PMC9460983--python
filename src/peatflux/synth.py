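"""Synthetic scenario generator.

Produces daily driver series and per-tree sap-flow observations with the
statistical structure the calibration assumes: seasonal sinusoid + AR(1)
weather, a water-table trajectory that sweeps the waterlogged, optimal and
dry conductance regimes, and observations generated by the full forward
model plus the group-wise heteroscedastic noise of the data model.  Driver
*realism* is not the goal — only ranges, autocorrelation and regime
coverage matter, because those are what identify the parameters.

The generated daily values stand directly for the daily top-decile-median
statistic of the reduction pipeline (daytime conditions), so they feed the
forward model without further reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .drivers import leaf_temperature, vpd, vpd_molar
from .forward import Dataset, simulate
from .inference import error_sd
from .params import ParameterSpace

logger = logging.getLogger(__name__)

#: Maximum observed sap flow density per tree (mol H2O m-2 sapwood s-1),
#: six published site values reused as realistic tree metadata.
DEFAULT_J_MAX = (2.116, 1.415, 1.230, 1.948, 1.877, 2.072)

#: Interior true parameter values used by the bundled scenarios.
DEFAULT_TRUTH = {
    "xi_m1": 0.09, "xi_m2": 0.11, "xi_m3": 0.10,
    "xi_m4": 0.14, "xi_m5": 0.10, "xi_m6": 0.12,
    "xi_p": 8.0, "eta_m": 0.08, "eta_p": 5.5, "delta_star": 45.0,
    "z0": -3.9, "z1": -0.75,
    "c1": 0.045, "c2": 0.050, "c3": 0.040,
    "c4": 0.060, "c5": 0.050, "c6": 0.055,
    "gamma": 2.2e-3,
    "alpha": -10.0, "beta_w1": 10.0, "beta_w2": 0.25,
}

#: Within-season water-table waypoints (fraction of season, WTD cm):
#: snowmelt waterlogging, drawdown through the optimal band, late-summer
#: drought, autumn recovery.
DEFAULT_WTD_ANCHORS = ((0.0, 8.0), (0.3, 30.0), (0.55, 47.0),
                       (0.8, 120.0), (1.0, 60.0))


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to regenerate a scenario from its seed."""

    name: str = "custom"
    n_trees: int = 6
    n_seasons: int = 4
    days_per_season: int = 184
    start_year: int = 2008
    seed: int = 0
    truth: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    j_max: tuple = DEFAULT_J_MAX
    wtd_anchors: tuple = DEFAULT_WTD_ANCHORS
    temp_mean: float = 12.0
    temp_amp: float = 8.0
    temp_ar1: float = 0.7
    temp_sd: float = 1.5
    hr_base: float = 0.75
    hr_ar1: float = 0.6
    hr_sd: float = 0.06
    i_peak: float = 1.5e-3
    cloud_beta: tuple = (4.0, 1.5)
    wtd_ar1: float = 0.8
    wtd_sd: float = 2.0


def _ar1(rng, n, phi, sd):
    x = np.zeros(n)
    innov = rng.standard_normal(n) * sd
    for k in range(1, n):
        x[k] = phi * x[k - 1] + innov[k]
    return x


def generate_drivers(spec: ScenarioSpec, config: RunConfig | None = None):
    """Daily drivers and water-table temperature for one scenario.

    Returns ``(drivers_df, wtt_df)`` with the standard daily columns; the
    same spec and seed always reproduce the same tables.
    """
    rng = np.random.default_rng(spec.seed)
    frames, wtt_rows = [], []
    for season in range(spec.n_seasons):
        year = spec.start_year + season
        dates = pd.date_range(f"{year}-05-01", periods=spec.days_per_season,
                              freq="D")
        frac = np.linspace(0.0, 1.0, spec.days_per_season)
        seasonal = np.sin(np.pi * frac)
        t = spec.temp_mean + spec.temp_amp * (seasonal - 0.4) \
            + _ar1(rng, spec.days_per_season, spec.temp_ar1, spec.temp_sd)
        h_r = np.clip(spec.hr_base - 0.10 * seasonal
                      + _ar1(rng, spec.days_per_season, spec.hr_ar1, spec.hr_sd),
                      0.3, 1.0)
        envelope = spec.i_peak * (0.45 + 0.55 * seasonal)
        cloud = rng.beta(*spec.cloud_beta, size=spec.days_per_season)
        i = envelope * cloud
        anchors = np.array(spec.wtd_anchors)
        delta = np.interp(frac, anchors[:, 0], anchors[:, 1]) \
            + _ar1(rng, spec.days_per_season, spec.wtd_ar1, spec.wtd_sd)
        delta = np.maximum(delta, 0.0)
        wtt = np.maximum(0.3 + 10.0 * seasonal
                         + _ar1(rng, spec.days_per_season, 0.8, 0.7), 0.0)
        frames.append(pd.DataFrame({
            "date": dates.strftime("%Y-%m-%d"),
            "D": vpd_molar(vpd(t, h_r), t),
            "I": i, "T": t, "T_l": leaf_temperature(t, i),
            "delta": delta,
        }))
        wtt_rows.append(pd.DataFrame({"date": dates.strftime("%Y-%m-%d"),
                                      "wtt": wtt}))
    return (pd.concat(frames, ignore_index=True),
            pd.concat(wtt_rows, ignore_index=True))


def trees_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Tree metadata table: id, nominal maximum sap flow density and error
    group (trees 4 and 6 form the semi-log group W1 when present)."""
    ids = list(range(1, spec.n_trees + 1))
    groups = ["W1" if k in (4, 6) else "W2" for k in ids]
    return pd.DataFrame({"tree_id": ids,
                         "j_max": list(spec.j_max[:spec.n_trees]),
                         "group": groups})


def generate_observations(drivers: pd.DataFrame, spec: ScenarioSpec,
                          config: RunConfig | None = None):
    """Per-tree observed transpiration: forward-model output at the true
    parameters plus heteroscedastic noise, clamped at zero.

    Returns ``(eobs_df, clamp_rate)``; the clamp rate (fraction of draws
    that went negative) is also logged, as clamping slightly biases the
    noise near zero.
    """
    config = config or RunConfig()
    trees = trees_table(spec)
    ds = Dataset.from_frames(drivers, trees=trees, config=config)
    space = ParameterSpace("FM", n_trees=spec.n_trees, config=config)
    truth = _truth_vector(space, spec)
    dp = space.decode(truth)
    sim = simulate(ds, dp)
    rng = np.random.default_rng(spec.seed + 1)
    sd = error_sd(sim.e_model, dp.alpha, dp.beta_w1, dp.beta_w2, ds.w1)
    e_obs = sim.e_model + rng.standard_normal(sim.e_model.shape) * sd
    clamp_rate = float(np.mean(e_obs < 0))
    if clamp_rate:
        logger.info("clamped %.2f%% negative observation draws to 0",
                    100 * clamp_rate)
    e_obs = np.maximum(e_obs, 0.0)
    rows = []
    for k, tid in enumerate(ds.tree_ids):
        rows.append(pd.DataFrame({"date": drivers["date"], "tree_id": tid,
                                  "E_obs": e_obs[k]}))
    return pd.concat(rows, ignore_index=True), clamp_rate


def _truth_vector(space: ParameterSpace, spec: ScenarioSpec) -> np.ndarray:
    missing = [n for n in space.names if n not in spec.truth]
    if missing:
        raise ValueError(f"truth lacks parameter(s) {missing}")
    v = space.encode(spec.truth)
    if not space.in_box(v):
        raise ValueError("true parameters must lie inside the prior boxes")
    return v


# ---------------------------------------------------------------------------
# Fixture registry

def _registry() -> dict[str, ScenarioSpec]:
    return {
        # smallest end-to-end scenario: every CLI subcommand loads it
        "tiny": ScenarioSpec(name="tiny", n_trees=3, n_seasons=1,
                             days_per_season=40),
        # identifiability scenario for the parameter-recovery experiment
        "recovery": ScenarioSpec(name="recovery"),
        # slow monotone WTD ramp across all three conductance regimes
        "regime_sweep": ScenarioSpec(
            name="regime_sweep", n_seasons=1, days_per_season=150,
            wtd_anchors=((0.0, 0.0), (1.0, 150.0)), wtd_sd=0.5),
        # waterlogging-heavy seasons that still visit the plateau and dry
        # regimes, so the monotonic reference model is pinned at depth but
        # cannot bend down under the shallow water table
        "waterlogged": ScenarioSpec(
            name="waterlogged", n_seasons=2,
            wtd_anchors=((0.0, 5.0), (0.35, 15.0), (0.6, 47.0),
                         (0.85, 95.0), (1.0, 25.0))),
    }


def make_fixture(name: str, seed: int = 0, out_dir: str | Path | None = None,
                 config: RunConfig | None = None) -> dict:
    """Generate a bundled scenario; optionally write the standard CSV/YAML
    file set (``daily_drivers.csv``, ``daily_E_obs.csv``, ``wtt.csv``,
    ``trees.csv``, ``truth.yaml``).

    Returns a dict with the frames, the spec and the clamp rate.
    """
    registry = _registry()
    if name not in registry:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{sorted(registry)}")
    spec = replace(registry[name], seed=seed)
    drivers, wtt = generate_drivers(spec, config)
    eobs, clamp_rate = generate_observations(drivers, spec, config)
    out = {"spec": spec, "drivers": drivers, "wtt": wtt, "eobs": eobs,
           "trees": trees_table(spec), "clamp_rate": clamp_rate}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        drivers.to_csv(out_dir / "daily_drivers.csv", index=False)
        eobs.to_csv(out_dir / "daily_E_obs.csv", index=False)
        wtt.to_csv(out_dir / "wtt.csv", index=False)
        out["trees"].to_csv(out_dir / "trees.csv", index=False)
        meta = {"scenario": spec.name, "seed": seed, "variant": "FM",
                "n_trees": spec.n_trees,
                "truth": {k: float(v) for k, v in spec.truth.items()},
                "clamp_rate": clamp_rate}
        (out_dir / "truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out
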
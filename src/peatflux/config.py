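"""Fixed model constants and run configuration.

Two kinds of quantity live here and are deliberately kept apart from the
estimated parameters:

* physical constants fixed by the study design (leaf-to-sapwood area ratio,
  minimum leaf water potential, the van Genuchten retention shape), and
* process constants of the temperature-acclimation ("S") canopy model that
  are taken from the literature rather than calibrated.

Every value can be overridden from a YAML file; ``load_config`` merges a
user file over the defaults and ``RunConfig.echo`` writes the fully resolved
configuration next to the outputs so a run is reproducible from the echo and
the seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SoilConfig:
    """Soil retention and conductance-chain constants.

    ``theta_sat``/``theta_res`` are the saturated and residual volumetric
    water contents of the peat (m3 m-3); ``a_vg`` (cm-1) and ``n_vg`` are the
    van Genuchten retention constants, fixed by the retention curve used to
    map water table depth to soil water content.  ``k0`` is the base-case
    xylem conductance of the marginal-water-use-efficiency bridge
    (mol H2O m-2 leaf s-1 Pa-1).  ``leaf_area_conversion`` maps the
    soil-to-root multiplier coefficients from the scale of their prior boxes
    (a root-module parameter product, mol m-2 s-1 Pa-1) to per-leaf-area
    conductance; it is applied exactly once, when a parameter vector is
    decoded.
    """

    theta_sat: float = 0.88
    theta_res: float = 0.108
    a_vg: float = 0.072
    n_vg: float = 1.371
    k0: float = 2.22e-8
    leaf_area_conversion: float = 9.31e-7


@dataclass(frozen=True)
class CanopyConfig:
    """Fixed constants of the optimal-stomata canopy model.

    ``r0`` (mol CO2 m-2 s-1) is dark respiration at 0 degC and ``q10`` its
    relative increase per 10 degC.  ``s0`` (degC) and ``tau`` (days) are the
    threshold and time constant of the delayed temperature acclimation.
    ``ca`` is atmospheric CO2 as a molar concentration (mol m-3; 0.0167
    corresponds to ~405 ppm at 20 degC).  ``spinup_days`` optionally repeats
    the first day of each season before the simulated period to settle the
    acclimation state.
    """

    r0: float = 1.0e-6
    q10: float = 2.0
    s0: float = 5.0
    tau: float = 7.0
    ca: float = 0.0167
    spinup_days: int = 0


@dataclass(frozen=True)
class TreeConfig:
    """Whole-tree conversion constants.

    ``rho`` is the leaf-to-sapwood area ratio (m2 leaf per m2 sapwood) used
    to convert sap flow density to leaf-area transpiration; ``psi_lmin``
    (Pa, negative) is the minimum leaf water potential of the isohydric
    assumption.  Both are held constant across trees and years.
    """

    rho: float = 2500.0
    psi_lmin: float = -2.0e6


@dataclass(frozen=True)
class InferenceConfig:
    n_walkers: int = 48
    n_steps: int = 3000
    seed: int = 0
    rm2_cap: str = "none"  # "none" | "ksr_star": whether RM2 caps k_sr at the plateau


@dataclass(frozen=True)
class RunConfig:
    soil: SoilConfig = field(default_factory=SoilConfig)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, path: str | Path) -> None:
        """Write the fully resolved configuration as YAML."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig`, merging a YAML file over the defaults.

    Unknown keys raise ``KeyError`` with the offending field path so a typo
    in a config file fails loudly rather than silently using a default.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    blocks = {}
    classes = {
        "soil": SoilConfig,
        "canopy": CanopyConfig,
        "tree": TreeConfig,
        "inference": InferenceConfig,
    }
    for block, cls in classes.items():
        override = raw.pop(block, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        for key in override:
            if key not in names:
                raise KeyError(f"unknown config field {block}.{key}")
        blocks[block] = cls(**override)
    if raw:
        raise KeyError(f"unknown config block(s): {sorted(raw)}")
    return RunConfig(**blocks)
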
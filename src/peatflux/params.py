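"""Parameter vectors, prior boxes and variant-specific layouts.

The full model (FM) estimates 22 quantities: per-tree soil-root multipliers
xi_m_i, shared xi_p/eta_m/eta_p/delta_star, the MWUE bridge z0/z1, per-tree
acclimation slopes c_i, the shared light saturation gamma, plus the three
error-model parameters alpha/beta_w1/beta_w2.  RM1 replaces the whole
belowground block with one temporally constant lambda_i per tree; RM2 drops
only the waterlogging branch (eta_m, eta_p, delta_star).  All priors are
independent uniform boxes.

The multipliers xi_m/eta_m are carried in the vector on the scale of their
prior boxes and converted to per-leaf-area conductance exactly once, in
``ParameterSpace.decode``, by the configured ``leaf_area_conversion``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig

VARIANTS = ("FM", "RM1", "RM2")

#: Default tree-number -> error-model group map (1-based tree numbers).
#: Group W1 uses a semi-log-linear SD, W2 a proportional SD.
DEFAULT_W1_TREES = (4, 6)

#: Uniform prior boxes for the shared/scalar parameters.
PRIOR_BOXES = {
    "xi_m": (0.07, 0.15),
    "xi_p": (7.0, 10.0),
    "eta_m": (0.05, 0.17),
    "eta_p": (1.5, 10.0),
    "delta_star": (20.0, 50.0),
    "z0": (-5.2, -3.8),
    "z1": (-1.0, -0.5),
    "c": (0.01, 0.07),
    "gamma": (1.6e-3, 3.0e-3),
    # error model (literature gives no ranges; wide boxes, overridable)
    "alpha": (-15.0, 0.0),
    "beta_w1": (0.0, 50.0),
    "beta_w2": (0.0, 1.0),
    # RM1 only: temporally constant per-tree MWUE
    "lambda": (1.0e-3, 1.0e-2),
}


@dataclass
class DecodedParams:
    """A parameter vector unpacked into named arrays (per-tree where
    applicable).  ``xi_m``/``eta_m`` are already on the per-leaf-area
    conductance scale."""

    variant: str
    xi_m: np.ndarray | None = None     # (n_trees,)
    xi_p: float | None = None
    eta_m: float | None = None
    eta_p: float | None = None
    delta_star: float | None = None
    z0: float | None = None
    z1: float | None = None
    c: np.ndarray = field(default_factory=lambda: np.empty(0))  # (n_trees,)
    gamma: float = float("nan")
    alpha: float = float("nan")
    beta_w1: float = float("nan")
    beta_w2: float = float("nan")
    lambda_const: np.ndarray | None = None  # (n_trees,) RM1 only


def _base_name(name: str) -> str:
    """Strip the tree index from per-tree parameter names."""
    m = re.fullmatch(r"(xi_m|c|lambda)(\d+)", name)
    return m.group(1) if m else name


class ParameterSpace:
    """Ordered name <-> position mapping for one model variant.

    Provides encode/decode (exact round-trip), box membership, and seeded
    prior sampling.  ``priors`` may override any box by base name (e.g.
    ``"xi_m"`` applies to every tree) or full name (``"xi_m3"``).
    """

    def __init__(self, variant: str = "FM", n_trees: int = 6,
                 priors: dict | None = None, config: RunConfig | None = None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.n_trees = n_trees
        self.config = config or RunConfig()
        boxes = dict(PRIOR_BOXES)
        trees = range(1, n_trees + 1)
        names: list[str] = []
        if variant == "RM1":
            names += [f"lambda{i}" for i in trees]
        else:
            names += [f"xi_m{i}" for i in trees] + ["xi_p"]
            if variant == "FM":
                names += ["eta_m", "eta_p", "delta_star"]
            names += ["z0", "z1"]
        names += [f"c{i}" for i in trees] + ["gamma", "alpha", "beta_w1", "beta_w2"]
        self.names = names
        lo, hi = [], []
        for name in names:
            base = _base_name(name)
            box = (priors or {}).get(name) or (priors or {}).get(base) or boxes[base]
            if box[0] >= box[1]:
                raise ValueError(f"prior for {name} has lower >= upper")
            lo.append(box[0])
            hi.append(box[1])
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    @property
    def ndim(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def in_box(self, vector) -> bool:
        v = np.asarray(vector, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def sample_prior(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))

    # -- encode / decode ----------------------------------------------------

    def encode(self, values: dict) -> np.ndarray:
        return np.array([values[name] for name in self.names], dtype=float)

    def decode(self, vector) -> DecodedParams:
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.ndim,):
            raise ValueError(f"expected vector of length {self.ndim}")
        d = dict(zip(self.names, v))
        t = range(1, self.n_trees + 1)
        conv = self.config.soil.leaf_area_conversion
        out = DecodedParams(
            variant=self.variant,
            c=np.array([d[f"c{i}"] for i in t]),
            gamma=d["gamma"], alpha=d["alpha"],
            beta_w1=d["beta_w1"], beta_w2=d["beta_w2"],
        )
        if self.variant == "RM1":
            out.lambda_const = np.array([d[f"lambda{i}"] for i in t])
        else:
            out.xi_m = conv * np.array([d[f"xi_m{i}"] for i in t])
            out.xi_p = d["xi_p"]
            out.z0, out.z1 = d["z0"], d["z1"]
            if self.variant == "FM":
                out.eta_m = conv * d["eta_m"]
                out.eta_p = d["eta_p"]
                out.delta_star = d["delta_star"]
        return out
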
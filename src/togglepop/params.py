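"""Parameter containers, named presets, and dimensional scaling.

Two dimensionless parameter presets are shipped: ``reference`` (the
mirror-symmetric working point) and ``modified`` (nonzero leakiness,
stronger repression rates, unequal autoinducer Hill coefficients, which
breaks the mirror symmetry).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "DimensionalParams",
    "get_preset",
    "PRESET_NAMES",
    "nondimensionalize",
    "mirror_params",
    "is_mirror_symmetric",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameters shared by the S and A population models.

    Attributes
    ----------
    a1, a2 : float
        Maximal cross-repression transcription rates (x repressed by y and
        vice versa).
    a3, a4 : float
        Maximal autoinducer-activated rates feeding x and y.
    a5, a6 : float
        Maximal intracellular autoinducer synthesis rates.
    nX, nY, nG, nR : float
        Hill coefficients (>= 1) of the repression/activation terms.
    gamma_x, gamma_y, gamma_g, gamma_r : float
        Promoter leakiness offsets.
    d : float
        Dimensionless membrane diffusion (cell-medium exchange) rate.
    delta_g, delta_r : float
        Lumped intracellular dilution/degradation rates of the autoinducers.
    delta_e : float
        Extracellular dilution rate.
    rho : float
        Population density in [0, 1].
    """

    a1: float = 20.0
    a2: float = 20.0
    a3: float = 10.0
    a4: float = 10.0
    a5: float = 3.0
    a6: float = 3.0
    nX: float = 3.0
    nY: float = 3.0
    nG: float = 3.0
    nR: float = 3.0
    gamma_x: float = 0.0
    gamma_y: float = 0.0
    gamma_g: float = 0.0
    gamma_r: float = 0.0
    d: float = 0.1
    delta_g: float = 1.0
    delta_r: float = 1.0
    delta_e: float = 0.5
    rho: float = 0.8

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "a5", "a6",
                     "gamma_x", "gamma_y", "gamma_g", "gamma_r", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("delta_g", "delta_r", "delta_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nX", "nY", "nG", "nR"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


#: The mirror-symmetric working preset used throughout the analysis.
REFERENCE = ModelParams()

#: Robustness preset: nonzero leakiness, a1=a2=100, unequal Hill
#: coefficients nG=1, nR=2 (mirror symmetry is broken).
MODIFIED = REFERENCE.replace(
    gamma_x=0.01, gamma_y=0.01, gamma_g=0.01, gamma_r=0.01,
    a1=100.0, a2=100.0, nX=2.0, nY=2.0, nG=1.0, nR=2.0,
)

_PRESETS = {"reference": REFERENCE, "modified": MODIFIED}
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> ModelParams:
    """Return a named parameter preset (``reference`` or ``modified``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


_MIRROR_PAIRS = [
    ("a1", "a2"), ("a3", "a4"), ("a5", "a6"),
    ("nX", "nY"), ("nG", "nR"),
    ("gamma_x", "gamma_y"), ("gamma_g", "gamma_r"),
    ("delta_g", "delta_r"),
]


def mirror_params(params: ModelParams) -> ModelParams:
    """Swap the green/red arms of the parameter set (involution)."""
    changes = {}
    for a, b in _MIRROR_PAIRS:
        changes[a] = getattr(params, b)
        changes[b] = getattr(params, a)
    return params.replace(**changes)


def is_mirror_symmetric(params: ModelParams, rtol: float = 0.0) -> bool:
    """True if the parameter set is a fixed point of the arm swap."""
    for a, b in _MIRROR_PAIRS:
        va, vb = getattr(params, a), getattr(params, b)
        if abs(va - vb) > rtol * max(abs(va), abs(vb), 1.0):
            return False
    return True


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional (biochemical) parameters feeding the scaling formulas.

    Burst sizes ``b_*``, transcription/synthesis rates ``k_*``, promoter
    copy numbers ``P_*``, repression thresholds ``K_X``/``K_Y``, activation
    thresholds ``K_G``/``K_R``, export rates ``D_G``/``D_R``, degradation
    rates ``r_d``/``r_G``/``r_R`` and growth/dilution rates ``mu``/``mu_e``.
    All strictly positive.
    """

    b_x: float
    b_y: float
    b_u: float
    b_w: float
    k_x: float
    k_y: float
    k_u: float
    k_w: float
    k_G: float
    k_R: float
    P_X: float
    P_Y: float
    P_G: float
    P_R: float
    K_X: float
    K_Y: float
    K_G: float
    K_R: float
    D_G: float
    D_R: float
    r_d: float
    r_G: float
    r_R: float
    mu: float
    mu_e: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


def nondimensionalize(dim: DimensionalParams, *, d: float | None = None,
                      rho: float = 0.8,
                      hill: tuple[float, float, float, float] = (3, 3, 3, 3),
                      leakiness: tuple[float, float, float, float] = (0, 0, 0, 0),
                      ) -> ModelParams:
    """Convert dimensional parameters to the dimensionless set.

    The repressor degradation scale ``r_d + mu`` sets the time unit; all
    rates below are expressed relative to it. Hill coefficients, leakiness,
    and density are dimensionless pass-throughs with no scaling formula.

    When ``d`` is omitted the green-arm export rate sets the diffusion
    coefficient, ``d = D_G / (r_d + mu)`` (the model carries a single
    diffusion coefficient; mirror symmetry requires D_G = D_R).
    """
    s = dim.r_d + dim.mu
    if s == 0:
        raise ZeroDivisionError("r_d + mu must be positive")
    d_g = dim.D_G / s
    d_r = dim.D_R / s
    if d is None:
        d = d_g
    return ModelParams(
        a1=dim.b_x * dim.k_x * dim.P_Y / (dim.K_X * s),
        a2=dim.b_y * dim.k_y * dim.P_X / (dim.K_Y * s),
        a3=dim.b_x * dim.k_x * dim.P_G / (dim.K_X * s),
        a4=dim.b_y * dim.k_y * dim.P_R / (dim.K_Y * s),
        a5=dim.b_u * dim.k_u * dim.k_G * dim.P_Y / (dim.K_G * s**2),
        a6=dim.b_w * dim.k_w * dim.k_R * dim.P_X / (dim.K_R * s**2),
        nX=hill[0], nY=hill[1], nG=hill[2], nR=hill[3],
        gamma_x=leakiness[0], gamma_y=leakiness[1],
        gamma_g=leakiness[2], gamma_r=leakiness[3],
        d=d,
        delta_g=(dim.r_G + dim.mu) / s,
        delta_r=(dim.r_R + dim.mu) / s,
        delta_e=dim.mu_e / s,
        rho=rho,
    )


def diffusion_rates(dim: DimensionalParams) -> tuple[float, float]:
    """Per-arm dimensionless export rates (d_g, d_r)."""
    s = dim.r_d + dim.mu
    return dim.D_G / s, dim.D_R / s


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter mapping from YAML or JSON; unknown keys rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
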
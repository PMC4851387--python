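"""Vector fields and analytic Jacobians of the S and A population models.

State layout
------------
S model (``4N + 2`` variables): per-cell blocks ``(x_i, y_i, g_i, r_i)``
in cell order, followed by the shared extracellular pair ``(g_e, r_e)``.

A model (``3N + 1`` variables): per-cell blocks ``(x_i, y_i, r_i)``
followed by the shared ``r_e``.

``x_i``/``y_i`` are the mutually repressing proteins, ``g_i``/``r_i`` the
intracellular autoinducers, ``g_e``/``r_e`` their extracellular pools. All
cells exchange autoinducer with the medium at rate ``d``; the medium sees
the population through the mean-field term ``(rho/N) * sum_i d(u_i - u_e)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, mirror_params

__all__ = [
    "PopulationSpec",
    "rhs",
    "s_rhs",
    "a_rhs",
    "jacobian",
    "mirror_state",
    "mirror_map",
    "hill_act",
    "hill_rep",
    "state_bounds",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Model identity plus the subpopulation structure of a cell population."""

    model_id: str
    subpop_counts: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.model_id not in ("S", "A"):
            raise ValueError("model_id must be 'S' or 'A'")
        counts = tuple(int(c) for c in self.subpop_counts)
        if not counts or any(c <= 0 for c in counts):
            raise ValueError("subpop_counts must be positive integers")
        object.__setattr__(self, "subpop_counts", counts)

    @property
    def N(self) -> int:
        return sum(self.subpop_counts)

    @property
    def n_cell_vars(self) -> int:
        return 4 if self.model_id == "S" else 3

    @property
    def n_ext_vars(self) -> int:
        return 2 if self.model_id == "S" else 1

    @property
    def dim(self) -> int:
        """State dimension: 4N+2 for S, 3N+1 for A."""
        return self.n_cell_vars * self.N + self.n_ext_vars

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(c / self.N for c in self.subpop_counts)

    def var_names(self) -> list[str]:
        per_cell = ("x", "y", "g", "r") if self.model_id == "S" else ("x", "y", "r")
        names = [f"{v}{i+1}" for i in range(self.N) for v in per_cell]
        names += ["ge", "re"] if self.model_id == "S" else ["re"]
        return names

    def cell_slice(self, i: int) -> slice:
        m = self.n_cell_vars
        return slice(m * i, m * (i + 1))

    def subpop_cells(self, k: int) -> range:
        start = sum(self.subpop_counts[:k])
        return range(start, start + self.subpop_counts[k])


def _clamped(u: np.ndarray | float, n: float) -> np.ndarray:
    # the state space is the non-negative orthant; transient solver
    # overshoots below zero must not produce NaN
    u = np.maximum(np.asarray(u, dtype=float), 0.0)
    if n < 1 and np.any(u == 0.0):
        raise FloatingPointError(
            "Hill term with exponent < 1 evaluated at zero component"
        )
    return u


def hill_act(u, n: float):
    """Activating Hill term u^n / (1 + u^n), clamped to u >= 0."""
    un = _clamped(u, n) ** n
    return un / (1.0 + un)


def hill_rep(u, n: float):
    """Repressing Hill term 1 / (1 + u^n), clamped to u >= 0."""
    return 1.0 / (1.0 + _clamped(u, n) ** n)


def _dhill(u, n: float):
    """|d/du| of both Hill terms: n u^(n-1) / (1 + u^n)^2."""
    u = _clamped(u, n)
    if n < 1:
        raise FloatingPointError("Hill derivative unbounded at zero for n < 1")
    with np.errstate(divide="ignore"):
        un1 = np.where(u > 0, u, 1.0) ** (n - 1.0)
        un1 = np.where(u > 0, un1, 0.0 if n > 1 else 1.0)
    return n * un1 / (1.0 + u**n) ** 2


def _check_state(state: np.ndarray, spec: PopulationSpec) -> np.ndarray:
    z = np.asarray(state, dtype=float)
    if z.shape != (spec.dim,):
        raise ValueError(
            f"state has shape {z.shape}, expected ({spec.dim},) for "
            f"model {spec.model_id} with N={spec.N}"
        )
    return z


def s_rhs(state, params: ModelParams, spec: PopulationSpec) -> np.ndarray:
    """Right-hand side of the S population model."""
    if spec.model_id != "S":
        raise ValueError("s_rhs requires an S-model spec")
    z = _check_state(state, spec)
    N = spec.N
    p = params
    cells = z[: 4 * N].reshape(N, 4)
    x, y, g, r = cells.T
    ge, re = z[4 * N], z[4 * N + 1]

    dx = p.gamma_x + p.a1 * hill_rep(y, p.nY) + p.a3 * hill_act(g, p.nG) - x
    dy = p.gamma_y + p.a2 * hill_rep(x, p.nX) + p.a4 * hill_act(r, p.nR) - y
    dg = p.gamma_g + p.a5 * hill_rep(y, p.nY) + p.d * (ge - g) - p.delta_g * g
    dr = p.gamma_r + p.a6 * hill_rep(x, p.nX) + p.d * (re - r) - p.delta_r * r
    dge = p.rho / N * np.sum(p.d * (g - ge)) - p.delta_e * ge
    dre = p.rho / N * np.sum(p.d * (r - re)) - p.delta_e * re

    out = np.empty_like(z)
    out[: 4 * N] = np.column_stack([dx, dy, dg, dr]).ravel()
    out[4 * N] = dge
    out[4 * N + 1] = dre
    return out


def a_rhs(state, params: ModelParams, spec: PopulationSpec) -> np.ndarray:
    """Right-hand side of the A population model."""
    if spec.model_id != "A":
        raise ValueError("a_rhs requires an A-model spec")
    z = _check_state(state, spec)
    N = spec.N
    p = params
    cells = z[: 3 * N].reshape(N, 3)
    x, y, r = cells.T
    re = z[3 * N]

    dx = p.gamma_x + p.a1 * hill_rep(y, p.nY) + p.a4 * hill_act(r, p.nR) - x
    dy = p.gamma_y + p.a2 * hill_rep(x, p.nX) - y
    dr = p.gamma_r + p.a6 * hill_rep(x, p.nX) + p.d * (re - r) - p.delta_r * r
    dre = p.rho / N * np.sum(p.d * (r - re)) - p.delta_e * re

    out = np.empty_like(z)
    out[: 3 * N] = np.column_stack([dx, dy, dr]).ravel()
    out[3 * N] = dre
    return out


def rhs(state, params: ModelParams, spec: PopulationSpec) -> np.ndarray:
    """Model-dispatching right-hand side."""
    f = s_rhs if spec.model_id == "S" else a_rhs
    return f(state, params, spec)


def jacobian(state, params: ModelParams, spec: PopulationSpec) -> np.ndarray:
    """Dense analytic Jacobian of :func:`rhs` at ``state``."""
    z = _check_state(state, spec)
    N, p = spec.N, params
    n = spec.dim
    J = np.zeros((n, n))

    if spec.model_id == "S":
        cells = z[: 4 * N].reshape(N, 4)
        x, y, g, r = cells.T
        dxy = -p.a1 * _dhill(y, p.nY)   # d(dx)/dy
        dxg = p.a3 * _dhill(g, p.nG)
        dyx = -p.a2 * _dhill(x, p.nX)
        dyr = p.a4 * _dhill(r, p.nR)
        dgy = -p.a5 * _dhill(y, p.nY)
        drx = -p.a6 * _dhill(x, p.nX)
        ge_row, re_row = 4 * N, 4 * N + 1
        for i in range(N):
            b = 4 * i
            J[b, b] = -1.0
            J[b, b + 1] = dxy[i]
            J[b, b + 2] = dxg[i]
            J[b + 1, b + 1] = -1.0
            J[b + 1, b] = dyx[i]
            J[b + 1, b + 3] = dyr[i]
            J[b + 2, b + 2] = -(p.d + p.delta_g)
            J[b + 2, b + 1] = dgy[i]
            J[b + 2, ge_row] = p.d
            J[b + 3, b + 3] = -(p.d + p.delta_r)
            J[b + 3, b] = drx[i]
            J[b + 3, re_row] = p.d
            J[ge_row, b + 2] = p.rho * p.d / N
            J[re_row, b + 3] = p.rho * p.d / N
        J[ge_row, ge_row] = -(p.rho * p.d + p.delta_e)
        J[re_row, re_row] = -(p.rho * p.d + p.delta_e)
    else:
        cells = z[: 3 * N].reshape(N, 3)
        x, y, r = cells.T
        dxy = -p.a1 * _dhill(y, p.nY)
        dxr = p.a4 * _dhill(r, p.nR)
        dyx = -p.a2 * _dhill(x, p.nX)
        drx = -p.a6 * _dhill(x, p.nX)
        re_row = 3 * N
        for i in range(N):
            b = 3 * i
            J[b, b] = -1.0
            J[b, b + 1] = dxy[i]
            J[b, b + 2] = dxr[i]
            J[b + 1, b + 1] = -1.0
            J[b + 1, b] = dyx[i]
            J[b + 2, b + 2] = -(p.d + p.delta_r)
            J[b + 2, b] = drx[i]
            J[b + 2, re_row] = p.d
            J[re_row, b + 2] = p.rho * p.d / N
        J[re_row, re_row] = -(p.rho * p.d + p.delta_e)
    return J


def mirror_state(state, spec: PopulationSpec) -> np.ndarray:
    """Swap x<->y, g<->r per cell and g_e<->r_e (S model only)."""
    if spec.model_id != "S":
        raise ValueError("mirror symmetry is defined for the S model only")
    z = _check_state(state, spec)
    out = z.copy()
    N = spec.N
    cells = out[: 4 * N].reshape(N, 4)
    cells[:, [0, 1, 2, 3]] = cells[:, [1, 0, 3, 2]]
    out[4 * N], out[4 * N + 1] = z[4 * N + 1], z[4 * N]
    return out


def mirror_map(state, params: ModelParams, spec: PopulationSpec):
    """Full mirror involution: (state, params) -> (state', params').

    Applying it twice is the identity; the S vector field is equivariant
    under it whenever the parameter set is mirror-symmetric.
    """
    return mirror_state(state, spec), mirror_params(params)


def _autoinducer_bounds(p: ModelParams, prod_max: float,
                        delta: float) -> tuple[float, float]:
    # Self-consistent trap for one autoinducer arm: at u = U with e <= E
    # the intracellular derivative is <= 0, and at e = E with u <= U the
    # extracellular derivative is <= 0.
    denom = (p.d + delta) * (p.rho * p.d + p.delta_e) - p.rho * p.d**2
    U = prod_max * (p.rho * p.d + p.delta_e) / denom
    E = p.rho * p.d * U / (p.rho * p.d + p.delta_e)
    return U, E


def state_bounds(params: ModelParams, spec: PopulationSpec) -> np.ndarray:
    """Componentwise upper bounds of a forward-invariant box.

    Every production term is bounded by leakiness plus maximal rates, so
    the box [0, ub] traps all trajectories started inside it.
    """
    p = params
    if spec.model_id == "S":
        ub_x = p.gamma_x + p.a1 + p.a3
        ub_y = p.gamma_y + p.a2 + p.a4
        ub_g, ub_ge = _autoinducer_bounds(p, p.gamma_g + p.a5, p.delta_g)
        ub_r, ub_re = _autoinducer_bounds(p, p.gamma_r + p.a6, p.delta_r)
        per_cell, ext = [ub_x, ub_y, ub_g, ub_r], [ub_ge, ub_re]
    else:
        ub_x = p.gamma_x + p.a1 + p.a4
        ub_y = p.gamma_y + p.a2
        ub_r, ub_re = _autoinducer_bounds(p, p.gamma_r + p.a6, p.delta_r)
        per_cell, ext = [ub_x, ub_y, ub_r], [ub_re]
    return np.array(per_cell * spec.N + ext)
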
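"""Equilibrium finding, classification, enumeration and spectrum reduction.

Newton refinement backs every equilibrium reported by the package; the
eigenvalues of the analytic Jacobian decide stability. The block structure
of the population Jacobian (identical intra-subpopulation blocks coupled
through a shared mean field) lets the full spectrum be reproduced from
small auxiliary systems, independently of the population size N; see
:func:`reduced_spectrum_check`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvals
from scipy.optimize import linear_sum_assignment

from .models import PopulationSpec, hill_act, hill_rep, jacobian, rhs, state_bounds
from .params import ModelParams

__all__ = [
    "NEWTON_TOL",
    "STABILITY_MARGIN",
    "EquilibriumRecord",
    "RegionMap",
    "MultistartPlan",
    "ConvergenceError",
    "find_equilibrium",
    "enumerate_equilibria",
    "classify_stability",
    "bistability_scan",
    "single_toggle_equilibria",
    "reduced_spectrum_check",
    "SpectrumReport",
]

NEWTON_TOL = 1e-10          # residual sup-norm
STABILITY_MARGIN = 1e-7     # |max Re(lambda)| below this -> marginal
MAX_ITER = 200
DEDUP_TOL = 1e-6            # relative sup-norm distance for deduplication


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class EquilibriumRecord:
    """A refined steady state with its linearization data."""

    state: np.ndarray
    params: ModelParams
    spec: PopulationSpec
    residual_norm: float
    eigenvalues: np.ndarray
    stable: bool
    labels: tuple[str, ...]       # per-cell 'G', 'R' or '?' (tie)
    ratio: tuple[int, int]        # (#G cells, #R cells)
    boundary_warning: bool = False

    @property
    def leading_eigenvalue(self) -> complex:
        return self.eigenvalues[np.argmax(self.eigenvalues.real)]

    @property
    def signature(self) -> str:
        g, r = self.ratio
        return f"{g}:{r}"

    @property
    def homogeneous(self) -> bool:
        return len(set(self.labels)) == 1 and "?" not in self.labels


def _labels(state: np.ndarray, spec: PopulationSpec,
            tie_tol: float = 1e-9) -> tuple[str, ...]:
    m = spec.n_cell_vars
    out = []
    for i in range(spec.N):
        x, y = state[m * i], state[m * i + 1]
        if abs(x - y) <= tie_tol * max(abs(x), abs(y), 1.0):
            out.append("?")
        elif x > y:
            out.append("G")
        else:
            out.append("R")
    return tuple(out)


def _record(state: np.ndarray, params: ModelParams, spec: PopulationSpec,
            residual: float, boundary: bool = False) -> EquilibriumRecord:
    eigs = eigvals(jacobian(state, params, spec))
    labels = _labels(state, spec)
    ratio = (labels.count("G"), labels.count("R"))
    return EquilibriumRecord(
        state=state, params=params, spec=spec, residual_norm=residual,
        eigenvalues=eigs, stable=bool(np.max(eigs.real) < -STABILITY_MARGIN),
        labels=labels, ratio=ratio, boundary_warning=boundary,
    )


def find_equilibrium(guess, params: ModelParams, spec: PopulationSpec,
                     tol: float = NEWTON_TOL,
                     max_iter: int = MAX_ITER) -> EquilibriumRecord:
    """Damped (Armijo) Newton iteration on the model right-hand side."""
    z = np.asarray(guess, dtype=float).copy()
    if z.shape != (spec.dim,):
        raise ValueError(f"guess has shape {z.shape}, expected ({spec.dim},)")
    if not np.all(np.isfinite(z)) or np.any(z < 0):
        raise ValueError("guess must be finite and non-negative")

    f = rhs(z, params, spec)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            break
        J = jacobian(z, params, spec)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        norm0 = np.linalg.norm(f)
        lam = 1.0
        for _ in range(40):
            z_new = z + lam * step
            f_new = rhs(z_new, params, spec)
            if np.linalg.norm(f_new) < (1.0 - 1e-4 * lam) * norm0:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("Armijo line search stalled", z)
        z, f = z_new, f_new
    else:
        raise ConvergenceError(
            f"no convergence within {max_iter} iterations "
            f"(residual {np.max(np.abs(f)):.2e})", z)

    boundary = bool(np.any(z < 0))
    z = np.maximum(z, 0.0)  # project to the non-negative orthant
    residual = float(np.max(np.abs(rhs(z, params, spec))))
    return _record(z, params, spec, residual, boundary)


def classify_stability(eq: EquilibriumRecord,
                       margin: float = STABILITY_MARGIN) -> tuple[str, complex]:
    """Return ('stable'|'unstable'|'marginal', leading eigenvalue)."""
    lead = eq.leading_eigenvalue
    if lead.real < -margin:
        return "stable", lead
    if lead.real > margin:
        return "unstable", lead
    return "marginal", lead


# ---------------------------------------------------------------------------
# single-toggle reductions (d = 0): the population decouples and equilibria
# solve a scalar fixed-point equation in x
# ---------------------------------------------------------------------------

def _scalar_curve(params: ModelParams, model_id: str, x: np.ndarray) -> np.ndarray:
    """phi(x) = x - F(x) whose roots are single-toggle equilibria at d=0."""
    p = params
    if model_id == "S":
        r = (p.gamma_r + p.a6 * hill_rep(x, p.nX)) / p.delta_r
        y = p.gamma_y + p.a2 * hill_rep(x, p.nX) + p.a4 * hill_act(r, p.nR)
        g = (p.gamma_g + p.a5 * hill_rep(y, p.nY)) / p.delta_g
        F = p.gamma_x + p.a1 * hill_rep(y, p.nY) + p.a3 * hill_act(g, p.nG)
    else:
        y = p.gamma_y + p.a2 * hill_rep(x, p.nX)
        r = (p.gamma_r + p.a6 * hill_rep(x, p.nX)) / p.delta_r
        F = p.gamma_x + p.a1 * hill_rep(y, p.nY) + p.a4 * hill_act(r, p.nR)
    return x - F


def _full_state_from_x(params: ModelParams, model_id: str, x: float) -> np.ndarray:
    p = params
    if model_id == "S":
        r = (p.gamma_r + p.a6 * hill_rep(x, p.nX)) / p.delta_r
        y = p.gamma_y + p.a2 * hill_rep(x, p.nX) + p.a4 * hill_act(r, p.nR)
        g = (p.gamma_g + p.a5 * hill_rep(y, p.nY)) / p.delta_g
        return np.array([x, y, g, r, 0.0, 0.0])
    y = p.gamma_y + p.a2 * hill_rep(x, p.nX)
    r = (p.gamma_r + p.a6 * hill_rep(x, p.nX)) / p.delta_r
    return np.array([x, y, r, 0.0])


def single_toggle_equilibria(params: ModelParams, model_id: str = "S",
                             n_scan: int = 4000) -> list[EquilibriumRecord]:
    """All equilibria of a decoupled (d = 0) single toggle.

    Uses the scalar fixed-point reduction in x: a dense sign-change scan
    followed by bisection and a full-system Newton polish. Exhaustive for
    the Hill-type curves here (finitely many simple roots).
    """
    if params.d != 0:
        raise ValueError("single-toggle reduction requires d = 0")
    spec = PopulationSpec(model_id, (1,))
    p = params
    x_max = p.gamma_x + p.a1 + (p.a3 if model_id == "S" else p.a4) + 1.0
    xs = np.linspace(0.0, x_max, n_scan)
    phi = _scalar_curve(params, model_id, xs)
    roots = []
    sign = np.sign(phi)
    for i in np.flatnonzero(np.diff(sign) != 0):
        lo, hi = xs[i], xs[i + 1]
        flo = phi[i]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            fm = _scalar_curve(params, model_id, np.array([mid]))[0]
            if fm == 0:
                lo = hi = mid
                break
            if (fm > 0) == (flo > 0):
                lo, flo = mid, fm
            else:
                hi = mid
        roots.append(0.5 * (lo + hi))
    records = []
    for x0 in roots:
        guess = np.maximum(_full_state_from_x(params, model_id, x0), 0.0)
        try:
            records.append(find_equilibrium(guess, params, spec))
        except ConvergenceError:
            continue
    return _dedup(records)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultistartPlan:
    """Deterministic lattice plus seeded random starting points."""

    n_lattice: int = 125       # lattice points (per-axis count is derived)
    n_random: int = 200
    seed: int = 0


def _dedup(records: list[EquilibriumRecord],
           tol: float = DEDUP_TOL) -> list[EquilibriumRecord]:
    kept: list[EquilibriumRecord] = []
    for rec in records:
        dup = False
        for other in kept:
            scale = max(np.max(np.abs(other.state)), 1.0)
            if np.max(np.abs(rec.state - other.state)) < tol * scale:
                dup = True
                break
        if not dup:
            kept.append(rec)
    kept.sort(key=lambda r: (-r.ratio[0], r.ratio[1], tuple(r.state[:2])))
    return kept


def enumerate_equilibria(params: ModelParams, spec: PopulationSpec,
                         multistart: MultistartPlan | None = None,
                         ) -> list[EquilibriumRecord]:
    """Newton from a guess lattice plus seeded random points, deduplicated.

    For a decoupled single toggle (N=1, d=0) the deterministic lattice is
    placed along the scalar fixed-point reduction, which is exhaustive;
    lattice and random multistarts are still run on the full system.
    """
    plan = multistart or MultistartPlan()
    records: list[EquilibriumRecord] = []

    if spec.N == 1 and params.d == 0:
        records.extend(single_toggle_equilibria(params, spec.model_id))

    ub = state_bounds(params, spec)
    n = spec.dim
    per_axis = max(2, int(round(plan.n_lattice ** (1.0 / n))))
    axes = [np.linspace(0.0, u, per_axis) for u in ub]
    mesh = np.meshgrid(*axes, indexing="ij")
    lattice = np.stack([m.ravel() for m in mesh], axis=1)
    rng = np.random.default_rng(plan.seed)
    randoms = rng.uniform(0.0, 1.0, size=(plan.n_random, n)) * ub

    for guess in np.vstack([lattice, randoms]):
        try:
            rec = find_equilibrium(guess, params, spec)
        except ConvergenceError:
            continue
        if rec.residual_norm < NEWTON_TOL * 10:
            records.append(rec)
    return _dedup(records)


# ---------------------------------------------------------------------------
# bistability region scan (single decoupled toggle)
# ---------------------------------------------------------------------------

@dataclass
class RegionMap:
    """Per-(a1, a2) count of distinct stable equilibria of a single toggle."""

    model_id: str
    a1_values: np.ndarray
    a2_values: np.ndarray
    counts: np.ndarray           # shape (len(a1), len(a2))
    failed: np.ndarray           # bool mask of solver failures

    @property
    def bistable_mask(self) -> np.ndarray:
        return self.counts >= 2

    @property
    def all_bistable(self) -> bool:
        return bool(np.all(self.counts[~self.failed] >= 2))

    @property
    def any_bistable(self) -> bool:
        return bool(np.any(self.counts[~self.failed] >= 2))


def bistability_scan(model_id: str, base_params: ModelParams,
                     a1_values=None, a2_values=None) -> RegionMap:
    """Count stable single-toggle equilibria over an (a1, a2) grid at d=0."""
    if base_params.d != 0:
        raise ValueError("bistability scan is defined for decoupled toggles (d = 0)")
    a1_values = np.arange(0.0, 51.0) if a1_values is None else np.asarray(a1_values, float)
    a2_values = np.arange(0.0, 51.0) if a2_values is None else np.asarray(a2_values, float)
    counts = np.zeros((len(a1_values), len(a2_values)), dtype=int)
    failed = np.zeros_like(counts, dtype=bool)
    for i, a1 in enumerate(a1_values):
        for j, a2 in enumerate(a2_values):
            p = base_params.replace(a1=float(a1), a2=float(a2))
            try:
                eqs = single_toggle_equilibria(p, model_id, n_scan=1500)
            except ConvergenceError:
                failed[i, j] = True
                continue
            counts[i, j] = sum(1 for e in eqs if e.stable)
            if counts[i, j] == 0:
                failed[i, j] = True   # flag, never silently dropped
    return RegionMap(model_id, a1_values, a2_values, counts, failed)


# ---------------------------------------------------------------------------
# N-independent spectrum reduction
# ---------------------------------------------------------------------------

@dataclass
class SpectrumReport:
    """Comparison of the full population spectrum with its reduction."""

    matched: bool
    max_mismatch: float
    reduction_size: int          # toggles in the auxiliary construction
    full_eigenvalues: np.ndarray
    reduced_eigenvalues: np.ndarray   # multiset predicted from the reduction
    tol: float


def _pairing_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-assignment sup distance between two eigenvalue multisets."""
    if len(a) != len(b):
        raise ValueError("multisets differ in size")
    cost = np.abs(a[:, None] - b[None, :])
    rr, cc = linear_sum_assignment(cost)
    return float(np.max(cost[rr, cc]))


def reduced_spectrum_check(eq: EquilibriumRecord,
                           reduction_size: int | None = None,
                           tol: float = 1e-6) -> SpectrumReport:
    """Verify the full linearization spectrum from small auxiliary systems.

    Within a subpopulation all cells hold identical blocks, and the shared
    extracellular pool couples to cells only through their mean, so the
    Jacobian eigenspace splits into a *synchronous* class (one representative
    cell per subpopulation plus the extracellular variables) and
    *anti-synchronous* classes (within-subpopulation perturbations summing
    to zero, which do not move the mean field). The full spectrum is then
    the synchronous eigenvalues plus each subpopulation cell block's
    eigenvalues repeated ``N_k - 1`` times.

    ``reduction_size`` (if given) is checked against the number of toggle
    blocks in the auxiliary construction: one per subpopulation in the
    synchronous system, plus one per anti-synchronous class with a distinct
    spectrum - giving 2 for homogeneous populations, 3 for symmetric (1:1)
    mixtures, and 4 for general (N1:N2) mixtures with N1, N2 >= 2.
    """
    spec, params, z = eq.spec, eq.params, eq.state
    counts = spec.subpop_counts
    K = len(counts)
    m = spec.n_cell_vars
    n_ext = spec.n_ext_vars
    N = spec.N

    J = jacobian(z, params, spec)
    full = eigvals(J)

    # representative cell index for each subpopulation
    reps = [spec.subpop_cells(k)[0] for k in range(K)]
    ext = list(range(m * N, m * N + n_ext))

    # synchronous reduced matrix: K representative blocks + extracellular,
    # with the mean-field coupling reweighted by the subpopulation sizes
    idx = [j for i in reps for j in range(m * i, m * (i + 1))] + ext
    S = J[np.ix_(idx, idx)].copy()
    for k in range(K):
        cols = slice(m * k, m * (k + 1))
        S[m * K:, cols] *= counts[k]       # rho*d/N per cell -> rho*d*p_k
    sync_eigs = eigvals(S)

    # anti-synchronous blocks: the bare cell block of each subpopulation
    # with >= 2 cells (extracellular variables held fixed)
    anti_blocks = []
    for k, (i, Nk) in enumerate(zip(reps, counts)):
        if Nk >= 2:
            blk = J[m * i:m * (i + 1), m * i:m * (i + 1)]
            anti_blocks.append((k, Nk, eigvals(blk)))

    reduced = list(sync_eigs)
    for _, Nk, be in anti_blocks:
        reduced.extend(list(be) * (Nk - 1))
    reduced = np.array(reduced)

    # count toggle blocks, merging anti classes with coincident spectra
    distinct_anti = []
    for _, _, be in anti_blocks:
        if not any(_pairing_distance(be, other) < tol for other in distinct_anti):
            distinct_anti.append(be)
    size = K + len(distinct_anti)
    if reduction_size is not None and size != reduction_size:
        raise ValueError(
            f"auxiliary construction has {size} toggle blocks, "
            f"expected {reduction_size}")

    mismatch = _pairing_distance(full, reduced)
    return SpectrumReport(
        matched=bool(mismatch < tol), max_mismatch=mismatch,
        reduction_size=size, full_eigenvalues=full,
        reduced_eigenvalues=reduced, tol=tol,
    )


# ---------------------------------------------------------------------------
# block guesses for mixed populations
# ---------------------------------------------------------------------------

def mixed_state_guess(params: ModelParams, spec: PopulationSpec,
                      g_block: np.ndarray, r_block: np.ndarray) -> np.ndarray:
    """Initial guess for a (N1:N2) mixed state from single-cell blocks.

    The first subpopulation is placed at the G block, the second at the R
    block; extracellular variables start at their mean-field balance.
    """
    if len(spec.subpop_counts) not in (1, 2):
        raise ValueError("mixed guesses support one or two subpopulations")
    m = spec.n_cell_vars
    blocks = [np.asarray(g_block, float)[:m], np.asarray(r_block, float)[:m]]
    cells = []
    for k, Nk in enumerate(spec.subpop_counts):
        cells.extend([blocks[k]] * Nk)
    z = np.concatenate(cells + [np.zeros(spec.n_ext_vars)])
    p = params
    scale = p.rho * p.d / (p.rho * p.d + p.delta_e)
    if spec.model_id == "S":
        gs = z[2::m][: spec.N]
        rs = z[3::m][: spec.N]
        z[-2] = scale * float(np.mean(gs))
        z[-1] = scale * float(np.mean(rs))
    else:
        rs = z[2::m][: spec.N]
        z[-1] = scale * float(np.mean(rs))
    return z
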
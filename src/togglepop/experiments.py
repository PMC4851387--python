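"""Population assembly, seeded perturbation sampling, and self-correction runs.

The self-correction protocol follows three logged steps: (1) find the
stable G- and R-homogeneous states, (2) flip a fraction of the population
to the opposite state, (3) sample random initial conditions in a small
multiplicative neighborhood of the flipped configuration and integrate.
An outcome counts as *corrected* only when the trajectory converges and
every cell holds the majority's original signature continuously from the
recorded correction time to the end of the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import (
    ConvergenceError,
    EquilibriumRecord,
    find_equilibrium,
    mixed_state_guess,
    single_toggle_equilibria,
)
from .models import PopulationSpec, rhs, state_bounds
from .monotone import oscillation_probe
from .params import ModelParams
from .simulate import integrate

__all__ = [
    "PerturbationPlan",
    "OutcomeRecord",
    "MixedStateResult",
    "make_population_state",
    "homogeneous_states",
    "generate_initial_conditions",
    "self_correction_experiment",
    "convergence_probe",
    "outcomes_to_frame",
]

CONVERGENCE_TOL = 1e-6   # terminal sup-norm of the vector field
DEFAULT_HORIZON = 500.0


@dataclass(frozen=True)
class PerturbationPlan:
    """Seeded recipe for flip-and-jitter initial conditions."""

    base: EquilibriumRecord
    opposite: EquilibriumRecord
    flip_fraction: float = 0.1
    noise_scale: float = 0.05
    n_samples: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")

    @property
    def n_flipped(self) -> int:
        return int(round(self.flip_fraction * self.base.spec.N))


@dataclass
class MixedStateResult:
    exists: bool
    record: EquilibriumRecord | None
    reason: str = ""


@dataclass
class OutcomeRecord:
    d: float
    sample_index: int
    terminal_ratio: tuple[int, int]
    converged: bool
    corrected: bool
    correction_time: float | None
    terminal_residual: float


def homogeneous_states(params: ModelParams, model_id: str = "S",
                       N: int = 10) -> tuple[EquilibriumRecord, EquilibriumRecord]:
    """Stable G- and R-homogeneous population equilibria at the given params.

    Raises if either is missing or unstable (protocol step 1 precondition).
    """
    singles = [e for e in single_toggle_equilibria(params.replace(d=0.0), model_id)
               if e.stable]
    g_single = next((e for e in singles if e.labels[0] == "G"), None)
    r_single = next((e for e in singles if e.labels[0] == "R"), None)
    if g_single is None or r_single is None:
        raise RuntimeError("single toggle is not bistable at these parameters")
    spec = PopulationSpec(model_id, (N,))
    out = []
    for single in (g_single, r_single):
        guess = mixed_state_guess(params, spec, single.state, single.state)
        rec = find_equilibrium(guess, params, spec)
        if not rec.stable:
            raise RuntimeError(
                f"homogeneous {single.labels[0]}-state is unstable at d={params.d}")
        out.append(rec)
    return out[0], out[1]


def make_population_state(ratio: tuple[int, int], params: ModelParams,
                          spec: PopulationSpec) -> MixedStateResult:
    """Build and refine a (p:q)-mixed population equilibrium.

    The guess stacks G-state blocks for the first subpopulation and R-state
    blocks for the second, with extracellular variables at mean-field
    balance. If Newton converges to a state whose signature differs from
    the requested ratio, the mixed state is reported as nonexistent.
    """
    n1, n2 = ratio
    expected_counts = (n1,) if n2 == 0 else ((n2,) if n1 == 0 else (n1, n2))
    total = n1 + n2
    if spec.N % total != 0 or tuple(
            c * (spec.N // total) for c in expected_counts) != spec.subpop_counts:
        raise ValueError(
            f"ratio {n1}:{n2} does not match subpop_counts {spec.subpop_counts}")

    singles = [e for e in single_toggle_equilibria(params.replace(d=0.0),
                                                   spec.model_id)
               if e.stable]
    g_single = next((e for e in singles if e.labels[0] == "G"), None)
    r_single = next((e for e in singles if e.labels[0] == "R"), None)
    if g_single is None or r_single is None:
        return MixedStateResult(False, None, "single toggle not bistable")

    if n2 == 0:
        blocks = (g_single.state, g_single.state)
    elif n1 == 0:
        blocks = (r_single.state, r_single.state)
    else:
        blocks = (g_single.state, r_single.state)
    guess = mixed_state_guess(params, spec, blocks[0], blocks[1])
    try:
        rec = find_equilibrium(guess, params, spec)
    except ConvergenceError as exc:
        return MixedStateResult(False, None, f"Newton failed: {exc}")

    scale = spec.N // total
    want = (n1 * scale, n2 * scale)
    if rec.ratio != want:
        return MixedStateResult(
            False, None,
            f"converged to signature {rec.signature}, not {want[0]}:{want[1]}")
    return MixedStateResult(True, rec)


def generate_initial_conditions(plan: PerturbationPlan) -> list[np.ndarray]:
    """Seeded flip-and-jitter samples around the base equilibrium.

    Each sample replaces the trailing ``round(flip_fraction * N)`` cells of
    the base state by the opposite equilibrium's per-cell block, then
    multiplies every component by ``exp(eps)`` with
    ``eps ~ Normal(0, noise_scale^2)`` drawn from a stream keyed on
    ``(seed, sample_index)`` - bit-for-bit reproducible for a fixed seed.
    """
    spec = plan.base.spec
    N, m = spec.N, spec.n_cell_vars
    k_exact = plan.flip_fraction * N
    k = plan.n_flipped
    if abs(k_exact - round(k_exact)) > 1e-9:
        warnings.warn(
            f"flip_fraction * N = {k_exact} is not integral; rounding to {k}")

    base = plan.base.state
    flipped = base.copy()
    if k > 0:
        opp = plan.opposite.state
        for i in range(N - k, N):
            flipped[m * i:m * (i + 1)] = opp[m * i:m * (i + 1)]

    samples = []
    for idx in range(plan.n_samples):
        rng = np.random.default_rng([plan.seed, idx])
        eps = rng.normal(0.0, plan.noise_scale, size=spec.dim)
        samples.append(flipped * np.exp(eps))
    return samples


def _majority_ok_from(times, traj, spec: PopulationSpec, majority: str):
    """Earliest time from which every cell holds the majority label onward."""
    m = spec.n_cell_vars
    x = traj[0::m, :][: spec.N]
    y = traj[1::m, :][: spec.N]
    good = (x > y) if majority == "G" else (y > x)
    all_good = np.all(good, axis=0)
    if not all_good[-1]:
        return None
    bad = np.flatnonzero(~all_good)
    first = 0 if bad.size == 0 else bad[-1] + 1
    return float(times[first])


def self_correction_experiment(model_id: str, params: ModelParams,
                               d_values, *, flip_fraction: float = 0.1,
                               noise_scale: float = 0.05, n_samples: int = 25,
                               seed: int = 0, N: int = 10,
                               horizon: float = DEFAULT_HORIZON,
                               n_times: int = 201,
                               log: list | None = None) -> list[OutcomeRecord]:
    """Run the flip/self-correction protocol over a set of coupling values.

    For each ``d``: (1) locate the stable G- and R-homogeneous equilibria,
    (2) flip ``flip_fraction`` of the cells of the G-majority state to the
    R block, (3) integrate seeded jittered neighbors of that configuration
    and classify the terminal signature. Non-convergent runs come back as
    undecided (``converged=False``), never as corrected.
    """
    outcomes: list[OutcomeRecord] = []
    for d in d_values:
        p_d = params.replace(d=float(d))
        g_hom, r_hom = homogeneous_states(p_d, model_id, N)
        if log is not None:
            log.append(("find_homogeneous", float(d)))
        plan = PerturbationPlan(base=g_hom, opposite=r_hom,
                                flip_fraction=flip_fraction,
                                noise_scale=noise_scale,
                                n_samples=n_samples, seed=seed)
        ics = generate_initial_conditions(plan)
        if log is not None:
            log.append(("flip", float(d), plan.n_flipped))
            log.append(("sample_neighborhood", float(d), n_samples))
        spec = g_hom.spec
        times = np.linspace(0.0, horizon, n_times)
        for idx, z0 in enumerate(ics):
            sol = integrate(z0, p_d, spec, horizon, t_eval=times)
            zT = sol.y[:, -1]
            resid = float(np.max(np.abs(rhs(zT, p_d, spec))))
            converged = resid < CONVERGENCE_TOL
            m = spec.n_cell_vars
            xs, ys = zT[0::m][: spec.N], zT[1::m][: spec.N]
            nG = int(np.sum(xs > ys))
            corrected = False
            t_corr = None
            if converged:
                t_corr = _majority_ok_from(sol.t, sol.y, spec, "G")
                corrected = t_corr is not None
            outcomes.append(OutcomeRecord(
                d=float(d), sample_index=idx, terminal_ratio=(nG, spec.N - nG),
                converged=converged, corrected=corrected,
                correction_time=t_corr, terminal_residual=resid))
    return outcomes


def outcomes_to_frame(outcomes: list[OutcomeRecord]) -> pd.DataFrame:
    rows = [{
        "d": o.d, "sample": o.sample_index,
        "terminal_ratio": f"{o.terminal_ratio[0]}:{o.terminal_ratio[1]}",
        "converged": o.converged, "corrected": o.corrected,
        "correction_time": o.correction_time,
        "terminal_residual": o.terminal_residual,
    } for o in outcomes]
    return pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    n_total: int
    n_converged: int
    n_oscillating: int
    terminal_residuals: np.ndarray
    equilibria: list[np.ndarray]
    undecided: int

    @property
    def all_converged(self) -> bool:
        return self.n_converged == self.n_total and self.n_oscillating == 0


def convergence_probe(model_id: str, params: ModelParams, n_random_ics: int = 50,
                      horizon: float = DEFAULT_HORIZON, seed: int = 0,
                      N: int = 2, n_times: int = 201,
                      tol: float = 1e-8) -> ConvergenceReport:
    """Integrate seeded random initial conditions and test for convergence.

    Initial conditions are log-uniform componentwise over [1e-3, ub] where
    ``ub`` is the forward-invariant box bound. A trajectory converges when
    the terminal vector-field sup-norm drops below ``tol``; the oscillation
    probe independently flags sustained oscillation. ``horizon = 0`` leaves
    every trajectory undecided.
    """
    spec = PopulationSpec(model_id, (N,))
    rng = np.random.default_rng(seed)
    ub = state_bounds(params, spec)
    lo = np.full(spec.dim, 1e-3)
    ics = np.exp(rng.uniform(np.log(lo), np.log(np.maximum(ub, 2 * lo)),
                             size=(n_random_ics, spec.dim)))
    n_conv = n_osc = undecided = 0
    residuals = np.empty(n_random_ics)
    finals = []
    if horizon <= 0:
        return ConvergenceReport(n_random_ics, 0, 0,
                                 np.full(n_random_ics, np.inf), [],
                                 n_random_ics)
    times = np.linspace(0.0, horizon, n_times)
    for i, z0 in enumerate(ics):
        sol = integrate(z0, params, spec, horizon, t_eval=times)
        resid = float(np.max(np.abs(rhs(sol.y[:, -1], params, spec))))
        residuals[i] = resid
        if resid < tol:
            n_conv += 1
            finals.append(sol.y[:, -1])
        else:
            undecided += 1
        if oscillation_probe(sol.t, sol.y):
            n_osc += 1
    return ConvergenceReport(n_random_ics, n_conv, n_osc, residuals,
                             finals, undecided)
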
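"""Pseudo-arclength continuation of equilibrium branches.

Secant-predictor / Newton-corrector continuation in one model parameter,
with eigenvalues recorded at every accepted point and two test functions
monitored between points:

* **LP (fold)** - the parameter component of the normalized branch tangent
  changes sign (the branch turns back in the parameter).
* **BP (branch point)** - the determinant of the bordered Jacobian (system
  Jacobian and parameter column augmented with the tangent row) changes
  sign, signalling a zero eigenvalue transversal to the branch.

Events are localized by bisection on the arclength step to a parameter
tolerance of 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eig, eigvals

from .equilibria import (
    ConvergenceError,
    EquilibriumRecord,
    NEWTON_TOL,
    STABILITY_MARGIN,
    find_equilibrium,
    mixed_state_guess,
    single_toggle_equilibria,
)
from .models import PopulationSpec, jacobian, rhs
from .params import ModelParams

__all__ = [
    "Branch",
    "BifurcationEvent",
    "StepControl",
    "continue_equilibrium",
    "branch_switch",
    "mixed_state_elimination_scan",
    "BranchSwitchError",
]

PARAM_TOL = 1e-4   # event localization tolerance in the parameter


class BranchSwitchError(RuntimeError):
    pass


@dataclass(frozen=True)
class StepControl:
    initial: float = 0.01
    min_step: float = 1e-5
    max_step: float = 0.1
    grow: float = 1.3
    grow_after: int = 4
    max_points: int = 5000


@dataclass
class BifurcationEvent:
    kind: str                    # 'LP' or 'BP'
    param_value: float
    state: np.ndarray
    test_values: tuple[float, float]   # bracketing test-function values
    eigenvector: np.ndarray | None = None
    localized: bool = True


@dataclass
class Branch:
    param_name: str
    bounds: tuple[float, float]
    params: list[float] = field(default_factory=list)
    states: list[np.ndarray] = field(default_factory=list)
    stable: list[bool] = field(default_factory=list)
    leading_eig: list[float] = field(default_factory=list)
    events: list[BifurcationEvent] = field(default_factory=list)
    termination: str = "completed"

    def __len__(self) -> int:
        return len(self.params)

    def point(self, i: int) -> tuple[float, np.ndarray]:
        return self.params[i], self.states[i]


class _Problem:
    """Extended system F(z, p) = f(z; params with param_name=p)."""

    def __init__(self, params: ModelParams, spec: PopulationSpec, param_name: str):
        if not hasattr(params, param_name):
            raise ValueError(f"unknown parameter {param_name!r}")
        self.base = params
        self.spec = spec
        self.name = param_name

    def params_at(self, p: float) -> ModelParams:
        return self.base.replace(**{self.name: float(p)})

    def f(self, z: np.ndarray, p: float) -> np.ndarray:
        return rhs(z, self.params_at(p), self.spec)

    def jac(self, z: np.ndarray, p: float) -> np.ndarray:
        return jacobian(z, self.params_at(p), self.spec)

    def f_p(self, z: np.ndarray, p: float) -> np.ndarray:
        h = 1e-7 * max(abs(p), 1.0)
        return (self.f(z, p + h) - self.f(z, p - h)) / (2 * h)


def _tangent(prob: _Problem, z: np.ndarray, p: float,
             prev: np.ndarray) -> np.ndarray:
    """Unit tangent of the branch, oriented along the previous tangent."""
    n = len(z)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = prob.jac(z, p)
    A[:n, n] = prob.f_p(z, p)
    A[n, :] = prev
    b = np.zeros(n + 1)
    b[n] = 1.0
    try:
        tau = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        tau = np.linalg.lstsq(A, b, rcond=None)[0]
    tau /= np.linalg.norm(tau)
    if np.dot(tau, prev) < 0:
        tau = -tau
    return tau


def _correct(prob: _Problem, u_pred: np.ndarray, tau: np.ndarray,
             tol: float = NEWTON_TOL, max_iter: int = 25) -> np.ndarray | None:
    """Newton corrector in the hyperplane orthogonal to the tangent."""
    n = len(u_pred) - 1
    u = u_pred.copy()
    for _ in range(max_iter):
        z, p = u[:n], u[n]
        F = prob.f(z, p)
        res = np.concatenate([F, [np.dot(tau, u - u_pred)]])
        if np.max(np.abs(res)) < tol:
            return u
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = prob.jac(z, p)
        A[:n, n] = prob.f_p(z, p)
        A[n, :] = tau
        try:
            du = np.linalg.solve(A, -res)
        except np.linalg.LinAlgError:
            return None
        u = u + du
        if not np.all(np.isfinite(u)):
            return None
    return None


def _bordered_det_sign(prob: _Problem, z: np.ndarray, p: float,
                       tau: np.ndarray) -> float:
    n = len(z)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = prob.jac(z, p)
    A[:n, n] = prob.f_p(z, p)
    A[n, :] = tau
    sign, _ = np.linalg.slogdet(A)
    return float(sign)


def _critical_eigenvector(prob: _Problem, z: np.ndarray, p: float) -> np.ndarray:
    w, v = eig(prob.jac(z, p))
    k = int(np.argmin(np.abs(w.real)))
    vec = np.real(v[:, k])
    nrm = np.linalg.norm(vec)
    if nrm == 0:
        vec = np.real(v[:, k] * 1j)
        nrm = np.linalg.norm(vec)
    return vec / nrm


def continue_equilibrium(start: EquilibriumRecord, param_name: str,
                         bounds: tuple[float, float],
                         step: StepControl | None = None,
                         direction: int = +1) -> Branch:
    """Continue an equilibrium branch in one parameter between bounds.

    ``start`` must be a converged equilibrium whose ``params`` lie inside
    ``bounds`` for ``param_name``. ``direction`` picks the initial sweep
    orientation in the parameter (+1 upward, -1 downward).
    """
    if start.residual_norm > 100 * NEWTON_TOL:
        raise ValueError("start is not a converged equilibrium")
    prob = _Problem(start.params, start.spec, param_name)
    p0 = float(getattr(start.params, param_name))
    return _run_continuation(prob, start.state, p0, bounds,
                             step or StepControl(), direction)


def _run_continuation(prob, z0: np.ndarray, p0: float,
                      bounds: tuple[float, float], sc: StepControl,
                      direction: int) -> Branch:
    lo, hi = bounds
    if not lo <= p0 <= hi:
        raise ValueError(f"start parameter {p0} outside bounds {bounds}")

    branch = Branch(param_name=prob.name, bounds=(lo, hi))
    n = len(z0)
    start_state = np.asarray(z0, dtype=float)
    u = np.concatenate([start_state, [p0]])
    seed = np.zeros(n + 1)
    seed[n] = float(np.sign(direction) or 1.0)
    tau = _tangent(prob, u[:n], u[n], seed)

    def accept(u, tau):
        eigs = eigvals(prob.jac(u[:n], u[n]))
        lead = float(np.max(eigs.real))
        branch.params.append(float(u[n]))
        branch.states.append(u[:n].copy())
        branch.stable.append(lead < -STABILITY_MARGIN)
        branch.leading_eig.append(lead)
        return _bordered_det_sign(prob, u[:n], u[n], tau), float(tau[n])

    det_prev, taup_prev = accept(u, tau)
    h = sc.initial
    successes = 0

    while len(branch) < sc.max_points:
        u_pred = u + h * tau
        u_new = _correct(prob, u_pred, tau)
        if u_new is None or np.linalg.norm(u_new - u) > 5 * max(h, sc.initial):
            h *= 0.5
            if h < sc.min_step:
                branch.termination = "step-size underflow"
                break
            successes = 0
            continue
        tau_new = _tangent(prob, u_new[:n], u_new[n], tau)
        det_new, taup_new = accept(u_new, tau_new)

        if det_new * det_prev < 0:
            _localize(prob, branch, u, tau, h, "BP", det_prev)
        if taup_new * taup_prev < 0:
            _localize(prob, branch, u, tau, h, "LP", taup_prev)

        u, tau = u_new, tau_new
        det_prev, taup_prev = det_new, taup_new
        successes += 1
        if successes >= sc.grow_after:
            h = min(h * sc.grow, sc.max_step)
            successes = 0
        if u[n] > hi + PARAM_TOL or u[n] < lo - PARAM_TOL:
            branch.termination = "bound reached"
            break
    else:
        branch.termination = "max points"
    return branch


def _localize(prob: _Problem, branch: Branch, u0: np.ndarray,
              tau0: np.ndarray, h: float, kind: str,
              test_lo: float) -> None:
    """Bisection on the arclength step bracketing a test-function zero."""
    n = len(u0) - 1

    def probe(s: float):
        u = _correct(prob, u0 + s * tau0, tau0)
        if u is None:
            return None, None
        tau = _tangent(prob, u[:n], u[n], tau0)
        if kind == "BP":
            val = _bordered_det_sign(prob, u[:n], u[n], tau)
        else:
            val = float(tau[n])
        return u, val

    s_lo, s_hi = 0.0, h
    u_best, val_hi = probe(s_hi)
    if u_best is None:
        branch.events.append(BifurcationEvent(
            kind, float("nan"), u0[:n].copy(), (test_lo, float("nan")),
            localized=False))
        return
    p_lo, p_hi = u0[n], u_best[n]
    for _ in range(60):
        if abs(p_hi - p_lo) < PARAM_TOL:
            break
        s_mid = 0.5 * (s_lo + s_hi)
        u_mid, val_mid = probe(s_mid)
        if u_mid is None:
            break
        if val_mid * test_lo > 0:
            s_lo, p_lo = s_mid, u_mid[n]
        else:
            s_hi, p_hi, u_best = s_mid, u_mid[n], u_mid
    vec = _critical_eigenvector(prob, u_best[:n], u_best[n]) if kind == "BP" else None
    branch.events.append(BifurcationEvent(
        kind=kind, param_value=float(u_best[n]), state=u_best[:n].copy(),
        test_values=(test_lo, -test_lo), eigenvector=vec))


def branch_switch(event: BifurcationEvent, params: ModelParams,
                  spec: PopulationSpec, param_name: str,
                  perturbation: float = 0.5,
                  direction: int = +1) -> EquilibriumRecord:
    """Jump onto the branch bifurcating at a localized BP.

    Solves the augmented system ``f(z, p) = 0``, ``v . (z - z_bp) = eps``
    for ``(z, p)``, where ``v`` is the critical eigenvector: the extra
    constraint pins a nonzero displacement along ``v`` so the corrector
    cannot fall back to the original branch.
    """
    if event.kind != "BP":
        raise ValueError("branch switching requires a BP event")
    if not event.localized:
        raise ValueError("event is not localized")
    if perturbation == 0:
        raise BranchSwitchError("zero perturbation returns the original branch")
    prob = _Problem(params, spec, param_name)
    z0 = event.state
    p0 = event.param_value
    v = event.eigenvector
    if v is None:
        v = _critical_eigenvector(prob, z0, p0)
    eps = float(direction) * perturbation
    n = spec.dim

    u = np.concatenate([z0 + eps * v, [p0]])
    for _ in range(60):
        z, p = u[:n], u[n]
        res = np.concatenate([prob.f(z, p), [np.dot(v, z - z0) - eps]])
        if np.max(np.abs(res)) < NEWTON_TOL:
            break
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = prob.jac(z, p)
        A[:n, n] = prob.f_p(z, p)
        A[n, :n] = v
        try:
            u = u + np.linalg.solve(A, -res)
        except np.linalg.LinAlgError:
            raise BranchSwitchError("singular augmented system during switch")
    else:
        raise BranchSwitchError(
            "corrector did not converge; try a larger perturbation")

    rec = find_equilibrium(np.maximum(u[:n], 0.0), prob.params_at(u[n]), spec)
    if np.max(np.abs(rec.state - z0)) < 1e-6 * max(1.0, np.max(np.abs(z0))):
        raise BranchSwitchError(
            "corrector fell back to the original branch; "
            "try a larger perturbation")
    return rec


@dataclass
class EliminationReport:
    ratio: tuple[int, int]
    stable_interval: tuple[float, float]
    terminal_event: BifurcationEvent | None
    persists: bool
    branch: Branch


def mixed_state_elimination_scan(ratio: tuple[int, int], params: ModelParams,
                                 model_id: str = "S", param_name: str = "d",
                                 bounds: tuple[float, float] = (0.1, 10.0),
                                 step: StepControl | None = None,
                                 ) -> EliminationReport:
    """Track a (p:q)-mixed state in ``param_name`` and report where it dies.

    Starts from the stable mixed equilibrium at the lower bound (which must
    exist), continues upward, and reports the parameter interval over which
    the state remains stable together with the terminating event, or that
    the state persists to the upper bound.
    """
    n1, n2 = ratio
    counts = (n1, n2) if n2 > 0 else (n1,)
    spec = PopulationSpec(model_id, counts)
    p_lo = bounds[0]
    base = params.replace(**{param_name: p_lo}) if param_name == "d" else params

    singles = single_toggle_equilibria(base.replace(d=0.0), model_id)
    stable_singles = [e for e in singles if e.stable]
    g_states = [e for e in stable_singles if e.labels[0] == "G"]
    r_states = [e for e in stable_singles if e.labels[0] == "R"]
    if not g_states or not r_states:
        raise RuntimeError("no bistable single-toggle states at the lower bound")
    if n2 > 0:
        guess = mixed_state_guess(base, spec,
                                  g_states[0].state, r_states[0].state)
    else:
        guess = mixed_state_guess(base, spec,
                                  g_states[0].state, g_states[0].state)
    start = find_equilibrium(guess, base, spec)
    if not start.stable:
        raise RuntimeError(f"mixed state at {param_name}={p_lo} is not stable")

    sc = step or StepControl(max_step=0.25)
    branch = continue_equilibrium(start, param_name, bounds, step=sc)

    # first loss of stability along the branch
    last_stable_p = branch.params[0]
    event = None
    for i in range(1, len(branch)):
        if branch.stable[i - 1] and not branch.stable[i]:
            cand = [e for e in branch.events
                    if min(branch.params[i - 1], branch.params[i]) - 10 * PARAM_TOL
                    <= e.param_value
                    <= max(branch.params[i - 1], branch.params[i]) + 10 * PARAM_TOL]
            event = cand[0] if cand else None
            last_stable_p = branch.params[i - 1]
            break
        if branch.stable[i]:
            last_stable_p = branch.params[i]
    persists = event is None and branch.termination == "bound reached"
    hi = event.param_value if event is not None else last_stable_p
    return EliminationReport(
        ratio=ratio, stable_interval=(p_lo, float(hi)),
        terminal_event=event, persists=persists, branch=branch,
    )
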
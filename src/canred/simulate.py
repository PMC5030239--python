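"""Stiff integration of canonical models and the reduction-error protocol.

The integration horizon is tied to the slowest relaxation mode at the steady
state, ``t_end = -5 / max(Re eig(J))``, five times the longest linear time
constant.  Integration is carried out in logarithmic coordinates
``y = log x``, where power-law and quasi-polynomial right-hand sides become
smooth exponential-affine expressions and positivity of the trajectory is
automatic; the stiff-capable LSODA integrator switches to BDF as needed.

The robustness of a quasi-steady-state reduction is quantified by perturbing
the fast initial values away from their QSS manifold by up to a given factor
and measuring

* the perturbation size ``delta_y``: Euclidean norm of the log-ratios of the
  fast initial values to their QSS values;
* per-slow-variable relative trajectory errors
  ``E_i = int |x_qssa - x| dt / int |x| dt`` (trapezoidal quadrature on a
  common time grid), aggregated as the Euclidean norm ``|E|``;
* ensemble envelopes: mean and standard deviation of the full model's slow
  trajectories across many randomized perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import AnyModel, ModelError, NormalizedSSystem, jacobian as model_jacobian
from .reduction import ReducedPair

__all__ = [
    "NotStableError",
    "IntegrationError",
    "Trajectory",
    "ErrorReport",
    "integration_horizon",
    "simulate",
    "perturb_fast_initials",
    "delta_y",
    "trajectory_error",
    "ensemble_compare",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: default number of uniformly spaced sample points on [0, t_end]
DEFAULT_N_POINTS = 100


class NotStableError(ModelError):
    """The steady state is not asymptotically stable."""


class IntegrationError(ModelError):
    """The ODE solver failed before reaching t_end."""


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_vars), strictly positive
    var_names: list[str] = field(default_factory=list)
    model_id: str = ""

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]


def _steady_state_of(model: AnyModel):
    from .models import SSystem, ssystem_steady_state

    if isinstance(model, NormalizedSSystem):
        return np.ones(model.n_vars)
    if isinstance(model, SSystem):
        return ssystem_steady_state(model)
    raise ModelError("a reference state is required for this formalism")


def integration_horizon(model: AnyModel, state=None) -> float:
    """t_end = -5 / max(Re eig(J)) at the (stable) steady state."""
    if state is None:
        state = _steady_state_of(model)
    J = model_jacobian(model, state)
    re = np.real(np.linalg.eigvals(J))
    mx = float(np.max(re))
    if mx >= 0:
        raise NotStableError(
            f"not asymptotically stable: Jacobian eigenvalue with Re = {mx:.3e} >= 0"
        )
    return -5.0 / mx


def simulate(
    model: AnyModel,
    x0,
    t_end: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    n_points: int = DEFAULT_N_POINTS,
    t_eval=None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate a model from a positive initial state over [0, t_end]."""
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if np.any(x0 <= 0):
        raise ModelError("initial state must be strictly positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    y0 = np.log(x0)
    sol = solve_ivp(lambda t, y: model.log_rhs(y), (0.0, float(t_end)), y0,
                    method=method, t_eval=np.asarray(t_eval, float),
                    rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(f"integration failed at t = {t_fail:.6g}: {sol.message}")
    names = list(getattr(model, "var_names", []) or [])
    return Trajectory(times=sol.t, states=np.exp(sol.y.T), var_names=names,
                      model_id=type(model).__name__)


def perturb_fast_initials(qss_values, factor: float = 10.0, rng=None,
                          seed=None, mode: str = "uniform") -> np.ndarray:
    """Random fast initial values at most ``factor`` away from QSS.

    Each value is ``qss_i * factor**u_i`` with ``u_i`` drawn independently
    and uniformly from [-1, 1] (``mode="uniform"``), bounding each ratio
    within [1/factor, factor]; ``mode="edges"`` draws u from {-1, +1}.
    """
    qss = np.asarray(qss_values, dtype=float).reshape(-1)
    if np.any(qss <= 0):
        raise ModelError("QSS values must be strictly positive")
    if factor < 1.0:
        raise ModelError("perturbation factor must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode == "uniform":
        u = rng.uniform(-1.0, 1.0, size=qss.size)
    elif mode == "edges":
        u = rng.choice([-1.0, 1.0], size=qss.size)
    else:
        raise ModelError(f"unknown perturbation mode {mode!r}")
    return qss * factor ** u


def delta_y(x_f0, x_f_qss) -> float:
    """Euclidean norm of the log-ratios between fast initials and QSS values."""
    a = np.asarray(x_f0, dtype=float).reshape(-1)
    b = np.asarray(x_f_qss, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ModelError("vectors must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ModelError("entries must be strictly positive")
    return float(np.linalg.norm(np.log(a / b)))


def trajectory_error(full: Trajectory, reduced: Trajectory,
                     slow_indices=None, n_grid: int | None = None):
    """Per-variable relative trajectory errors and their Euclidean norm.

    Both trajectories are linearly interpolated onto a common uniform grid
    over the overlapping time span; then
    ``E_i = int |x_red,i - x_full,i| dt / int |x_full,i| dt`` by trapezoidal
    quadrature.  ``slow_indices`` selects which columns of ``full`` to
    compare against the (entire) reduced trajectory.
    """
    cols = np.arange(full.n_vars) if slow_indices is None else np.asarray(slow_indices)
    if cols.size != reduced.n_vars:
        raise ModelError(
            f"variable sets mismatch: comparing {cols.size} full columns with "
            f"{reduced.n_vars} reduced variables"
        )
    t0 = max(full.times[0], reduced.times[0])
    t1 = min(full.times[-1], reduced.times[-1])
    if t1 <= t0:
        raise ModelError("trajectories do not overlap in time")
    if n_grid is None:
        n_grid = max(full.times.size, reduced.times.size)
    grid = np.linspace(t0, t1, n_grid)
    E = np.empty(cols.size)
    for a, i in enumerate(cols):
        xf = np.interp(grid, full.times, full.states[:, i])
        xr = np.interp(grid, reduced.times, reduced.states[:, a])
        num = np.trapezoid(np.abs(xr - xf), grid)
        den = np.trapezoid(np.abs(xf), grid)
        E[a] = num / den
    return E, float(np.linalg.norm(E))


@dataclass
class ErrorReport:
    """Ensemble comparison of a full model against its QSS reduction.

    Per accepted simulation: the perturbation ``delta_y`` and the error
    vector/norm against the (shared) reduced trajectory.  ``mean``/``std``
    are the per-time envelopes of the full model's slow trajectories; the
    paper-style plots use mean +/- 3 std.
    """

    delta_y: np.ndarray            # (n_ok,)
    E: np.ndarray                  # (n_ok, n_slow)
    E_norm: np.ndarray             # (n_ok,)
    sample_times: np.ndarray
    mean: np.ndarray               # (n_times, n_slow)
    std: np.ndarray                # (n_times, n_slow)
    reduced_states: np.ndarray     # (n_times, n_slow)
    slow_indices: np.ndarray
    n_sims: int
    n_failed: int
    seed: int | None
    slow_x0: np.ndarray | None = None
    factor: float = 10.0


def ensemble_compare(
    full_model: NormalizedSSystem,
    reduced: ReducedPair,
    n_sims: int = 1000,
    factor: float = 10.0,
    seed: int | None = None,
    n_sample_times: int = DEFAULT_N_POINTS,
    slow_x0=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    perturb_mode: str = "uniform",
) -> ErrorReport:
    """Randomized-perturbation ensemble for a QSS reduction.

    The slow initial state is displaced from equilibrium once (drawn from the
    seed with the same factor law unless ``slow_x0`` is given) and shared by
    the full and reduced runs, so the slow dynamics are non-trivial.  Each
    simulation then perturbs the fast initial values around their QSS-manifold
    values by at most ``factor`` and records (delta_y, E, |E|) against the
    reduced trajectory.  Failed integrations are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    slow_idx = reduced.qss_map.slow_indices
    fast_idx = reduced.qss_map.fast_indices
    if slow_x0 is None:
        u = rng.uniform(-1.0, 1.0, size=slow_idx.size)
        slow_x0 = factor ** u
    else:
        slow_x0 = np.asarray(slow_x0, dtype=float).reshape(-1)
        if np.any(slow_x0 <= 0):
            raise ModelError("slow initial state must be strictly positive")
    qss0 = reduced.qss_map(slow_x0)

    t_end = integration_horizon(full_model)
    sample_times = np.linspace(0.0, t_end, n_sample_times)

    red_traj = simulate(reduced.slow, slow_x0, t_end, rtol=rtol, atol=atol,
                        t_eval=sample_times)

    dys, Es, Enorms, slow_states = [], [], [], []
    n_failed = 0
    n = full_model.n_vars
    for _ in range(n_sims):
        xf0 = perturb_fast_initials(qss0, factor=factor, rng=rng, mode=perturb_mode)
        x0 = np.empty(n)
        x0[slow_idx] = slow_x0
        x0[fast_idx] = xf0
        try:
            full_traj = simulate(full_model, x0, t_end, rtol=rtol, atol=atol,
                                 t_eval=sample_times)
        except IntegrationError:
            n_failed += 1
            continue
        E, En = trajectory_error(full_traj, red_traj, slow_indices=slow_idx)
        dys.append(delta_y(xf0, qss0))
        Es.append(E)
        Enorms.append(En)
        slow_states.append(full_traj.states[:, slow_idx])

    if not slow_states:
        raise IntegrationError("all ensemble integrations failed")
    stack = np.stack(slow_states)  # (n_ok, n_times, n_slow)
    return ErrorReport(
        delta_y=np.array(dys), E=np.array(Es), E_norm=np.array(Enorms),
        sample_times=sample_times, mean=stack.mean(axis=0), std=stack.std(axis=0),
        reduced_states=red_traj.states, slow_indices=np.asarray(slow_idx),
        n_sims=n_sims, n_failed=n_failed, seed=seed,
        slow_x0=np.asarray(slow_x0), factor=factor,
    )
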
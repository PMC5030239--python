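"""Canonical non-linear model formalisms and exact conversions between them.

Three mathematically equivalent formalisms for positive dynamical systems are
represented:

* **GMA** (Generalized Mass Action): ``xdot = N diag(gamma) x^F``, a linear
  combination of power-law fluxes.  ``N`` (n x m) carries the stoichiometry,
  ``gamma`` (m) the positive rate constants and ``F`` (m x n) the kinetic
  orders.  Environmental/independent variables are assumed pre-folded into
  ``gamma``.
* **s-system**: one aggregate production and one aggregate degradation
  power-law per variable, ``xdot = diag(alpha) x^G - diag(beta) x^H``.
  Steady states are log-linear and therefore available in closed form.
* **GLV** (Generalized Lotka-Volterra / quasi-polynomial):
  ``xdot = diag(x) (lam + A x^B)``; per-capita rates are sums of
  quasimonomials ``x^{B_j}``.

``x^E`` denotes the componentwise monomial vector ``prod_j x_j^{E_ij}``;
all states live on the open positive orthant, where real exponents are
well defined.

The conversions here are *exact* (no approximation): an s-system embeds in a
GMA structurally; a GMA becomes a GLV by factoring each variable out of its
own equation; a GLV folds back to an s-system whenever each equation has a
single positive and a single negative power-law term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelError",
    "SteadyStateError",
    "NotSSystemRepresentableError",
    "PowerLawModel",
    "SSystem",
    "NormalizedSSystem",
    "GLVModel",
    "LVModel",
    "ssystem_to_gma",
    "gma_to_glv",
    "glv_to_ssystem",
    "ssystem_steady_state",
    "normalize",
    "evaluate_rhs",
    "jacobian",
    "DEDUP_DECIMALS",
]

#: Decimal places used when comparing quasimonomial exponent rows for
#: deduplication.  Floating-point exponent rows produced by conversions must
#: merge deterministically.
DEDUP_DECIMALS = 12

_RANK_RTOL = 1e-12


class ModelError(ValueError):
    """Invalid model data or an evaluation outside the model's domain."""


class SteadyStateError(ModelError):
    """No unique positive steady state exists."""


class NotSSystemRepresentableError(ModelError):
    """A GLV equation has more than one positive or negative term."""


def _as_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ModelError(f"{name} must be finite")
    return a


def _default_names(n: int) -> list[str]:
    return [f"x{i}" for i in range(1, n + 1)]


def _check_state(x, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape != (n,):
        raise ModelError(f"state has length {x.size}, expected {n}")
    if not np.all(x > 0):
        bad = np.flatnonzero(x <= 0) + 1
        raise ModelError(
            "state must be strictly positive (power laws with real exponents "
            f"are undefined at 0); offending variable(s): {bad.tolist()}"
        )
    return x


def _monomials(E: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate ``x^E`` row-wise: component i is prod_j x_j**E[i, j]."""
    return np.exp(E @ np.log(x))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PowerLawModel:
    """GMA system ``xdot = N diag(gamma) x^F``."""

    N: np.ndarray
    gamma: np.ndarray
    F: np.ndarray
    var_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.N = _as_matrix(self.N, "N")
        self.gamma = _as_matrix(self.gamma, "gamma").reshape(-1)
        self.F = _as_matrix(self.F, "F")
        n, m = self.N.shape
        if self.gamma.shape != (m,):
            raise ModelError(f"gamma has length {self.gamma.size}, expected {m}")
        if self.F.shape != (m, n):
            raise ModelError(f"F has shape {self.F.shape}, expected {(m, n)}")
        if np.any(self.gamma <= 0):
            bad = np.flatnonzero(self.gamma <= 0) + 1
            raise ModelError(f"rate constants gamma must be positive; entry {bad.tolist()}")
        if np.any(np.all(self.N == 0, axis=1)):
            bad = np.flatnonzero(np.all(self.N == 0, axis=1)) + 1
            raise ModelError(f"variable(s) {bad.tolist()} appear in no flux (zero row of N)")
        if self.var_names is None:
            self.var_names = _default_names(n)

    @property
    def n_vars(self) -> int:
        return self.N.shape[0]

    @property
    def n_terms(self) -> int:
        return self.N.shape[1]

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        return self.N @ (self.gamma * _monomials(self.F, x))

    def log_rhs(self, y: np.ndarray) -> np.ndarray:
        """d/dt log x as a function of y = log x (positivity-preserving form)."""
        v = self.gamma * np.exp(self.F @ y)
        return (self.N @ v) * np.exp(-y)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        v = self.gamma * _monomials(self.F, x)
        return (self.N * v) @ (self.F / x)


@dataclass
class SSystem:
    """s-system ``xdot = diag(alpha) x^G - diag(beta) x^H``."""

    alpha: np.ndarray
    beta: np.ndarray
    G: np.ndarray
    H: np.ndarray
    var_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alpha = _as_matrix(self.alpha, "alpha").reshape(-1)
        self.beta = _as_matrix(self.beta, "beta").reshape(-1)
        self.G = _as_matrix(self.G, "G")
        self.H = _as_matrix(self.H, "H")
        n = self.alpha.size
        if self.beta.shape != (n,):
            raise ModelError("alpha and beta must have equal length")
        for name, M in (("G", self.G), ("H", self.H)):
            if M.shape != (n, n):
                raise ModelError(f"{name} has shape {M.shape}, expected {(n, n)}")
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if np.any(v <= 0):
                bad = np.flatnonzero(v <= 0) + 1
                raise ModelError(f"{name} must be strictly positive; entry {bad.tolist()}")
        if self.var_names is None:
            self.var_names = _default_names(n)

    @property
    def n_vars(self) -> int:
        return self.alpha.size

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        return self.alpha * _monomials(self.G, x) - self.beta * _monomials(self.H, x)

    def log_rhs(self, y: np.ndarray) -> np.ndarray:
        return self.alpha * np.exp(self.G @ y - y) - self.beta * np.exp(self.H @ y - y)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        vp = self.alpha * _monomials(self.G, x)
        vn = self.beta * _monomials(self.H, x)
        return (self.G * vp[:, None] - self.H * vn[:, None]) / x


@dataclass
class NormalizedSSystem:
    """Steady-state-normalized s-system ``zdot = diag(f) (z^G - z^H)``.

    Variables are scaled by their steady-state values, so the equilibrium is
    the all-ones vector.  The positive turnovers ``f`` (steady-state flux per
    pool size, the reciprocal transition times) carry the time-scale
    information of each variable.
    """

    f: np.ndarray
    G: np.ndarray
    H: np.ndarray
    steady_state_raw: np.ndarray | None = None
    var_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.f = _as_matrix(self.f, "f").reshape(-1)
        self.G = _as_matrix(self.G, "G")
        self.H = _as_matrix(self.H, "H")
        n = self.f.size
        if np.any(self.f <= 0):
            bad = np.flatnonzero(self.f <= 0) + 1
            raise ModelError(f"turnovers f must be strictly positive; entry {bad.tolist()}")
        for name, M in (("G", self.G), ("H", self.H)):
            if M.shape != (n, n):
                raise ModelError(f"{name} has shape {M.shape}, expected {(n, n)}")
        if self.steady_state_raw is None:
            self.steady_state_raw = np.ones(n)
        else:
            self.steady_state_raw = _as_matrix(self.steady_state_raw, "steady_state_raw").reshape(-1)
            if self.steady_state_raw.shape != (n,):
                raise ModelError("steady_state_raw has wrong length")
        if self.var_names is None:
            self.var_names = _default_names(n)

    @property
    def n_vars(self) -> int:
        return self.f.size

    def rhs(self, z: np.ndarray) -> np.ndarray:
        z = _check_state(z, self.n_vars)
        return self.f * (_monomials(self.G, z) - _monomials(self.H, z))

    def log_rhs(self, y: np.ndarray) -> np.ndarray:
        return self.f * (np.exp(self.G @ y - y) - np.exp(self.H @ y - y))

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        z = _check_state(z, self.n_vars)
        vp = self.f * _monomials(self.G, z)
        vn = self.f * _monomials(self.H, z)
        return (self.G * vp[:, None] - self.H * vn[:, None]) / z

    def to_ssystem(self) -> SSystem:
        """View as a plain s-system (alpha = beta = f) in the z coordinates."""
        return SSystem(self.f.copy(), self.f.copy(), self.G.copy(), self.H.copy(),
                       list(self.var_names))


@dataclass
class GLVModel:
    """Generalized Lotka-Volterra system ``xdot = diag(x) (lam + A x^B)``.

    Rows of ``B`` (the quasimonomial exponents) are kept pairwise distinct:
    duplicate rows, compared after rounding to ``DEDUP_DECIMALS`` decimals,
    are merged by summing the corresponding columns of ``A``.
    """

    lam: np.ndarray
    A: np.ndarray
    B: np.ndarray
    var_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lam = _as_matrix(self.lam, "lambda").reshape(-1)
        self.A = _as_matrix(self.A, "A")
        self.B = _as_matrix(self.B, "B")
        n = self.lam.size
        if self.A.ndim != 2 or self.A.shape[0] != n:
            raise ModelError(f"A has shape {self.A.shape}, expected ({n}, m)")
        m = self.A.shape[1]
        if self.B.shape != (m, n):
            raise ModelError(f"B has shape {self.B.shape}, expected {(m, n)}")
        # merge duplicate quasimonomial rows
        seen: dict[tuple, int] = {}
        keep: list[int] = []
        merged = False
        cols: list[np.ndarray] = []
        for j in range(m):
            key = tuple(np.round(self.B[j], DEDUP_DECIMALS) + 0.0)
            if key in seen:
                cols[seen[key]] = cols[seen[key]] + self.A[:, j]
                merged = True
            else:
                seen[key] = len(keep)
                keep.append(j)
                cols.append(self.A[:, j].copy())
        if merged:
            warnings.warn("duplicate quasimonomial exponent rows merged", stacklevel=2)
            self.B = self.B[keep]
            self.A = np.column_stack(cols) if cols else np.zeros((n, 0))
        if self.var_names is None:
            self.var_names = _default_names(n)

    @property
    def n_vars(self) -> int:
        return self.lam.size

    @property
    def n_monomials(self) -> int:
        return self.B.shape[0]

    def quasimonomials(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        return _monomials(self.B, x)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        return x * (self.lam + self.A @ _monomials(self.B, x))

    def log_rhs(self, y: np.ndarray) -> np.ndarray:
        return self.lam + self.A @ np.exp(self.B @ y)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = _check_state(x, self.n_vars)
        q = _monomials(self.B, x)
        J = np.diag(self.lam + self.A @ q)
        J = J + x[:, None] * ((self.A * q) @ (self.B / x))
        return J


@dataclass
class LVModel:
    """Lotka-Volterra canonical form ``qdot = diag(q) (bias + M q)``.

    Produced by the embedding ``q = x^B`` of a GLV; ``bias = B lam`` and
    ``M = B A``.  Every system in a quasimonomial equivalence class maps to
    the same LV representation.
    """

    bias: np.ndarray
    M: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bias = _as_matrix(self.bias, "bias").reshape(-1)
        self.M = _as_matrix(self.M, "M")
        m = self.bias.size
        if self.M.shape != (m, m):
            raise ModelError(f"M has shape {self.M.shape}, expected {(m, m)}")

    @property
    def m_vars(self) -> int:
        return self.bias.size

    def rhs(self, q: np.ndarray) -> np.ndarray:
        q = _check_state(q, self.m_vars)
        return q * (self.bias + self.M @ q)

    def log_rhs(self, y: np.ndarray) -> np.ndarray:
        return self.bias + self.M @ np.exp(y)

    def jacobian(self, q: np.ndarray) -> np.ndarray:
        q = _check_state(q, self.m_vars)
        return np.diag(self.bias + self.M @ q) + q[:, None] * self.M


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def ssystem_to_gma(model: SSystem) -> PowerLawModel:
    """Embed an s-system in GMA form: N = [I | -I], gamma = (alpha, beta), F = [G; H]."""
    n = model.n_vars
    N = np.hstack([np.eye(n), -np.eye(n)])
    gamma = np.concatenate([model.alpha, model.beta])
    F = np.vstack([model.G, model.H])
    return PowerLawModel(N, gamma, F, list(model.var_names))


def gma_to_glv(model: PowerLawModel) -> GLVModel:
    """Rewrite a GMA as a GLV by factoring each variable out of its equation.

    For variable i and flux j with ``N[i, j] != 0`` the per-capita term has
    coefficient ``N[i, j] * gamma[j]`` and exponent row ``F[j] - e_i``.
    All-zero exponent rows (terms proportional to the variable itself)
    contribute to ``lam``; duplicate rows are merged.
    """
    n, m = model.N.shape
    lam = np.zeros(n)
    rows: list[np.ndarray] = []
    keys: dict[tuple, int] = {}
    cols: list[np.ndarray] = []
    for i in range(n):
        for j in range(m):
            if model.N[i, j] == 0:
                continue
            coeff = model.N[i, j] * model.gamma[j]
            row = model.F[j].copy()
            row[i] -= 1.0
            rounded = np.round(row, DEDUP_DECIMALS)
            if np.all(rounded == 0):
                lam[i] += coeff
                continue
            key = tuple(rounded + 0.0)
            if key not in keys:
                keys[key] = len(rows)
                rows.append(row)
                cols.append(np.zeros(n))
            cols[keys[key]][i] += coeff
    B = np.array(rows).reshape(len(rows), n)
    A = np.column_stack(cols) if cols else np.zeros((n, 0))
    return GLVModel(lam, A, B, list(model.var_names))


def glv_to_ssystem(model: GLVModel) -> SSystem:
    """Fold a GLV back into s-system form, when exactly representable.

    Multiplying by ``diag(x)`` restores power-law terms with exponents
    ``B_j + e_i`` (plus ``lam_i x_i``).  The rewrite is exact only when every
    equation then carries exactly one positive and one negative term;
    otherwise :class:`NotSSystemRepresentableError` is raised.
    """
    n = model.n_vars
    alpha = np.empty(n)
    beta = np.empty(n)
    G = np.empty((n, n))
    H = np.empty((n, n))
    for i in range(n):
        terms: list[tuple[float, np.ndarray]] = []
        if model.lam[i] != 0.0:
            e = np.zeros(n)
            e[i] = 1.0
            terms.append((model.lam[i], e))
        for j in range(model.n_monomials):
            c = model.A[i, j]
            if c == 0.0:
                continue
            row = model.B[j].copy()
            row[i] += 1.0
            terms.append((c, row))
        # merge equal exponent rows within the equation
        merged: dict[tuple, list] = {}
        for c, row in terms:
            key = tuple(np.round(row, DEDUP_DECIMALS) + 0.0)
            if key in merged:
                merged[key][0] += c
            else:
                merged[key] = [c, row]
        pos = [(c, r) for c, r in merged.values() if c > 0]
        neg = [(c, r) for c, r in merged.values() if c < 0]
        if len(pos) != 1 or len(neg) != 1:
            raise NotSSystemRepresentableError(
                f"equation {i + 1} has {len(pos)} positive and {len(neg)} negative "
                "power-law terms; an s-system needs exactly one of each"
            )
        alpha[i], G[i] = pos[0]
        beta[i] = -neg[0][0]
        H[i] = neg[0][1]
    return SSystem(alpha, beta, G, H, list(model.var_names))


# ---------------------------------------------------------------------------
# steady states and normalization
# ---------------------------------------------------------------------------


def ssystem_steady_state(model: SSystem, rank_rtol: float = _RANK_RTOL) -> np.ndarray:
    """Closed-form positive steady state: solve (G - H) log x = log(beta/alpha)."""
    D = model.G - model.H
    s = np.linalg.svd(D, compute_uv=False)
    if s.size == 0 or s[-1] <= rank_rtol * max(s[0], 1.0):
        rank = int(np.sum(s > rank_rtol * max(s[0] if s.size else 0.0, 1.0)))
        raise SteadyStateError(
            f"no unique steady state: G - H is rank deficient "
            f"(numerical rank {rank} of {model.n_vars})"
        )
    logx = np.linalg.solve(D, np.log(model.beta / model.alpha))
    return np.exp(logx)


def normalize(model: SSystem) -> NormalizedSSystem:
    """Normalize by the steady state so the equilibrium moves to z = 1.

    Turnovers are the steady-state fluxes per pool size,
    ``f_i = alpha_i x*^{G_i} / x*_i = beta_i x*^{H_i} / x*_i``; both
    expressions are computed and must agree.
    """
    xs = ssystem_steady_state(model)
    f_pos = model.alpha * _monomials(model.G, xs) / xs
    f_neg = model.beta * _monomials(model.H, xs) / xs
    rel = np.max(np.abs(f_pos - f_neg) / np.abs(f_pos))
    if rel > 1e-8:
        raise ModelError(
            f"internal consistency failure: production and degradation turnovers "
            f"disagree by relative {rel:.2e}"
        )
    return NormalizedSSystem(f_pos, model.G.copy(), model.H.copy(),
                             steady_state_raw=xs, var_names=list(model.var_names))


# ---------------------------------------------------------------------------
# generic evaluation
# ---------------------------------------------------------------------------

AnyModel = PowerLawModel | SSystem | NormalizedSSystem | GLVModel | LVModel


def evaluate_rhs(model: AnyModel, state) -> np.ndarray:
    """Time derivatives of any formalism at a strictly positive state."""
    return model.rhs(np.asarray(state, dtype=float))


def jacobian(model: AnyModel, state) -> np.ndarray:
    """Analytic Jacobian of any formalism at a strictly positive state.

    For a :class:`NormalizedSSystem` at z = 1 this equals diag(f) (G - H).
    """
    return model.jacobian(np.asarray(state, dtype=float))
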
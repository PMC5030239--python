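"""Quasimonomial transformations and spectral diagnostics of GLV systems.

A quasimonomial transformation ``x = y^C`` (``C`` square, invertible) maps a
GLV system to another GLV with ``Ahat = C^-1 A``, ``lamhat = C^-1 lam`` and
``Bhat = B C``.  All systems connected this way form an equivalence class
sharing steady-state structure and stability; substituting ``q = x^B``
collapses the whole class onto one quadratic Lotka-Volterra system with
constant interaction matrix ``B A``.

Two spectral diagnostics identify slow directions and near-decoupled
variables:

* the SVD of the kinetic exponent matrix ``B``: transforming with
  ``C = V_B`` multiplies every exponent of the new variable ``y_i`` by the
  singular value ``sigma_i``, so the right singular vector of the smallest
  singular value spans the slow manifold;
* the joint factorization ``B A = U_B S_B W S_A V_A^T`` (``W = V_B^T U_A``),
  separating the kinetic (``S_B``) from the stoichiometric (``S_A``)
  contribution to the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .models import GLVModel, LVModel, AnyModel, ModelError, jacobian as model_jacobian

__all__ = [
    "QuasimonomialTransform",
    "SVDReport",
    "BADecomposition",
    "LogModeBasis",
    "DefectiveJacobianError",
    "apply_quasimonomial",
    "kernel_decoupling",
    "lv_embedding",
    "svd_analysis",
    "ba_decomposition",
    "log_modes",
    "modal_decomposition",
]

_COND_LIMIT = 1e12


class DefectiveJacobianError(ModelError):
    """The Jacobian is numerically non-diagonalizable."""


@dataclass
class QuasimonomialTransform:
    """Change of variables x = y^C with C square and non-singular."""

    C: np.ndarray
    cond: float = field(init=False)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        n = self.C.shape[0]
        if self.C.ndim != 2 or self.C.shape != (n, n):
            raise ModelError("C must be square")
        self.cond = float(np.linalg.cond(self.C))
        if not np.isfinite(self.cond) or self.cond > _COND_LIMIT:
            raise ModelError(
                f"transformation matrix C is singular or near-singular "
                f"(condition number {self.cond:.3e})"
            )

    def inverse(self) -> "QuasimonomialTransform":
        return QuasimonomialTransform(np.linalg.inv(self.C))

    def map_state(self, x: np.ndarray) -> np.ndarray:
        """y such that x = y^C (log x = C log y), i.e. y = x^(C^-1)."""
        return np.exp(np.linalg.solve(self.C, np.log(np.asarray(x, float))))

    def unmap_state(self, y: np.ndarray) -> np.ndarray:
        """x = y^C."""
        return np.exp(self.C @ np.log(np.asarray(y, float)))


def apply_quasimonomial(model: GLVModel, t: QuasimonomialTransform) -> GLVModel:
    """Transformed GLV: Ahat = C^-1 A, lamhat = C^-1 lam, Bhat = B C."""
    if t.C.shape[0] != model.n_vars:
        raise ModelError("transform dimension does not match model")
    Ahat = np.linalg.solve(t.C, model.A)
    lamhat = np.linalg.solve(t.C, model.lam)
    Bhat = model.B @ t.C
    names = [f"y{i}" for i in range(1, model.n_vars + 1)]
    return GLVModel(lamhat, Ahat, Bhat, names)


def kernel_decoupling(
    model: GLVModel, rank_tol: float = 1e-10
) -> tuple[GLVModel, list[int]]:
    """Decouple variables associated with the kernel of B.

    When rank(B) = r < n, the transformation ``C = [completion | phi_1..phi_k]``
    (kernel basis in the trailing columns) yields ``Bhat`` with k = n - r
    all-zero trailing columns: the corresponding new variables enter no
    equation but their own and reduce to quadratures.  The completion picks
    the r standard basis vectors least explained by the kernel (pivoted
    selection), which keeps C well conditioned for any variable ordering.

    Returns the transformed model and the (0-based) positions of the
    decoupled variables; a full-rank B returns the model unchanged with an
    empty list ("nothing to decouple").
    """
    B = model.B
    K = scipy.linalg.null_space(B, rcond=rank_tol)
    k = K.shape[1]
    n = model.n_vars
    if k == 0:
        return model, []
    r = n - k
    # residual of each standard basis vector after projecting onto span(K);
    # rounding makes the tie-break (lowest index) deterministic
    scores = np.round(1.0 - np.sum(K * K, axis=1), 12)
    chosen = sorted(np.lexsort((np.arange(n), -scores))[:r])
    C = np.hstack([np.eye(n)[:, chosen], K]) if r else K
    out = apply_quasimonomial(model, QuasimonomialTransform(C))
    tail = out.B[:, r:]
    resid = np.max(np.abs(tail)) if tail.size else 0.0
    if resid > 1e-8 * max(1.0, np.max(np.abs(B))):
        raise ModelError(f"kernel columns did not vanish (residual {resid:.2e})")
    out.B[:, r:] = 0.0
    return out, list(range(r, n))


def lv_embedding(model: GLVModel) -> LVModel:
    """Lotka-Volterra canonical form via q = x^B: bias = B lam, M = B A."""
    return LVModel(model.B @ model.lam, model.B @ model.A)


# ---------------------------------------------------------------------------
# SVD diagnostics
# ---------------------------------------------------------------------------


def _sign_fix_columns(V: np.ndarray, *coupled: np.ndarray) -> None:
    """Orient each column so its largest-magnitude entry is positive (in place).

    Ties go to the first maximal entry.  Matrices in ``coupled`` (e.g. the
    matching U columns) are flipped consistently.
    """
    for j in range(V.shape[1]):
        col = V[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            V[:, j] = -col
            for M in coupled:
                M[:, j] = -M[:, j]


@dataclass
class SVDReport:
    """Thin SVD with deterministic signs and an effective-rank estimate."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray  # right singular vectors as columns
    rank_tol: float
    effective_rank: int
    slow_vector: np.ndarray  # last column of V, sign-normalized


def svd_analysis(matrix, rank_tol: float = 1e-10) -> SVDReport:
    """SVD of a real matrix with the conventions used throughout this package.

    Singular values are non-increasing, so the slow direction — the right
    singular vector of the smallest singular value — is always the last
    column of V.  Each right singular vector is oriented so that its
    largest-magnitude component is positive.  ``effective_rank`` counts
    singular values above ``rank_tol * sigma_max``.
    """
    A = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ModelError("matrix must be finite")
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T
    _sign_fix_columns(V, U)
    smax = S[0] if S.size else 0.0
    eff = int(np.sum(S > rank_tol * smax)) if S.size else 0
    return SVDReport(U=U, S=S, V=V, rank_tol=rank_tol,
                     effective_rank=eff, slow_vector=V[:, -1].copy())


@dataclass
class BADecomposition:
    """Factorization B A = U_B S_B W S_A V_A^T with W = V_B^T U_A.

    The unitary factors cannot amplify or dampen perturbations; any change in
    norm comes from the kinetic singular values ``S_B`` or the stoichiometric
    ``S_A``.  ``dominance`` labels which of the two spreads (max/min over
    nonzero singular values) dominates.
    """

    U_B: np.ndarray
    S_B: np.ndarray
    W: np.ndarray
    S_A: np.ndarray
    V_A: np.ndarray
    sb_range: tuple[float, float]
    sa_range: tuple[float, float]
    dominance: str  # "kinetic" | "stoichiometric" | "mixed"

    def reconstruct(self) -> np.ndarray:
        return self.U_B @ np.diag(self.S_B) @ self.W @ np.diag(self.S_A) @ self.V_A.T


def _spread(S: np.ndarray, rank_tol: float) -> tuple[float, float]:
    nz = S[S > rank_tol * (S[0] if S.size else 0.0)]
    if nz.size == 0:
        return (0.0, 0.0)
    return (float(nz.min()), float(nz.max()))


def ba_decomposition(
    model: GLVModel, spread_factor: float = 10.0, rank_tol: float = 1e-10
) -> BADecomposition:
    """Split the LV interaction matrix B A into kinetic and stoichiometric parts."""
    rb = svd_analysis(model.B, rank_tol)
    ra = svd_analysis(model.A, rank_tol)
    W = rb.V.T @ ra.U
    sb_lo, sb_hi = _spread(rb.S, rank_tol)
    sa_lo, sa_hi = _spread(ra.S, rank_tol)
    spread_b = sb_hi / sb_lo if sb_lo > 0 else np.inf
    spread_a = sa_hi / sa_lo if sa_lo > 0 else np.inf
    if spread_b >= spread_factor * spread_a:
        dominance = "kinetic"
    elif spread_a >= spread_factor * spread_b:
        dominance = "stoichiometric"
    else:
        dominance = "mixed"
    return BADecomposition(U_B=rb.U, S_B=rb.S, W=W, S_A=ra.S, V_A=ra.V,
                           sb_range=(sb_lo, sb_hi), sa_range=(sa_lo, sa_hi),
                           dominance=dominance)


# ---------------------------------------------------------------------------
# log-modes
# ---------------------------------------------------------------------------


@dataclass
class LogModeBasis:
    """Modal decomposition of the Jacobian in logarithmic coordinates.

    The modes ``l = x^M`` are monomials of the original variables, so slow or
    fast manifolds read off from them remain power laws and back-substitute
    into any of the canonical formalisms without creating algebraic
    constraints.  ``M`` satisfies ``M J M^-1 = Lambda`` with ``Lambda``
    diagonal, except that complex-conjugate eigenvalue pairs are kept
    together as real 2x2 rotation-scaling blocks.
    """

    M: np.ndarray
    eigenvalues: np.ndarray  # complex, in block order
    block_structure: list[tuple[tuple[int, ...], complex]]
    slow_direction: np.ndarray  # unit right eigenvector, smallest |eigenvalue|
    warnings: list[str] = field(default_factory=list)

    @property
    def modes(self) -> np.ndarray:
        """Rows of M: exponent vectors of the log-modes."""
        return self.M


def modal_decomposition(J: np.ndarray, hyperbolic_tol: float = 1e-9) -> LogModeBasis:
    """Eigendecomposition of a real matrix with real-Jordan pairing.

    Raises :class:`DefectiveJacobianError` when J is numerically
    non-diagonalizable; attaches a warning (without failing) when an
    eigenvalue's real part is within ``hyperbolic_tol * max|eig|`` of zero
    (non-hyperbolic steady state).
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    w, V = np.linalg.eig(J)
    scale = float(np.max(np.abs(w))) if n else 0.0
    imag_tol = 1e-12 * max(scale, 1.0)

    cols: list[np.ndarray] = []
    blocks: list[tuple[tuple[int, ...], complex]] = []
    eigs: list[complex] = []
    used = np.zeros(n, dtype=bool)
    for i in range(n):
        if used[i]:
            continue
        li = w[i]
        if abs(li.imag) <= imag_tol:
            used[i] = True
            v = np.real(V[:, i])
            nv = np.linalg.norm(v)
            if nv == 0:  # purely imaginary eigenvector for a real eigenvalue
                raise DefectiveJacobianError("degenerate eigenvector")
            cols.append(v / nv)
            blocks.append(((len(cols) - 1,), complex(li.real, 0.0)))
            eigs.append(complex(li.real, 0.0))
        else:
            # find unused conjugate partner
            partner = None
            for j in range(i + 1, n):
                if not used[j] and abs(w[j] - np.conj(li)) <= 1e-8 * max(scale, 1.0):
                    partner = j
                    break
            if partner is None:
                raise DefectiveJacobianError("unpaired complex eigenvalue")
            used[i] = used[partner] = True
            ref = V[:, i] if li.imag > 0 else V[:, partner]
            lref = li if li.imag > 0 else w[partner]
            p, q = np.real(ref), np.imag(ref)
            s = max(np.linalg.norm(p), np.linalg.norm(q))
            cols.append(p / s)
            cols.append(q / s)
            blocks.append(((len(cols) - 2, len(cols) - 1), lref))
            eigs.extend([lref, np.conj(lref)])

    Vr = np.column_stack(cols)
    condV = np.linalg.cond(Vr)
    if not np.isfinite(condV) or condV > _COND_LIMIT:
        raise DefectiveJacobianError(
            f"Jacobian is defective at tolerance (eigenbasis condition {condV:.3e})"
        )
    M = np.linalg.inv(Vr)

    # verify block-diagonality of M J M^-1
    T = M @ J @ Vr
    mask = np.ones((n, n), dtype=bool)
    for idx, _ in blocks:
        for a in idx:
            for b in idx:
                mask[a, b] = False
    off = float(np.max(np.abs(T[mask]))) if mask.any() else 0.0
    if off > 1e-8 * max(scale, 1.0):
        raise DefectiveJacobianError(
            f"modal decomposition failed: off-block residual {off:.2e}"
        )

    warns: list[str] = []
    if np.any(np.abs(np.real(w)) <= hyperbolic_tol * max(scale, 1.0)):
        warns.append("non-hyperbolic steady state: eigenvalue with near-zero real part")
        warnings.warn(warns[-1], stacklevel=2)

    i_slow = int(np.argmin(np.abs(w)))
    u = V[:, i_slow]
    if abs(w[i_slow].imag) > imag_tol:
        warns.append("slowest eigenvalue is complex; slow_direction uses its real part")
    u = np.real(u)
    u = u / np.linalg.norm(u)
    imax = int(np.argmax(np.abs(u)))
    if u[imax] < 0:
        u = -u

    return LogModeBasis(M=M, eigenvalues=np.array(eigs), block_structure=blocks,
                        slow_direction=u, warnings=warns)


def log_modes(model: AnyModel, state, hyperbolic_tol: float = 1e-9) -> LogModeBasis:
    """Log-modes of a model linearized at a (steady) state.

    In logarithmic coordinates the Jacobian of an s-system at steady state is
    identical to the original one, so the eigen-coefficients define monomial
    modes ``l = x^M`` valid for every formalism here.
    """
    J = model_jacobian(model, state)
    return modal_decomposition(J, hyperbolic_tol=hyperbolic_tol)
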
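"""Turnover-based time-scale classification and quasi-steady-state reduction.

For a normalized s-system ``zdot = diag(f) (z^G - z^H)`` the turnover ``f_i``
is a proxy for the time scale of variable i.  Sorting turnovers in
non-increasing order and cutting at the largest gap splits the system into a
fast block (indices before the cut) and a slow block, with separation ratio
``eps = f_slowest-fast-side / f_fastest-fast-side < 1``.

Setting the fast derivatives to zero gives, in logarithmic coordinates, the
*linear* constraint ``D_FF log z_F = -D_FS log z_S`` (``D = G - H``
partitioned by fast F / slow S blocks; the right-hand side offset vanishes
because the normalized equilibrium is the all-ones vector).  Because
s-systems are closed under power-law substitution (the telescopic property),
back-substituting the resulting power-law QSS manifold

    log z_F = Phi log z_S,   Phi = -D_FF^-1 D_FS

into the slow equations yields *another s-system* with exponents

    ghat = G_SS + G_SF Phi,   hhat = H_SS + H_SF Phi

and unchanged turnovers, never a differential-algebraic system.  The fast
block, with the slow variables frozen, is likewise an s-system whose rate
constants absorb the frozen slow monomials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import (
    ModelError,
    NormalizedSSystem,
    SSystem,
    _monomials,
)

__all__ = [
    "NoSeparationError",
    "QSSError",
    "TimescalePartition",
    "QSSMap",
    "FastSubsystem",
    "ReducedPair",
    "timescale_partition",
    "qss_reduce",
    "multi_scale_split",
]

#: Above this separation ratio the fast/slow split is considered weak and a
#: warning is emitted (the reduction is still produced; its quality is judged
#: empirically by simulation).
WEAK_SEPARATION = 0.1

_RANK_RTOL = 1e-12


class NoSeparationError(ModelError):
    """All turnovers are equal: no time-scale split exists."""


class QSSError(ModelError):
    """The fast block admits no isolated quasi-steady state."""


@dataclass
class TimescalePartition:
    """Variable ordering by non-increasing turnover with a fast/slow cut.

    ``order`` is a permutation of 0..n-1; variables ``order[:k]`` are fast,
    ``order[k:]`` slow.  ``epsilon`` is the ratio of the turnovers straddling
    the cut and ``gap_scores`` holds all n-1 candidate gap values.
    """

    order: np.ndarray
    k: int
    epsilon: float
    gap_scores: np.ndarray
    mode: str = "raw"

    @property
    def fast_indices(self) -> np.ndarray:
        return np.sort(self.order[: self.k])

    @property
    def slow_indices(self) -> np.ndarray:
        return np.sort(self.order[self.k:])


def timescale_partition(f, mode: str = "raw") -> TimescalePartition:
    """Split variables into fast and slow at the largest turnover gap.

    ``mode="raw"`` maximizes ``f_k - f_{k+1}`` along the sorted turnovers;
    ``mode="log"`` maximizes the gap of log10 turnovers instead (useful when
    scales span many orders of magnitude).  Ties pick the smallest k, i.e.
    the most aggressive reduction.
    """
    f = np.asarray(f, dtype=float).reshape(-1)
    n = f.size
    if n < 2:
        raise ModelError("need at least two variables to partition")
    if np.any(f <= 0):
        raise ModelError("turnovers must be strictly positive")
    order = np.argsort(-f, kind="stable")
    fs = f[order]
    if fs[0] == fs[-1]:
        raise NoSeparationError("no separation: all turnovers are equal")
    if mode == "raw":
        gaps = fs[:-1] - fs[1:]
    elif mode == "log":
        gaps = np.log10(fs[:-1]) - np.log10(fs[1:])
    else:
        raise ModelError(f"unknown gap mode {mode!r}")
    k = int(np.argmax(gaps)) + 1
    eps = float(fs[k] / fs[k - 1])
    if eps > WEAK_SEPARATION:
        warnings.warn(f"separation weak: epsilon = {eps:.3g} > {WEAK_SEPARATION}",
                      stacklevel=2)
    return TimescalePartition(order=order, k=k, epsilon=eps,
                              gap_scores=gaps, mode=mode)


@dataclass
class QSSMap:
    """Power-law quasi-steady-state manifold log z_F = Phi log z_S + c."""

    Phi: np.ndarray
    c: np.ndarray
    fast_indices: np.ndarray
    slow_indices: np.ndarray

    def __call__(self, z_slow) -> np.ndarray:
        z_slow = np.asarray(z_slow, dtype=float).reshape(-1)
        if np.any(z_slow <= 0):
            raise ModelError("slow state must be strictly positive")
        return np.exp(self.Phi @ np.log(z_slow) + self.c)


@dataclass
class FastSubsystem:
    """Fast block with the slow variables frozen to constants.

    The slow state enters only through the lumped rate constants
    ``alphahat_i = f_i * s^{G_iS}`` and ``betahat_i = f_i * s^{H_iS}``; the
    exponents on the fast variables are the unmodified blocks G_FF, H_FF.
    """

    f: np.ndarray
    G_FF: np.ndarray
    H_FF: np.ndarray
    G_FS: np.ndarray
    H_FS: np.ndarray
    var_names: list[str]
    slow_names: list[str]
    slow_defaults: np.ndarray

    def frozen(self, z_slow=None) -> SSystem:
        """Concrete fast s-system for a given (positive) frozen slow state."""
        s = self.slow_defaults if z_slow is None else np.asarray(z_slow, float).reshape(-1)
        if np.any(s <= 0):
            raise ModelError("frozen slow values must be strictly positive")
        alphahat = self.f * _monomials(self.G_FS, s)
        betahat = self.f * _monomials(self.H_FS, s)
        return SSystem(alphahat, betahat, self.G_FF.copy(), self.H_FF.copy(),
                       list(self.var_names))


@dataclass
class ReducedPair:
    """Result of a QSS reduction: slow s-system, fast subsystem, QSS map."""

    slow: NormalizedSSystem
    fast: FastSubsystem
    qss_map: QSSMap
    partition: TimescalePartition
    full_var_names: list[str] = field(default_factory=list)


def _qss_eliminate(G, H, fast, keep, rank_rtol=_RANK_RTOL, var_names=None):
    """Eliminate ``fast`` by QSS; return (ghat, hhat, Phi) over ``keep``.

    Frozen variables (neither fast nor kept) sit at z = 1 and drop out of the
    log-linear solve.
    """
    D = G - H
    D_FF = D[np.ix_(fast, fast)]
    s = np.linalg.svd(D_FF, compute_uv=False) if len(fast) else np.array([1.0])
    if len(fast) and s[-1] <= rank_rtol * max(s[0], 1.0):
        # identify the fast variables supporting the null space
        ns = np.linalg.svd(D_FF)[2][-1]
        dep = [
            (var_names[fast[i]] if var_names else f"x{fast[i] + 1}")
            for i in np.flatnonzero(np.abs(ns) > 1e-8)
        ]
        raise QSSError(
            "fast block has no isolated quasi-steady state: G - H restricted to "
            f"the fast variables is singular (dependent fast variables: {dep})"
        )
    D_FK = D[np.ix_(fast, keep)]
    Phi = -np.linalg.solve(D_FF, D_FK) if len(fast) else np.zeros((0, len(keep)))
    ghat = G[np.ix_(keep, keep)] + G[np.ix_(keep, fast)] @ Phi
    hhat = H[np.ix_(keep, keep)] + H[np.ix_(keep, fast)] @ Phi
    return ghat, hhat, Phi


def qss_reduce(model: NormalizedSSystem, partition: TimescalePartition) -> ReducedPair:
    """Split a normalized s-system into slow and fast s-system subsystems.

    The slow subsystem evolves on the slow time scale with the fast variables
    replaced by their QSS manifold values; its steady state is the slow block
    of the full steady state (all ones).  The fast subsystem treats the slow
    variables as frozen constants (defaulting to their steady-state values).
    """
    n = model.n_vars
    if partition.order.size != n:
        raise ModelError("partition does not match model size")
    fast = list(partition.fast_indices)
    slow = list(partition.slow_indices)
    names = list(model.var_names)
    ghat, hhat, Phi = _qss_eliminate(model.G, model.H, fast, slow, var_names=names)
    slow_model = NormalizedSSystem(
        model.f[slow], ghat, hhat,
        steady_state_raw=model.steady_state_raw[slow],
        var_names=[names[i] for i in slow],
    )
    fast_sub = FastSubsystem(
        f=model.f[fast],
        G_FF=model.G[np.ix_(fast, fast)], H_FF=model.H[np.ix_(fast, fast)],
        G_FS=model.G[np.ix_(fast, slow)], H_FS=model.H[np.ix_(fast, slow)],
        var_names=[names[i] for i in fast],
        slow_names=[names[i] for i in slow],
        slow_defaults=np.ones(len(slow)),
    )
    qss_map = QSSMap(Phi=Phi, c=np.zeros(len(fast)),
                     fast_indices=np.asarray(fast), slow_indices=np.asarray(slow))
    return ReducedPair(slow=slow_model, fast=fast_sub, qss_map=qss_map,
                       partition=partition, full_var_names=names)


def multi_scale_split(model: NormalizedSSystem, cut_indices) -> list[NormalizedSSystem]:
    """Split into one submodel per time scale (slowest group first).

    Variables are ordered by non-decreasing turnover (stable sort) and cut at
    the given strictly increasing positions; ``cut_indices = [c]`` therefore
    reproduces a single :func:`qss_reduce`.  Submodel j keeps its own block,
    eliminates every faster variable through the QSS manifold and freezes
    every slower variable at its steady-state value (z = 1, which contributes
    a unit factor and drops out).
    """
    n = model.n_vars
    cuts = [int(c) for c in cut_indices]
    if any(c2 <= c1 for c1, c2 in zip(cuts, cuts[1:])):
        raise ModelError("cut indices must be strictly increasing")
    if cuts and (cuts[0] < 1 or cuts[-1] > n - 1):
        raise ModelError(f"cut indices must lie in 1..{n - 1}")
    asc = np.argsort(model.f, kind="stable")  # slowest first
    bounds = [0] + cuts + [n]
    blocks = [asc[bounds[j]: bounds[j + 1]] for j in range(len(bounds) - 1)]
    names = list(model.var_names)
    out: list[NormalizedSSystem] = []
    for j, block in enumerate(blocks):
        keep = sorted(block.tolist())
        fast = sorted(np.concatenate(blocks[j + 1:]).tolist()) if j + 1 < len(blocks) else []
        ghat, hhat, _ = _qss_eliminate(model.G, model.H, fast, keep, var_names=names)
        out.append(NormalizedSSystem(
            model.f[keep], ghat, hhat,
            steady_state_raw=model.steady_state_raw[keep],
            var_names=[names[i] for i in keep],
        ))
    return out
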
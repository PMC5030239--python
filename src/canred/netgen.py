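"""Random multi-time-scale genetic networks in s-system form.

A synthetic gene network is modeled as ``xdot_i = F_i (prod_j x_j^{g_ij} - x_i)``
in normalized coordinates: all regulatory interactions sit in the kinetic
orders of the production term (matrix G), degradation is first order
(H = I), and the turnover ``F_i`` sets the time scale of gene i.  The
equilibrium is the all-ones vector by construction, so no steady-state solve
is needed during rejection sampling.

Turnovers are drawn in groups (slowest group first) from normal
distributions whose standard deviations derive from the distances between
the group means, guaranteeing distinct time scales.  The kinetic-order
matrix is sparse with an exact nonzero count of ``floor(density * n^2)``
positions sampled uniformly over the full n x n grid (self-edges allowed).
Candidate networks are rejected until they are both asymptotically stable
at the equilibrium and connected as an (undirected) interaction graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelError, NormalizedSSystem, SSystem, normalize

__all__ = [
    "NetworkSpec",
    "NetworkGenerationError",
    "generate_network",
    "check_stability",
    "check_connected",
    "export_graph",
]

#: kinetic-order magnitude range; random sign.  Keeps entries comfortably
#: inside the usual band of power-law kinetic orders while avoiding
#: near-zero values that would defeat the sparsity bookkeeping.
KINETIC_ORDER_RANGE = (0.1, 1.0)


class NetworkGenerationError(ModelError):
    """Rejection sampling exhausted without an acceptable network."""


@dataclass
class NetworkSpec:
    """Prescription for a random multi-time-scale network.

    ``group_sizes`` lists the number of variables per time-scale group,
    slowest first; ``turnover_means`` the matching (strictly increasing)
    mean turnovers in per-time units.  ``density`` is the fraction of
    nonzero kinetic orders over the full n x n grid.
    """

    group_sizes: list[int]
    turnover_means: list[float]
    density: float = 0.05
    seed: int | None = None
    max_attempts: int = 100
    kinetic_order_range: tuple[float, float] = KINETIC_ORDER_RANGE

    def __post_init__(self):
        if len(self.group_sizes) != len(self.turnover_means):
            raise ModelError("group_sizes and turnover_means must match in length")
        if any(s < 1 for s in self.group_sizes):
            raise ModelError("group sizes must be positive")
        means = list(self.turnover_means)
        if any(m <= 0 for m in means):
            raise ModelError("turnover means must be positive")
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ModelError("turnover means must be strictly increasing")
        if not (0.0 < self.density <= 1.0):
            raise ModelError("density must lie in (0, 1]")

    @property
    def n_vars(self) -> int:
        return int(sum(self.group_sizes))


def _group_sds(means: list[float]) -> list[float]:
    """sd per group: (distance to nearest neighbouring group mean) / 6."""
    if len(means) == 1:
        return [means[0] / 6.0]
    sds = []
    for i, m in enumerate(means):
        gaps = []
        if i > 0:
            gaps.append(m - means[i - 1])
        if i + 1 < len(means):
            gaps.append(means[i + 1] - m)
        sds.append(min(gaps) / 6.0)
    return sds


def _draw_turnovers(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    sds = _group_sds(list(spec.turnover_means))
    out = []
    for size, mean, sd in zip(spec.group_sizes, spec.turnover_means, sds):
        lo = mean / 10.0  # truncate below to keep turnovers positive and grouped
        a = (lo - mean) / sd
        out.append(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                       size=size, random_state=rng))
    return np.concatenate(out)


def _draw_kinetic_orders(n: int, density: float, lo: float, hi: float,
                         rng: np.random.Generator) -> np.ndarray:
    nnz = math.floor(density * n * n)
    flat = rng.choice(n * n, size=nnz, replace=False)
    vals = rng.uniform(lo, hi, size=nnz) * rng.choice([-1.0, 1.0], size=nnz)
    G = np.zeros(n * n)
    G[flat] = vals
    return G.reshape(n, n)


def generate_network(spec: NetworkSpec) -> NormalizedSSystem:
    """Rejection-sample a stable, connected multi-time-scale network."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vars
    lo, hi = spec.kinetic_order_range
    rej_stab = rej_conn = 0
    for _ in range(spec.max_attempts):
        f = _draw_turnovers(spec, rng)
        G = _draw_kinetic_orders(n, spec.density, lo, hi, rng)
        model = NormalizedSSystem(f, G, np.eye(n))
        stable, _ = check_stability(model)
        connected = check_connected(model)
        if stable and connected:
            model.metadata.update({
                "generator": "canred.netgen",
                "group_sizes": list(spec.group_sizes),
                "turnover_means": [float(m) for m in spec.turnover_means],
                "density": spec.density,
                "seed": spec.seed,
            })
            return model
        if not stable:
            rej_stab += 1
        elif not connected:
            rej_conn += 1
    raise NetworkGenerationError(
        f"no acceptable network in {spec.max_attempts} attempts "
        f"({rej_stab} rejected for stability, {rej_conn} for connectivity)"
    )


def check_stability(model: SSystem | NormalizedSSystem) -> tuple[bool, float]:
    """Asymptotic stability at the normalized equilibrium z = 1.

    Returns (stable, spectral abscissa) for the Jacobian diag(f) (G - H).
    """
    if not isinstance(model, NormalizedSSystem):
        model = normalize(model)
    J = model.f[:, None] * (model.G - model.H)
    absc = float(np.max(np.real(np.linalg.eigvals(J))))
    return absc < 0.0, absc


def check_connected(model: SSystem | NormalizedSSystem) -> bool:
    """Connectivity of the undirected interaction graph.

    Variables i and j are linked when ``g_ij != 0`` or ``g_ji != 0``
    (i != j); all n variables must lie in one component.
    """
    n = model.G.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(model.G)
    g.add_edges_from((i, j) for i, j in zip(rows, cols) if i != j)
    return nx.is_connected(g) if n > 0 else True


def export_graph(model: SSystem | NormalizedSSystem) -> pd.DataFrame:
    """Directed regulatory edge list with sign labels.

    Each nonzero kinetic order ``g_ij`` becomes an edge regulator j ->
    target i, labeled "activation" (g > 0) or "inhibition" (g < 0) with its
    magnitude.  Variable labels are 1-based names.
    """
    names = list(getattr(model, "var_names", None) or
                 [f"x{i}" for i in range(1, model.G.shape[0] + 1)])
    rows, cols = np.nonzero(model.G)
    records = [
        {
            "source": names[j],
            "target": names[i],
            "sign": "activation" if model.G[i, j] > 0 else "inhibition",
            "weight": float(abs(model.G[i, j])),
        }
        for i, j in zip(rows, cols)
    ]
    return pd.DataFrame.from_records(records,
                                     columns=["source", "target", "sign", "weight"])
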
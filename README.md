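# canred — time hierarchies and model reduction for canonical non-linear models

Biochemical and gene-regulatory models written in one of the *canonical*
non-linear formalisms carry all of their structure in a handful of matrices,
which makes time-scale analysis and model reduction a matter of linear
algebra rather than ad-hoc asymptotics.  `canred` implements that workflow
for modelers in systems biology:

* **GMA (Generalized Mass Action)** — `ẋ = N diag(γ) x^F`
* **s-system** — `ẋ = diag(α) x^G − diag(β) x^H`, with closed-form
  (log-linear) steady states
* **GLV (Generalized Lotka–Volterra / quasi-polynomial)** —
  `ẋ = diag(x)(λ + A x^B)`

where `x^E` is the monomial vector with components `∏_j x_j^{E_ij}`.  The
package provides:

* exact, loss-free conversions between the three formalisms;
* quasimonomial transformations `x = y^C` (`Â = C⁻¹A`, `λ̂ = C⁻¹λ`,
  `B̂ = BC`), kernel-based decoupling of rank-deficient `B`, and the
  Lotka–Volterra embedding `q = x^B` with constant interaction matrix `BA`;
* SVD diagnostics: the right singular vector of the smallest singular value
  of `B` spans the slow manifold, and the factorization
  `BA = U_B Σ_B W Σ_A V_Aᵀ` (`W = V_Bᵀ U_A`) separates kinetic from
  stoichiometric stiffness;
* log-modes `ℓ = x^M` from the Jacobian eigenbasis in logarithmic
  coordinates — modal variables that remain power laws of the originals;
* turnover-based quasi-steady-state (QSS) reduction: variables are ranked
  by their turnover `f_i` (steady-state flux per pool size), split at the
  largest gap with separation ratio `ε = f_{k+1}/f_k`, and the fast block is
  eliminated through the log-linear QSS manifold
  `log z_F = Φ log z_S`, `Φ = −D_FF⁻¹ D_FS` (`D = G − H`).  Because
  s-systems are closed under power-law substitution, the reduced slow model
  is again an s-system (`ĝ = G_SS + G_SF Φ`), never a
  differential-algebraic system;
* stiff simulation (log-coordinate LSODA) and the reduction-error protocol:
  perturbation size `δy = ‖ln(x_{f,0}/x_{f,qss})‖`, per-variable errors
  `E_i = ∫|x_qssa − x| dt / ∫|x| dt`, and seeded randomized ensembles with
  mean ± 3σ envelopes;
* a generator of random multi-time-scale genetic networks
  `ẋ_i = F_i(∏_j x_j^{g_ij} − x_i)` with grouped turnovers, exact sparsity,
  and stability/connectivity rejection filters.

## Worked example: the three-gene network

A small regulatory circuit — gene 1 induces itself and gene 2, gene 2
induces gene 3, gene 3 inhibits gene 1, all with unit rate constants — has
identical turnovers (`f = 1` for every gene), so turnover ranking alone sees
a single time scale.  The kinetic matrix `B` of its GLV form still reveals a
slow manifold:

```python
import numpy as np
from canred import (make_toy_model, ssystem_to_gma, gma_to_glv,
                    normalize, svd_analysis, log_modes)

toy = make_toy_model()
glv = gma_to_glv(ssystem_to_gma(toy))
print(glv.B)
# [[ 0.1   0.   -0.48]
#  [ 0.3  -1.    0.  ]
#  [ 0.    0.7  -1.  ]]

rep = svd_analysis(glv.B)
print(rep.S)           # [1.446573 0.853128 0.000648]
print(rep.slow_vector) # [0.939143 0.281555 0.19682 ]

basis = log_modes(normalize(toy), np.ones(3))
print(basis.slow_direction)  # [0.938871 0.281944 0.197559]
```

The smallest singular value (6.5·10⁻⁴) is three orders of magnitude below
the others: trajectories collapse onto the one-dimensional manifold spanned
by `rep.slow_vector` before creeping to the equilibrium at `x = (1, 1, 1)`.
The slow log-mode direction agrees with that singular vector to better than
0.5% per component, so both diagnostics identify the same slow subspace.

A minimal QSS reduction, for a two-variable system whose second pool turns
over 100× faster:

```python
from canred import (NormalizedSSystem, timescale_partition, qss_reduce,
                    ensemble_compare)

m = NormalizedSSystem(f=[1.0, 100.0], G=[[0.0, 0.5], [1.0, 0.0]],
                      H=np.eye(2))
pair = qss_reduce(m, timescale_partition(m.f))
print(pair.partition.epsilon)  # 0.01
print(pair.qss_map.Phi)        # [[1.]]   -> on the manifold, z2 = z1
print(pair.slow.G)             # [[0.5]]  -> slow model: ż1 = z1^0.5 − z1

report = ensemble_compare(m, pair, n_sims=100, factor=10.0, seed=0)
print(report.delta_y.max(), report.E_norm.max())  # 2.290 0.0061
```

Even with the fast variable started up to 10-fold off its quasi-steady
state (`δy` up to 2.3), the slow trajectory of the reduced model stays
within 0.6% integrated relative error of the full system.

The same operations are available from the shell:

```bash
canred generate --groups 10,25,40 --turnovers 1,100,1e4 --density 0.05 \
       --seed 1 -o net.json
canred svd net.json
canred reduce net.json -o slow.json --fast fast.json --qss-map map.json
canred compare net.json --n 1000 --seed 42 --out report.json
```

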
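# mvhmm — parsimonious hidden Markov models for matrix-variate longitudinal data

`mvhmm` fits hidden Markov models to balanced four-way panels: `I` units,
each observed as a `P × R` real matrix at `T` common occasions (for
example, an epidemiological rate recorded by gender × age class for every
region and year).  A latent first-order Markov chain `S_it ∈ {1,…,K}` moves
each unit between states over time; given the state, the observation
follows a matrix-normal law

```
φ(X | M_k, Σ_k, Ψ_k) = exp{ -½ tr[Σ_k⁻¹ (X−M_k) Ψ_k⁻¹ (X−M_k)′] }
                        / ( (2π)^{PR/2} |Σ_k|^{R/2} |Ψ_k|^{P/2} )
```

with state mean matrix `M_k`, row covariance `Σ_k` (`P × P`) and column
covariance `Ψ_k` (`R × R`).  Because `(aΣ, a⁻¹Ψ)` gives the same law, `Ψ_k`
is constrained to unit determinant.

Parsimony comes from the eigen decomposition `Σ_k = λ_k Γ_k Δ_k Γ_k′`
(volume λ, orthogonal orientation Γ, unit-determinant diagonal shape Δ).
Constraining each component to be equal (E) or variable (V) across states,
or fixed to the identity (I), gives 14 row structures (`EII` … `VVV`); the
determinant restriction removes the column volume and leaves 7 column
structures (`II` … `VV`), hence a family of 14 × 7 = 98 models, addressed
by codes such as `VEE-EE`.

Estimation is full maximum likelihood by an ECM algorithm: a scaled
forward–backward E-step, a first CM-step for the chain (`π`, `Π`), means
and row covariances, and a second CM-step for the column covariances.
Structures with a shared orientation but state-specific shapes (`EVE`,
`VVE`, column `VE`) use an inner minorization–maximization rotation update;
structures with state-specific orientations and a shared shape (`EEV`,
`VEV`, column `EV`) use an eigen-decomposition update.  Starting values
come from a short-EM search (default: best of `H = 100` random one-iteration
runs).  Model selection across structures and state counts uses the BIC
(`−2ℓ + m log(I·T)`, lower is better), and the geometric sojourn-time
implication of the hidden chain can be tested per state by χ² goodness-of-fit
tests combined with Holm's step-down adjustment.

## Worked example

```python
import numpy as np
from mvhmm import ecm_fit, InitConfig, preset, simulate_data, sojourn_geometric_test

# the D1-K2-O2 preset: 2x2 matrices, K=2 well-separated states
scn, gen = preset("D1-T1-K2-O2")
data, states = simulate_data(gen, I=100, T=50, seed=1)

fit = ecm_fit(data, "EII", "II", K=2, init=InitConfig(seed=0))
print(f"loglik {fit.loglik:.2f}  BIC {fit.bic:.2f}  params {fit.n_params}")
print("state means:", np.round(fit.params.means.mean(axis=(1, 2)), 3))
print("decoding accuracy:", (fit.labels == states).mean())

test = sojourn_geometric_test(fit.labels, fit.params.Pi)
print("min Holm-adjusted p:", round(test.min_adjusted_p, 3))
```

Output:

```
loglik -30354.18  BIC 60810.57  params 12
state means: [-0.014  3.994]
decoding accuracy: 1.0
min Holm-adjusted p: 0.15
```

The fitted model has 12 parameters (1 initial + 2 transition probabilities,
8 mean entries, 1 spherical volume); the two fitted state levels recover
the generating separation of 4 within-state standard deviations (0 and
about 4); every occasion is decoded correctly; and the sojourn test finds
no evidence against geometric run lengths — as expected, since the data
came from a homogeneous hidden Markov chain.  (Sojourn runs are counted
with boundary truncation ignored, so for short panels — T within a few
mean sojourn lengths — the test reads truncated runs as evidence against
the geometric law; see `docs/methods.md`.)

The same workflow is available from a shell:

```sh
mvhmm simulate --preset D1-T1-K2-O2 --seed 1 --out panel.csv
mvhmm fit --data panel.csv --model EII-II -K 2 --seed 0 --out fit.yaml
mvhmm select --data panel.csv --models all --K-min 1 --K-max 3 --out grid.csv
mvhmm sojourn-test --fit fit.yaml --data panel.csv
```

Data files are five-column delimited long tables
(`unit_id,time,row_level,col_level,value`); fitted parameters are YAML.

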
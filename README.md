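# tenet — validating MI/TE network inference against ground truth

Functional and effective brain networks are routinely inferred from time
series — with pairwise correlation/mutual information, with pairwise
(bivariate) transfer entropy, or with multivariate transfer-entropy
models of each node's parents — and their graph-theoretic properties
(path length, clustering, small-worldness, hubs, modules, rich clubs)
are then interpreted scientifically. `tenet` asks, under controlled
conditions where the ground truth is known: *which of these properties
does each inference algorithm actually preserve?*

The package is aimed at methods researchers in network neuroscience and
systems biology. It provides:

* **Ground-truth generators** (`tenet.netgen`): directed ring lattices
  with source-rewiring (regular → small-world → random), linear
  preferential attachment (scale-free), and modular networks with
  controlled between-group connectivity, plus text I/O for user-supplied
  connectomes.
* **Dynamics** (`tenet.dynamics`): stationary VAR(1)
  `Z(t+1) = Z(t) C + eps(t)` with Gaussian innovations, and a delayed
  stochastic neural mass model (FitzHugh-Nagumo-derived oscillators,
  sigmoidal coupling, stochastic Heun integration, subsampling).
* **Estimators and tests** (`tenet.gaussian_info`): closed-form Gaussian
  MI `-1/2 ln(1 - rho^2)`, conditional MI, single-link and collective
  transfer entropy `T_{X->Y} = I(X_{<t}; Y_t | Y_{<t})`; chi-square
  likelihood-ratio nulls and FFT-accelerated max-statistic surrogate
  tests for family-wise error control.
* **Inference algorithms** (`tenet.infer`): bivariate MI at
  `alpha/N`, bivariate TE at `alpha/N` with nonuniform target-past
  embedding, and greedy multivariate TE with per-target family-wise
  error rate `alpha = 0.01` and backward pruning.
* **Evaluation** (`tenet.netmetrics`): precision/recall/specificity
  against the ground truth; characteristic path length, efficiency,
  Fagiolo directed clustering, small-world sigma, betweenness,
  modularity of a known partition, rich-club coefficients, and a
  discrete Clauset-style power-law fit for degree distributions.
* **Orchestration** (`tenet.experiments`): deterministic, seed-derived
  end-to-end studies, with `reproduce(study, scale)` for the four
  canonical designs (ring sweep, scale-free, modular, user connectome).

The headline result the pipeline reproduces: bivariate methods cannot
control false positives as data grow (correlation transitivity inserts
links across open triangles), which inflates clustering and small-world
coefficients and shortens path lengths; greedy multivariate TE keeps the
per-target false-positive rate at its nominal level and recovers both
the individual links and the macroscale statistics of the ground truth.

## Worked example

A three-node chain `X -> Y -> Z` (coupling 0.4, self-memory 0.5,
noise 0.1) distinguishes the algorithms:

```python
import numpy as np
from tenet import dynamics, infer, netgen

C = np.array([[0.5, 0.4, 0.0],
              [0.0, 0.5, 0.4],
              [0.0, 0.0, 0.5]])   # C[i, j] couples node i into node j
coupling = netgen.WeightedCoupling(C, noise_std=0.1)
ts = dynamics.simulate_var(coupling, 10000, rng_seed=1)

cfg = infer.InferenceConfig(algorithm="multi_te", seed=1)
multi, parents = infer.infer_multivariate_te(ts, cfg)
print(multi.adjacency.astype(int))
for p in parents:
    print(f"target {p.target}: sources={[(v.node, v.lag) for v in p.sources]} "
          f"collective TE={p.collective_te:.4f} nats")
```

prints

```
[[0 1 0]
 [0 0 1]
 [0 0 0]]
target 0: sources=[] collective TE=0.0000 nats
target 1: sources=[(0, 1)] collective TE=0.0919 nats
target 2: sources=[(1, 1)] collective TE=0.1169 nats
```

— exactly the generating chain: each target's own memory is captured by
the lag-1 embedding (not reported as a link), Y's parent is X at lag 1
with ~0.09 nats of transfer entropy, and no spurious `X -> Z` link is
inserted because conditioning on Y's past removes the pathway effect.
Bivariate TE on the same system with ten times more data
(`infer_bivariate_te`, T = 100,000) returns

```
[[0 1 1]
 [0 0 1]
 [0 1 0]]
```

with precision 0.50 at recall 1.00: the weak transitive dependencies
`X -> Z` and `Z <- Y` reverse become statistically distinguishable from
noise precisely *because* the series is long — the characteristic
failure mode of pairwise inference.

## Analysis scripts

The numbered drivers under `analysis/` rerun the validation studies at
reduced scale and write tidy tables under `results/`:

* `01_small_world.py` — ring-to-random sweep; per-algorithm
  precision/recall/specificity across rewiring probabilities.
* `02_scale_free.py` — preferential-attachment study and ground-truth
  power-law fits.
* `03_modular.py` — within- vs between-group false positives and
  modularity fidelity.
* `04_null_calibration.py` — family-wise false-positive control on
  disconnected noise systems.

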
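# Methods

## Scope and model

`tenet` is a validation pipeline for network inference from multivariate
time series. It generates ground-truth directed networks, simulates
dynamics on them, infers functional and effective networks from the
resulting series with Gaussian information-theoretic estimators, and
scores the inferred networks against the ground truth at the microscale
(link classification) and the macroscale (summary statistics).

Three inference algorithms are compared:

* **Bivariate mutual information (MI).** Zero-lag Gaussian MI,
  `I = -1/2 ln(1 - rho^2)` nats, between every pair of nodes; pairs
  passing an analytic chi-square test at level `alpha / N` become
  *undirected* links. For stationary Gaussian processes this is
  one-to-one with the magnitude of the Pearson correlation, so the
  resulting networks are equivalent to correlation-based functional
  connectivity.
* **Bivariate transfer entropy (TE).** For each ordered pair,
  `T_{X->Y} = I(X_{t-1}; Y_t | Y_{<t})` conditioned on a nonuniformly
  embedded past of the target, tested with the same chi-square null at
  `alpha / N`. For Gaussian variables TE equals Granger causality, which
  the test suite verifies against an independent regression oracle.
* **Multivariate TE.** Per target, greedy selection of the minimal set of
  lagged sources maximizing the collective TE
  `I(X_{<t}; Y_t | Y_{<t})`: at each step the candidate with the highest
  conditional MI given the target's embedding and the already-selected
  sources is accepted only if it passes a max-statistic surrogate test,
  which controls the per-target family-wise error rate at `alpha`. A
  backward pass then prunes any source that fails a surrogate test given
  all other selected variables.

### Assumptions

The validation logic presumes full observability, stationarity, and (for
the convergence claims) sampling at the causal process resolution. The
estimators are Gaussian/linear; on nonlinear dynamics they measure the
linear component of the dependence. Self-dynamics are represented by
self-loops in the structural networks and handled through the target-past
embedding — they are never reported as inferred links.

## Synthetic networks

* **Ring / small-world family** (`make_ws_ring`): a directed ring lattice
  (default N = 100, two in-neighbors per side, so non-self in-degree 4)
  whose link *sources* are rewired with probability `p`, preserving every
  in-degree exactly; a rewiring is accepted only if the non-self graph
  stays strongly connected, because the characteristic path length is
  computed on directed paths. Per-link retry cap 100, after which the
  link is left unchanged.
* **Scale-free** (`make_preferential_attachment`): linear preferential
  attachment; two seed nodes connected by a reciprocal pair, each new
  node linked bidirectionally to (default) 2 distinct existing nodes
  drawn proportionally to current total degree, giving density ~ 4/N and
  an asymptotic in-degree exponent of 3.
* **Modular** (`make_modular`): equal groups (default 5 x 20) with each
  node sending (default) 10 out-links inside its own group, of which
  `links_between_per_node` are redirected to uniformly chosen nodes in
  uniformly chosen other groups — out-degrees and the total density are
  preserved exactly, so within/overall densities start at 50% / 10%.
* **User connectomes**: any weighted directed adjacency matrix (plus
  optional delay matrix and partition) in the delimited text dialects of
  `netgen.read_network`; connectome data is not bundled.

Every node carries a self-loop whose only role is the self-weight of the
dynamics. Density is directed non-self links over N^2.

## Dynamics

**VAR(1)** (`simulate_var`): `Z(t+1) = Z(t) C + eps(t)` with i.i.d.
Gaussian innovations of standard deviation `theta = 0.1`. Spectral radius
of `C` < 1 is enforced (stability implies stationarity); the stationary
covariance solves `Sigma = C' Sigma C + theta^2 I`, which the tests use
as an oracle. Burn-in defaults to 1,000 steps from the zero state.
Uniform weight conventions follow the study designs: cross = self = 0.15
(ring), 0.1 (scale-free), 0.08 (modular); connectome sweeps instead fix
the per-target incoming sum `C_in` (split equally among parents) with
self-weight 0.2.

**Neural mass** (`simulate_neural_mass`): a two-variable oscillator per
node (membrane potential V, recovery W) derived from the FitzHugh-Nagumo
neuron, coupled through delayed sigmoidal firing rates
`S = 1/(1 + exp(-sigma (V - m)))` with gain `sigma = 0.5`, threshold
`m = 1.5`, excitability `gamma = 0.3`. Integration is stochastic Heun at
a 0.5 ms step with one shared noise increment per step
(Euler-Maruyama-consistent, `sqrt(dt)`-scaled); output is V subsampled by
30 (15 ms sampling). The drift rate constants are per second — with a
millisecond time unit the explicit scheme is unstable at any useful step
— so the integrator works in seconds internally while the interface
stays in ms. Delay buffers are initialized by holding the initial state
constant over the pre-history; one second of simulated time plus the
longest delay is discarded. The Wiener noise amplitudes are not fixed by
the model statement and default to 1 per unit time, exposed in
`NeuralMassSpec`.

## Statistics and significance

* Covariances use the maximum-likelihood (1/n) convention; near-singular
  matrices get a 1e-10 diagonal ridge. All logarithms are natural; all
  information quantities are in nats.
* Conditional MI uses the Gaussian log-determinant identity; for scalar
  candidates it is computed through partial correlations after QR
  residualization, which is algebraically identical and much faster.
* The analytic null is the likelihood-ratio result `2 n I ~ chi^2(dof)`
  with dof = (source dimension) x (target dimension); conditioning does
  not add dof. Bivariate links are tested at `alpha / N`
  (Bonferroni-style, alpha = 0.01), so each target has a ~0.01 chance of
  at least one spurious parent under independence.
* The max-statistic surrogate test builds the null of the *maximum*
  statistic over the candidate set: each candidate's aligned column is
  circularly shifted by a uniform offset in [20, n - 20] (preserving
  autocorrelation, destroying the temporal relation to the target), its
  conditional MI recomputed, and the per-surrogate maximum recorded;
  `p = (1 + #{max >= observed}) / (1 + S)` with S = 500 surrogates by
  default (p resolution 0.002 < alpha = 0.01). Because circular shifts
  preserve norms, all S statistics per candidate are computed at once
  with FFT cross-correlations; this makes the greedy algorithm's
  surrogate stage essentially free of the candidate-set size.
* Greedy ties (CMI within 1e-12) break toward smaller lag, then smaller
  node index. All statistics for one target are aligned at the maximum
  configured lag L so every comparison uses the same rows. The maximum
  lag is L = 1 for VAR experiments (matching the generating recurrence)
  and L = 4 for subsampled neural mass data.

## Evaluation

Microscale: confusion counts over all ordered non-self pairs, with
undirected MI links expanded to two directed links first; precision is
reported as NaN when nothing is inferred and excluded from averages.

Macroscale (binary non-self graphs throughout): directed characteristic
path length (requires strong connectivity), global and local efficiency,
Fagiolo directed clustering, betweenness centrality normalized by
(N-1)(N-2), small-world sigma normalized by up to 100 size- and
link-matched strongly connected directed Erdos-Renyi realizations
(non-connected draws are discarded and redrawn; an error is raised if
fewer than half the requested ensemble can be obtained), directed
Newman-Girvan modularity of the *known* partition (no community
detection), and the rich-club coefficient phi(k) on the undirected
projection with total degree.

Degree-distribution fits use a discrete maximum-likelihood power law
(zeta-function likelihood) with xmin selected by Kolmogorov-Smirnov
minimization; logarithmic binning is never used for fitting. The fitter
reproduces igraph's independent plfit implementation to three decimals on
shared inputs. One convention matters: the degree sequences pooled for
the scale-free study are in-degrees of the *raw* adjacency, self-link
included, since the dynamics genuinely include the self-connection and
the reference fits count it; excluding the diagonal lowers the pooled
exponent by ~0.3.

## Problem sizes

The canonical study parameters (N = 100-200, T in {1,000, 10,000}, 10
repetitions, the full rewiring grid) are encoded in
`experiments.reproduce` and run end-to-end in hours on one core. The
default test suite and `scripts/acceptance.py` use reduced sizes chosen
to keep the full validation in minutes: N = 30 rings with 3 repetitions
for the macroscale comparisons, 3-node motifs with 100 seeds for the
structure-learning discrimination, N = 5 nulls with 200 runs for the
false-positive calibration, and ten N = 200 nets (plus one N = 20,000
net) for the power-law fits. `reproduce(study, scale)` shrinks network
size and repetition count — never alpha and never T unless explicitly
overridden.

## What the generators do and do not emulate

The synthetic data reproduce the study conditions: exact degree
constraints, uniform coupling weights, stationary Gaussian innovations,
and (for the neural mass model) delayed nonlinear coupling with
subsampling. They do not emulate hidden nodes, nonstationarity,
measurement noise, hemodynamic convolution, or heterogeneous weight
distributions; passing tests therefore validate the algorithms under the
stated idealized conditions, not on real recordings. The known failure
modes the suite *does* exercise are the transitivity-driven false
positives of bivariate methods (chain and common-driver motifs, inflated
clustering, shortened path lengths) and their growth with series length.

## Known limitations

* Only Gaussian (linear) estimators are provided; nonlinear estimators
  are out of scope.
* The characteristic path length is undefined on non-strongly-connected
  inferred networks and propagates as NaN in summaries.
* The per-link p-values stored for multivariate TE come from the
  selection-stage surrogate tests and are conservative; inclusion is
  decided by the stopping rule, not by those p-values.
* `run_experiment` drives VAR dynamics; neural-mass experiments are
  composed directly from the `dynamics` and `infer` modules.
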
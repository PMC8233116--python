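"""Time-series simulators: stationary VAR(1) and a delayed stochastic
neural mass model.

The VAR recurrence is ``Z(t+1) = Z(t) @ C + eps(t)`` with spatially and
serially uncorrelated Gaussian innovations of standard deviation theta;
``C[i, j]`` couples node i into node j, and spectral radius < 1
guarantees stability and hence stationarity.

The neural mass model is a two-dimensional oscillator per node (membrane
potential V, slow recovery W) derived from the FitzHugh-Nagumo neuron:

    dV_i = [20 W_i + 3 V_i^2 - V_i^3 + gamma * I_i] dt + dxi_i
    dW_i = 20 (-W_i - 10 V_i) dt + deta_i
    I_i  = sum_j C_ji * S_j(t - tau_ji),    S = 1 / (1 + exp(-sigma (V - m)))

integrated with the stochastic Heun scheme and subsampled, emulating a
recording at coarser temporal resolution than the causal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import WeightedCoupling

__all__ = [
    "TimeSeriesSet",
    "NeuralMassSpec",
    "simulate_var",
    "simulate_neural_mass",
    "autocorrelation_decay_time",
]


@dataclass
class TimeSeriesSet:
    """T x N sample matrix (rows = time, columns = nodes) with metadata."""

    samples: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError("samples must be a T x N matrix")
        if s.shape[0] < 1:
            raise ValueError("need at least one time sample")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples contain non-finite values")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.samples.shape[1]


def simulate_var(
    coupling: WeightedCoupling,
    n_samples: int,
    burn_in: int = 1000,
    rng_seed: int = 0,
) -> TimeSeriesSet:
    """Simulate the stationary VAR(1) recurrence on a weighted network.

    Starts from the zero state, discards ``burn_in`` initial steps and
    returns exactly ``n_samples`` rows. The stationary covariance solves
    the discrete Lyapunov equation ``Sigma = C.T Sigma C + theta^2 I``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rho = coupling.spectral_radius()
    if rho >= 1.0:
        raise ValueError(f"spectral radius {rho:.3f} >= 1: nonstationary VAR")
    C = coupling.weights
    theta = coupling.noise_std
    n = coupling.n_nodes
    rng = np.random.default_rng(rng_seed)
    z = np.zeros(n)
    out = np.empty((n_samples, n))
    noise = rng.normal(0.0, theta, size=(burn_in + n_samples, n))
    for t in range(burn_in):
        z = z @ C + noise[t]
    for t in range(n_samples):
        z = z @ C + noise[burn_in + t]
        out[t] = z
    return TimeSeriesSet(
        out, dt=1.0, meta={"generator": "var", "seed": rng_seed, "theta": theta}
    )


@dataclass
class NeuralMassSpec:
    """Parameters of the delayed stochastic neural mass simulation.

    gain_sigma and threshold_m shape the sigmoid converting membrane
    potential to normalized firing rate; excitability_gamma scales the
    synaptic current. Delays are integer multiples of ``dt_ms``; the noise
    scales are the Wiener amplitudes per unit time of the V and W noises.
    """

    coupling: WeightedCoupling
    gain_sigma: float = 0.5
    threshold_m: float = 1.5
    excitability_gamma: float = 0.3
    dt_ms: float = 0.5
    subsample_factor: int = 30
    noise_scale_v: float = 1.0
    noise_scale_w: float = 1.0

    def __post_init__(self) -> None:
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.coupling.delays is not None and np.any(self.coupling.delays < 0):
            raise ValueError("delays must be nonnegative")


def sigmoid_rate(v: np.ndarray, sigma: float, m: float) -> np.ndarray:
    """Normalized firing rate S(V) = 1 / (1 + exp(-sigma (V - m)))."""
    return 1.0 / (1.0 + np.exp(-sigma * (np.asarray(v) - m)))


def _drift(v, w, current, gamma):
    dv = 20.0 * w + 3.0 * v**2 - v**3 + gamma * current
    dw = 20.0 * (-w - 10.0 * v)
    return dv, dw


def simulate_neural_mass(
    spec: NeuralMassSpec,
    n_steps: int,
    rng_seed: int = 0,
    burn_in_ms: float = 1000.0,
    divergence_bound: float = 1e3,
) -> TimeSeriesSet:
    """Integrate the delayed neural mass model with stochastic Heun.

    ``n_steps`` counts *output* samples after subsampling; the burn-in
    (default 1 s of simulated time, plus the longest delay) is discarded.
    The delay buffer is initialized by holding the initial state constant
    over the pre-history. One noise increment per step is shared between
    the predictor and corrector stages. Returns membrane potentials V at
    sampling interval ``dt_ms * subsample_factor``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    C = spec.coupling.weights
    n = spec.coupling.n_nodes
    # the model's rate constants are per second; integrate in seconds
    dt = spec.dt_ms / 1000.0
    delays = (
        spec.coupling.delays
        if spec.coupling.delays is not None
        else np.zeros((n, n), dtype=int)
    )
    max_delay = int(delays.max())
    rng = np.random.default_rng(rng_seed)
    n_int = (
        int(np.ceil(burn_in_ms / spec.dt_ms))
        + max_delay
        + n_steps * spec.subsample_factor
    )
    keep_from = n_int - n_steps * spec.subsample_factor

    v = rng.normal(0.0, 0.01, size=n)
    w = np.zeros(n)
    # circular history of firing rates; pre-history = initial state held constant
    hist_len = max_delay + 2
    s_hist = np.tile(sigmoid_rate(v, spec.gain_sigma, spec.threshold_m), (hist_len, 1))
    # per-(source,target) delay lookups, grouped by unique delay for speed
    unique_delays = np.unique(delays[C != 0]) if np.any(C != 0) else np.array([0])
    masks = {int(d): (delays == d) & (C != 0) for d in unique_delays}

    sqrt_dt = np.sqrt(dt)
    out = np.empty((n_steps, n))
    n_out = 0
    for step in range(n_int):
        head = step % hist_len

        def current_at(offset: int, s_now: np.ndarray | None = None) -> np.ndarray:
            # I_i = sum_j C_ji S_j(t - tau_ji); offset 0 -> time t, 1 -> t+dt
            cur = np.zeros(n)
            for d, mask in masks.items():
                if d == 0 and offset == 1 and s_now is not None:
                    s_del = s_now
                else:
                    s_del = s_hist[(head - d + offset) % hist_len]
                cur += (C * mask).T @ s_del
            return cur

        xi = rng.normal(0.0, spec.noise_scale_v * sqrt_dt, size=n)
        eta = rng.normal(0.0, spec.noise_scale_w * sqrt_dt, size=n)
        cur0 = current_at(0)
        dv1, dw1 = _drift(v, w, cur0, spec.excitability_gamma)
        v_pred = v + dv1 * dt + xi
        w_pred = w + dw1 * dt + eta
        s_pred = sigmoid_rate(v_pred, spec.gain_sigma, spec.threshold_m)
        cur1 = current_at(1, s_now=s_pred)
        dv2, dw2 = _drift(v_pred, w_pred, cur1, spec.excitability_gamma)
        v = v + 0.5 * (dv1 + dv2) * dt + xi
        w = w + 0.5 * (dw1 + dw2) * dt + eta
        if np.any(np.abs(v) > divergence_bound):
            raise RuntimeError(f"trajectory diverged at step {step}")
        s_hist[(head + 1) % hist_len] = sigmoid_rate(
            v, spec.gain_sigma, spec.threshold_m
        )
        if step >= keep_from and (step - keep_from) % spec.subsample_factor == 0:
            out[n_out] = v
            n_out += 1
    return TimeSeriesSet(
        out[:n_out],
        dt=spec.dt_ms * spec.subsample_factor,
        meta={"generator": "neural_mass", "seed": rng_seed},
    )


def autocorrelation_decay_time(ts: TimeSeriesSet, node: int) -> float:
    """First lag (interpolated, in the series' time units) at which the
    empirical autocorrelation of one node falls below 1/e."""
    x = ts.samples[:, node]
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for lag estimation")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has no autocorrelation decay")
    max_lag = n // 2
    target = 1.0 / np.e
    prev = 1.0
    for lag in range(1, max_lag + 1):
        acf = np.dot(x[:-lag], x[lag:]) / var
        if acf < target:
            # linear interpolation between (lag-1, prev) and (lag, acf)
            frac = (prev - target) / (prev - acf)
            return (lag - 1 + frac) * ts.dt
        prev = acf
    raise ValueError("autocorrelation did not fall below 1/e within T/2 lags")
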
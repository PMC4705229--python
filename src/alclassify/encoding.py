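"""Virtual-receptor encoding of real-valued samples into spike trains.

A set of *virtual receptors* (VRs) tiles the feature space, placed by the
neural gas vector-quantization algorithm fitted on training data alone.
Each VR responds to a sample through a cone-shaped radial basis function
(linearly decreasing with distance, cut off at `sigma`), the responses map
affinely onto firing rates, and each rate drives a cluster of stochastic
receptor neurons emitting Poisson (per-timestep Bernoulli) or Gamma-renewal
spike trains on the simulation grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "VRSet",
    "RatePattern",
    "SpikeTrainSet",
    "EncoderConfig",
    "fit_neural_gas",
    "vr_response",
    "vr_responses",
    "responses_to_rates",
    "gen_poisson_trains",
    "gen_gamma_trains",
    "save_spike_trains",
    "load_spike_trains",
    "save_vrset",
    "load_vrset",
]

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class VRSet:
    """Virtual receptor centroids plus the response cutoff radius.

    `sigma` is the feature-space distance at which a VR's response reaches
    zero; by default it is set to the maximum pairwise centroid distance,
    giving large, overlapping receptive fields.
    """

    centroids: np.ndarray  # (n_vr, d)
    sigma: float
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=np.float64))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_vr(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]


@dataclass
class RatePattern:
    """Per-VR-channel firing rates in Hz."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


@dataclass
class SpikeTrainSet:
    """Events (neuron index, spike time in ms) over a fixed horizon.

    Events are sorted by time, then neuron index; under clock-driven
    generation all times are integer multiples of `dt`.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if self.times.size and (self.times.min() < 0 or self.times.max() >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        order = np.lexsort((self.neuron_ids, self.times))
        self.neuron_ids = self.neuron_ids[order]
        self.times = self.times[order]

    @property
    def n_events(self) -> int:
        return self.times.size

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def window(self, start: float, end: float) -> "SpikeTrainSet":
        """Events in [start, end), re-referenced to start."""
        lo = np.searchsorted(self.times, start, side="left")
        hi = np.searchsorted(self.times, end, side="left")
        return SpikeTrainSet(self.neuron_ids[lo:hi], self.times[lo:hi] - start,
                             duration=end - start, dt=self.dt, n_neurons=self.n_neurons)

    def shifted(self, offset: float, duration: float) -> "SpikeTrainSet":
        return SpikeTrainSet(self.neuron_ids, self.times + offset,
                             duration=duration, dt=self.dt, n_neurons=self.n_neurons)


def concatenate_trains(trains: list[SpikeTrainSet], offsets: list[float],
                       duration: float, dt: float, n_neurons: int) -> SpikeTrainSet:
    """Merge per-sample trains onto one timeline at the given offsets."""
    ids = [t.neuron_ids for t in trains]
    ts = [t.times + off for t, off in zip(trains, offsets)]
    return SpikeTrainSet(
        np.concatenate(ids) if ids else np.empty(0, dtype=np.int64),
        np.concatenate(ts) if ts else np.empty(0),
        duration=duration, dt=dt, n_neurons=n_neurons)


@dataclass
class EncoderConfig:
    """How VR responses become spike trains.

    f_min/f_max bound the rate code (Hz); generator selects Poisson
    (per-step Bernoulli) or Gamma-renewal input processes, the latter with
    `gamma_order` controlling regularity (ISI CV = 1/sqrt(order)).
    """

    f_min: float = 0.0
    f_max: float = 70.0
    generator: str = "poisson"
    gamma_order: int = 5
    sigma: float | None = None  # override the fitted VRSet cutoff radius

    def __post_init__(self) -> None:
        if not 0 <= self.f_min < self.f_max:
            raise ValueError("need 0 <= f_min < f_max")
        if self.generator not in ("poisson", "gamma"):
            raise ValueError("generator must be 'poisson' or 'gamma'")
        if self.gamma_order < 1:
            raise ValueError("gamma_order must be >= 1")


def fit_neural_gas(samples: np.ndarray, n_vr: int, iterations: int | None = None,
                   eps_schedule: tuple[float, float] = (0.5, 0.01),
                   lambda_schedule: tuple[float, float] | None = None,
                   seed: int = 0, metric: str = "euclidean",
                   sigma: float | None = None) -> VRSet:
    """Place `n_vr` VR centroids on the samples with the neural gas algorithm.

    Per presented sample all centroids are ranked by distance and centroid k
    moves by eps(t) * exp(-rank_k / lambda(t)) * (x - w_k); eps and lambda
    decay exponentially from their start to end values over `iterations`
    presentations (default 20 per training sample). Centroids initialize as
    randomly drawn training samples; presentations draw samples with
    replacement. Deterministic for a fixed seed.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ValueError("samples must be a nonempty (n, d) matrix")
    if np.any(~np.isfinite(samples)):
        raise ValueError("samples contain NaN or inf")
    if n_vr < 1:
        raise ValueError("n_vr must be >= 1")
    n = samples.shape[0]
    if n_vr > n:
        warnings.warn(f"n_vr={n_vr} exceeds sample count {n}; "
                      "duplicate initializations allowed", stacklevel=2)
    if iterations is None:
        iterations = 20 * n
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    eps0, eps1 = eps_schedule
    if lambda_schedule is None:
        lambda_schedule = (max(n_vr / 2.0, 0.01), 0.01)
    lam0, lam1 = lambda_schedule
    if min(eps0, eps1, lam0, lam1) <= 0 or eps0 < eps1 or lam0 < lam1:
        raise ValueError("schedules must be positive with start >= end")

    rng = np.random.default_rng(seed)
    centroids = samples[rng.integers(0, n, size=n_vr)].copy()
    for t in range(iterations):
        frac = t / max(iterations - 1, 1)
        eps_t = eps0 * (eps1 / eps0) ** frac
        lam_t = lam0 * (lam1 / lam0) ** frac
        x = samples[rng.integers(0, n)]
        d = _dists(x[None, :], centroids, metric)[0]
        ranks = np.empty(n_vr, dtype=np.float64)
        ranks[np.argsort(d, kind="stable")] = np.arange(n_vr)
        centroids += (eps_t * np.exp(-ranks / lam_t))[:, None] * (x - centroids)

    if sigma is None:
        sigma = float(pdist(centroids, _METRICS[metric]).max()) if n_vr > 1 else 1.0
        if sigma <= 0:
            sigma = 1.0
    return VRSet(centroids=centroids, sigma=float(sigma), metric=metric)


def _dists(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    return cdist(x, centroids, _METRICS[metric])


def vr_responses(samples: np.ndarray, vrs: VRSet, sigma: float | None = None) -> np.ndarray:
    """Cone-shaped radial basis response max(0, 1 - d/sigma) of every VR to
    every sample; shape (n_samples, n_vr), values in [0, 1]."""
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    if samples.shape[1] != vrs.n_features:
        raise ValueError(
            f"sample dimensionality {samples.shape[1]} != VR dimensionality {vrs.n_features}")
    s = vrs.sigma if sigma is None else sigma
    d = _dists(samples, vrs.centroids, vrs.metric)
    return np.maximum(0.0, 1.0 - d / s)


def vr_response(sample: np.ndarray, vrs: VRSet, sigma: float | None = None) -> np.ndarray:
    """Response vector of all VRs to a single sample."""
    return vr_responses(np.asarray(sample)[None, :], vrs, sigma=sigma)[0]


def responses_to_rates(responses: np.ndarray, f_min: float, f_max: float) -> RatePattern:
    """Affine map of responses in [0, 1] onto firing rates [f_min, f_max] Hz."""
    responses = np.asarray(responses, dtype=np.float64)
    if not 0 <= f_min < f_max:
        raise ValueError("need 0 <= f_min < f_max")
    if np.any(responses < 0) or np.any(responses > 1):
        raise ValueError("responses must lie in [0, 1]")
    return RatePattern(rates=f_min + responses * (f_max - f_min))


def gen_poisson_trains(pattern: RatePattern, cluster_size: int, duration: float,
                       dt: float, seed: int) -> SpikeTrainSet:
    """Clock-driven Poisson spike trains: each of the `cluster_size` neurons
    of VR channel i fires independently with probability rate_i * dt / 1000
    per step. Neuron indices are contiguous blocks of `cluster_size` per
    channel."""
    rates = pattern.rates
    p = rates * dt / 1000.0
    if np.any(p >= 1.0):
        raise ValueError("rate * dt / 1000 must be < 1; reduce dt")
    n_ch = rates.size
    n_neurons = n_ch * cluster_size
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    p_per_neuron = np.repeat(p, cluster_size)
    # chunk the (steps x neurons) Bernoulli draw to bound memory on long horizons
    ids_parts, t_parts = [], []
    chunk = max(1, int(4_000_000 / max(n_neurons, 1)))
    for s0 in range(0, n_steps, chunk):
        s1 = min(s0 + chunk, n_steps)
        hits = rng.random((s1 - s0, n_neurons)) < p_per_neuron
        step_idx, nid = np.nonzero(hits)
        ids_parts.append(nid)
        t_parts.append((step_idx + s0) * dt)
    ids = np.concatenate(ids_parts) if ids_parts else np.empty(0, dtype=np.int64)
    ts = np.concatenate(t_parts) if t_parts else np.empty(0)
    return SpikeTrainSet(ids, ts, duration=n_steps * dt, dt=dt, n_neurons=n_neurons)


def gen_gamma_trains(pattern: RatePattern, order: int, cluster_size: int,
                     duration: float, seed: int, dt: float = 1.0) -> SpikeTrainSet:
    """Gamma-renewal spike trains of the given order (shape), rate-preserving.

    Inter-spike intervals are Gamma(shape=order, mean=1000/rate) ms,
    accumulated from a random initial phase and snapped to the `dt` grid.
    Higher order gives more regular firing (ISI CV = 1/sqrt(order)) and a
    lower spike-count variability than a Poisson process of equal rate.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    rates = pattern.rates
    n_ch = rates.size
    n_neurons = n_ch * cluster_size
    rng = np.random.default_rng(seed)
    ids_parts, t_parts = [], []
    for ch in range(n_ch):
        rate = rates[ch]
        if rate <= 0:
            continue
        mean_isi = 1000.0 / rate
        scale = mean_isi / order
        n_exp = max(int(duration / mean_isi * 1.5) + 10, 20)
        for k in range(cluster_size):
            nid = ch * cluster_size + k
            isis = rng.gamma(order, scale, size=n_exp)
            t = np.cumsum(isis)
            t += (rng.random() - 1.0) * isis[0]  # random phase of the first interval
            while t[-1] < duration:
                extra = rng.gamma(order, scale, size=n_exp)
                t = np.concatenate([t, t[-1] + np.cumsum(extra)])
            t = t[(t >= 0) & (t < duration)]
            t = np.round(t / dt) * dt
            t = t[t < duration]
            if t.size:
                t = np.unique(t)  # grid snapping may collide very short ISIs
                ids_parts.append(np.full(t.size, nid, dtype=np.int64))
                t_parts.append(t)
    ids = np.concatenate(ids_parts) if ids_parts else np.empty(0, dtype=np.int64)
    ts = np.concatenate(t_parts) if t_parts else np.empty(0)
    return SpikeTrainSet(ids, ts, duration=duration, dt=dt, n_neurons=n_neurons)


# ---------------------------------------------------------------------------
# plain-text serialization


def save_spike_trains(path: str, trains: SpikeTrainSet) -> None:
    """Two-column delimited text (neuron_id, time_ms), time-sorted; doubles
    as the raster-export format."""
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={trains.duration} dt_ms={trains.dt} "
                 f"n_neurons={trains.n_neurons}\n")
        for nid, t in zip(trains.neuron_ids, trains.times):
            fh.write(f"{nid}\t{t:.6f}\n")


def load_spike_trains(path: str) -> SpikeTrainSet:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        data = np.loadtxt(fh, ndmin=2)
    ids = data[:, 0].astype(np.int64) if data.size else np.empty(0, dtype=np.int64)
    ts = data[:, 1] if data.size else np.empty(0)
    return SpikeTrainSet(ids, ts, duration=float(meta["duration_ms"]),
                         dt=float(meta["dt_ms"]), n_neurons=int(meta["n_neurons"]))


def save_vrset(path: str, vrs: VRSet) -> None:
    """One centroid per row, preceded by a small header (sigma, metric)."""
    with open(path, "w") as fh:
        fh.write(f"# sigma={vrs.sigma!r} metric={vrs.metric}\n")
        np.savetxt(fh, vrs.centroids, delimiter="\t")


def load_vrset(path: str) -> VRSet:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        centroids = np.loadtxt(fh, ndmin=2)
    return VRSet(centroids=centroids, sigma=float(meta["sigma"]), metric=meta["metric"])
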
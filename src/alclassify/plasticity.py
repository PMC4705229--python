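"""Supervised plasticity for the PN->AN readout.

Two schemes are implemented, mirroring the two control flows the model was
deployed with:

* **Symmetric STDP with a teaching signal** — one continuous simulation
  over the whole training schedule (120 ms presentations separated by
  20 ms silences by default). Weights start at zero; a Poisson teaching
  source forces activity in the correct class cluster while a sample is
  presented, and any pre/post spike pair inside a narrow window adds the
  same positive increment regardless of order (simple Hebbian
  association). Nearest-neighbor pairing bounds the per-spike update.

* **Per-sample perceptron rule** — the simulation is restarted from rest
  for each sample (500 ms presentations by default); at the end of a
  presentation the winner is read out and, on error, cluster-level weights
  to the true class are potentiated and to the predicted winner depressed,
  proportionally to normalized PN-cluster activity; the full weight matrix
  is then replaced atomically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import Dataset
from .encoding import (EncoderConfig, RatePattern, SpikeTrainSet, VRSet,
                       concatenate_trains, gen_gamma_trains,
                       gen_poisson_trains, responses_to_rates, vr_responses)
from .network import (Topology, cluster_spike_counts,
                      expand_cluster_weights, simulate)

__all__ = [
    "STDPParams",
    "PerceptronParams",
    "TeachingSchedule",
    "stdp_delta",
    "build_teaching_schedule",
    "train_stdp",
    "perceptron_update",
    "train_perceptron",
    "derive_seed",
]


@dataclass(frozen=True)
class STDPParams:
    """Symmetric STDP: the same positive increment for pre-before-post and
    post-before-pre pairings inside the window, zero outside."""

    a_plus: float = 0.00125   # weight increment per pairing (= w_max / 200)
    tau_window: float = 10.0  # ms, pairing half-window
    w_max: float = 0.25

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.tau_window <= 0 or self.w_max <= 0:
            raise ValueError("STDP parameters must be positive")


@dataclass(frozen=True)
class PerceptronParams:
    """Error-driven cluster-level perceptron rule."""

    learning_rate: float = 0.02  # weight units per unit normalized PN activity
    w_max: float = 0.25
    init: str = "random"         # "zero" or "random"
    init_scale: float = 0.1      # random init uniform on [0, init_scale * w_max]

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.init not in ("zero", "random"):
            raise ValueError("init must be 'zero' or 'random'")


@dataclass
class TeachingSchedule:
    """Teaching spikes targeting the correct AN cluster for each sample."""

    trains: SpikeTrainSet
    presentation_ms: float
    silence_ms: float
    teach_rate: float


def stdp_delta(delta_t: float | np.ndarray, p: STDPParams) -> float | np.ndarray:
    """Weight change for a pre/post spike pair separated by `delta_t` ms:
    `a_plus` anywhere inside the symmetric window, zero outside. Even in
    `delta_t` by construction."""
    inside = np.abs(delta_t) <= p.tau_window
    out = np.where(inside, p.a_plus, 0.0)
    return float(out) if np.isscalar(delta_t) else out


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic per-component seed derived from a master seed."""
    ss = np.random.SeedSequence([int(master) % (2 ** 31), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_teaching_schedule(labels, presentation_ms: float, silence_ms: float,
                            teach_rate: float, an_partition: list[np.ndarray],
                            seed: int, dt: float = 1.0,
                            class_index: dict[int, int] | None = None) -> TeachingSchedule:
    """Poisson teaching spikes at `teach_rate` Hz into every neuron of the
    correct AN cluster during each sample's presentation window; silence
    gaps contain no events."""
    if presentation_ms <= 0:
        raise ValueError("presentation_ms must be > 0")
    if silence_ms < 0:
        raise ValueError("silence_ms must be >= 0")
    labels = list(labels)
    n_classes = len(an_partition)
    n_neurons = int(max(idx.max() for idx in an_partition)) + 1 if an_partition else 0
    period = presentation_ms + silence_ms
    total = period * len(labels)
    rng_seeds = [derive_seed(seed, k) for k in range(len(labels))]
    parts, offs = [], []
    for k, lab in enumerate(labels):
        c = class_index[lab] if class_index is not None else int(lab)
        if not 0 <= c < n_classes:
            raise ValueError(f"label {lab} outside the class set")
        cluster = an_partition[c]
        if teach_rate > 0:
            pat = RatePattern(np.full(cluster.size, float(teach_rate)))
            seg = gen_poisson_trains(pat, cluster_size=1,
                                     duration=presentation_ms, dt=dt,
                                     seed=rng_seeds[k])
            # remap the contiguous channel ids onto the cluster's AN ids
            seg = SpikeTrainSet(cluster[seg.neuron_ids], seg.times,
                                duration=presentation_ms, dt=dt,
                                n_neurons=n_neurons)
            parts.append(seg)
            offs.append(k * period)
    trains = concatenate_trains(parts, offs, duration=total, dt=dt,
                                n_neurons=n_neurons)
    return TeachingSchedule(trains=trains, presentation_ms=presentation_ms,
                            silence_ms=silence_ms, teach_rate=teach_rate)


def _encode_sample(rates: np.ndarray, encoder: EncoderConfig, cluster_size: int,
                   duration: float, dt: float, seed: int) -> SpikeTrainSet:
    pat = RatePattern(rates)
    if encoder.generator == "gamma":
        return gen_gamma_trains(pat, encoder.gamma_order, cluster_size,
                                duration, seed=seed, dt=dt)
    return gen_poisson_trains(pat, cluster_size, duration, dt, seed=seed)


def train_stdp(topology: Topology, train_set: Dataset, vrs: VRSet,
               encoder: EncoderConfig, stdp: STDPParams,
               presentation_ms: float = 120.0, silence_ms: float = 20.0,
               teach_rate: float = 200.0, dt: float = 1.0,
               seed: int = 0) -> np.ndarray:
    """Hebbian association training: one continuous run over the full
    training schedule with teaching-forced AN activity. Weights start at
    zero and are clipped to [0, w_max] throughout; returns the final
    per-synapse PN->AN matrix."""
    rn_size = topology.pop("RN").cluster_size
    responses = vr_responses(train_set.samples, vrs, sigma=encoder.sigma)
    period = presentation_ms + silence_ms
    n = train_set.n_samples
    total = period * n

    parts, offs = [], []
    for k in range(n):
        rates = responses_to_rates(responses[k], encoder.f_min, encoder.f_max).rates
        seg = _encode_sample(rates, encoder, rn_size, presentation_ms, dt,
                             seed=derive_seed(seed, 1, k))
        parts.append(seg)
        offs.append(k * period)
    inputs = concatenate_trains(parts, offs, duration=total, dt=dt,
                                n_neurons=topology.pop("RN").size)

    class_index = {c: i for i, c in enumerate(train_set.class_set)}
    teaching = build_teaching_schedule(train_set.labels, presentation_ms,
                                       silence_ms, teach_rate,
                                       topology.an_partition(),
                                       seed=derive_seed(seed, 2), dt=dt,
                                       class_index=class_index)

    topology.set_plastic_weights(np.zeros_like(topology.plastic_projection.weights))
    simulate(topology, inputs, duration=total, dt=dt, record=("AN",),
             teaching=teaching.trains, stdp=stdp)
    return topology.plastic_projection.weights.copy()


def perceptron_update(cluster_w: np.ndarray, pn_counts: np.ndarray,
                      predicted: int | None, true_class: int,
                      p: PerceptronParams) -> np.ndarray:
    """Error-driven cluster-level update; returns a new matrix (the caller
    replaces the old one atomically, as on stepped-simulation platforms).

    On a correct prediction the matrix is unchanged. Otherwise weights from
    PN cluster i to the true class rise by learning_rate * a_i and to the
    predicted winner (if any) fall by the same amount, where
    a_i = pn_counts_i / max(pn_counts); the result is clipped to
    [0, w_max].
    """
    cluster_w = np.asarray(cluster_w, dtype=np.float64)
    pn_counts = np.asarray(pn_counts, dtype=np.float64)
    if np.any(pn_counts < 0):
        raise ValueError("pn_counts must be nonnegative")
    if predicted == true_class:
        return cluster_w
    peak = pn_counts.max()
    if peak == 0:
        warnings.warn("all-zero PN activity; perceptron update skipped", stacklevel=2)
        return cluster_w
    a = pn_counts / peak
    out = cluster_w.copy()
    out[:, true_class] += p.learning_rate * a
    if predicted is not None:
        out[:, predicted] -= p.learning_rate * a
    np.clip(out, 0.0, p.w_max, out=out)
    return out


def init_perceptron_weights(n_vr: int, n_classes: int, p: PerceptronParams,
                            seed: int) -> np.ndarray:
    if p.init == "zero":
        return np.zeros((n_vr, n_classes))
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, p.init_scale * p.w_max, size=(n_vr, n_classes))


def train_perceptron(topology: Topology, train_set: Dataset, vrs: VRSet,
                     encoder: EncoderConfig, p: PerceptronParams,
                     presentation_ms: float = 500.0, dt: float = 0.5,
                     seed: int = 0) -> np.ndarray:
    """One pass over the training set with per-sample restarts.

    Each sample is encoded and simulated from rest with the current
    weights; the winner is read from AN cluster spike counts with the same
    window-counting used at test time, the cluster-level matrix is updated
    on errors, and the per-synapse matrix is rebuilt. Returns the final
    cluster-level (n_vr x n_classes) matrix.
    """
    from .evaluate import classify_window  # local import to avoid a cycle
    rn_size = topology.pop("RN").cluster_size
    pn_size = topology.pop("PN").cluster_size
    an_size = topology.pop("AN").cluster_size
    responses = vr_responses(train_set.samples, vrs, sigma=encoder.sigma)
    class_index = {c: i for i, c in enumerate(train_set.class_set)}
    cluster_w = init_perceptron_weights(topology.n_vr, topology.n_classes, p,
                                        seed=derive_seed(seed, 3))
    pn_part = topology.pn_partition()
    an_part = topology.an_partition()
    for k in range(train_set.n_samples):
        rates = responses_to_rates(responses[k], encoder.f_min, encoder.f_max).rates
        inputs = _encode_sample(rates, encoder, rn_size, presentation_ms, dt,
                                seed=derive_seed(seed, 4, k))
        topology.set_plastic_weights(
            expand_cluster_weights(cluster_w, pn_size, an_size))
        rec = simulate(topology, inputs, duration=presentation_ms, dt=dt,
                       record=("PN", "AN"))
        predicted = classify_window(rec, (0.0, presentation_ms), an_part)
        pn_counts = cluster_spike_counts(rec.spikes["PN"], pn_part)
        cluster_w = perceptron_update(cluster_w, pn_counts, predicted,
                                      class_index[int(train_set.labels[k])], p)
    topology.set_plastic_weights(expand_cluster_weights(cluster_w, pn_size, an_size))
    return cluster_w
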
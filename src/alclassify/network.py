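"""Three-layer spiking network topology and clock-driven LIF simulation.

The network mirrors the insect antennal lobe: receptor neurons (RN, one
cluster per virtual receptor) relay stochastic rate-coded input to
projection neurons (PN), whose clusters inhibit each other laterally to
decorrelate and sparsen the code; PNs project all-to-all through plastic
synapses onto association neurons (AN), one cluster per class, where strong
mutual inhibition implements a winner-take-all decision.

Two presets are provided: `standard` replaces inhibitory interneurons with
direct inhibitory synapses between principal cells (the efficient
abstraction used on large digital platforms), while `spikey` keeps explicit
local-interneuron (LN) populations and the small cluster sizes (6 RN / 7 PN
/ 8 AN) of the analog system the model was also deployed on.

Neurons are leaky integrate-and-fire with exponential current-based
synapses, advanced by exponential-Euler updates (exact for piecewise
constant input) on a fixed timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import SpikeTrainSet

__all__ = [
    "NeuronParams",
    "NetworkParams",
    "Population",
    "Projection",
    "Topology",
    "SimRecord",
    "build_topology",
    "lif_step",
    "synapse_step",
    "simulate",
    "expand_cluster_weights",
    "cluster_spike_counts",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane parameters (conventional cortical-model defaults)."""

    tau_m: float = 20.0      # ms
    v_rest: float = -65.0    # mV
    v_thresh: float = -50.0  # mV
    v_reset: float = -70.0   # mV
    t_ref: float = 2.0       # ms
    r_m: float = 40.0        # MOhm

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError("need v_reset <= v_rest < v_thresh")
        if self.tau_m <= 0 or self.t_ref < 0:
            raise ValueError("need tau_m > 0 and t_ref >= 0")


@dataclass
class NetworkParams:
    """Synaptic weights (nA per spike, signed) and time constants.

    Lateral inhibition is expressed as two scalars: `an_inh_w` is much
    stronger than `pn_inh_w`, realizing a hard winner-take-all between AN
    class clusters versus a mild sparsening between PN clusters. Both are
    *budgets*: the per-synapse weight is the scalar divided by the number
    of competing (other) clusters, so the total lateral inhibition a
    neuron receives does not grow with network size and behavior is
    stable across the 10-200 VR range.
    """

    rn_pn_w: float = 4.0        # one-to-one excitatory relay
    pn_inh_w: float = -0.09     # PN cross-cluster sparsening budget (standard preset)
    an_inh_w: float = -0.4      # AN cross-cluster winner-take-all budget
    w_max: float = 0.25         # bound on plastic PN->AN weights
    teach_w: float = 6.0        # teaching-signal synapse onto AN
    tau_syn_exc: float = 5.0    # ms
    tau_syn_inh: float = 10.0   # ms
    delay_steps: int = 1
    density: float = 1.0        # connection density for non-plastic projections
    # spikey preset: explicit inhibitory interneurons mediate both stages
    ln_cluster_size: int = 6
    pn_ln_w: float = 1.0
    ln_pn_w: float = -0.1
    an_ln_w: float = 1.0
    ln_an_w: float = -0.6
    neuron_budget: int | None = None

    def __post_init__(self) -> None:
        if self.pn_inh_w > 0 or self.an_inh_w > 0 or self.ln_pn_w > 0 or self.ln_an_w > 0:
            raise ValueError("inhibitory weights must be <= 0")
        if min(self.rn_pn_w, self.teach_w, self.pn_ln_w, self.an_ln_w) < 0:
            raise ValueError("excitatory weights must be >= 0")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")


@dataclass
class Population:
    name: str
    size: int
    cluster_size: int
    kind: str = "lif"  # "lif" or "source"
    params: NeuronParams = field(default_factory=NeuronParams)

    @property
    def n_clusters(self) -> int:
        return self.size // self.cluster_size

    def cluster_slice(self, c: int) -> slice:
        return slice(c * self.cluster_size, (c + 1) * self.cluster_size)

    def partition(self) -> list[np.ndarray]:
        return [np.arange(c * self.cluster_size, (c + 1) * self.cluster_size)
                for c in range(self.n_clusters)]


@dataclass
class Projection:
    """Dense (n_source x n_target) signed weight matrix with one synaptic
    time constant and an integer conduction delay in timesteps."""

    source: str
    target: str
    weights: np.ndarray
    tau_syn: float
    delay_steps: int = 1
    plastic: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")


@dataclass
class Topology:
    populations: dict[str, Population]
    projections: list[Projection]
    n_vr: int
    n_classes: int
    preset: str
    teach_w: float = 6.0   # teaching-signal synapse strength onto AN (nA)
    teach_tau: float = 5.0  # ms

    def pop(self, name: str) -> Population:
        return self.populations[name]

    @property
    def plastic_projection(self) -> Projection:
        for proj in self.projections:
            if proj.plastic:
                return proj
        raise ValueError("topology has no plastic projection")

    def set_plastic_weights(self, weights: np.ndarray) -> None:
        proj = self.plastic_projection
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != proj.weights.shape:
            raise ValueError(f"weight shape {weights.shape} != {proj.weights.shape}")
        proj.weights = weights

    def an_partition(self) -> list[np.ndarray]:
        return self.pop("AN").partition()

    def pn_partition(self) -> list[np.ndarray]:
        return self.pop("PN").partition()


@dataclass
class SimRecord:
    """Recorded spikes per population (and optional membrane traces)."""

    spikes: dict[str, SpikeTrainSet]
    duration: float
    dt: float
    voltages: dict[str, np.ndarray] = field(default_factory=dict)


def _cross_cluster_matrix(n_src_clusters: int, src_size: int, tgt_size: int,
                          weight: float) -> np.ndarray:
    """All-to-all between distinct clusters, zero within the same cluster."""
    n = n_src_clusters
    w = np.full((n * src_size, n * tgt_size), weight)
    for c in range(n):
        w[c * src_size:(c + 1) * src_size, c * tgt_size:(c + 1) * tgt_size] = 0.0
    return w


def _apply_density(w: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    if density >= 1.0:
        return w
    mask = rng.random(w.shape) < density
    return w * mask


def build_topology(n_vr: int, n_classes: int, cluster_size: int = 30,
                   preset: str = "standard",
                   params: NetworkParams | None = None,
                   neuron_params: NeuronParams | None = None,
                   seed: int = 0) -> Topology:
    """Construct the three-layer topology.

    standard preset: RN->PN one-to-one between matching clusters
    (excitatory), direct PN->PN inhibition between distinct clusters,
    PN->AN all-to-all plastic (initialized to zero), strong AN->AN
    inhibition between distinct clusters.

    spikey preset: per-cluster LN populations mediate both inhibition
    stages (PN->LN->other PNs, AN->LN->other ANs); principal cluster sizes
    default to 6 RN / 7 PN / 8 AN.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_vr < n_classes:
        raise ValueError("n_vr must be >= n_classes")
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    params = params or NetworkParams()
    neuron_params = neuron_params or NeuronParams()
    rng = np.random.default_rng(seed)

    if preset == "standard":
        rn_size = pn_size = an_size = cluster_size
    elif preset == "spikey":
        rn_size, pn_size, an_size = 6, 7, 8
    else:
        raise ValueError(f"unknown preset {preset!r}")

    total = n_vr * (rn_size + pn_size) + n_classes * an_size
    if params.neuron_budget is not None and total > params.neuron_budget:
        import warnings
        warnings.warn(f"topology needs {total} neurons, budget {params.neuron_budget}",
                      stacklevel=2)

    pops = {
        "RN": Population("RN", n_vr * rn_size, rn_size, kind="source"),
        "PN": Population("PN", n_vr * pn_size, pn_size, params=neuron_params),
        "AN": Population("AN", n_classes * an_size, an_size, params=neuron_params),
    }
    projections: list[Projection] = []

    # RN -> PN: excitatory relay within matching clusters
    if rn_size == pn_size:
        rn_pn = np.kron(np.eye(n_vr), np.eye(rn_size)) * params.rn_pn_w
    else:
        # unequal cluster sizes: all-to-all within the matching cluster,
        # scaled to deliver the same total drive per target neuron
        block = np.full((rn_size, pn_size), params.rn_pn_w / rn_size)
        rn_pn = np.kron(np.eye(n_vr), block)
    projections.append(Projection("RN", "PN", _apply_density(rn_pn, params.density, rng),
                                  params.tau_syn_exc, params.delay_steps))

    # PN -> AN: all-to-all plastic, zero-initialized
    projections.append(Projection("PN", "AN",
                                  np.zeros((n_vr * pn_size, n_classes * an_size)),
                                  params.tau_syn_exc, params.delay_steps, plastic=True))

    if preset == "standard":
        pn_pn = _cross_cluster_matrix(n_vr, pn_size, pn_size,
                                      params.pn_inh_w / max(n_vr - 1, 1))
        projections.append(Projection("PN", "PN", _apply_density(pn_pn, params.density, rng),
                                      params.tau_syn_inh, params.delay_steps))
        an_an = _cross_cluster_matrix(n_classes, an_size, an_size,
                                      params.an_inh_w / max(n_classes - 1, 1))
        projections.append(Projection("AN", "AN", _apply_density(an_an, params.density, rng),
                                      params.tau_syn_inh, params.delay_steps))
    else:
        ln = params.ln_cluster_size
        pops["LN_PN"] = Population("LN_PN", n_vr * ln, ln, params=neuron_params)
        pops["LN_AN"] = Population("LN_AN", n_classes * ln, ln, params=neuron_params)
        # PN cluster drives its own LN cluster ...
        pn_ln = np.kron(np.eye(n_vr), np.full((pn_size, ln), params.pn_ln_w))
        projections.append(Projection("PN", "LN_PN", pn_ln,
                                      params.tau_syn_exc, params.delay_steps))
        # ... which inhibits all other PN clusters (same budget convention)
        ln_pn = _cross_cluster_matrix(n_vr, ln, pn_size,
                                      params.ln_pn_w / max(n_vr - 1, 1))
        projections.append(Projection("LN_PN", "PN", ln_pn,
                                      params.tau_syn_inh, params.delay_steps))
        an_ln = np.kron(np.eye(n_classes), np.full((an_size, ln), params.an_ln_w))
        projections.append(Projection("AN", "LN_AN", an_ln,
                                      params.tau_syn_exc, params.delay_steps))
        ln_an = _cross_cluster_matrix(n_classes, ln, an_size,
                                      params.ln_an_w / max(n_classes - 1, 1))
        projections.append(Projection("LN_AN", "AN", ln_an,
                                      params.tau_syn_inh, params.delay_steps))

    return Topology(populations=pops, projections=projections,
                    n_vr=n_vr, n_classes=n_classes, preset=preset,
                    teach_w=params.teach_w, teach_tau=params.tau_syn_exc)


def lif_step(v, refractory, i_syn, p: NeuronParams, dt: float):
    """One exponential-Euler LIF update (vectorized over arrays).

    Refractory neurons are held at v_reset while their timer runs down;
    otherwise the membrane relaxes toward v_rest + r_m * i_syn with time
    constant tau_m, and a threshold crossing emits a spike, resets the
    membrane and restarts the refractory timer.

    Returns (v_next, spiked, refractory_next).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.asarray(v, dtype=np.float64)
    refractory = np.asarray(refractory, dtype=np.float64)
    i_syn = np.asarray(i_syn, dtype=np.float64)
    alpha = np.exp(-dt / p.tau_m)
    target = p.v_rest + p.r_m * i_syn
    in_ref = refractory > 0
    v_next = np.where(in_ref, p.v_reset, target + (v - target) * alpha)
    spiked = (~in_ref) & (v_next >= p.v_thresh)
    v_next = np.where(spiked, p.v_reset, v_next)
    refractory_next = np.where(spiked, max(p.t_ref - dt, 0.0),
                               np.maximum(refractory - dt, 0.0))
    return v_next, spiked, refractory_next


def synapse_step(i_syn, incoming_weighted_spikes, tau_syn: float, dt: float):
    """Exponential current-based synapse: decay plus linear superposition of
    weighted incoming spikes."""
    if tau_syn <= 0:
        raise ValueError("tau_syn must be > 0")
    return np.asarray(i_syn) * np.exp(-dt / tau_syn) + incoming_weighted_spikes


def _events_by_step(trains: SpikeTrainSet | None, dt: float, n_steps: int,
                    n_expected: int, what: str):
    """Per-step spike index lookup from a sorted event list."""
    if trains is None or trains.n_events == 0:
        return None, None
    if trains.times.max() >= n_steps * dt + 1e-9:
        raise ValueError(f"{what} events extend beyond the simulation duration")
    if trains.neuron_ids.max() >= n_expected or trains.neuron_ids.min() < 0:
        raise ValueError(f"{what} neuron indices out of range")
    steps = np.floor(trains.times / dt + 0.5).astype(np.int64)
    steps = np.minimum(steps, n_steps - 1)
    bounds = np.searchsorted(steps, np.arange(n_steps + 1))
    return trains.neuron_ids, bounds


def simulate(topology: Topology, input_trains: SpikeTrainSet | None,
             duration: float, dt: float,
             record: tuple[str, ...] = ("AN",),
             teaching: SpikeTrainSet | None = None,
             stdp=None, record_v: tuple[str, ...] = ()) -> SimRecord:
    """Run the clock-driven simulation.

    `input_trains` are the RN source spikes; `teaching` spikes are delivered
    to AN neurons through a strong excitatory teaching synapse. If `stdp`
    (an STDPParams) is given, the plastic PN->AN projection is updated
    online with the symmetric nearest-neighbor pairing rule; the
    projection's weight matrix is modified in place.

    The simulation is fully deterministic given its inputs: all
    stochasticity lives in spike-train generation.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be > 0")
    n_steps = int(round(duration / dt))
    pops = topology.populations
    lif_names = [n for n, p in pops.items() if p.kind == "lif"]

    in_ids, in_bounds = _events_by_step(input_trains, dt, n_steps,
                                        pops["RN"].size, "input")
    te_ids, te_bounds = _events_by_step(teaching, dt, n_steps,
                                        pops["AN"].size, "teaching")

    projections = topology.projections
    # per-projection synaptic current on the target population
    currents = [np.zeros(pops[pr.target].size) for pr in projections]
    decays = [np.exp(-dt / pr.tau_syn) for pr in projections]
    # charge-matched spike delivery: the integrated current per spike of a
    # discretized exponential synapse is amp * dt / (1 - exp(-dt/tau)); scale
    # amplitudes so every timestep injects the charge of the 1 ms reference
    # grid, keeping population drive (and hence spike counts) dt-robust
    gains = [_charge_gain(dt, pr.tau_syn) for pr in projections]
    rings: list[list[np.ndarray]] = [[np.empty(0, dtype=np.int64)] * pr.delay_steps
                                     for pr in projections]
    teach_current = np.zeros(pops["AN"].size)
    teach_decay = np.exp(-dt / topology.teach_tau)
    teach_ring: list[np.ndarray] = [np.empty(0, dtype=np.int64)]
    teach_w = topology.teach_w
    teach_gain = _charge_gain(dt, topology.teach_tau)

    v = {n: np.full(pops[n].size, pops[n].params.v_rest) for n in lif_names}
    refrac = {n: np.zeros(pops[n].size) for n in lif_names}
    input_current = {n: np.zeros(pops[n].size) for n in lif_names}

    spike_log: dict[str, list[tuple[int, np.ndarray]]] = {n: [] for n in lif_names}
    v_log = {n: np.empty((n_steps, pops[n].size)) for n in record_v if n in lif_names}

    plastic = topology.plastic_projection if stdp is not None else None
    if plastic is not None:
        w = plastic.weights
        last_pre = np.full(pops["PN"].size, -np.inf)
        last_post = np.full(pops["AN"].size, -np.inf)

    spikes_now: dict[str, np.ndarray] = {n: np.empty(0, dtype=np.int64)
                                         for n in pops}
    for step in range(n_steps):
        t = step * dt
        # source spikes for this step
        spikes_now["RN"] = (in_ids[in_bounds[step]:in_bounds[step + 1]]
                            if in_ids is not None else _EMPTY)
        teach_now = (te_ids[te_bounds[step]:te_bounds[step + 1]]
                     if te_ids is not None else _EMPTY)

        # advance synaptic currents: decay then deliver delayed spikes
        for name in lif_names:
            input_current[name].fill(0.0)
        for k, pr in enumerate(projections):
            cur = currents[k]
            cur *= decays[k]
            ring = rings[k]
            arriving = ring.pop(0)
            if arriving.size:
                cur += gains[k] * pr.weights[arriving].sum(axis=0)
            input_current[pr.target] += cur
        teach_current *= teach_decay
        arriving_teach = teach_ring.pop(0)
        if arriving_teach.size:
            np.add.at(teach_current, arriving_teach, teach_gain * teach_w)
        input_current["AN"] += teach_current

        # membrane update
        for name in lif_names:
            p = pops[name].params
            v[name], spiked, refrac[name] = lif_step(
                v[name], refrac[name], input_current[name], p, dt)
            idx = np.flatnonzero(spiked)
            spikes_now[name] = idx
            if idx.size:
                spike_log[name].append((step, idx))
            if name in v_log:
                v_log[name][step] = v[name]

        # symmetric nearest-neighbor STDP on the plastic projection
        if plastic is not None:
            pn_idx = spikes_now["PN"]
            an_idx = spikes_now["AN"]
            if pn_idx.size:
                # pair new PN spikes with the most recent earlier AN spikes
                post_mask = np.flatnonzero(t - last_post <= stdp.tau_window)
                if post_mask.size:
                    w[np.ix_(pn_idx, post_mask)] += stdp.a_plus
                last_pre[pn_idx] = t
            if an_idx.size:
                # pair new AN spikes with recent PN spikes (incl. simultaneous)
                pre_mask = np.flatnonzero(t - last_pre <= stdp.tau_window)
                if pre_mask.size:
                    w[np.ix_(pre_mask, an_idx)] += stdp.a_plus
                last_post[an_idx] = t
            if pn_idx.size or an_idx.size:
                np.clip(w, 0.0, stdp.w_max, out=w)

        # queue this step's spikes for delayed delivery
        for k, pr in enumerate(projections):
            rings[k].append(spikes_now[pr.source])
        teach_ring.append(teach_now)

    spikes: dict[str, SpikeTrainSet] = {}
    if input_trains is not None and "RN" in record:
        spikes["RN"] = input_trains
    for name in lif_names:
        if record and name not in record:
            continue
        log = spike_log[name]
        if log:
            ids = np.concatenate([idx for _, idx in log])
            ts = np.concatenate([np.full(idx.size, s * dt) for s, idx in log])
        else:
            ids, ts = np.empty(0, dtype=np.int64), np.empty(0)
        spikes[name] = SpikeTrainSet(ids, ts, duration=n_steps * dt, dt=dt,
                                     n_neurons=pops[name].size)
    return SimRecord(spikes=spikes, duration=n_steps * dt, dt=dt, voltages=v_log)


_EMPTY = np.empty(0, dtype=np.int64)

_REFERENCE_DT = 1.0  # ms; amplitudes are specified on this grid


def _charge_gain(dt: float, tau_syn: float) -> float:
    """Amplitude factor making the injected charge per spike equal to that
    of the 1 ms reference grid (identity at dt = 1 ms)."""
    def charge(step: float) -> float:
        return step / (1.0 - np.exp(-step / tau_syn))
    return charge(_REFERENCE_DT) / charge(dt)


def expand_cluster_weights(cluster_w: np.ndarray, pn_cluster_size: int,
                           an_cluster_size: int) -> np.ndarray:
    """Broadcast an (n_vr x n_classes) cluster-level weight matrix to
    per-synapse granularity."""
    return np.kron(np.asarray(cluster_w, dtype=np.float64),
                   np.ones((pn_cluster_size, an_cluster_size)))


def cluster_spike_counts(trains: SpikeTrainSet, partition: list[np.ndarray]) -> np.ndarray:
    """Total spike count per cluster of the given partition."""
    counts = trains.counts()
    return np.array([counts[idx].sum() for idx in partition], dtype=np.int64)
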
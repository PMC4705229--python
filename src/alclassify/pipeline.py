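"""End-to-end train/test orchestration and scaling experiments.

The canonical pipeline: fit virtual receptors on the training split alone,
encode samples as rate-coded stochastic spike trains, train the PN->AN
readout with the selected plasticity scheme, freeze the weights, run a
single pass over the test set, and score the winner-take-all decisions.

All randomness derives from one master seed; a run with the same config
and seed reproduces weights and results bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import Dataset
from .encoding import (EncoderConfig, VRSet, concatenate_trains,
                       fit_neural_gas, responses_to_rates, save_vrset,
                       vr_responses)
from .evaluate import EvalResult, classify_window, score
from .network import (NetworkParams, NeuronParams, Topology, build_topology,
                      expand_cluster_weights, simulate)
from .plasticity import (PerceptronParams, STDPParams, _encode_sample,
                         derive_seed, train_perceptron, train_stdp)

__all__ = [
    "ClassifierConfig",
    "run_experiment",
    "train_stage",
    "test_stage",
    "fit_vrs",
    "scaling_grid",
    "save_weights",
    "load_weights",
]

_MODE_DEFAULTS = {
    # mode: (dt_ms, presentation_ms, silence_ms, weight init)
    "stdp": (1.0, 120.0, 20.0, "zero"),
    "perceptron": (0.5, 500.0, 0.0, "random"),
}


def _build_nested(cls, data: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {what}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class ClassifierConfig:
    """Everything needed to reproduce a train->test run.

    Mode-consistent defaults: stdp -> 1 ms timestep, 120 ms presentations
    with 20 ms silences and zero weight init; perceptron -> 0.5 ms
    timestep, 500 ms presentations, no silence, seeded random init.
    Explicit values override the mode defaults.
    """

    n_vr: int = 10
    cluster_size: int = 30
    preset: str = "standard"
    mode: str = "perceptron"
    dt: float | None = None
    presentation_ms: float | None = None
    silence_ms: float | None = None
    teach_rate: float = 200.0
    seed: int = 0
    allowed_classes: list[int] | None = None
    max_per_class: int = 1000
    neural_gas_iters: int | None = None  # default 20 per training sample
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    perceptron: PerceptronParams = field(default_factory=PerceptronParams)

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEFAULTS:
            raise ValueError("mode must be 'stdp' or 'perceptron'")
        if self.preset not in ("standard", "spikey"):
            raise ValueError("preset must be 'standard' or 'spikey'")
        dt0, pres0, sil0, init0 = _MODE_DEFAULTS[self.mode]
        if self.dt is None:
            self.dt = dt0
        if self.dt not in (0.1, 0.5, 1.0):
            raise ValueError("dt must be one of 0.1, 0.5, 1.0 ms")
        if self.presentation_ms is None:
            self.presentation_ms = pres0
        if self.silence_ms is None:
            self.silence_ms = sil0
        if self.presentation_ms <= 0 or self.silence_ms < 0:
            raise ValueError("presentation_ms > 0 and silence_ms >= 0 required")
        # default learning rate scales inversely with the VR count so the
        # total weight change per error (~ lr * sum of normalized cluster
        # activities) stays commensurate with w_max at any network size
        if self.perceptron == PerceptronParams():
            self.perceptron = dataclasses.replace(
                self.perceptron, learning_rate=0.2 / self.n_vr)

    # -- plain-text (YAML) round-trip ------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ClassifierConfig":
        data = dict(data)
        nested = {"encoder": EncoderConfig, "network": NetworkParams,
                  "neuron": NeuronParams, "stdp": STDPParams,
                  "perceptron": PerceptronParams}
        for key, sub in nested.items():
            if key in data and isinstance(data[key], dict):
                data[key] = _build_nested(sub, data[key], key)
        return _build_nested(cls, data, "config")

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "ClassifierConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def save_weights(path: str, weights: np.ndarray, meta: dict | None = None) -> None:
    """Delimited-text weight matrix with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta or {}, sort_keys=True)}\n")
        np.savetxt(fh, np.atleast_2d(weights), delimiter="\t")


def load_weights(path: str) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = json.loads(header) if header else {}
        w = np.loadtxt(fh, ndmin=2)
    return w, meta


def weights_digest(weights: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(weights).tobytes()).hexdigest()


def fit_vrs(config: ClassifierConfig, train: Dataset) -> VRSet:
    """Neural gas fit on the training split alone."""
    return fit_neural_gas(train.samples, config.n_vr,
                          iterations=config.neural_gas_iters,
                          seed=derive_seed(config.seed, 10),
                          sigma=config.encoder.sigma)


def _test_pass(config: ClassifierConfig, topology: Topology, vrs: VRSet,
               test: Dataset) -> list[int | None]:
    """Single frozen-weights pass over the test set.

    In stdp mode the whole test set runs as one continuous simulation (the
    extended-run control flow); in perceptron mode each sample restarts
    from rest (the stepped control flow). Counting windows align exactly
    with presentation windows; silences are excluded.
    """
    enc = config.encoder
    rn_size = topology.pop("RN").cluster_size
    an_part = topology.an_partition()
    responses = vr_responses(test.samples, vrs, sigma=enc.sigma)
    pres, sil, dt = config.presentation_ms, config.silence_ms, config.dt
    predictions: list[int | None] = []
    if config.mode == "stdp":
        period = pres + sil
        total = period * test.n_samples
        parts, offs = [], []
        for k in range(test.n_samples):
            rates = responses_to_rates(responses[k], enc.f_min, enc.f_max).rates
            parts.append(_encode_sample(rates, enc, rn_size, pres, dt,
                                        seed=derive_seed(config.seed, 20, k)))
            offs.append(k * period)
        inputs = concatenate_trains(parts, offs, duration=total, dt=dt,
                                    n_neurons=topology.pop("RN").size)
        rec = simulate(topology, inputs, duration=total, dt=dt, record=("AN",))
        for k in range(test.n_samples):
            start = k * period
            predictions.append(classify_window(rec, (start, start + pres), an_part))
    else:
        for k in range(test.n_samples):
            rates = responses_to_rates(responses[k], enc.f_min, enc.f_max).rates
            inputs = _encode_sample(rates, enc, rn_size, pres, dt,
                                    seed=derive_seed(config.seed, 20, k))
            rec = simulate(topology, inputs, duration=pres, dt=dt, record=("AN",))
            predictions.append(classify_window(rec, (0.0, pres), an_part))
    return predictions


def train_stage(config: ClassifierConfig, train: Dataset,
                vrs: VRSet | None = None) -> tuple[np.ndarray, np.ndarray | None, VRSet, Topology]:
    """Fit VRs (training data only, unless a pre-fitted set is supplied) and
    train the PN->AN readout; returns (per-synapse weights, cluster-level
    weights or None, VR set, topology)."""
    if vrs is None:
        vrs = fit_vrs(config, train)
    topology = build_topology(config.n_vr, train.n_classes, config.cluster_size,
                              preset=config.preset, params=config.network,
                              neuron_params=config.neuron,
                              seed=derive_seed(config.seed, 11))
    if config.mode == "stdp":
        weights = train_stdp(topology, train, vrs, config.encoder, config.stdp,
                             presentation_ms=config.presentation_ms,
                             silence_ms=config.silence_ms,
                             teach_rate=config.teach_rate, dt=config.dt,
                             seed=config.seed)
        cluster_w = None
    else:
        cluster_w = train_perceptron(topology, train, vrs, config.encoder,
                                     config.perceptron,
                                     presentation_ms=config.presentation_ms,
                                     dt=config.dt, seed=config.seed)
        weights = topology.plastic_projection.weights.copy()
    return weights, cluster_w, vrs, topology


def test_stage(config: ClassifierConfig, test: Dataset, vrs: VRSet,
               weights: np.ndarray, class_set: tuple[int, ...],
               topology: Topology | None = None) -> EvalResult:
    """Single-pass scoring of the test set with frozen weights."""
    if topology is None:
        topology = build_topology(config.n_vr, len(class_set),
                                  config.cluster_size, preset=config.preset,
                                  params=config.network,
                                  neuron_params=config.neuron,
                                  seed=derive_seed(config.seed, 11))
    topology.set_plastic_weights(np.asarray(weights, dtype=np.float64).copy())
    digest_before = weights_digest(topology.plastic_projection.weights)
    predictions = _test_pass(config, topology, vrs, test)
    digest_after = weights_digest(topology.plastic_projection.weights)
    assert digest_before == digest_after, "test pass mutated frozen weights"
    class_index = {c: i for i, c in enumerate(class_set)}
    return score(predictions, [class_index[int(l)] for l in test.labels],
                 class_set=tuple(range(len(class_set))))


def run_experiment(config: ClassifierConfig, train: Dataset, test: Dataset,
                   out_dir: str | None = None,
                   vrs: VRSet | None = None) -> tuple[EvalResult, dict]:
    """Full pipeline: fit VRs (training data only) -> encode -> train ->
    freeze weights -> single test pass -> score.

    Returns the evaluation plus an artifact dict (weights, VR set, config,
    stage timings); with `out_dir` the artifacts are also written to disk.
    """
    t0 = time.perf_counter()
    weights, cluster_w, vrs, topology = train_stage(config, train, vrs=vrs)
    t_train = time.perf_counter()
    result = test_stage(config, test, vrs, weights, tuple(train.class_set),
                        topology=topology)
    t_test = time.perf_counter()
    digest_before = weights_digest(weights)
    artifacts = {
        "weights": weights,
        "cluster_weights": cluster_w,
        "vrs": vrs,
        "config": config,
        "weights_sha256": digest_before,
        "timing_s": {"train": t_train - t0, "test": t_test - t_train},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"mode": config.mode, "seed": config.seed,
                "n_vr": config.n_vr, "sha256": digest_before}
        save_weights(out / "weights.tsv", weights, meta)
        save_vrset(out / "vrset.tsv", vrs)
        config.save(out / "config.yaml")
        with open(out / "result.txt", "w") as fh:
            fh.write(result.summary() + "\n")
        with open(out / "log.json", "w") as fh:
            json.dump({"timing_s": artifacts["timing_s"],
                       "accuracy": result.accuracy,
                       "undecided": result.undecided_count}, fh, indent=2)
    return result, artifacts


def scaling_grid(base_config: ClassifierConfig, vr_list: list[int],
                 class_sets: list[list[int]], train: Dataset, test: Dataset,
                 out_path: str | None = None) -> pd.DataFrame:
    """One run per (n_vr, class set) cell, in the spirit of the VR sweep.

    For each cell the train/test splits are restricted to the allowed
    classes, the VR set is fitted once per (n_vr, class set) and reused
    across learning modes if the caller re-runs with another mode.
    Infeasible cells (n_vr below the class count) are skipped with a
    logged reason. Returns a long-format results table.
    """
    from .datasets import build_subset
    rows = []
    for class_set in class_sets:
        sub_train = build_subset(train, class_set, base_config.max_per_class)
        sub_test = build_subset(test, class_set, base_config.max_per_class)
        for n_vr in vr_list:
            if n_vr < len(class_set):
                rows.append({"n_vr": n_vr, "classes": str(class_set),
                             "accuracy": np.nan, "undecided": np.nan,
                             "n_test": sub_test.n_samples,
                             "skipped": "n_vr below class count"})
                continue
            cfg = dataclasses.replace(base_config, n_vr=n_vr)
            result, _ = run_experiment(cfg, sub_train, sub_test)
            rows.append({"n_vr": n_vr, "classes": str(class_set),
                         "accuracy": result.accuracy,
                         "undecided": result.undecided_count,
                         "n_test": sub_test.n_samples, "skipped": ""})
    table = pd.DataFrame(rows, columns=["n_vr", "classes", "accuracy",
                                        "undecided", "n_test", "skipped"])
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table
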
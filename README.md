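# alclassify

A spiking neural-network classifier for multivariate real-valued data,
modeled on the insect antennal lobe — the olfactory circuit that turns
broadly tuned receptor responses into a sparse, decorrelated code and
routes it to a decision stage. The package is a portable, single-machine
implementation of a network design originally deployed on neuromorphic
hardware, intended for researchers who want to study rate-coded spiking
classification, supervised spike-timing plasticity, and winner-take-all
decision circuits without any special hardware.

## The model in brief

* **Encoding.** A sample `x ∈ [0,1]^d` is projected onto `N_VR` *virtual
  receptors* — points `w_i` placed by the neural gas algorithm on the
  training data — through cone-shaped radial basis functions
  `r_i = max(0, 1 − ‖x − w_i‖/σ)`. Responses become firing rates
  `f_i = f_min + r_i(f_max − f_min)` that drive clusters of stochastic
  receptor neurons (Poisson or Gamma-renewal spike trains).
* **Network.** Receptor neurons (RN) excite projection neurons (PN)
  one-to-one per cluster; PN clusters inhibit each other laterally
  (sparsening); PNs project through plastic all-to-all synapses onto
  association neurons (AN), one cluster per class, where strong lateral
  inhibition implements a winner-take-all. Neurons are leaky
  integrate-and-fire with exponential current synapses, simulated
  clock-driven at 0.5–1 ms timesteps.
* **Learning.** Two supervised schemes: (1) *symmetric STDP with a
  teaching signal* — one continuous run, zero-initialized weights, a
  teaching spike source forces the correct AN cluster, and closely paired
  PN/AN spikes potentiate their synapse regardless of order; (2) a
  *per-sample perceptron rule* — each presentation restarts from rest,
  and on errors cluster-level weights move by `±η·a_i` with `a_i` the
  normalized PN-cluster spike count.
* **Decision.** The class whose AN cluster spikes most during the
  presentation window wins.

## Worked example

```python
from alclassify import ClassifierConfig, Dataset, make_synthetic, run_experiment

ds = make_synthetic(k_classes=2, dim=10, n_per_class=60,
                    separation=0.8, noise_sd=0.05, seed=1)
train = Dataset(ds.samples[:60], ds.labels[:60])
test = Dataset(ds.samples[60:], ds.labels[60:])

config = ClassifierConfig(mode="perceptron", n_vr=10, cluster_size=30, seed=5)
result, artifacts = run_experiment(config, train, test)
print(f"accuracy {result.accuracy:.3f}, undecided {result.undecided_count}")
print(result.confusion)
```

prints

```
accuracy 1.000, undecided 0
[[30  0]
 [ 0 30]]
```

i.e., all 60 held-out samples are classified correctly (rows are true
classes, columns predicted ones) and every presentation produced at least
one output spike. The `artifacts` dict carries the trained 300×60 PN→AN
weight matrix, the fitted VR set and per-stage timings. The
`examples/` directory holds one short narrative script per capability
(VR fitting, spike statistics, the LIF f–I curve, STDP association,
perceptron classification, the small-population preset with explicit
inhibitory interneurons).

A thin CLI wraps the same pipeline:

```bash
alclassify synth --classes 2 --dim 10 --n-per-class 100 --out train.tsv
alclassify run --train train.tsv --test test.tsv --vrs 10 --mode perceptron --out results/
```

## Data formats

MNIST-style IDX image/label pairs (`load_idx`, pixels scaled by 1/255),
delimited-text tables with a label column (`load_table`, min–max scaling
fitted on the training split), and a synthetic Gaussian-cluster generator
(`make_synthetic`) so the full pipeline is testable without downloads.
Spike rasters, VR sets, weight matrices and configs all serialize to
plain text.

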
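# Methods

## The model

`alclassify` implements a generic multivariate classifier built from a
spiking neural-network abstraction of the insect antennal lobe. The
processing chain is:

1. **Virtual receptors (VRs).** Real-valued samples `x ∈ [0,1]^d` are
   encoded by `N_VR` receptor points `w_i` placed in feature space by the
   neural gas vector-quantization algorithm, fitted on training data only.
   Each VR responds through a cone-shaped radial basis function

       r_i(x) = max(0, 1 − d(x, w_i) / σ),

   a linear cone cut off at distance σ. The metric is Euclidean by
   default (Manhattan available). σ defaults to the maximum pairwise
   centroid distance, giving large, overlapping receptive fields; it is
   configurable, and narrow fields (small σ) make class responses nearly
   disjoint, which is the regime the Hebbian learning mode needs.

2. **Rate coding.** Responses map affinely onto firing rates,
   `f_i = f_min + r_i (f_max − f_min)` with defaults 0–70 Hz, and each
   rate drives a cluster of `cluster_size` receptor neurons (RNs, default
   30 per VR) emitting independent stochastic spike trains: per-timestep
   Bernoulli ("Poisson") by default, or Gamma-renewal processes of
   configurable order. An order-k Gamma process has ISI CV = 1/√k; order 5
   is the preset used with very small populations, where its lower
   spike-count variability substitutes for population averaging.

3. **Network.** Three layers of clusters: RN (one cluster per VR) → PN
   (projection neurons, one-to-one excitatory relay between matching
   clusters) → AN (association neurons, one cluster per class, all-to-all
   plastic PN→AN synapses). PN clusters inhibit each other laterally
   (sparsening/decorrelation); AN clusters inhibit each other strongly
   (winner-take-all). In the `standard` preset both inhibition stages are
   direct inhibitory synapses; the `spikey` preset models explicit local
   interneuron (LN) populations and uses the small cluster sizes 6 RN /
   7 PN / 8 AN of a 192-neuron analog system.

4. **Decision.** The predicted class of a presentation window is the AN
   cluster with the highest spike count in that window (ties go to the
   lowest index by default; a seeded-random tie rule is available). A
   completely silent window is *undecided* and always scored as an error.

Neurons are leaky integrate-and-fire (LIF):

    τ_m dV/dt = −(V − V_rest) + R·I_syn(t),

with threshold/reset and an absolute refractory period; synapses are
exponential current-based, `I'(t) = I(t)·e^(−dt/τ_syn) + Σ w·δ_spike`.
Both are advanced by exponential-Euler updates, which are exact for
piecewise-constant input, so the integrator is stable at the 1 ms platform
timestep.

## Learning rules

**Symmetric STDP with a teaching signal** (the on-platform, extended-run
control flow). One continuous simulation covers the whole training
schedule: 120 ms per sample followed by a 20 ms silence. PN→AN weights
start at zero. A Poisson teaching source (default 200 Hz per neuron)
forces the correct AN cluster to fire during each presentation. Any
PN/AN spike pair within ±`tau_window` (default 10 ms) on a connected
synapse adds the same increment `a_plus` (default w_max/200) regardless
of order; weights are clipped to `[0, w_max]` at every step. Pairing is
nearest-neighbor: each new spike pairs once with the most recent spike of
each opposite-side partner, bounding the per-spike update and limiting
accidental pairings — together with the narrow window and the silence
gaps, this keeps associations specific to co-activity.

**Per-sample perceptron rule** (the stepped, host-in-the-loop control
flow). Each sample runs from rest for 500 ms at 0.5 ms timestep with the
current weights (random init, uniform on `[0, 0.1·w_max]`). The winner is
read with the same window counting as at test time. On an error, the
cluster-level weight from PN cluster i to the true class rises by
`η·a_i` and to the predicted winner falls by `η·a_i`, where
`a_i = counts_i / max(counts)` is normalized PN-cluster activity; the
matrix is clipped to `[0, w_max]` and replaced atomically. If the window
is undecided only the true class is potentiated.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| tau_m / v_rest / v_thresh / v_reset / t_ref / R | 20 / −65 / −50 / −70 / 2 / 40 | ms, mV, MΩ | conventional cortical LIF values |
| tau_syn exc / inh | 5 / 10 | ms | fast excitation, slower inhibition |
| rn_pn_w | 4.0 | nA | a 70 Hz input stream drives its PN well above threshold |
| pn_inh_w | −0.09 | nA (budget) | mild sparsening between PN clusters |
| an_inh_w | −0.4 | nA (budget) | hard winner-take-all between classes |
| w_max | 0.25 | nA | a fully potentiated cluster reliably drives its AN cluster |
| perceptron η | 0.2/N_VR (0.02 at 10 VRs) | | total update per error ≈ η·Σa_i stays commensurate with w_max at any size |
| a_plus | w_max/200 | nA | tens of pairings per presentation reach saturation over a short schedule |
| teach_w / teach_rate | 6.0 nA / 200 Hz | | teaching must defeat WTA inhibition |
| f_min / f_max | 0 / 70 | Hz | keeps per-step Bernoulli probability ≪ 1 at 1 ms |
| neural gas ε, λ, iters | 0.5→0.01, N_VR/2→0.01, 20·n | | standard annealed schedules |

Three normalizations are deliberate design choices:

* **Learning-rate scaling.** The *default* perceptron learning rate is
  0.2/N_VR. The error update moves every PN cluster's weight by
  `η·a_i`, so the total change per error grows with the number of
  clusters; a flat η that is well-behaved at 10 VRs makes the single-pass
  endpoint oscillate violently at 50+. An explicitly supplied
  `PerceptronParams` is never rescaled.

* **Inhibition budgets.** `pn_inh_w` and `an_inh_w` are totals divided by
  the number of *competing* clusters to obtain per-synapse weights
  (identity at two competing clusters for AN, at ten VR clusters for PN,
  i.e., at the small reference configuration). Without this, total
  lateral inhibition grows linearly with network size and PN activity
  collapses at large VR counts, destroying the property that performance
  should not degrade as VRs are added.

* **Charge-matched spike delivery.** A discrete exponential synapse
  injects `amp·dt/(1−e^(−dt/τ))` of charge per spike, which varies ~5%
  between the 1 ms and 0.5 ms grids and is amplified by the neuron's f–I
  gain. Spike amplitudes are therefore scaled so each spike injects the
  charge of the 1 ms reference grid (a no-op at dt = 1 ms). This keeps
  population spike counts within a few percent when the timestep is
  halved.

## Random numbers and reproducibility

Every stochastic operation takes an explicit seed. A run derives all
component seeds (neural gas, per-sample input trains, teaching trains,
weight init) from the master seed through `SeedSequence` with fixed
integer keys, so a config plus master seed reproduces weights,
predictions and scores bit-identically; the simulation itself is fully
deterministic given its input trains. The test stage never mutates
weights — the pipeline hashes the matrix before and after the test pass
and asserts identity.

## What the synthetic generator does and does not emulate

`make_synthetic` draws each class from an isotropic Gaussian; means sit on
a regular simplex with exact pairwise distance `separation`, samples are
clipped into `[0,1]^d`, and classes are interleaved in the sample stream.
This exercises every pipeline stage — VR placement, response overlap, rate
coding, lateral inhibition, both learning rules, scoring — under
controllable difficulty (separation vs. noise). It does *not* reproduce
the structure of real image data: classes are unimodal, isotropic and
equally sized, whereas handwritten digits are multimodal, anisotropic
manifolds. Consequently a small VR count already saturates the achievable
accuracy on the synthetic task, and the benefit of many VRs appears here
as "more receptors never hurt" rather than the strong gains seen on real
digit data; passing tests demonstrate correct mechanics and trends, not
image-level performance.

## The label-shuffled control

Training with randomly permuted labels must not yield above-chance test
accuracy. On this generator the per-seed outcome is strongly *bimodal*
rather than uniformly ~1/k: the network still discovers the cluster
structure of the data, but which output population claims which cluster
is decided by the noise in the shuffled labels, so a single seed can
score near 0 or near 1 and only the mean over seeds converges to chance.
The control is therefore evaluated as a mean over ≥10 seeds against a
3-standard-error band around 1/k, not per seed.

## Problem sizes used in tests and the acceptance script

Statistical generator checks use 200 s horizons at 50 Hz (≈10⁴ spikes).
The LIF f–I check integrates 8 s per current at 0.1 ms. End-to-end runs
use the 30-neuron clusters and 10 VRs of the reference configuration:
the separable two-class perceptron check uses 100 train + 100 test
samples per class (separation 0.8, noise 0.05, dim 10); its label-shuffled
control uses 25 + 25 per class over 10 seeds; the STDP association check
uses 10 + 5 per class over 3 seeds with σ = 0.35 (disjoint fields); the
VR-scaling comparison uses a 4-class task (separation 0.5, noise 0.12)
with 100 train + 30 test per class over 5 seeds at 10 vs. 50 VRs. These
sizes were chosen as the smallest at which the measured quantities are
stable across seeds.

## Numerical choices and degenerate inputs

* Spike times are multiples of dt; events are sorted by time then neuron
  index. Gamma ISIs are drawn continuously, accumulated from a random
  phase and snapped to the grid (collisions deduplicated).
* Conduction delays are a uniform 1 timestep.
* Ties in the winner-take-all readout go to the lowest cluster index
  (logged as ties by returning deterministically), unless the seeded
  random rule is selected.
* `n_vr` may exceed the number of training samples (duplicated
  initializations, with a warning); NaNs in samples are rejected.
* An all-zero PN activity vector makes the perceptron update a warned
  no-op; a silent AN window is an undecided (always wrong) prediction.
* `build_subset` keeps first-come order; classes absent from the data are
  dropped with a warning.

## Known limitations

* Map-based (Rulkov) neurons are not implemented; LIF is used uniformly.
  This is supported by the observation that classification performance is
  determined by the model, not the neuron implementation details.
* The shared-Poisson-pool input trick used on event-driven hardware is
  replaced by direct per-neuron stochastic generation, which produces the
  same population rate code.
* No conductance-based synapses, delay heterogeneity, or three-factor
  (reward-modulated, eligibility-trace) learning rules.
* The perceptron mode's single-pass endpoint is sensitive to sample order
  on hard multi-class tasks; accuracy variance across seeds shrinks with
  more training data.
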
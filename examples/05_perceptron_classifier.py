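"""End-to-end perceptron-mode classification of Gaussian-cluster data.

The stepped control flow: each 500 ms presentation restarts from rest, the
winner is read from AN spike counts, and on errors the cluster-level
PN->AN matrix is updated and atomically replaced. A single pass over the
training set suffices on well-separated data; the frozen network then
scores a single pass over the test set.
"""

from alclassify import ClassifierConfig, Dataset, make_synthetic, run_experiment

ds = make_synthetic(k_classes=2, dim=10, n_per_class=60,
                    separation=0.8, noise_sd=0.05, seed=1)
n = ds.n_samples
train = Dataset(ds.samples[: n // 2], ds.labels[: n // 2])
test = Dataset(ds.samples[n // 2:], ds.labels[n // 2:])

config = ClassifierConfig(mode="perceptron", n_vr=10, cluster_size=30, seed=5)
result, artifacts = run_experiment(config, train, test)

print(f"test accuracy: {result.accuracy:.3f} "
      f"({int(result.accuracy * test.n_samples)}/{test.n_samples} correct, "
      f"{result.undecided_count} undecided)")
print("confusion matrix (rows = true class, cols = predicted):")
print(result.confusion)
print("stage timings (s):",
      {k: round(v, 1) for k, v in artifacts["timing_s"].items()})
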
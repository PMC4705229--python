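"""Generate Gaussian-cluster data and place virtual receptors with neural gas.

Builds a 2-class dataset in the unit cube, fits 10 virtual receptors on a
training split, and reports the vector-quantization error before and after
fitting: the fitted centroids should tile the data much more tightly than
their random initialization.
"""

import numpy as np
from scipy.spatial.distance import cdist

from alclassify import fit_neural_gas, make_synthetic, vr_responses

ds = make_synthetic(k_classes=2, dim=10, n_per_class=100,
                    separation=0.8, noise_sd=0.05, seed=1)
print(f"dataset: {ds.n_samples} samples, {ds.n_features} features, "
      f"classes {ds.class_set}")

init = fit_neural_gas(ds.samples, n_vr=10, iterations=0, seed=7)
fitted = fit_neural_gas(ds.samples, n_vr=10, seed=7)


def quantization_error(vrs):
    return cdist(ds.samples, vrs.centroids).min(axis=1).mean()


print(f"quantization error: init {quantization_error(init):.4f} -> "
      f"fitted {quantization_error(fitted):.4f}")
print(f"receptive-field cutoff sigma = {fitted.sigma:.3f} "
      "(max pairwise centroid distance)")

responses = vr_responses(ds.samples[:5], fitted)
print("VR responses of the first 5 samples (rows; 1 = at the centroid):")
print(np.round(responses, 2))
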
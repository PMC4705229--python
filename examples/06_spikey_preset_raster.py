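"""The small-population preset with explicit inhibitory interneurons.

Mirrors the configuration used on small analog neuromorphic systems: 6 RN,
7 PN and 8 AN neurons per cluster, order-5 Gamma input processes (more
regular spiking compensates the tiny populations), and local interneuron
(LN) populations mediating both lateral-inhibition stages instead of
direct inhibitory synapses. Prints a per-population spike summary and
exports the AN raster in the two-column text format.
"""

import os
import tempfile

import numpy as np

from alclassify import (RatePattern, build_topology, cluster_spike_counts,
                        expand_cluster_weights, gen_gamma_trains,
                        save_spike_trains, simulate)

topo = build_topology(n_vr=10, n_classes=2, preset="spikey")
print("populations:", {name: pop.size for name, pop in topo.populations.items()})

# hand-set weights that associate VR clusters 0-4 with class 0, 5-9 with 1
cluster_w = np.zeros((10, 2))
cluster_w[:5, 0] = 0.5
cluster_w[5:, 1] = 0.5
topo.set_plastic_weights(expand_cluster_weights(cluster_w, 7, 8))

# drive the first five VR channels hard (a "class 0" input), 1 s presentation
rates = np.where(np.arange(10) < 5, 60.0, 5.0)
trains = gen_gamma_trains(RatePattern(rates), order=5, cluster_size=6,
                          duration=1000.0, seed=0, dt=1.0)
rec = simulate(topo, trains, duration=1000.0, dt=1.0,
               record=("PN", "AN", "LN_AN"))

for pop in ("PN", "AN", "LN_AN"):
    print(f"{pop}: {rec.spikes[pop].n_events} spikes")
an_counts = cluster_spike_counts(rec.spikes["AN"], topo.an_partition())
print(f"AN cluster spike counts {an_counts.tolist()} -> "
      f"winner class {int(np.argmax(an_counts))} (expected 0)")
raster_path = os.path.join(tempfile.gettempdir(), "an_raster.tsv")
save_spike_trains(raster_path, rec.spikes["AN"])
print(f"AN raster written to {raster_path} (neuron_id, time_ms)")
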
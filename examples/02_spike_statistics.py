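"""Rate-coded stochastic spike generation: Poisson vs Gamma inputs.

Commands a 50 Hz rate on one channel and generates 200 s of spikes with
both input processes. The Poisson generator should show an inter-spike
interval coefficient of variation (ISI CV) near 1, the order-5 Gamma
process near 1/sqrt(5) ~ 0.45 with visibly lower per-second count
variance — the property that makes Gamma inputs preferable for very small
neuron populations.
"""

import numpy as np

from alclassify import RatePattern, gen_gamma_trains, gen_poisson_trains

RATE = 50.0
DURATION = 200_000.0  # ms
pattern = RatePattern(np.array([RATE]))


def stats(trains):
    t = np.sort(trains.times[trains.neuron_ids == 0])
    isi = np.diff(t)
    counts = np.histogram(t, np.arange(0.0, DURATION + 1, 1000.0))[0]
    return t.size / (DURATION / 1000.0), isi.std() / isi.mean(), counts.var()


poisson = gen_poisson_trains(pattern, cluster_size=1, duration=DURATION,
                             dt=1.0, seed=42)
gamma5 = gen_gamma_trains(pattern, order=5, cluster_size=1, duration=DURATION,
                          seed=42)

for name, trains in [("poisson", poisson), ("gamma(5)", gamma5)]:
    rate, cv, var = stats(trains)
    print(f"{name:9s} empirical rate {rate:6.2f} Hz  ISI CV {cv:.3f}  "
          f"per-second count variance {var:.1f}")
print("both processes preserve the commanded rate; the Gamma process is "
      "more regular (lower CV) and less variable in counts")
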
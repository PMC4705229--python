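"""The LIF neuron's f-I curve against its closed form.

Drives a single leaky integrate-and-fire neuron with constant currents and
compares the simulated steady firing rate (0.1 ms timestep) with the
analytic rate 1 / (t_ref + tau_m * ln((RI + v_rest - v_reset) /
(RI + v_rest - v_thresh))). Agreement within a few percent validates the
exponential-Euler integrator and the refractory handling.
"""

import numpy as np

from alclassify import NeuronParams, lif_step

p = NeuronParams()
DT, HORIZON = 0.1, 10_000.0  # ms

print(f"LIF: tau_m={p.tau_m} ms, threshold {p.v_thresh} mV, "
      f"reset {p.v_reset} mV, t_ref={p.t_ref} ms, R={p.r_m} MOhm")
print(f"{'I (nA)':>8} {'simulated (Hz)':>15} {'analytic (Hz)':>14} {'error':>7}")
for i_syn in [0.45, 0.6, 0.8, 1.2, 2.0]:
    v, r = np.array([p.v_rest]), np.array([0.0])
    count = 0
    for _ in range(int(HORIZON / DT)):
        v, s, r = lif_step(v, r, np.array([i_syn]), p, DT)
        count += int(s[0])
    sim = count / (HORIZON / 1000.0)
    drive = p.r_m * i_syn
    ana = 1000.0 / (p.t_ref + p.tau_m * np.log(
        (drive + p.v_rest - p.v_reset) / (drive + p.v_rest - p.v_thresh)))
    print(f"{i_syn:8.2f} {sim:15.2f} {ana:14.2f} {abs(sim - ana) / ana:7.2%}")
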
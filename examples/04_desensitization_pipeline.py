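"""Chain delay-decay fits into the dose dependence of desensitization.

Rebuilds the delayed-restimulation readout: at each ADP dose the
aggregation response decays exponentially with the delay between weak
pre-activation and restimulation. Fitting each decay gives a
desensitization constant k5; fitting the inhibitory Hill law through the
(dose, k5) points gives the maximal constant, IC50 and h — high agonist
doses protect platelets against exhaustion.
"""

import numpy as np

from plateletkin import DecayDataset, dose_dependence_of_decay, half_time

doses_nm = [1000.0, 2000.0, 5000.0]
k5_true = [0.0019, 0.0013, 0.0005]

datasets = []
for dose, k in zip(doses_nm, k5_true):
    delays = np.array([60.0, 180.0, 360.0, 600.0])
    responses = 100.0 * np.exp(-k * delays)  # % of zero-delay control
    datasets.append(DecayDataset(delays, responses, agonist_conc=dose))
    print(f"ADP {dose:6.0f} nM: k5 = {k:.4f} 1/s, "
          f"half-time {half_time(k):5.0f} s")

fit = dose_dependence_of_decay(datasets)
print(
    f"Hill fit: k_max = {fit.params.k_max:.5f} 1/s, "
    f"IC50 = {fit.params.half_conc:.0f} nM, h = {fit.params.h:.2f}"
)
print("higher ADP -> slower desensitization (protection by strong stimulus)")
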
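"""Fit a Hill dose-response curve and read off EC50 and steepness.

Generates an 8-point ADP dose series for the integrin-activation rate
constant with 5% multiplicative noise and refits the activating Hill
law. EC50 is the dose giving the half-maximal rate; h sets how switch-
like the response is (h ~ 4 for ADP-driven integrin activation).
"""

import numpy as np

from plateletkin import HillParams, fit_hill, generate_dose_response_dataset

truth = HillParams(k_max=0.03, half_conc=589.8, h=3.92)
doses = np.geomspace(59.0, 5898.0, 8)
dataset = generate_dose_response_dataset(truth, doses, noise_sd=0.05, seed=4)
fit = fit_hill(dataset, mode="activation")

print(f"true law:   EC50 = {truth.half_conc:.1f} nM, h = {truth.h:.2f}")
print(
    f"fitted law: EC50 = {fit.params.half_conc:.1f} nM, "
    f"h = {fit.params.h:.2f}, k_max = {fit.params.k_max:.4f} 1/s "
    f"(r2 = {fit.r2:.4f})"
)
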
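# plateletkin

Kinetic modeling of platelet phenotype transitions, and analysis of the
low-angle light-scattering (laser-diffraction) aggregometry traces that
measure them.

Circulating platelets are not a homogeneous population: on stimulation
they move through functionally distinct states — resting, sphered
(shape-changed), integrin-activated, aggregated — and can branch into an
inhibited state (cyclic-nucleotide signaling) or an exhausted,
refractory state. `plateletkin` implements this six-phenotype scheme as
a mass-conserving kinetic model, plus the estimators needed to extract
its rate constants from instrument traces and dose–response tables, and
a synthetic-data generator that emulates the experiments for testing and
validation.

## The model

State variables are population fractions N (percent of all platelets):

    dN_rest/dt = k4r·N_inh + k1r·N_exh − k4·N_rest − k1·N_rest
    dN_sph /dt = k1·N_rest − k2·N_sph − k5·N_sph
    dN_gp  /dt = k2·N_sph − k3·N_gp² − k6·N_gp
    dN_agg /dt = k3·N_gp² − k7·N_agg
    dN_exh /dt = k5·N_sph + k6·N_gp + k7·N_agg − k1r·N_exh
    dN_inh /dt = k4·N_rest − k4r·N_inh

All transitions are first order except aggregation (k3), which is second
order in the integrin-active fraction (collision-driven, Smoluchowski
regime). The concentration dependence of each measurable constant is a
Hill law:

    activation:  k(A) = k_max · Aʰ / (EC50ʰ + Aʰ)
    inhibition:  k(I) = k_max · IC50ʰ / (IC50ʰ + Iʰ)

Agonists (ADP, TRAP) drive k1 (shape change) and k2 (integrin
activation) and — at high dose — protect against the desensitization
constants k5 and k6. The cAMP-pathway agonist iloprost suppresses the
forward constants non-competitively, drives the rest→inhibited
transition (k4), and enables disaggregation (k7), which is only possible
within a ~180 s window after activation. The inhibitory effect builds up
first order with a measured onset rate (0.31 1/s), so pre-incubation and
co-administration protocols genuinely differ. Stirring gates k3.

The constants that no trace isolates directly — k1r (exhausted→rest),
k4r (inhibited→rest) and k7 — are estimated by fitting simulated
trajectories to traces with a seeded basin-hopping-style global stage
and an L-BFGS-B local stage, scored by R².

## Worked example

```sh
python examples/01_simulate_dose_series.py
```

prints, for one agonist addition per run:

```
   ADP-100nM: peak aggregated   0.0 %  peak sphered  92.3 %  exhausted at 300 s  43.3 %  (fraction total error 1.4e-15)
   ADP-500nM: peak aggregated   9.4 %  peak sphered  81.8 %  exhausted at 300 s  73.8 %  (fraction total error 8.5e-16)
  ADP-2000nM: peak aggregated  54.8 %  peak sphered  70.1 %  exhausted at 300 s  36.9 %  (fraction total error 2.0e-15)
 ADP-10000nM: peak aggregated  89.4 %  peak sphered  70.6 %  exhausted at 300 s   3.2 %  (fraction total error 7.1e-16)
```

A 100 nM dose only sphers the platelets, which then drain into the
exhausted pool; 500 nM gives weak aggregation with fast exhaustion;
10 µM gives strong, stable aggregation with slow exhaustion. The
fraction total stays at 100% to machine precision.

The other examples mirror the remaining capabilities, each printing the
numbers it computes and what they mean:

* `02_extract_rate_constant.py` — refit of the monoexponential
  saturation law to an unstirred saturating-dose trace
  (`fitted k = 0.1913 1/s (± 0.0012), r2 = 0.9989` against a 0.19 1/s
  generator).
* `03_hill_dose_response.py` — Hill fit of a noisy 8-dose integrin-
  activation series (EC50 615 nM recovered against a 589.8 nM truth at
  5% noise).
* `04_desensitization_pipeline.py` — delay-decay fits chained into the
  agonist-dose dependence of the desensitization constant.
* `05_recover_hidden_constants.py` — recovery of k1r, k4r, k7 from the
  three-protocol identification suite at 2% trace noise (errors ~1–3%).

There is also a thin CLI (`plateletkin simulate|synthesize|fit-trace|
fit-dose-response|fit-decay|fit-model`), each subcommand writing a JSON
manifest alongside its output.

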
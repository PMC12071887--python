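# Methods

## Model structure and assumptions

The package models early platelet hemostasis as transitions between six
population-level phenotypes (resting, sphered, integrin-activated,
aggregated, exhausted, inhibited), expressed as percentages of the total
population. Transitions are treated as formal chemical kinetics: first
order in the source fraction, except aggregation, which is second order
in the integrin-active fraction because it is collision-driven. The
right-hand sides sum to zero by construction, so the six fractions
conserve their 100% total; the integrator is required to preserve this
to 1e-6 relative (it does so to machine precision in practice). Platelet
count, calcium (2 mM), pH (7.4) and fibrinogen are assumed fixed at the
values where aggregation is collision-saturated and otherwise
non-limiting; the model deliberately excludes procoagulant/apoptotic
phenotypes, microparticles, coagulation, and any spatial or flow
effects. Downstream readouts treat the low-angle (1°) scatter channel as
proportional to the aggregated fraction and the 12° channel as
proportional to sphered + integrin-active single cells, through a
configurable affine map; the fluorescence channel is a crude activation
proxy only.

## Rate-constant laws and parameters

Measured constants and their concentration dependence (concentrations
internally in nM, time in s):

| constant | meaning | law | values |
|---|---|---|---|
| k1 | rest→sphered | Hill in agonist | k_max 0.19 1/s; ADP EC50 46.8 nM, h 1.27; TRAP 204 nM, 1.24 |
| k2 | sphered→integrin-active | Hill in agonist | k_max 0.03 1/s; ADP 589.8 nM, 3.92; TRAP 2309 nM, 6.68 |
| k3 | integrin-active→aggregated | constant while stirred | 2·k2_max/100 per (%·s) |
| k4 | rest→inhibited | onset rate × iloprost occupancy | 0.31 1/s × Hill(0.21 nM, 2.14) |
| k5 | sphered→exhausted | inhibitory Hill in agonist | k_max 0.0028 1/s; IC50 1840 nM, h 1.4 |
| k6 | integrin-active→exhausted | inhibitory Hill in agonist | k_max 0.055 1/s; IC50 990 nM, h 1.9 |
| k7 | aggregated→exhausted (disaggregation) | fitted; gated | default 0.02 1/s |
| k1r | exhausted→rest | fitted | default 0.002 1/s |
| k4r | inhibited→rest | fitted | default 0.005 1/s |

Design choices where the experimental record leaves the law open:

* **k3 scale.** The aggregation constant is second order, but the
  available constraint is a ratio to the first-order integrin-activation
  maximum ("twice as fast, never rate-limiting"). We set
  k3 = 2·k2_max/100 per (%·s), so that at 100% integrin-active platelets
  the pseudo-first-order aggregation rate equals 2·k2_max. Stirring off
  sets k3 = 0 and changes nothing else (desensitization continues).
* **Non-competitive inhibition.** Iloprost multiplies k1 and k2 by the
  inhibitory Hill factor evaluated at an *effective* inhibitor level
  e(t)·I, where the per-reaction exposure e(t) relaxes first order
  toward the Hill occupancy with the measured onset rate (0.31 1/s for
  both the shape-change and aggregation pathways; the slower 0.085 1/s
  calcium-linked onset is recorded but the calcium readout is outside
  the ODE state). This reproduces the time-offset phenomenology: ~5 s of
  pre-incubation suffices to block aggregation, while co-administration
  lets a fast shape-change transient through.
* **k4 law.** No standalone rest→inhibited law was measured; we use the
  measured onset rate times the aggregation-pathway Hill occupancy of
  iloprost, applied instantaneously.
* **Disaggregation gating.** k7 is nonzero only while an inhibitor is
  present *and* within 180 s of the last agonist addition; afterwards
  aggregates are treated as irreversible on the modeled time scale.
* **Desensitization at zero agonist.** k5/k6 evaluate to zero with no
  agonist on board (their source states are unpopulated anyway); with
  several agonists the strongest protection (smallest constant) wins,
  and agonist additions are cumulative step functions (no degradation
  or dilution over the ~10 min horizon).
* **Exhausted recovery.** k1r routes exhausted→rest only; there is no
  direct inhibited→exhausted path.

## Numerics

Integration is piecewise between protocol events (and the
disaggregation-window closure) with hard solver restarts; within a
segment all stimulus levels are constant and only the exposure states
evolve, so the right-hand side is smooth. The solver is LSODA with
rtol 1e-8 / atol 1e-10 and dense output sampled on a uniform grid
(0.1 s default, matching the sub-second inhibition half-times);
trajectory fitting uses rtol 1e-6 and a 0.5–1 s grid for speed. Fractions
are clipped at zero only for reporting. The saturation-curve fit uses
nonlinear least squares with an analytic Jacobian, initialized at
Im = max, Io = first sample, k = ln2 / time-to-half-range; flat signals
(range below the noise floor) are rejected rather than fitted, and fits
with r² below 0.5 are flagged. Rates-at-a-time are tangent slopes from a
±2 s local linear regression (chord-vs-tangent ambiguity resolved in
favor of the tangent; the window is configurable, and the finite window
carries a ~(k·w)²/10 curvature bias, 1.4% at k = 0.19 with the default
window). Baselines default to the median of the 5 s before the first
event. Hill fits run bounded least squares (half-max within two decades
of the dosed range, h in [0.3, 10]) from five log-spaced half-max seeds,
inverse-variance weighted when SDs are given; three distinct doses with
three free parameters are allowed and fit as an exact interpolation,
which is how tabulated three-dose summaries are refit. Decay fits anchor
the zero-delay response at the 100% control and assume single-
exponential decay in the delay — the tabulated half-times imply
first-order kinetics but the functional form is an assumption.

## Hidden-constant estimation

k1r, k4r and k7 are estimated in log space by a seeded
basin-hopping-style global stage (accept-if-better hops of 0.4 decades)
around an L-BFGS-B local stage with numerical gradients; the loss is the
sum over traces and channels of squared residuals after per-channel
range normalization, and per-trace R² is reported alongside. Because
these constants are not directly measurable, identifiability reporting
is mandatory: the fitter flags any parameter whose ±20% wiggle at the
optimum moves the loss by less than numerical noise, and tests verify
positive curvature at the optimum.

The three-protocol identification suite pairs a low-ADP run (100 nM,
600 s — pins k1r via the late balance of the rest→sphered→exhausted→rest
cycle), a high-ADP run (5000 nM — anchors the activation chain), and a
high-ADP run with iloprost 0.2 nM added 3 s after activation. The last
design is deliberate: a saturating inhibitor dose blocks re-activation
so completely that the release of inhibited platelets is invisible, and
a long delay leaves the inhibited pool unpopulated (the resting pool is
exhausted within ~20 s at high ADP); a partially suppressing dose added
while ~60% of platelets are still resting populates the inhibited pool
*and* lets its k4r-limited release feed an observable late aggregation
component, while also opening the disaggregation window for k7. With
this suite, noiseless recovery is exact and recovery at 2%-of-scale
trace noise is within a few percent for all three constants.

## Synthetic data

The generator wraps forward simulation + the observable map + seeded
Gaussian noise (additive, optional multiplicative and linear drift).
Default noise is additive with SD 1% of the 0–100 channel scale, chosen
conservatively relative to the visible quality of laser-diffraction
traces; at this level saturation-rate recovery error stays under 5%, so
fixture failures indicate code defects rather than noise. Every noisy
fixture can return its noiseless twin, and estimator tests always score
against the generating truth, never against a noise realization. What
the generator does **not** emulate: instrument-specific baselines and
gains, multiple-scattering nonlinearity at high platelet density,
pipetting/mixing transients at additions, agonist degradation, and
donor-to-donor variability — so passing tests demonstrate estimator
correctness under the model's own assumptions, not robustness to every
artifact of real traces.

## Problem sizes

Tests and the acceptance script run at deliberately modest sizes: dose-
response fits use 8-point series, trace fits 0.1 s grids over 60–200 s,
trajectory fitting a 1 s grid over 600 s horizons, and the seed-sweep
recovery study 20 noise seeds with one global hop per fit — enough for
the medians being asserted while keeping the whole suite in the
minutes range on a single core.

## Known limitations

* The inhibitor-exposure construction (effective level e(t)·I inside the
  Hill factor) is a reconstruction of time-dependent inhibition from
  onset-rate and dose-response measurements, not an experimentally
  anchored law; alternative forms (e.g. a factor relaxing toward the
  Hill value directly) would fit the same end points.
* Refitting tabulated three-dose summaries is exactly determined, so the
  recovered Hill parameters inherit the rounding of the printed digits;
  where a table also prints half-times, those carry an extra significant
  digit and both rows should enter the fit (see
  `scripts/acceptance.py`).
* k4r is only identifiable from protocols that both populate the
  inhibited pool and leave its release observable; with saturating
  inhibitor doses the fitter correctly reports it unidentifiable rather
  than returning a spurious estimate.
* The calcium/fluorescence channel is a phenomenological activation
  proxy; intracellular signaling is not modeled.
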
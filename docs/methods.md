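# Methods

This note records the model, the numerical choices, and the design decisions
behind `chlamycycle`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Growth law and light response

Cell volume grows exponentially during the interdivision phase,
V(t) = V(0)·e^(μt), with μ (h⁻¹) constant while the irradiance is constant.
The endpoint estimator μ = (1/T)·ln(V(T)/V(0)) inverts the law exactly;
`fit_exponential` realises it on sampled data as ordinary least squares of
ln V on t, which matches the multiplicative noise model and is exact on
noiseless data (tested at 1e-10 relative error).

The PAR → μ response is a shifted rectangular hyperbola

μ(P) = μ_max · (P − P₀) / (K + P − P₀) for P > P₀, else 0,

the simplest saturating form consistent with the three observed constraints:
no net growth at P₀ = 0.2 μmol m⁻² s⁻¹; a ratio μ(200)/μ(10) = 8 (the
interdivision duration is inversely proportional to μ, and the observed
durations differ by a factor of 8 between these intensities); and saturation
at high PAR. Two constraints fix two of the three parameters; the remaining
degree of freedom is pinned by setting the interdivision duration at PAR 200
to 10 h, an order-of-magnitude calibration choice rather than a measured
value. The resulting defaults, shipped as `data/default_calibration.json`,
are K = 112.902 μmol m⁻² s⁻¹ and μ_max = 0.2208 h⁻¹. Both are configurable;
μ_max in particular is an extrapolation, since all quantitative observations
were made at PAR ≤ 200 while saturation is only reported "near 300".

## Cycle decision rules

**Interdivision timer.** A single accumulator s(t) unifies the observed
products under the four illumination conditions. Its rate is the
instantaneous growth rate before commitment — so s = ln(V/V(0)) exactly, and
it pauses in darkness — and the *memorised* commitment-time growth rate
after commitment, accruing even in darkness. Division-phase entry occurs at
s = timer_threshold. This single mechanism yields:

* continuous light: μ·T = threshold for every PAR above compensation;
* light–dark, committed: μ_L·T_LD = threshold regardless of when the light
  went out (the dark cell divides "on schedule");
* light–dark–light, uncommitted at light-off: accrual pauses, so
  μ_L·(T − T_D) = threshold — a dark interval shifts entry by exactly its
  duration and changes nothing else;
* a PAR step before commitment: μ₁T₁ + μ₂T₂ = threshold (additive accrual).

The default threshold is ln 4.1 ≈ 1.411: under continuous light the cell
then enters division at exactly 4.1× its initial volume, and the product
μ·T prints as 1.4. The reported products under the different conditions
(1.4 for LL/LD/LDL, 1.5 for the PAR-step condition) differ by less than
their dispersion (±0.2), so a single threshold is used; it is a parameter,
not a constant of the code.

Whether the memorised rate should be the instantaneous rate at commitment or
the average over the first light period is indistinguishable under
piecewise-constant PAR; the segment rate at commitment is used.

**Commitment sizer.** commitment_ratio = 2.0: a cell that has not doubled
by the time the light goes out never enters the division phase (verified
over ≥ 48 h of simulated darkness). Because the threshold exceeds
ln 2, commitment always precedes timer firing, so a cell that fires has
always committed.

**Mitotic sizer.** The final/initial ratio maps to the daughter number with
deterministic cutpoints 2.0 (below: no division) and 2.9 (two vs four
daughters). The observations actually show indeterminate bands — roughly
1.8–2.2 and 2.7–3.1, with condition-to-condition midpoints between 2.7 and
3.1 — so a stochastic mode (`stochastic_bands`) draws per-cell cutpoints
uniformly from those bands. The deterministic defaults are the band
midpoints (the lower tied to the commitment ratio); the tested property is
that the output is always 0, 2 or 4 — asymmetric division never occurs.

**Division phase.** Five subphases (shrinkage, rotation, first and second
mitosis, completion) with fixed durations {0.3, 0.3, 0.5, 0.5, 0.4} h.
These magnitudes are not measured values — only the light- and
volume-independence of the division phase is an observed property, and that
is what the tests assert. Daughters split the final volume equally;
lineages follow one daughter per generation (as in a microchamber, where the
other daughters are flushed away), starting at V_final/daughter-number.

**Integration.** Event-driven and closed-form: within each constant-PAR
segment the commitment time and firing time are solved analytically, so
noiseless runs satisfy the model identities to machine precision — there is
no ODE stepper and no step-size tolerance. Per-cell noise enters as
unit-mean lognormal multipliers on μ (CV 0.25) and on the threshold
(CV 0.10), drawn once per cell from a seeded generator; noiseless mode is
the default and is bit-reproducible.

## Measurement pipeline

Division-phase entry is detected from the only signal a volume series
offers: a sustained drop below (1 − drop_fraction) of the running maximum
(defaults: 5%, 5 consecutive samples). Multiplicative measurement noise
inflates a raw running maximum (the maximum of n lognormal draws grows with
n), which makes the raw rule fire spuriously, so the pipeline first applies
a running median spanning ~0.25 h of samples (reflect padding, so a single
noisy endpoint cannot dominate a boundary window). The detection time lags
the true shrinkage onset by however long the volume takes to fall below
threshold; the segmentation therefore backtracks to the last sample at which
the smoothed series still sits at its running maximum within a
noise-adaptive tolerance (4 robust standard errors, estimated from
successive log-volume differences), then snaps to the last raw-maximum
sample in that neighbourhood. On noiseless data the tolerance collapses to
zero and the recovered entry time, final volume and ratio are exact; this is
asserted for all four illumination conditions.

Growth rates are fitted per illuminated period, clipped to the
interdivision phase; dark intervals never enter a fit. The per-cell products
are μ_first·T (the quantity plotted against condition in the source
experiments), the dark-adjusted μ_first·(T − T_D), and the additive
Σ μᵢ·Tᵢ when the schedule has several light periods. The ratio of the
volume at the end of the first light period to the initial volume is also
reported — it is the quantity the commitment sizer gates on, and cohort
analyses condition on it exceeding 2, as the experimental analysis did.
Cohort summaries use the sample SD (n − 1) and report the CV of T in
percent.

The initial volume is taken as the first sample of the trajectory
(trajectories are assumed to start at mother-mitosis completion). Measured
hatched-daughter volumes exceed the quarter of the mother's final volume
(87 vs 69 μm³ in the motivating observations) because growth resumes inside
the mother wall before hatching; the quarter convention is used for
simulated lineages, and an explicit v0 can be supplied where an analysis
prefers the hatched volume.

## Image volumetry

A micrograph is thresholded (Otsu by default, fixed override available),
the largest connected component kept and holes filled. The principal axes of
the mask's second moments give the full axis lengths L_a ≥ L_b and the
orientation. Because the cell is axisymmetric about its long axis, the
volume is the solid of revolution of the half-width profile,
V = π ∫ h(x)² dx, computed by projecting foreground pixels onto the long
axis, binning into one-pixel slabs (bins centred so an axis-aligned pixel
grid falls on bin centres, avoiding aliasing), and integrating by trapezoid
with zero-width end caps. The prolate-spheroid closed form
V = (4/3)π(L_a/2)(L_b/2)² serves as the analytic cross-check; the two agree
within 3% at the default resolution and within 1% at ≥ 200 px along the
long axis. Sub-pixel accuracy is not attempted: targets are set at the 2–3%
level appropriate to ~0.2 μm optical resolution. A published formula for
this quantity, V = (4/3)π(L_a + L_b), is dimensionally inconsistent (linear
in length); the implementation follows the described procedure — rotation of
the cross-section about the long axis — and provides the spheroid form as
its closed-form counterpart.

## Synthetic data

The generator emulates the on-chip recordings: per cell it draws an initial
volume (lognormal, mean 79.7 μm³, CV 12.6/79.7 ≈ 0.158 — the reported
population mean ± SD), per-cell μ and threshold multipliers, runs the
simulator, samples the volume path every 30 s (1/120 h, the recording
interval; coarser for fast tests), and applies i.i.d. multiplicative
measurement noise (CV 0.03). At division entry it renders a 10% linear
shrinkage over the shrinkage subphase followed by a plateau until hatching —
a rendering convention that gives the detector the morphological signature
it needs; the 10% magnitude is invented and configurable. The noise
defaults cv_mu = 0.25 and cv_threshold = 0.10 were chosen once so that the
cohort CV of T lands in the observed 21–38% band and the μT dispersion is
≈ ±0.2; only the initial-volume mean and SD are measured values.

What the generator does *not* emulate: temporal autocorrelation of
measurement error, segmentation artefacts, focus drift, flagella or eyespot
features, chamber walls, or any within-cell physiology beyond the three
rules. Passing tests therefore demonstrate internal consistency of model,
generator and pipeline — parameter recovery under the stated noise model —
not validation against real micrographs.

Synthetic cell images are anti-aliased ellipses (3×3 subpixel coverage) on
a darker background with Gaussian pixel noise, carrying exact geometric
ground truth.

## Problem sizes and determinism

Cohort analyses use 26 cells per PAR at the five experimental intensities
(10, 20, 40, 100, 200 μmol m⁻² s⁻¹) for continuous light, 9 cells per PAR
at three intensities for light–dark, and 12 cells for the PAR-step
condition — the sizes reported for the original cohorts. Every stochastic
path is driven by a single seed (spawned per cohort via `SeedSequence`);
identical seed and spec give byte-identical CSV output. The acceptance
script derives all cohort seeds from its `--seed` argument and completes in
about a second.

## Known limitations

* The light-response curve above PAR 200 is an extrapolation.
* Division subphase durations are placeholders with the correct invariance
  properties, not measured values.
* The simulator models single cycles and single-daughter lineages; it does
  not model populations, mother-wall geometry, or gametogenesis.
* Behaviour of uncommitted cells re-illuminated after very long darkness
  (≫ 9 h) is an extrapolation of the pause-and-resume rule beyond the
  range in which it was observed.
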
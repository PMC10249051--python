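# Methods

## Scattering model

Single spheres are evaluated with the standard Mie series: the logarithmic
derivative of the Riccati–Bessel function of the internal field is obtained
by downward recurrence, the external Riccati–Bessel functions by upward
recurrence, and the series is truncated at the Wiscombe order
`n_max = x + 4x^(1/3) + 2`, which converges for every size parameter the
model encounters (the largest is the RBC equivalent sphere at 730 nm,
x ≈ 32). All refractive indices are real: the model describes scattering
only, and the lipid additions studied here leave blood absorption
essentially unchanged at these concentrations. The plasma/water medium
index is fixed at 1.345 across 730–1100 nm; index dispersion is not
modelled. An index-matched sphere returns `Q_scat = 0`, `g = 0` rather than
an error so that titration curves remain defined at zero contrast.

The test suite cross-checks this implementation against a second,
independently coded Mie evaluator built directly on `scipy.special`
spherical Bessel functions (different recurrence, different truncation);
fifty random spheres with x < 50 agree to 1e−6 relative in both `Q_scat`
and `g`, and the x < 0.05 regime matches the closed-form Rayleigh
expression to better than 1%.

For a polydisperse population, μs′ is the distribution-weighted sum of
per-size contributions; μs is the same sum without the `(1 − g)` factor,
and the effective anisotropy of a population or mixture is the μs-weighted
mean of per-size (or per-species) `g`, so `μs′ = μs(1 − g_eff)` holds by
construction. This mixing rule is the standard one; nothing in the model
constrains it otherwise.

## Size distributions

Lipoprotein and intralipid size distributions are truncated exponentials
in diameter. Weights are the exponential density evaluated at the midpoints
of `n_bins = 200` equal-width diameter bins, renormalized to sum to one;
midpoint quadrature converges quadratically, and refining 100 → 1000 bins
moves downstream μs′ by well under 0.1% for every distribution used here.

Two parameterizations coexist deliberately:

* **Lipoproteins** use the literature "average size" (100 nm fasting /
  200 nm postprandial for chylomicrons, 50 nm for VLDL) directly as the
  exponential scale parameter, matching how those values are quoted.
* **Intralipid**'s 97 nm average is an empirical electron-microscopy mean
  of the truncated 25–675 nm distribution, so the scale is solved by 1-D
  root finding until the truncated weighted mean equals 97 nm.

## From triglycerides to particles

Blood TG (mg/dL) splits 30%/70% between chylomicrons and VLDL in the
fasting state (a configurable default). Each class's TG mass is scaled to
particle mass by its TG mass fraction (0.90 chylomicron, 0.50 VLDL),
converted to a volume fraction via particle density (0.93 and
1.00 g/ml), and converted to number density by dividing by a per-particle
volume. Two divisor conventions are exposed:

* `mean_volume` (default for lipoproteins): the distribution-weighted mean
  particle volume Σ f(aᵢ)V(aᵢ) — the exact inverse of the volume
  bookkeeping, so TG mass is conserved to machine precision.
* `volume_of_mean` (default for the intralipid species): the volume of the
  mean-size particle. For a heavy-tailed exponential this divisor is
  several-fold smaller, giving a correspondingly higher number density.
  Under this normalization the Twersky-corrected intralipid predictions
  reproduce the measured titration increments consistently at all three
  wavelengths, which is why it ships as the intralipid default; the two
  conventions are otherwise identical for monodisperse species.

Postprandially, all added TG is assigned to the chylomicron pool — dietary
fat enters the blood as chylomicrons — while fasting VLDL TG, size and
index are held fixed; the chylomicron exponential scale moves to 200 nm
and its refractive index to 1.5, with the 75–1200 nm truncation range
unchanged. How a meal's TG actually partitions between classes is not
well constrained by the literature; this all-to-chylomicron rule is the
documented default and is configurable through `postprandial_state`.

## Dependent scattering

The Twersky factor `W = (1−h)^(p+1) / (1 + h(p−1))^(p−1)` multiplies the
Mie μs′ (and μs). In titration replication W multiplies only the
added-particle contribution, which is then added to the measured pure-blood
baseline; in the whole-blood simulation W multiplies the full RBC + TRL
scattering. Shipped per-wavelength packing factors are 0.97 / 1.78 / 1.61
at 730 / 880 / 1100 nm with h = 0.33 (bovine titration conditions).

Fitting `p` from a titration curve exploits the fact that the residuals
depend on `p` only through the scalar `W`: the optimal `W*` has a closed
form (a one-dimensional linear least-squares coefficient), and `W(p) = W*`
is then inverted by Brent root finding. `W` is not monotone in `p` — it
peaks near p ≈ 0.55 at h = 0.33 before decreasing — so part of its range
is attained at two `p` values with *identical* residuals. The fit
deterministically returns the solution on the decreasing branch, the
regime containing both the classical integer packing shapes (1–3) and the
blood-titration fits; a `W*` outside the attainable range clamps to the
nearest bound. The search domain is p ∈ [0, 5].

## Whole blood and scenarios

RBCs are modelled as the usual volume-equivalent sphere: diameter 5.56 μm,
number density 0.005 cells/μm³ (hematocrit 0.45), refractive index 1.4.
The TG sweep starts at 50 mg/dL with chylomicron scale 100 nm and RI 1.46
and takes ten 50 mg/dL steps, growing the scale 5 nm per step and ramping
the RI linearly to 1.5; it uses h = 0.45 in the Twersky factor, consistent
with its RBC density. Along the sweep, μs′ rises monotonically (~+39% at
730 nm over the full ramp) and g falls, while μs moves by only ~1% — the
postprandial signal is an anisotropy effect, not a raw-scattering one.

The scenario table uses measured-blood baselines instead of the simulated
RBC suspension: baseline μs′ values (≈0.937, 0.525, 0.692 mm⁻¹ at
730/880/1100 nm) are recovered from reported titration increment/percent
pairs (0.089 mm⁻¹ = 9.5%, 0.042 mm⁻¹ = 8%, 0.036 mm⁻¹ = 5.2%) and shipped
as named constants. Percent changes are relative to the fasting total
(baseline + Twersky-corrected fasting-TRL contribution) with h = 0.33 and
the fitted packing factors; both the denominator convention and the
hematocrit are configurable, since reasonable alternatives (blood-only
denominator, h = 0.45) shift the percentages by several relative percent.

## Synthetic titration data

The generator emulates diffuse-optics titration measurements by running
the package's own forward model and adding i.i.d. zero-mean Gaussian noise
(default σ = 0.02 mm⁻¹, the order of the reported model–measurement mean
absolute errors, 0.012–0.098 mm⁻¹). A single integer seed drives all
randomness. What passing round-trip tests show is that the fitting
pipeline is a correct inverse of this forward model under realistic noise;
they do not probe instrument systematics, concentration-dependent noise,
inter-sample hematocrit variation, or deviations of real lipoprotein
ensembles from truncated-exponential Mie spheres (coated or non-spherical
particles, index dispersion).

## Problem sizes and numerical choices

Default runs use 200 size bins per distribution, three wavelengths, and
11 sweep steps; every headline quantity is deterministic and computes in
seconds. Packing-factor recovery statistics in the tests use 20 noise
realizations. Tolerances: distribution weights must sum to 1 within 1e−9;
TG mass conservation holds to 1e−9 relative; the Mie cross-check demands
1e−6 relative agreement. Degenerate inputs are defined rather than fatal
where a physical convention exists (index matching, zero TG, zero
concentration) and raise `ValueError` otherwise (negative sizes, invalid
ranges, non-positive Twersky denominator base).

## Known limitations

* Chylomicron/VLDL refractive indices are single literature point values;
  VLDL's postprandial index change is unknown and held fixed.
* The Twersky correction is a scalar crowding factor; it does not capture
  angular redistribution, so `g` is reported uncorrected.
* Scattering only: absorption changes from lipids are not modelled.
* The RBC equivalent-sphere approximation ignores shape and orientation
  effects beyond what the fitted packing factors absorb.
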
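# lipoptics

Forward model of how triglyceride-rich lipoproteins (TRLs) — chylomicrons
and VLDLs — change the optical scattering of whole blood, for researchers in
diffuse optics and biophotonics exploring blood-lipid monitoring.

After a high-fat meal, chylomicron concentration, size and refractive index
all rise. Because these particles are large (75–1200 nm) and index-mismatched
against plasma, they are strong Mie scatterers in the NIR, and the
postprandial state measurably raises the reduced scattering coefficient
μs′ of blood. `lipoptics` turns a blood triglyceride (TG) concentration into
particle populations, evaluates their polydisperse Mie scattering, corrects
for dependent scattering, and predicts fasting-to-postprandial Δμs′ for
healthy, diabetic and hypertriglyceridemic TG excursions.

## Model

The reduced scattering coefficient of a polydisperse sphere suspension is

    μs′(λ) = N₀ Σᵢ f(aᵢ) · π aᵢ² · Q_scat(m, aᵢ, λ) · [1 − g(m, aᵢ, λ)]

with `N₀` the number density, `f(aᵢ)` the normalized size distribution over
radii `aᵢ`, `Q_scat` and `g` the Mie scattering efficiency and anisotropy,
and `m = n₁/n₀` the particle/medium relative refractive index. Lipoprotein
size distributions are truncated exponentials (chylomicron scale 100 nm
fasting → 200 nm postprandial over 75–1200 nm; VLDL scale 50 nm over
30–80 nm); number densities follow from the TG level via each class's TG
mass fraction, density, and mean particle volume:

    N = P / Σᵢ f(aᵢ) V(aᵢ)

Because red blood cells are crowded, independent-scattering Mie theory
overshoots; the Twersky packing-factor correction

    W = (1 − h)^(p+1) / (1 + h(p − 1))^(p−1)

(h hematocrit, p packing factor) multiplies the Mie μs′. Per-wavelength
packing factors (0.97 / 1.78 / 1.61 at 730 / 880 / 1100 nm, h = 0.33) were
fitted against intralipid-in-bovine-blood titration measurements and ship
as defaults; `fit_packing_factor` refits them from any titration CSV.

## Worked example

```python
from lipoptics import postprandial_scenarios

for r in postprandial_scenarios():
    print(f"{r.label:22s} {r.wavelength:6.0f} nm  "
          f"fasting {r.musp_baseline:.3f} -> post {r.musp_post:.3f} mm^-1  "
          f"(+{r.delta_musp_percent:.2f}%)")
```

prints

```
healthy                   730 nm  fasting 0.943 -> post 0.977 mm^-1  (+3.65%)
healthy                   880 nm  fasting 0.528 -> post 0.546 mm^-1  (+3.41%)
healthy                  1100 nm  fasting 0.694 -> post 0.711 mm^-1  (+2.44%)
type2_diabetes            730 nm  fasting 0.961 -> post 1.099 mm^-1  (+14.34%)
type2_diabetes            880 nm  fasting 0.536 -> post 0.608 mm^-1  (+13.45%)
type2_diabetes           1100 nm  fasting 0.701 -> post 0.769 mm^-1  (+9.65%)
hypertriglyceridemia      730 nm  fasting 0.961 -> post 1.585 mm^-1  (+64.88%)
hypertriglyceridemia      880 nm  fasting 0.536 -> post 0.860 mm^-1  (+60.39%)
hypertriglyceridemia     1100 nm  fasting 0.701 -> post 1.002 mm^-1  (+42.92%)
```

Each row is one subject scenario at one wavelength: the fasting μs′ of blood
(measured-blood baseline plus the Twersky-corrected fasting-TRL
contribution), the postprandial μs′ after the meal's TG is added to the
chylomicron pool (mean size 100 → 200 nm, refractive index 1.46 → 1.5), and
the percent change. A healthy post-meal excursion (+50 mg/dL TG) raises μs′
by a few percent; a hypertriglyceridemic one (+1000 mg/dL) by ~65% at
730 nm, with the effect shrinking toward longer wavelengths.

The same pipeline is available from the shell:

```bash
lipoptics predict-postprandial --out scenarios.csv
lipoptics blood-sweep --out sweep.csv
lipoptics simulate-titration --seed 1 --out titration.csv
lipoptics fit-packing titration.csv
```

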
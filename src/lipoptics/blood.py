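"""Whole-blood scattering model: RBC equivalent sphere + TRL populations.

Red blood cells dominate blood scattering; they are modelled as the
standard volume-equivalent sphere (diameter 5.56 um, number density
0.005 cells/um^3 for hematocrit 0.45, refractive index 1.4).  Adding the
chylomicron and VLDL populations of a blood lipid state and applying the
Twersky dependent-scattering correction yields mu_s, effective g and
mu_s' of whole blood, the titration-experiment predictions, the TG sweep
and the postprandial percent-change scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

from .distributions import (
    DEFAULT_N_BINS,
    intralipid_distribution,
    monodisperse,
)
from .lipoproteins import (
    BloodLipidState,
    build_trl_species,
    fasting_state,
    postprandial_state,
    volume_fraction_to_number_density,
)
from .mie import (
    N_MEDIUM_PLASMA,
    OpticalProperties,
    ParticleSpecies,
    combine_mus_g,
    mus_and_g_polydisperse,
    musp_polydisperse,
)
from .twersky import (
    BOVINE_HEMATOCRIT,
    FITTED_PACKING_FACTORS,
    TwerskyParams,
    twersky_factor,
)

__all__ = [
    "RBCParams",
    "ScenarioResult",
    "BLOOD_BASELINE_MUSP",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_SCENARIOS",
    "INTRALIPID_RI",
    "BEAD_RI",
    "rbc_species",
    "intralipid_species",
    "bead_species",
    "musp_uncorrected_intralipid",
    "whole_blood_properties",
    "tg_sweep",
    "titration_predict",
    "postprandial_scenarios",
]

DEFAULT_WAVELENGTHS = (730.0, 880.0, 1100.0)

# Measured bovine-blood baseline mu_s' (mm^-1) per wavelength, recovered
# from reported titration measurements: an 0.1% intralipid addition
# raised mu_s' by 0.089 mm^-1 (9.5%) at 730 nm, 0.042 mm^-1 (8%) at
# 880 nm and 0.036 mm^-1 (5.2%) at 1100 nm, so baseline = increment / pct.
BLOOD_BASELINE_MUSP = {
    730.0: 0.089 / 0.095,
    880.0: 0.042 / 0.080,
    1100.0: 0.036 / 0.052,
}

#: (label, fasting TG mg/dL, postprandial delta-TG mg/dL)
DEFAULT_SCENARIOS = (
    ("healthy", 50.0, 50.0),
    ("type2_diabetes", 200.0, 200.0),
    ("hypertriglyceridemia", 200.0, 1000.0),
)

INTRALIPID_RI = 1.46
BEAD_RI = 1.57  # polystyrene microspheres

#: 1 um^3 contains 1e-9 mm^3, so per-um^3 densities scale by 1e9 per mm^3.
_PER_UM3_TO_PER_MM3 = 1e9


@dataclass(frozen=True)
class RBCParams:
    """Red-blood-cell volume-equivalent sphere parameters.

    Defaults correspond to hematocrit 0.45: diameter 5.56 um, number
    density 0.005 cells/um^3, refractive index 1.4.
    """

    equivalent_diameter: float = 5560.0  # nm
    number_density: float = 0.005  # per um^3
    refractive_index: float = 1.4


@dataclass(frozen=True)
class ScenarioResult:
    """Fasting/postprandial mu_s' of one scenario at one wavelength."""

    label: str
    wavelength: float
    musp_baseline: float  # mm^-1, fasting total (blood + fasting TRLs)
    musp_post: float  # mm^-1, postprandial total
    delta_musp_percent: float


def rbc_species(rbc: RBCParams = RBCParams()) -> ParticleSpecies:
    """RBC population as a monodisperse equivalent-sphere species."""
    return ParticleSpecies(
        n_particle=rbc.refractive_index,
        distribution=monodisperse(rbc.equivalent_diameter),
        number_density=rbc.number_density * _PER_UM3_TO_PER_MM3,
        name="RBC",
    )


def intralipid_species(
    volume_fraction: float,
    n_bins: int = DEFAULT_N_BINS,
    convention: str = "volume_of_mean",
) -> ParticleSpecies:
    """Intralipid micelles at a given volume fraction (v/v).

    The default number-density normalization divides by the volume of the
    mean-size (97 nm) micelle; see
    :func:`lipoptics.lipoproteins.volume_fraction_to_number_density`.
    """
    dist = intralipid_distribution(n_bins)
    return ParticleSpecies(
        n_particle=INTRALIPID_RI,
        distribution=dist,
        number_density=volume_fraction_to_number_density(
            volume_fraction, dist, convention
        ),
        name="intralipid",
    )


def bead_species(diameter: float, volume_fraction: float) -> ParticleSpecies:
    """Monodisperse polystyrene beads at a given volume fraction (v/v)."""
    dist = monodisperse(diameter)
    return ParticleSpecies(
        n_particle=BEAD_RI,
        distribution=dist,
        number_density=volume_fraction_to_number_density(volume_fraction, dist),
        name=f"bead_{diameter:g}nm",
    )


def musp_uncorrected_intralipid(
    volume_fraction: float,
    wavelength: float,
    n_medium: float = N_MEDIUM_PLASMA,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Independent-scattering Mie delta mu_s' of an intralipid addition."""
    if volume_fraction == 0:
        return 0.0
    return musp_polydisperse(
        intralipid_species(volume_fraction, n_bins), n_medium, wavelength
    )


def _packing(wavelength: float,
             packing_factors: Mapping[float, float] | None) -> float:
    table = FITTED_PACKING_FACTORS if packing_factors is None else packing_factors
    try:
        return table[float(wavelength)]
    except KeyError:
        raise KeyError(
            f"no packing factor for wavelength {wavelength} nm; "
            "supply packing_factors explicitly"
        ) from None


def whole_blood_properties(
    state: BloodLipidState,
    rbc: RBCParams = RBCParams(),
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    packing_factors: Mapping[float, float] | None = None,
    n_medium: float = N_MEDIUM_PLASMA,
    n_bins: int = DEFAULT_N_BINS,
) -> dict[float, OpticalProperties]:
    """Twersky-corrected mu_s, g and mu_s' of whole blood per wavelength.

    Combines the RBC equivalent sphere with the state's chylomicron and
    VLDL populations; the mixture anisotropy is the mu_s-weighted mean of
    the species anisotropies, and the Twersky factor (state hematocrit,
    per-wavelength packing factor) multiplies the full mu_s and mu_s'.
    """
    species = [rbc_species(rbc)] + build_trl_species(state, n_bins)
    out: dict[float, OpticalProperties] = {}
    for wl in wavelengths:
        components = [
            mus_and_g_polydisperse(sp, n_medium, wl) for sp in species
        ]
        mus, g_eff, musp = combine_mus_g(components)
        w = twersky_factor(
            TwerskyParams(state.hematocrit, _packing(wl, packing_factors))
        )
        out[float(wl)] = OpticalProperties(
            wavelength=float(wl), mus=mus * w, g=g_eff, musp=musp * w
        )
    return out


def tg_sweep(
    start_tg: float = 50.0,
    step_tg: float = 50.0,
    n_steps: int = 11,
    size_step: float = 5.0,
    ri_ramp: tuple[float, float] = (1.46, 1.5),
    rbc: RBCParams = RBCParams(),
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    hematocrit: float = 0.45,
    packing_factors: Mapping[float, float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> list[dict]:
    """Whole-blood properties along a postprandial TG ramp.

    Step 0 is the fasting state at ``start_tg`` with chylomicron mean
    size 100 nm and RI ``ri_ramp[0]``; each further step adds ``step_tg``
    of TG (all to chylomicrons), grows the chylomicron mean size by
    ``size_step`` and ramps the chylomicron RI linearly to ``ri_ramp[1]``
    at the last step.  Returns one record per step with the per-wavelength
    :class:`~lipoptics.mie.OpticalProperties`.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    base = fasting_state(start_tg, hematocrit=hematocrit)
    results = []
    for k in range(n_steps):
        tg = start_tg + k * step_tg
        cm_tg = base.cm_tg + k * step_tg
        frac = ri_ramp[0] if n_steps == 1 else (
            ri_ramp[0] + (ri_ramp[1] - ri_ramp[0]) * k / (n_steps - 1)
        )
        cm_mean = base.chylomicron.mean_diameter + k * size_step
        state = BloodLipidState(
            tg_total=tg,
            cm_tg_fraction=cm_tg / tg if tg > 0 else 0.0,
            chylomicron=replace(
                base.chylomicron, mean_diameter=cm_mean, refractive_index=frac
            ),
            vldl=base.vldl,
            hematocrit=hematocrit,
        )
        props = whole_blood_properties(
            state, rbc, wavelengths, packing_factors, n_bins=n_bins
        )
        results.append(
            {
                "step": k,
                "tg_total": tg,
                "cm_mean_diameter": cm_mean,
                "cm_refractive_index": frac,
                "properties": props,
            }
        )
    return results


def titration_predict(
    species_builder: Callable[[float], ParticleSpecies],
    concentrations: Sequence[float],
    baseline_musp: Mapping[float, float],
    twersky: Mapping[float, TwerskyParams],
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    n_medium: float = N_MEDIUM_PLASMA,
) -> dict[float, list[float]]:
    """Predicted mu_s' titration curves: baseline + W * Mie delta mu_s'.

    The Twersky factor multiplies only the added-particle contribution;
    the measured blood baseline is taken as-is.
    """
    conc = [float(c) for c in concentrations]
    if any(c < 0 for c in conc):
        raise ValueError("concentrations must be non-negative")
    if any(b >= a for a, b in zip(conc[1:], conc[:-1])):
        raise ValueError("concentrations must be increasing")
    out: dict[float, list[float]] = {}
    for wl in wavelengths:
        wl = float(wl)
        w = twersky_factor(twersky[wl])
        curve = []
        for c in conc:
            if c == 0:
                curve.append(baseline_musp[wl])
                continue
            delta = musp_polydisperse(species_builder(c), n_medium, wl)
            curve.append(baseline_musp[wl] + w * delta)
        out[wl] = curve
    return out


def postprandial_scenarios(
    scenarios: Sequence[tuple[str, float, float]] = DEFAULT_SCENARIOS,
    baseline_musp: Mapping[float, float] | None = None,
    hematocrit: float = BOVINE_HEMATOCRIT,
    packing_factors: Mapping[float, float] | None = None,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
    n_medium: float = N_MEDIUM_PLASMA,
    n_bins: int = DEFAULT_N_BINS,
) -> list[ScenarioResult]:
    """Postprandial percent change in blood mu_s' per scenario and wavelength.

    For each scenario the Twersky-corrected TRL mu_s' (fasting and
    postprandial) is added to the measured blood baseline; the percent
    change is taken relative to the fasting total (baseline + fasting
    TRL contribution).
    """
    if baseline_musp is None:
        baseline_musp = BLOOD_BASELINE_MUSP
    results = []
    for label, fasting_tg, delta_tg in scenarios:
        fast = fasting_state(fasting_tg, hematocrit=hematocrit)
        post = postprandial_state(fast, delta_tg)
        for wl in wavelengths:
            wl = float(wl)
            w = twersky_factor(
                TwerskyParams(hematocrit, _packing(wl, packing_factors))
            )
            musp_fast = baseline_musp[wl] + w * sum(
                musp_polydisperse(sp, n_medium, wl)
                for sp in build_trl_species(fast, n_bins)
            )
            musp_post = baseline_musp[wl] + w * sum(
                musp_polydisperse(sp, n_medium, wl)
                for sp in build_trl_species(post, n_bins)
            )
            results.append(
                ScenarioResult(
                    label=label,
                    wavelength=wl,
                    musp_baseline=musp_fast,
                    musp_post=musp_post,
                    delta_musp_percent=100.0 * (musp_post - musp_fast) / musp_fast,
                )
            )
    return results
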
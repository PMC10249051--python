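"""Triglyceride-rich lipoprotein (TRL) populations from blood TG levels.

Chylomicrons and VLDLs carry most of the triglyceride (TG) in blood.
Given a total TG concentration, this module splits it between the two
particle classes, converts each class's TG mass to a particle volume
fraction (via TG mass fraction and particle density), and then to a
number density via the mean particle volume of the class's size
distribution:

    N = P / sum_i f(a_i) V(a_i),

where P is the particle volume per unit volume of blood, f the normalized
size distribution and V(a) = (4/3) pi a^3.

Literature parameter set (fasting): chylomicrons 75-1200 nm with 100 nm
exponential mean, density 0.93 g/ml, 90% TG by mass, RI 1.46; VLDL
30-80 nm with 50 nm mean, density 1.00 g/ml, 50% TG, RI 1.46; 30% of
fasting TG in chylomicrons, 70% in VLDL.  Postprandially the chylomicron
mean size grows to 200 nm and its RI to 1.5; VLDL is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .distributions import DEFAULT_N_BINS, exponential_distribution
from .mie import MM3_PER_NM3, ParticleSpecies, SizeDistribution

__all__ = [
    "LipoproteinParams",
    "BloodLipidState",
    "CHYLOMICRON_FASTING",
    "CHYLOMICRON_POSTPRANDIAL_MEAN_NM",
    "CHYLOMICRON_POSTPRANDIAL_RI",
    "VLDL_DEFAULT",
    "FASTING_CM_TG_FRACTION",
    "tg_to_volume_fraction",
    "volume_fraction_to_number_density",
    "build_trl_species",
    "fasting_state",
    "postprandial_state",
    "implied_tg_total",
]

# 1 mg/dL = 0.01 mg/mL; densities in g/ml = 1000 mg/mL
_MGDL_TO_MG_PER_ML = 0.01
_GML_TO_MG_PER_ML = 1000.0


@dataclass(frozen=True)
class LipoproteinParams:
    """Physical parameters of one lipoprotein class."""

    name: str
    mean_diameter: float  # nm, exponential scale parameter
    d_min: float  # nm
    d_max: float  # nm
    density: float  # g/ml
    tg_mass_fraction: float  # fraction of particle mass that is TG
    refractive_index: float

    def __post_init__(self):
        if not (0.0 < self.tg_mass_fraction <= 1.0):
            raise ValueError("tg_mass_fraction must be in (0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.d_min >= self.d_max:
            raise ValueError("d_min must be below d_max")

    def distribution(self, n_bins: int = DEFAULT_N_BINS) -> SizeDistribution:
        return exponential_distribution(
            self.mean_diameter, self.d_min, self.d_max, n_bins
        )


CHYLOMICRON_FASTING = LipoproteinParams(
    name="chylomicron",
    mean_diameter=100.0,
    d_min=75.0,
    d_max=1200.0,
    density=0.93,
    tg_mass_fraction=0.90,
    refractive_index=1.46,
)

VLDL_DEFAULT = LipoproteinParams(
    name="VLDL",
    mean_diameter=50.0,
    d_min=30.0,
    d_max=80.0,
    density=1.00,
    tg_mass_fraction=0.50,
    refractive_index=1.46,
)

#: Postprandial chylomicron exponential mean size and peak refractive index.
CHYLOMICRON_POSTPRANDIAL_MEAN_NM = 200.0
CHYLOMICRON_POSTPRANDIAL_RI = 1.5

#: Fraction of fasting TG carried by chylomicrons (remainder in VLDL).
FASTING_CM_TG_FRACTION = 0.30


@dataclass(frozen=True)
class BloodLipidState:
    """Blood TG level plus the TRL model parameters that realize it.

    ``cm_tg_fraction`` is the fraction of ``tg_total`` carried by
    chylomicrons; the rest is in VLDL.
    """

    tg_total: float  # mg/dL
    cm_tg_fraction: float
    chylomicron: LipoproteinParams
    vldl: LipoproteinParams
    hematocrit: float

    def __post_init__(self):
        if self.tg_total < 0:
            raise ValueError("tg_total must be >= 0")
        if not (0.0 <= self.cm_tg_fraction <= 1.0):
            raise ValueError("cm_tg_fraction must be in [0, 1]")
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in [0, 1)")

    @property
    def cm_tg(self) -> float:
        """TG carried by chylomicrons, mg/dL."""
        return self.tg_total * self.cm_tg_fraction

    @property
    def vldl_tg(self) -> float:
        """TG carried by VLDL, mg/dL."""
        return self.tg_total * (1.0 - self.cm_tg_fraction)


def tg_to_volume_fraction(tg_in_species: float,
                          params: LipoproteinParams) -> float:
    """Particle volume fraction implied by the TG mass of one class.

    TG mass (mg/dL) is scaled up to total particle mass by the class's TG
    mass fraction, converted to mg/mL, and divided by the particle density
    (mg/mL) to give a dimensionless volume fraction.
    """
    if tg_in_species < 0:
        raise ValueError("tg_in_species must be >= 0")
    particle_mass_mg_per_ml = (
        tg_in_species / params.tg_mass_fraction * _MGDL_TO_MG_PER_ML
    )
    return particle_mass_mg_per_ml / (params.density * _GML_TO_MG_PER_ML)


def volume_fraction_to_number_density(
    volume_fraction: float,
    distribution: SizeDistribution,
    convention: str = "mean_volume",
) -> float:
    """Particles per mm^3 occupying ``volume_fraction`` of the suspension.

    ``convention`` selects the per-particle volume used as the divisor:

    ``"mean_volume"``
        The distribution-weighted mean particle volume, sum_i f(a_i) V(a_i)
        — the exact inverse of the volume bookkeeping (default; used for
        the lipoprotein populations).
    ``"volume_of_mean"``
        The volume of the mean-size particle, V(d_bar/2).  For a
        heavy-tailed distribution this is several-fold smaller, giving a
        correspondingly higher number density.  This is the normalization
        under which the Twersky-corrected intralipid predictions line up
        with the measured titration increments at every wavelength, and
        is therefore the default for the intralipid species.
    """
    if volume_fraction < 0:
        raise ValueError("volume_fraction must be >= 0")
    if convention == "mean_volume":
        volume_nm3 = distribution.mean_volume()
    elif convention == "volume_of_mean":
        radius = distribution.mean_diameter / 2.0
        volume_nm3 = (4.0 / 3.0) * np.pi * radius**3
    else:
        raise ValueError(f"unknown convention {convention!r}")
    volume_mm3 = volume_nm3 * MM3_PER_NM3
    if volume_mm3 <= 0:
        raise ValueError("distribution has zero mean particle volume")
    return volume_fraction / volume_mm3


def _species_from_params(
    tg_in_species: float, params: LipoproteinParams, n_bins: int
) -> ParticleSpecies:
    dist = params.distribution(n_bins)
    vf = tg_to_volume_fraction(tg_in_species, params)
    return ParticleSpecies(
        n_particle=params.refractive_index,
        distribution=dist,
        number_density=volume_fraction_to_number_density(vf, dist),
        name=params.name,
    )


def build_trl_species(
    state: BloodLipidState, n_bins: int = DEFAULT_N_BINS
) -> list[ParticleSpecies]:
    """Chylomicron and VLDL particle populations for a blood lipid state."""
    return [
        _species_from_params(state.cm_tg, state.chylomicron, n_bins),
        _species_from_params(state.vldl_tg, state.vldl, n_bins),
    ]


def fasting_state(
    tg_total: float,
    hematocrit: float = 0.33,
    cm_tg_fraction: float = FASTING_CM_TG_FRACTION,
) -> BloodLipidState:
    """Fasting blood lipid state with the literature defaults."""
    return BloodLipidState(
        tg_total=tg_total,
        cm_tg_fraction=cm_tg_fraction,
        chylomicron=CHYLOMICRON_FASTING,
        vldl=VLDL_DEFAULT,
        hematocrit=hematocrit,
    )


def postprandial_state(
    fasting: BloodLipidState,
    delta_tg: float,
    cm_mean_diameter: float = CHYLOMICRON_POSTPRANDIAL_MEAN_NM,
    cm_refractive_index: float = CHYLOMICRON_POSTPRANDIAL_RI,
) -> BloodLipidState:
    """Post-meal state: added TG goes to chylomicrons, which grow and densify.

    All of ``delta_tg`` is assigned to the chylomicron class (a meal's
    dietary fat enters the blood as chylomicrons); the fasting VLDL TG is
    held fixed.  The chylomicron exponential mean size and refractive
    index are set to their postprandial values while the size range is
    unchanged.
    """
    if delta_tg < 0:
        raise ValueError("delta_tg must be >= 0")
    tg_total = fasting.tg_total + delta_tg
    cm_tg = fasting.cm_tg + delta_tg
    cm_fraction = cm_tg / tg_total if tg_total > 0 else 0.0
    cm_params = replace(
        fasting.chylomicron,
        mean_diameter=cm_mean_diameter,
        refractive_index=cm_refractive_index,
    )
    return BloodLipidState(
        tg_total=tg_total,
        cm_tg_fraction=cm_fraction,
        chylomicron=cm_params,
        vldl=fasting.vldl,
        hematocrit=fasting.hematocrit,
    )


def implied_tg_total(state: BloodLipidState,
                     n_bins: int = DEFAULT_N_BINS) -> float:
    """TG (mg/dL) implied by the generated particle populations.

    Inverse of the TG -> number-density chain; used to verify mass
    conservation.
    """
    total = 0.0
    for params, species in zip(
        (state.chylomicron, state.vldl), build_trl_species(state, n_bins)
    ):
        vf = species.number_density * species.distribution.mean_volume() * MM3_PER_NM3
        mass_mg_per_ml = vf * params.density * _GML_TO_MG_PER_ML
        total += mass_mg_per_ml * params.tg_mass_fraction / _MGDL_TO_MG_PER_ML
    return total
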
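"""Mie core: single-sphere quantities and polydisperse mu_s'."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _mie_reference import mie_reference
from lipoptics.distributions import intralipid_distribution, monodisperse
from lipoptics.lipoproteins import volume_fraction_to_number_density
from lipoptics.mie import (
    N_MEDIUM_PLASMA,
    ParticleSpecies,
    SizeDistribution,
    combine_mus_g,
    mie_single,
    mus_and_g_polydisperse,
    musp_polydisperse,
)

N_MED = N_MEDIUM_PLASMA


def _radius_for_x(x, wavelength=730.0, n_medium=N_MED):
    return x * wavelength / (2.0 * np.pi * n_medium)


def test_agrees_with_independent_reference_across_regimes():
    """50 random spheres with x < 50 match the scipy-Bessel reference
    implementation in Qscat and g to 1e-6 relative."""
    rng = np.random.default_rng(20230608)
    for _ in range(50):
        x = rng.uniform(0.1, 45.0)
        m = rng.uniform(1.02, 1.2)
        wavelength = rng.uniform(500.0, 1200.0)
        radius = x * wavelength / (2.0 * np.pi * N_MED)
        res = mie_single(radius, m * N_MED, N_MED, wavelength)
        q_ref, _, g_ref = mie_reference(m, x)
        assert res.q_scat == pytest.approx(q_ref, rel=1e-6)
        assert res.g == pytest.approx(g_ref, rel=1e-6)


def test_rayleigh_limit_small_spheres():
    """For x < 0.05, Qscat approaches the closed-form Rayleigh expression
    and scattering becomes isotropic (g ~ 0)."""
    m = 1.46 / N_MED
    for x in (0.01, 0.03, 0.049):
        radius = _radius_for_x(x)
        expected = (8.0 / 3.0) * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        res = mie_single(radius, 1.46, N_MED, 730.0)
        assert res.q_scat == pytest.approx(expected, rel=0.01)
        assert abs(res.g) < 0.01


def test_index_matched_sphere_does_not_scatter():
    res = mie_single(500.0, N_MED, N_MED, 730.0)
    assert res.q_scat == 0.0
    assert res.g == 0.0


def test_extinction_equals_scattering_for_real_index():
    # non-absorbing spheres: Qext = Qscat up to roundoff
    for radius in (50.0, 500.0, 2780.0):
        res = mie_single(radius, 1.4, N_MED, 730.0)
        assert res.q_ext == pytest.approx(res.q_scat, rel=1e-9)
        assert -1.0 <= res.g <= 1.0


@pytest.mark.parametrize("bad", [
    {"radius": -1.0},
    {"radius": 0.0},
    {"wavelength_vacuum": 0.0},
    {"n_particle": -1.0},
])
def test_invalid_inputs_rejected(bad):
    kwargs = dict(radius=100.0, n_particle=1.46, n_medium=N_MED,
                  wavelength_vacuum=730.0)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        mie_single(**kwargs)


def test_monodisperse_musp_collapses_to_single_term():
    dist = monodisperse(500.0)
    species = ParticleSpecies(1.57, dist, number_density=1e6)
    res = mie_single(250.0, 1.57, N_MED, 730.0)
    expected = 1e6 * np.pi * 250.0**2 * 1e-12 * res.q_scat * (1 - res.g)
    assert musp_polydisperse(species, N_MED, 730.0) == pytest.approx(
        expected, rel=1e-12
    )
    mus, g = mus_and_g_polydisperse(species, N_MED, 730.0)
    assert mus == pytest.approx(1e6 * np.pi * 250.0**2 * 1e-12 * res.q_scat)
    assert g == pytest.approx(res.g)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(factor=st.floats(0.1, 100.0))
def test_musp_linear_in_number_density(factor):
    dist = monodisperse(300.0)
    base = ParticleSpecies(1.46, dist, number_density=1e5)
    scaled = ParticleSpecies(1.46, dist, number_density=1e5 * factor)
    assert musp_polydisperse(scaled, N_MED, 880.0) == pytest.approx(
        factor * musp_polydisperse(base, N_MED, 880.0), rel=1e-12
    )


def test_polydisperse_sum_converges_on_refined_grid(intralipid_dist):
    """The discrete size sum at the default resolution agrees with a 10x
    finer quadrature of the same distribution within 0.5%."""
    vf = 0.001
    coarse = intralipid_dist
    fine = intralipid_distribution(n_bins=2000)
    musps = []
    for dist in (coarse, fine):
        n = volume_fraction_to_number_density(vf, dist)
        musps.append(
            musp_polydisperse(ParticleSpecies(1.46, dist, n), N_MED, 730.0)
        )
    assert musps[0] == pytest.approx(musps[1], rel=0.005)


def test_musp_equals_mus_times_one_minus_g(intralipid_dist):
    species = ParticleSpecies(1.46, intralipid_dist, number_density=1e9)
    mus, g = mus_and_g_polydisperse(species, N_MED, 730.0)
    assert mus * (1 - g) == pytest.approx(
        musp_polydisperse(species, N_MED, 730.0), rel=1e-12
    )
    assert mus >= musp_polydisperse(species, N_MED, 730.0)


def test_mixture_anisotropy_lies_between_component_values():
    # forward-peaked RBC-sized spheres vs nearly isotropic 100 nm spheres
    big = ParticleSpecies(1.4, monodisperse(5560.0), number_density=5e6)
    small = ParticleSpecies(1.46, monodisperse(100.0), number_density=1e9)
    comp = [
        mus_and_g_polydisperse(sp, N_MED, 730.0) for sp in (big, small)
    ]
    g_vals = sorted(g for _, g in comp)
    _, g_eff, _ = combine_mus_g(comp)
    assert g_vals[0] < g_eff < g_vals[1]


def test_mixture_of_equal_anisotropies_preserves_g():
    comp = [(1.0, 0.8), (2.5, 0.8)]
    _, g_eff, _ = combine_mus_g(comp)
    assert g_eff == pytest.approx(0.8, rel=1e-12)


def test_size_distribution_validation():
    with pytest.raises(ValueError):
        SizeDistribution(radii=np.array([2.0, 1.0]),
                         weights=np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        SizeDistribution(radii=np.array([1.0, 2.0]),
                         weights=np.array([0.7, 0.7]))
    with pytest.raises(ValueError):
        SizeDistribution(radii=np.array([-1.0, 2.0]),
                         weights=np.array([0.5, 0.5]))
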
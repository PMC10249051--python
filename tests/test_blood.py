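"""Whole-blood model: RBC + TRL mixtures, titration and scenario tables."""

import pytest

from lipoptics.blood import (
    BLOOD_BASELINE_MUSP,
    bead_species,
    postprandial_scenarios,
    rbc_species,
    tg_sweep,
    titration_predict,
    whole_blood_properties,
)
from lipoptics.lipoproteins import fasting_state
from lipoptics.mie import N_MEDIUM_PLASMA, mus_and_g_polydisperse
from lipoptics.twersky import TwerskyParams, twersky_factor


def test_zero_tg_reduces_to_rbc_suspension(rbc):
    state = fasting_state(0.0, hematocrit=0.45)
    props = whole_blood_properties(state, rbc, wavelengths=(730.0,))[730.0]
    mus_rbc, g_rbc = mus_and_g_polydisperse(
        rbc_species(rbc), N_MEDIUM_PLASMA, 730.0
    )
    w = twersky_factor(TwerskyParams(0.45, 0.97))
    assert props.mus == pytest.approx(mus_rbc * w, rel=1e-12)
    assert props.g == pytest.approx(g_rbc, rel=1e-12)
    assert props.musp == pytest.approx(mus_rbc * (1 - g_rbc) * w, rel=1e-12)


def test_musp_rises_and_g_falls_with_tg(rbc):
    lo = fasting_state(50.0, hematocrit=0.45)
    hi = fasting_state(500.0, hematocrit=0.45)
    p_lo = whole_blood_properties(lo, rbc, wavelengths=(730.0,))[730.0]
    p_hi = whole_blood_properties(hi, rbc, wavelengths=(730.0,))[730.0]
    assert p_hi.musp > p_lo.musp
    assert p_hi.g < p_lo.g


def test_sweep_starts_at_fasting_state():
    sweep = tg_sweep(n_steps=3, wavelengths=(730.0,))
    first = sweep[0]
    assert first["tg_total"] == 50.0
    assert first["cm_mean_diameter"] == 100.0
    assert first["cm_refractive_index"] == 1.46
    assert sweep[-1]["cm_refractive_index"] == 1.5
    for rec in sweep:
        p = rec["properties"][730.0]
        assert p.musp == pytest.approx(p.mus * (1 - p.g), rel=1e-9)


def test_titration_zero_concentration_returns_baseline():
    twersky = {730.0: TwerskyParams(0.33, 0.97)}
    curves = titration_predict(
        lambda c: bead_species(500.0, c),
        [0.0, 0.001, 0.002],
        {730.0: 0.937},
        twersky,
        wavelengths=(730.0,),
    )[730.0]
    assert curves[0] == 0.937
    assert curves[1] > curves[0]
    assert curves[2] > curves[1]


def test_bead_size_effect_saturates():
    """mu_s' grows with bead size at equal concentration, with the
    100->500 nm jump exceeding the 500->1000 nm jump."""
    twersky = {730.0: TwerskyParams(0.33, 0.97)}
    base = {730.0: BLOOD_BASELINE_MUSP[730.0]}
    vals = {}
    for diam in (100.0, 500.0, 1000.0):
        vals[diam] = titration_predict(
            lambda c, d=diam: bead_species(d, c),
            [0.003],
            base,
            twersky,
            wavelengths=(730.0,),
        )[730.0][0]
    # at 730 nm the 1000 nm point sits on a Mie oscillation below the
    # 500 nm one, so only the 100 -> 500 nm rise and the gap ordering
    # are asserted
    assert vals[100.0] < vals[500.0]
    assert vals[500.0] - vals[100.0] > vals[1000.0] - vals[500.0]


def test_scenarios_zero_delta_gives_zero_percent():
    results = postprandial_scenarios([("null", 100.0, 0.0)])
    # delta 0 still applies the postprandial size/RI change, so restrict
    # to a scenario with no TRLs at all for the exact-zero check
    results_empty = postprandial_scenarios([("empty", 0.0, 0.0)])
    for r in results_empty:
        assert r.delta_musp_percent == pytest.approx(0.0, abs=1e-12)
        assert r.musp_baseline == pytest.approx(
            BLOOD_BASELINE_MUSP[r.wavelength], rel=1e-12
        )
    for r in results:
        assert r.delta_musp_percent >= 0.0


def test_scenario_percent_identity():
    for r in postprandial_scenarios([("healthy", 50.0, 50.0)]):
        assert r.delta_musp_percent == pytest.approx(
            100.0 * (r.musp_post - r.musp_baseline) / r.musp_baseline,
            abs=1e-9,
        )


def test_unknown_wavelength_needs_explicit_packing():
    state = fasting_state(100.0, hematocrit=0.45)
    with pytest.raises(KeyError):
        whole_blood_properties(state, wavelengths=(650.0,))
    props = whole_blood_properties(
        state, wavelengths=(650.0,), packing_factors={650.0: 1.0}
    )
    assert props[650.0].musp > 0
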
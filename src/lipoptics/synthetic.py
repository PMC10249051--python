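"""Synthetic titration datasets emulating the diffuse-optics measurements.

Real mu_s' titration curves come from spatial frequency domain imaging of
additive-in-blood mixtures.  This module generates stand-ins from the
package's own forward model (baseline + Twersky-corrected Mie delta
mu_s') with additive zero-mean Gaussian noise, so the packing-factor
fitting pipeline can be exercised and validated end to end without
instrument data.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .blood import (
    BLOOD_BASELINE_MUSP,
    DEFAULT_WAVELENGTHS,
    bead_species,
    intralipid_species,
    titration_predict,
)
from .datasets import TitrationDataset
from .twersky import BOVINE_HEMATOCRIT, TwerskyParams

__all__ = ["generate_titration", "default_blood_baseline",
           "DEFAULT_NOISE_SIGMA"]

#: Default measurement-noise std, mm^-1 — the order of the reported
#: model-vs-measurement mean absolute errors (0.012-0.098 mm^-1).
DEFAULT_NOISE_SIGMA = 0.02


def default_blood_baseline(
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
) -> dict[float, float]:
    """Bovine-blood baseline mu_s' (mm^-1) at the standard wavelengths.

    Values are derived from reported titration increment/percent pairs
    (see :data:`lipoptics.blood.BLOOD_BASELINE_MUSP`); other wavelengths
    require a user-supplied baseline.
    """
    out = {}
    for wl in wavelengths:
        wl = float(wl)
        if wl not in BLOOD_BASELINE_MUSP:
            raise KeyError(
                f"no derived baseline for {wl} nm; supply one explicitly"
            )
        out[wl] = BLOOD_BASELINE_MUSP[wl]
    return out


def generate_titration(
    true_packing: Mapping[float, float] | None = None,
    hematocrit: float = BOVINE_HEMATOCRIT,
    baseline_musp: Mapping[float, float] | None = None,
    additive: str = "intralipid",
    bead_diameter: float | None = None,
    concentrations: Sequence[float] = tuple(
        np.round(np.arange(0.001, 0.0101, 0.001), 6)
    ),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
) -> list[TitrationDataset]:
    """Synthetic mu_s' titration curves, one dataset per wavelength.

    The forward model is :func:`lipoptics.blood.titration_predict` with
    the given packing factors; Gaussian noise of std ``noise_sigma`` is
    added independently per point.  Default concentrations are the
    intralipid titration's 0.1%-1% (v/v) in 0.1% steps.

    Parameters
    ----------
    additive : {"intralipid", "bead"}
        Additive particle type; ``bead`` requires ``bead_diameter`` (nm).
    """
    from .twersky import FITTED_PACKING_FACTORS

    if true_packing is None:
        true_packing = FITTED_PACKING_FACTORS
    if baseline_musp is None:
        baseline_musp = default_blood_baseline(wavelengths)
    if additive == "intralipid":
        builder = intralipid_species
    elif additive == "bead":
        if bead_diameter is None:
            raise ValueError("bead additive requires bead_diameter")
        builder = lambda c: bead_species(bead_diameter, c)  # noqa: E731
    else:
        raise ValueError(f"unknown additive {additive!r}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    twersky = {
        float(wl): TwerskyParams(hematocrit, true_packing[float(wl)])
        for wl in wavelengths
    }
    curves = titration_predict(
        builder, concentrations, baseline_musp, twersky, wavelengths
    )
    rng = np.random.default_rng(seed)
    datasets = []
    for wl in wavelengths:
        wl = float(wl)
        clean = np.asarray(curves[wl])
        noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
        datasets.append(
            TitrationDataset(
                wavelength=wl,
                concentrations=np.asarray(concentrations, dtype=float),
                musp_measured=noisy,
                noise_sigma=noise_sigma,
                seed=seed,
            )
        )
    return datasets
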
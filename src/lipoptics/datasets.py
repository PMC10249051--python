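"""Container for titration measurements (mu_s' vs additive concentration)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TitrationDataset"]


@dataclass(frozen=True)
class TitrationDataset:
    """Per-wavelength mu_s' measurements along an additive titration.

    Attributes
    ----------
    wavelength : float
        Measurement wavelength, nm.
    concentrations : array of float
        Additive volume fractions (v/v, dimensionless), strictly increasing.
    musp_measured : array of float
        Measured (or synthetic) mu_s' in mm^-1, one per concentration.
    noise_sigma : float
        Std of the additive Gaussian measurement noise used to generate
        the data (0 for real/noiseless data), mm^-1.
    seed : int or None
        RNG seed used for generation, if synthetic.
    """

    wavelength: float
    concentrations: np.ndarray
    musp_measured: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        musp = np.asarray(self.musp_measured, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "musp_measured", musp)
        if conc.shape != musp.shape:
            raise ValueError("concentrations and musp_measured lengths differ")
        if conc.size > 1 and np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
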
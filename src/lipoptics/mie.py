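"""Single-sphere Mie quantities and polydisperse reduced scattering.

The central quantity is the reduced scattering coefficient of a suspension
of polydisperse spheres,

    mu_s'(lambda) = N0 * sum_i f(a_i) * pi a_i^2 * Qscat(m, a_i, lambda)
                         * [1 - g(m, a_i, lambda)],

where ``N0`` is the particle number density, ``f(a_i)`` the normalized size
distribution over radii ``a_i``, ``Qscat`` the Mie scattering efficiency,
``g`` the anisotropy (mean cosine of the scattering angle) and
``m = n_particle / n_medium`` the relative refractive index.

Unit convention (used package-wide): radii and wavelengths in nm, number
densities per mm^3, scattering coefficients in mm^-1.  All refractive
indices are treated as real (non-absorbing particles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MieResult",
    "SizeDistribution",
    "ParticleSpecies",
    "OpticalProperties",
    "mie_single",
    "musp_polydisperse",
    "mus_and_g_polydisperse",
    "combine_mus_g",
    "N_MEDIUM_PLASMA",
    "MM2_PER_NM2",
    "MM3_PER_NM3",
]

#: Refractive index of blood plasma / water, held constant across the NIR.
N_MEDIUM_PLASMA = 1.345

#: Area conversion: 1 nm^2 expressed in mm^2.
MM2_PER_NM2 = 1e-12
#: Volume conversion: 1 nm^3 expressed in mm^3.
MM3_PER_NM3 = 1e-18

#: Relative-index mismatch below which a particle is treated as index
#: matched (zero scattering, g = 0 by convention).
_INDEX_MATCH_TOL = 1e-12


@dataclass(frozen=True)
class MieResult:
    """Mie efficiencies and anisotropy of a single sphere.

    Attributes
    ----------
    q_scat : float
        Scattering efficiency (scattering cross-section over geometric
        cross-section), dimensionless, >= 0.
    q_ext : float
        Extinction efficiency; equals ``q_scat`` for real refractive
        indices up to numerical tolerance.
    g : float
        Anisotropy factor, mean cosine of the scattering angle, in [-1, 1].
    """

    q_scat: float
    q_ext: float
    g: float


@dataclass(frozen=True)
class SizeDistribution:
    """Discretized, normalized particle-size distribution.

    Parameters
    ----------
    radii : array of float
        Particle radii in nm, strictly increasing, all positive.
    weights : array of float
        Probability mass per radius bin; non-negative, summing to 1
        within 1e-9.
    """

    radii: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "weights", weights)
        if radii.ndim != 1 or radii.size == 0:
            raise ValueError("radii must be a non-empty 1-D array")
        if radii.shape != weights.shape:
            raise ValueError("radii and weights must have matching shapes")
        if np.any(radii <= 0):
            raise ValueError("all radii must be positive")
        if radii.size > 1 and np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    @property
    def mean_diameter(self) -> float:
        """Weighted mean particle diameter in nm."""
        return float(2.0 * np.sum(self.radii * self.weights))

    def mean_volume(self) -> float:
        """Weighted mean particle volume, nm^3."""
        return float(np.sum(self.weights * (4.0 / 3.0) * np.pi * self.radii**3))


@dataclass(frozen=True)
class ParticleSpecies:
    """A scatterer population: refractive index, sizes, number density.

    ``number_density`` is particles per mm^3 of suspension.
    """

    n_particle: float
    distribution: SizeDistribution
    number_density: float
    name: str = ""

    def __post_init__(self):
        if self.number_density < 0:
            raise ValueError("number_density must be >= 0")
        if self.n_particle <= 1:
            raise ValueError("n_particle must exceed 1 (denser than vacuum)")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength scattering summary of a suspension.

    ``musp == mus * (1 - g)`` holds by construction.
    """

    wavelength: float
    mus: float
    g: float
    musp: float


def _lentz_start(nmax: int, mx: float) -> int:
    # starting order for the downward logarithmic-derivative recurrence
    return max(nmax, int(abs(mx))) + 16


def _mie_efficiencies(m: float, x: float) -> tuple[float, float, float]:
    """Qscat, Qext and g for relative index ``m`` and size parameter ``x``.

    Bohren-Huffman scheme: the logarithmic derivative D_n(mx) by downward
    recurrence, Riccati-Bessel functions psi_n(x), chi_n(x) by upward
    recurrence, series truncated at the Wiscombe order
    ``nmax = x + 4 x^{1/3} + 2``.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x

    # log derivative D_n(mx), downward (stable) recurrence
    nstart = _lentz_start(nmax, mx)
    D = np.zeros(nmax + 1)
    d = 0.0
    for n in range(nstart, 0, -1):
        rn = n / mx
        # D_{n-1} = n/mx - 1 / (D_n + n/mx)
        d = rn - 1.0 / (d + rn)
        if n - 1 <= nmax:
            D[n - 1] = d

    # Riccati-Bessel psi_n = x j_n(x), chi_n = -x y_n(x), upward recurrence
    psi_m1, psi0 = np.cos(x), np.sin(x)
    chi_m1, chi0 = -np.sin(x), np.cos(x)

    a = np.zeros(nmax + 1, dtype=complex)
    b = np.zeros(nmax + 1, dtype=complex)
    psi_nm1, psi_nm2 = psi0, psi_m1
    chi_nm1, chi_nm2 = chi0, chi_m1
    for n in range(1, nmax + 1):
        fac = (2 * n - 1) / x
        psi = fac * psi_nm1 - psi_nm2
        chi = fac * chi_nm1 - chi_nm2
        xi = complex(psi, -chi)
        xi_nm1 = complex(psi_nm1, -chi_nm1)
        ta = D[n] / m + n / x
        tb = D[n] * m + n / x
        a[n] = (ta * psi - psi_nm1) / (ta * xi - xi_nm1)
        b[n] = (tb * psi - psi_nm1) / (tb * xi - xi_nm1)
        psi_nm2, psi_nm1 = psi_nm1, psi
        chi_nm2, chi_nm1 = chi_nm1, chi

    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ArithmeticError(
            f"Mie series failed to converge for x={x:.6g}, m={m:.6g}"
        )

    n = np.arange(1, nmax + 1)
    two_n_plus_1 = 2.0 * n + 1.0
    qext = (2.0 / x**2) * float(np.sum(two_n_plus_1 * (a[1:] + b[1:]).real))
    qsca = (2.0 / x**2) * float(
        np.sum(two_n_plus_1 * (np.abs(a[1:]) ** 2 + np.abs(b[1:]) ** 2))
    )

    # asymmetry parameter g (cross terms a_n a_{n+1}, b_n b_{n+1}, a_n b_n)
    an, bn = a[1:-1], b[1:-1]
    an1, bn1 = a[2:], b[2:]
    nn = n[:-1].astype(float)
    cross = np.sum(
        nn * (nn + 2.0) / (nn + 1.0)
        * (an * np.conj(an1) + bn * np.conj(bn1)).real
    )
    same = np.sum(
        two_n_plus_1 / (n * (n + 1.0)) * (a[1:] * np.conj(b[1:])).real
    )
    gq = (4.0 / x**2) * float(cross + same)
    g = gq / qsca if qsca > 0 else 0.0
    return qsca, qext, g


def mie_single(
    radius: float,
    n_particle: float,
    n_medium: float,
    wavelength_vacuum: float,
) -> MieResult:
    """Mie efficiencies and anisotropy of a single homogeneous sphere.

    Parameters
    ----------
    radius : float
        Sphere radius in nm.
    n_particle, n_medium : float
        Real refractive indices of the sphere and the host medium.
    wavelength_vacuum : float
        Vacuum wavelength in nm.

    Returns
    -------
    MieResult
        ``q_scat``, ``q_ext`` and ``g``.  An index-matched sphere
        (``n_particle == n_medium``) returns all zeros rather than raising,
        which keeps titration curves defined at zero optical contrast.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if wavelength_vacuum <= 0:
        raise ValueError("wavelength must be positive")
    if n_medium < 1:
        raise ValueError("n_medium must be >= 1")
    if n_particle <= 0:
        raise ValueError("n_particle must be positive")

    m = n_particle / n_medium
    if abs(m - 1.0) < _INDEX_MATCH_TOL:
        return MieResult(q_scat=0.0, q_ext=0.0, g=0.0)
    x = 2.0 * np.pi * radius * n_medium / wavelength_vacuum
    qsca, qext, g = _mie_efficiencies(m, x)
    return MieResult(q_scat=qsca, q_ext=qext, g=g)


def _per_size_terms(
    species: ParticleSpecies, n_medium: float, wavelength: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mu_s contribution (mm^-1) and per-bin anisotropy."""
    dist = species.distribution
    mus_terms = np.empty(dist.radii.size)
    g_terms = np.empty(dist.radii.size)
    for i, (a_nm, f) in enumerate(zip(dist.radii, dist.weights)):
        res = mie_single(a_nm, species.n_particle, n_medium, wavelength)
        cross_section_mm2 = np.pi * a_nm**2 * MM2_PER_NM2
        mus_terms[i] = species.number_density * f * cross_section_mm2 * res.q_scat
        g_terms[i] = res.g
    return mus_terms, g_terms


def musp_polydisperse(
    species: ParticleSpecies, n_medium: float, wavelength: float
) -> float:
    """Reduced scattering coefficient (mm^-1) of a polydisperse population.

    Evaluates ``N0 sum_i f(a_i) pi a_i^2 Qscat [1 - g]`` with the package
    unit convention (radii nm, N0 per mm^3, result mm^-1).
    """
    mus_terms, g_terms = _per_size_terms(species, n_medium, wavelength)
    return float(np.sum(mus_terms * (1.0 - g_terms)))


def mus_and_g_polydisperse(
    species: ParticleSpecies, n_medium: float, wavelength: float
) -> tuple[float, float]:
    """Scattering coefficient mu_s (mm^-1) and effective anisotropy.

    The effective anisotropy is the scattering-weighted mean of the
    per-size ``g``, so ``mu_s * (1 - g_eff)`` equals
    :func:`musp_polydisperse` by construction.
    """
    mus_terms, g_terms = _per_size_terms(species, n_medium, wavelength)
    mus = float(np.sum(mus_terms))
    if mus <= 0:
        return 0.0, 0.0
    g_eff = float(np.sum(mus_terms * g_terms) / mus)
    return mus, g_eff


def combine_mus_g(
    components: list[tuple[float, float]],
) -> OpticalProperties | tuple[float, float, float]:
    """Combine per-species (mu_s, g) pairs into mixture (mu_s, g_eff, mu_s').

    Mixture mu_s is additive; g_eff is the mu_s-weighted mean of the
    per-species anisotropies (standard mixing rule).
    """
    mus_total = sum(m for m, _ in components)
    if mus_total <= 0:
        return 0.0, 0.0, 0.0
    g_eff = sum(m * g for m, g in components) / mus_total
    return mus_total, g_eff, mus_total * (1.0 - g_eff)
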
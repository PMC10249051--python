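"""Independent reference Mie implementation used as a test oracle.

Deliberately coded along a different route from the package: the Mie
coefficients a_n, b_n are evaluated directly from scipy's spherical
Bessel functions of the first and second kind (no logarithmic-derivative
recurrence, different truncation order), so agreement with the package
is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn


def mie_reference(m: float, x: float) -> tuple[float, float, float]:
    """Return (Qscat, Qext, g) for relative index m and size parameter x."""
    nmax = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 10.0))
    n = np.arange(1, nmax + 1)
    mx = m * x

    jx = spherical_jn(n, x)
    jxp = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    yxp = spherical_yn(n, x, derivative=True)
    jm = spherical_jn(n, mx)
    jmp = spherical_jn(n, mx, derivative=True)

    # Riccati-Bessel: psi(z) = z j(z), xi(z) = z (j(z) - i y(z))
    psi_x = x * jx
    psi_x_p = jx + x * jxp
    xi_x = x * (jx - 1j * yx)
    xi_x_p = (jx - 1j * yx) + x * (jxp - 1j * yxp)
    psi_m = mx * jm
    psi_m_p = jm + mx * jmp

    a = (m * psi_m * psi_x_p - psi_x * psi_m_p) / (
        m * psi_m * xi_x_p - xi_x * psi_m_p
    )
    b = (psi_m * psi_x_p - m * psi_x * psi_m_p) / (
        psi_m * xi_x_p - m * xi_x * psi_m_p
    )

    c = 2.0 * n + 1.0
    qext = (2.0 / x**2) * np.sum(c * (a + b).real)
    qsca = (2.0 / x**2) * np.sum(c * (np.abs(a) ** 2 + np.abs(b) ** 2))

    nf = n[:-1].astype(float)
    cross = np.sum(
        nf * (nf + 2.0) / (nf + 1.0)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    same = np.sum(c / (n * (n + 1.0)) * (a * np.conj(b)).real)
    g = (4.0 / x**2) * (cross + same) / qsca
    return float(qsca), float(qext), float(g)
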
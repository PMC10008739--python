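"""Complex NMR line-shape primitives.

The building blocks of every spectral fit in this package: a rational
(Weideman-type) approximation of the Faddeeva function ``w(z)`` and complex
Lorentzian / Gaussian / (pseudo-)Voigt profiles sharing a single amplitude and
phase convention.

Conventions
-----------
All profiles are normalised to **unit real-part height at the line center**
(zero phase).  The dispersion (imaginary) part is the one produced by the
one-sided Fourier transform of the corresponding free-induction decay, i.e.
negative immediately above the center frequency.  Widths are full widths at
half maximum (FWHM) of the real part, in the same unit as the frequency axis.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_SQRT_LN2 = np.sqrt(np.log(2.0))


@lru_cache(maxsize=16)
def _weideman_coefficients(order: int) -> tuple[float, np.ndarray]:
    """Polynomial coefficients of Weideman's rational Faddeeva approximation.

    Built once per order from the FFT of the kernel ``exp(-t^2) (L^2 + t^2)``
    sampled on a tangent grid; ``L = sqrt(order / sqrt(2))`` is the optimal
    scale parameter.
    """
    n = int(order)
    m = 2 * n
    big_l = np.sqrt(n / np.sqrt(2.0))
    theta = (np.arange(-m + 1, m)) * np.pi / m
    t = big_l * np.tan(theta / 2.0)
    f = np.exp(-t * t) * (big_l * big_l + t * t)
    f = np.concatenate(([0.0], f))
    a = np.real(np.fft.fft(np.fft.fftshift(f))) / (2 * m)
    a = a[1 : n + 1][::-1]
    return big_l, a


def faddeeva(z: np.ndarray | complex, order: int = 32) -> np.ndarray | complex:
    """Faddeeva function ``w(z) = exp(-z^2) erfc(-iz)``.

    Evaluated with Weideman's rational approximation of the given ``order``
    (number of polynomial terms).  Relative accuracy is better than 1e-6 for
    ``order >= 24`` and close to machine precision by ``order = 48``.  The
    approximation is valid on the upper half-plane; the lower half-plane is
    reached through the reflection identity ``w(z) = 2 exp(-z^2) - w(-z)``.

    Parameters
    ----------
    z : complex scalar or array
    order : int
        Number of terms, ``>= 8``.
    """
    if order < 8:
        raise ValueError(f"order must be >= 8, got {order}")
    z = np.asarray(z, dtype=complex)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    big_l, a = _weideman_coefficients(order)

    out = np.empty_like(z)
    lower = z.imag < 0.0
    zz = np.where(lower, -z, z)
    big_z = (big_l + 1j * zz) / (big_l - 1j * zz)
    p = np.polyval(a, big_z)
    w_up = 2.0 * p / (big_l - 1j * zz) ** 2 + (1.0 / np.sqrt(np.pi)) / (big_l - 1j * zz)
    out = np.where(lower, 2.0 * np.exp(-z * z) - w_up, w_up)
    return out[0] if scalar else out


def lorentzian_complex(delta: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-height complex Lorentzian, ``1 / (1 + 2i*delta/fwhm)``."""
    return 1.0 / (1.0 + 2j * np.asarray(delta, dtype=float) / fwhm)


def gaussian_complex(delta: np.ndarray, fwhm: float, order: int = 32) -> np.ndarray:
    """Unit-height complex Gaussian (absorption + Dawson-type dispersion).

    Real part ``exp(-4 ln2 delta^2 / fwhm^2)``; the imaginary part follows
    from the one-sided transform of the Gaussian decay envelope,
    ``w(-2 sqrt(ln2) delta / fwhm)``.
    """
    x = 2.0 * _SQRT_LN2 * np.asarray(delta, dtype=float) / fwhm
    return faddeeva(-x + 0j, order=order)


def voigt_complex(
    delta: np.ndarray,
    fwhm: float,
    mixing: float,
    convention: str = "pseudo",
    order: int = 32,
) -> np.ndarray:
    """Complex Voigt profile of FWHM ``fwhm`` and mixing parameter ``mixing``.

    ``convention="pseudo"`` (default): convex combination
    ``m * Lorentzian + (1 - m) * Gaussian`` of unit-height components sharing
    the same FWHM.  ``convention="faddeeva"``: true Voigt evaluated through
    the Faddeeva function, with the Lorentzian/Gaussian widths apportioned as
    ``wL = m*w`` and ``wG = (1-m)*w``, normalised to unit height.  Both are
    exposed because the mixing-parameter and Faddeeva formulations are both
    established in the spectroscopy literature; fits record which one was
    used.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm}")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    delta = np.asarray(delta, dtype=float)
    if convention == "pseudo":
        lor = lorentzian_complex(delta, fwhm)
        gau = gaussian_complex(delta, fwhm, order=order)
        return mixing * lor + (1.0 - mixing) * gau
    if convention == "faddeeva":
        w_l = mixing * fwhm
        w_g = (1.0 - mixing) * fwhm
        if w_g < 1e-6 * fwhm:
            return lorentzian_complex(delta, fwhm)
        if w_l < 1e-6 * fwhm:
            return gaussian_complex(delta, fwhm, order=order)
        c = 2.0 * _SQRT_LN2 / w_g
        z = -c * delta + 1j * c * (w_l / 2.0)
        z0 = 1j * c * (w_l / 2.0)
        return faddeeva(z, order=order) / faddeeva(z0, order=order)
    raise ValueError(f"unknown convention {convention!r}")
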
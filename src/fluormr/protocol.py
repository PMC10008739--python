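"""Closed-form pulse-sequence optimisation and sensitivity arithmetic.

Everything here is desk arithmetic a sequence developer does before going to
the scanner: the Ernst angle for spoiled gradient echo, the optimal bSSFP
flip angle, the RARE echo-train length compatible with a point-spread
function (PSF) criterion, SNR efficiency, detection-limit time scaling,
fluorine atoms per voxel, cross-species voxel scaling and dose-proportional
concentration projections.  Angles are returned in degrees; raw double
precision is kept everywhere (rounding is the caller's business).
"""

from __future__ import annotations

import numpy as np

from .relaxometry import RelaxParams

__all__ = [
    "ernst_angle",
    "bssfp_optimal_angle",
    "steady_state_signal",
    "rare_psf",
    "rare_max_etl",
    "snr_efficiency",
    "detection_limit_scale",
    "atoms_per_voxel",
    "cross_species_scaling",
    "snr_time_equivalence",
    "dose_scaled_concentration",
]

AVOGADRO = 6.02214076e23


def ernst_angle(tr_ms: float, t1_ms: float) -> float:
    """Ernst flip angle ``arccos(exp(-TR/T1))`` in degrees."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be > 0")
    return float(np.degrees(np.arccos(np.exp(-tr_ms / t1_ms))))


def bssfp_optimal_angle(t1_ms: float, t2_ms: float) -> float:
    """Optimal on-resonance bSSFP angle ``arccos((T1/T2 - 1)/(T1/T2 + 1))`` (deg)."""
    if t2_ms <= 0:
        raise ValueError("T2 must be > 0")
    if t2_ms > t1_ms:
        raise ValueError("T2 cannot exceed T1")
    ratio = t1_ms / t2_ms
    return float(np.degrees(np.arccos((ratio - 1.0) / (ratio + 1.0))))


def steady_state_signal(
    seq: str,
    tr_ms: float,
    te_ms: float,
    alpha_deg: float,
    t1_ms: float,
    t2_ms: float = np.inf,
) -> float:
    """Relative steady-state signal of a spoiled GE (FLASH/UTE) or bSSFP run.

    Spoiled gradient echo: ``sin(a) (1-E1) / (1 - cos(a) E1) * exp(-TE/T2*)``
    with ``E1 = exp(-TR/T1)``; on-resonance bSSFP:
    ``sin(a) (1-E1) / (1 - (E1-E2) cos(a) - E1 E2) * exp(-TE/T2)``.
    Only meaningful for relative comparisons.
    """
    a = np.radians(alpha_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    te_decay = np.exp(-te_ms / t2_ms) if np.isfinite(t2_ms) else 1.0
    if seq in ("flash", "ute", "spoiled_ge"):
        return float(np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1) * te_decay)
    if seq == "bssfp":
        e2 = np.exp(-tr_ms / t2_ms)
        return float(np.sin(a) * (1.0 - e1) / (1.0 - (e1 - e2) * np.cos(a) - e1 * e2) * te_decay)
    raise ValueError(f"unknown sequence {seq!r}")


# ---------------------------------------------------------------------------
# RARE point-spread function
# ---------------------------------------------------------------------------

def _echo_modulation(etl: int, delta_te_ms: float, decay, n_phase: int, ordering: str) -> np.ndarray:
    if n_phase % etl != 0:
        raise ValueError(f"etl={etl} must divide n_phase={n_phase}")
    if etl > n_phase:
        raise ValueError("etl cannot exceed the number of phase-encode lines")
    shots = n_phase // etl
    k = np.arange(n_phase) - n_phase // 2
    if ordering == "centric":
        rank = np.argsort(np.argsort(np.abs(k + 0.25)))  # center-out, ties broken left
        echo = rank // shots + 1
    elif ordering == "linear":
        idx = np.arange(n_phase)
        echo = (idx % etl) + 1 if shots > 1 else idx + 1
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    t = echo * delta_te_ms
    s = decay(t)
    return s / decay(np.zeros(1))[0]


def rare_psf(
    etl: int,
    delta_te_ms: float,
    t2_params: RelaxParams,
    n_phase: int = 32,
    ordering: str = "centric",
    oversample: int = 64,
) -> tuple[np.ndarray, float]:
    """Phase-encode PSF of a RARE echo train and its FWHM in voxels.

    Each phase-encode line k carries the echo-train amplitude ``S(t_k)`` of
    the echo that acquired it (centric: the first echo of every shot fills
    the most central lines).  The magnitude PSF is the zero-padded inverse
    DFT of that modulation; the FWHM of its central lobe is measured by
    linear interpolation and expressed in voxel units.  With no decay the
    PSF is the Dirichlet kernel of a flat window (FWHM ~1.2 voxels).
    """
    decay = lambda t: np.asarray(t2_params.signal(np.asarray(t, dtype=float)))
    mod = _echo_modulation(etl, delta_te_ms, decay, n_phase, ordering)
    n_fine = n_phase * oversample
    padded = np.zeros(n_fine)
    padded[n_fine // 2 - n_phase // 2 : n_fine // 2 + n_phase // 2] = mod
    psf = np.abs(np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(padded))))
    x = (np.arange(n_fine) - n_fine // 2) / oversample  # voxel units
    peak = np.max(psf)
    half = peak / 2.0
    ic = int(np.argmax(psf))
    i = ic
    while i + 1 < n_fine and psf[i + 1] >= half:
        i += 1
    right = np.interp(half, [psf[i + 1], psf[i]], [x[i + 1], x[i]]) if i + 1 < n_fine else x[-1]
    i = ic
    while i - 1 >= 0 and psf[i - 1] >= half:
        i -= 1
    left = np.interp(half, [psf[i - 1], psf[i]], [x[i - 1], x[i]]) if i - 1 >= 0 else x[0]
    return psf, float(right - left)


def rare_max_etl(
    delta_te_ms: float,
    t2_params: RelaxParams,
    n_phase: int = 32,
    fwhm_limit: float = 1.5,
    ordering: str = "centric",
) -> int:
    """Highest echo-train length whose PSF FWHM stays below ``fwhm_limit`` voxels."""
    candidates = [e for e in range(1, n_phase + 1) if n_phase % e == 0]
    best = 1
    for etl in candidates:
        _, fwhm = rare_psf(etl, delta_te_ms, t2_params, n_phase, ordering)
        if fwhm < fwhm_limit:
            best = etl
    return best


# ---------------------------------------------------------------------------
# sensitivity arithmetic
# ---------------------------------------------------------------------------

def snr_efficiency(snr: float, ta_s: float) -> float:
    """SNR per square-root hour, ``SNR / sqrt(TA in h)``."""
    if ta_s <= 0:
        raise ValueError("acquisition time must be > 0")
    return float(snr / np.sqrt(ta_s / 3600.0))


def detection_limit_scale(limit_um: float, t_ref_s: float, t_new_s: float) -> float:
    """Detection limit rescaled to a new measurement time.

    The limit is inversely proportional to the square root of the time:
    ``limit_new = limit * sqrt(t_ref / t_new)`` (shorter scans detect less).
    """
    if t_ref_s <= 0 or t_new_s <= 0:
        raise ValueError("times must be > 0")
    return float(limit_um * np.sqrt(t_ref_s / t_new_s))


def atoms_per_voxel(
    conc_um: float,
    voxel: float,
    atoms_per_molecule: int = 3,
    voxel_is_volume: bool = False,
) -> float:
    """Number of ¹⁹F atoms per voxel at a molar concentration.

    ``voxel`` is the isotropic edge length in mm (or the volume in mm³ when
    ``voxel_is_volume``); ``atoms_per_molecule`` defaults to 3, the CF₃
    group.  ``N = N_A * c * V * n_F``.
    """
    if conc_um < 0 or voxel <= 0 or atoms_per_molecule <= 0:
        raise ValueError("inputs must be positive (concentration >= 0)")
    vol_mm3 = voxel if voxel_is_volume else voxel**3
    vol_l = vol_mm3 * 1e-6  # mm^3 -> L
    return float(AVOGADRO * conc_um * 1e-6 * vol_l * atoms_per_molecule)


def cross_species_scaling(v_a_cm3: float, v_b_cm3: float) -> tuple[float, float]:
    """Volume ratio and its cube root (edge-length ratio) between two brains."""
    if v_a_cm3 <= 0 or v_b_cm3 <= 0:
        raise ValueError("volumes must be > 0")
    ratio = v_a_cm3 / v_b_cm3
    return float(ratio), float(ratio ** (1.0 / 3.0))


def snr_time_equivalence(snr_ratio: float) -> float:
    """Acquisition-time factor equivalent to an SNR ratio (square law)."""
    if snr_ratio <= 0:
        raise ValueError("snr_ratio must be > 0")
    return float(snr_ratio**2)


def dose_scaled_concentration(c_ref_um: float, dose_ref: float, dose_new: float) -> float:
    """Dose-proportional steady-state concentration projection."""
    if c_ref_um < 0 or dose_ref <= 0 or dose_new <= 0:
        raise ValueError("doses must be > 0 and concentration >= 0")
    return float(c_ref_um * dose_new / dose_ref)
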
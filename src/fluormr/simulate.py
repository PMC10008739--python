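"""Synthetic ¹⁹F MR data generation.

Every input the analysis chain consumes can be generated here with stated
distributions: multi-channel complex FIDs carrying a drug resonance near
-59 ppm plus the two coil-intrinsic contaminant lines near -83 and -147 ppm,
saturation-recovery and echo/FID decay series, radial UTE k-space of
piecewise-constant ellipsoid phantoms with per-sample T2* decay and
off-resonance, and zero-excitation noise scans.  All generators are pure
functions of their inputs and a seed.

The drug and acquisition defaults emulate the study conditions this package
was written for: a 9.4 T ¹⁹F setup (reference frequency 376.8 MHz), 200 kHz
spectral bandwidth, a two-channel cryogenic surface probe, and a siponimod
resonance at -59.09 ppm (ex vivo) / -59.13 ppm (serum, room temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .spectra import Fid, SpectralModel, VoigtPeak

__all__ = [
    "SpectroAcqParams",
    "Ellipsoid",
    "EllipsoidPhantom",
    "NoiseModel",
    "COIL_ARTIFACT_STATS",
    "DRUG_SHIFT_PPM",
    "simulate_fid",
    "simulate_relaxation_series",
    "simulate_radial_kspace",
    "coil_artifact_model",
    "coil_artifact_stats",
]

#: chemical shift of the drug resonance under the conditions we emulate (ppm)
DRUG_SHIFT_PPM = {"dmso_rt": -57.08, "dmso_pt": -57.06, "serum_rt": -59.13,
                  "serum_pt": -59.06, "ex_vivo": -59.09}

#: per-channel means and standard deviations of the coupled two-line
#: coil-contaminant model, as characterised from 18 empty-coil control spectra
#: (ratio r, centers v in ppm, FWHMs w in ppm, mixing parameters m).
COIL_ARTIFACT_STATS: dict[int, dict[str, tuple[float, float]]] = {
    1: {
        "r": (0.84, 0.02),
        "v1": (-82.96, 0.08),
        "w1": (5.1, 0.4),
        "m1": (0.82, 0.06),
        "v2": (-147.9, 0.4),
        "w2": (6.0, 1.0),
        "m2": (0.8, 0.2),
    },
    2: {
        "r": (0.85, 0.01),
        "v1": (-82.5, 0.1),
        "w1": (4.8, 0.3),
        "m1": (0.79, 0.06),
        "v2": (-146.9, 0.4),
        "w2": (5.0, 1.0),
        "m2": (0.7, 0.2),
    },
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectroAcqParams:
    """Spectroscopy acquisition settings (defaults: 200 kHz bandwidth at 9.4 T)."""

    dwell_time: float = 5e-6  # s per complex point
    n_points: int = 512
    carrier_ppm: float = -90.0
    reference_frequency: float = 376.8  # MHz
    n_channels: int = 2
    filter_delay_points: int = 0

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.n_points < 16:
            raise ValueError("n_points must be >= 16")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.filter_delay_points < 0:
            raise ValueError("filter_delay_points must be >= 0")

    @property
    def bandwidth(self) -> float:
        return 1.0 / self.dwell_time


@dataclass
class Ellipsoid:
    center: tuple[float, ...]  # mm
    semi_axes: tuple[float, ...]  # mm
    amplitude: float = 1.0  # signal units
    t2_star: float = np.inf  # ms
    delta_f: float = 0.0  # Hz, offset in the receiver frame

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi_axes must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.t2_star <= 0:
            raise ValueError("t2_star must be > 0 (or infinite)")


@dataclass
class EllipsoidPhantom:
    """Piecewise-constant phantom: a list of (possibly overlapping) ellipsoids."""

    ellipsoids: list[Ellipsoid] = field(default_factory=list)


@dataclass
class NoiseModel:
    """Circularly symmetric complex Gaussian channel noise.

    ``channel_covariance`` is the Hermitian positive-definite complex
    covariance ``E[n n^H]`` between channels, in signal units squared; the
    real and imaginary parts within a channel are i.i.d. with variance
    ``C_ii / 2`` each.
    """

    channel_covariance: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.channel_covariance, dtype=complex))
        if not np.allclose(c, c.conj().T):
            raise ValueError("channel covariance must be Hermitian")
        eig = np.linalg.eigvalsh(c)
        if np.any(eig <= 0):
            raise ValueError("channel covariance must be positive definite")
        self.channel_covariance = c
        self._chol = np.linalg.cholesky(c)

    @property
    def n_channels(self) -> int:
        return self.channel_covariance.shape[0]

    def sample(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw ``(n_channels, n)`` correlated complex noise samples."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        z = (rng.standard_normal((self.n_channels, n)) + 1j * rng.standard_normal((self.n_channels, n))) / np.sqrt(2.0)
        return self._chol @ z


# ---------------------------------------------------------------------------
# FID synthesis
# ---------------------------------------------------------------------------

def _peak_envelope(t: np.ndarray, fwhm_hz: float, mixing: float) -> np.ndarray:
    """Time-domain envelope whose one-sided FT is a unit-height pseudo-Voigt."""
    lor = np.pi * fwhm_hz * np.exp(-np.pi * fwhm_hz * t)
    a_g = (np.pi * fwhm_hz) ** 2 / (4.0 * np.log(2.0))
    gau = 2.0 * np.sqrt(a_g / np.pi) * np.exp(-a_g * t * t)
    return mixing * lor + (1.0 - mixing) * gau


def simulate_fid(
    model: SpectralModel,
    acq: SpectroAcqParams,
    envelope: dict[int, tuple[float, float, float]] | None = None,
    noise: NoiseModel | None = None,
    channel_gains: np.ndarray | None = None,
) -> Fid:
    """Synthesise a multi-channel FID whose spectrum is the given model.

    Each pseudo-Voigt peak is generated exactly in the time domain (the
    Lorentzian and Gaussian parts are Fourier pairs of exponential and
    Gaussian decays), so with zero noise the DFT reproduces the model line
    shape to within discretisation error.  ``envelope`` optionally replaces
    the line-width-derived decay of a peak (by index) with a bi-exponential
    ``(beta, t2a_ms, t2b_ms)`` whose initial amplitude is the peak amplitude.
    A global first-order phase is realised as the equivalent acquisition
    delay.  Identical seeds give identical output.
    """
    t = np.arange(acq.n_points) * acq.dwell_time
    tau = model.first_order_phase / (2.0 * np.pi * acq.reference_frequency)  # s
    ts = t + tau
    nyq = acq.bandwidth / 2.0

    signal = np.zeros(acq.n_points, dtype=complex)
    for i, pk in enumerate(model.peaks):
        df_hz = (pk.center - acq.carrier_ppm) * acq.reference_frequency
        if abs(df_hz) >= nyq:
            raise ValueError(
                f"peak at {pk.center} ppm is {df_hz:.0f} Hz off-carrier, outside the "
                f"sampled bandwidth (+-{nyq:.0f} Hz)"
            )
        if envelope is not None and i in envelope:
            beta, t2a, t2b = envelope[i]
            if not 0.0 <= beta <= 1.0:
                raise ValueError("envelope mixture weight must be in [0, 1]")
            env = beta * np.exp(-ts * 1e3 / t2a) + (1.0 - beta) * np.exp(-ts * 1e3 / t2b)
        else:
            fwhm_hz = pk.fwhm * acq.reference_frequency
            env = _peak_envelope(ts, fwhm_hz, pk.mixing)
        env = np.where(ts >= 0, env, 0.0)
        signal += pk.amplitude * np.exp(-1j * pk.phase) * env * np.exp(2j * np.pi * df_hz * ts)

    if channel_gains is None:
        channel_gains = np.ones(acq.n_channels, dtype=complex)
    channel_gains = np.asarray(channel_gains, dtype=complex)
    if channel_gains.shape != (acq.n_channels,):
        raise ValueError("channel_gains must have one entry per channel")
    data = channel_gains[:, None] * signal[None, :]

    if noise is not None:
        if noise.n_channels != acq.n_channels:
            raise ValueError(
                f"noise model has {noise.n_channels} channels, acquisition {acq.n_channels}"
            )
        data = data + noise.sample(acq.n_points)

    return Fid(
        data=data,
        dwell_time=acq.dwell_time,
        reference_frequency=acq.reference_frequency,
        carrier_ppm=acq.carrier_ppm,
        filter_delay_points=acq.filter_delay_points,
    )


# ---------------------------------------------------------------------------
# relaxation series
# ---------------------------------------------------------------------------

def simulate_relaxation_series(
    kind: str,
    params: dict,
    timing: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy saturation-recovery or decay series at the given timings (ms).

    ``kind`` is one of ``saturation_recovery`` (``S = A (1 - exp(-TR/T1))``),
    ``echo_decay`` or ``fid_decay`` (mono- or bi-exponential
    ``S = A (beta exp(-t/T2a) + (1-beta) exp(-t/T2b))``; mono when ``beta``
    is absent or 1).  Gaussian noise of the stated sd is added.
    """
    timing = np.asarray(timing, dtype=float)
    if np.any(timing <= 0):
        raise ValueError("timing must be strictly positive")
    if np.any(np.diff(timing) <= 0):
        raise ValueError("timing must be strictly increasing")
    amp = float(params.get("amplitude", 1.0))

    if kind == "saturation_recovery":
        t1 = float(params["t1"])
        s = amp * (1.0 - np.exp(-timing / t1))
    elif kind in ("echo_decay", "fid_decay"):
        beta = float(params.get("beta", 1.0))
        if not 0.0 <= beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {beta}")
        t2a = float(params.get("t2a", params.get("t2", np.nan)))
        t2b = float(params.get("t2b", t2a))
        s = amp * (beta * np.exp(-timing / t2a) + (1.0 - beta) * np.exp(-timing / t2b))
    else:
        raise ValueError(f"unknown series kind {kind!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + noise_sd * rng.standard_normal(s.shape)
    return timing, s


# ---------------------------------------------------------------------------
# radial k-space
# ---------------------------------------------------------------------------

def _ball_ft(u: np.ndarray) -> np.ndarray:
    """FT of the unit ball, 3 (sin u - u cos u) / u^3, with the u->0 limit."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    us = np.where(small, 1.0, u)
    val = 3.0 * (np.sin(us) - us * np.cos(us)) / us**3
    return np.where(small, 1.0 - u * u / 10.0, val)


def _disc_ft(u: np.ndarray) -> np.ndarray:
    """FT of the unit disc, 2 J1(u) / u, with the u->0 limit."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-6
    us = np.where(small, 1.0, u)
    return np.where(small, 1.0 - u * u / 8.0, 2.0 * j1(us) / us)


def ellipsoid_kspace(phantom: EllipsoidPhantom, kcoords: np.ndarray, t_s: np.ndarray) -> np.ndarray:
    """Analytic Fourier transform of the phantom at sample positions.

    ``kcoords`` has shape ``(..., d)`` in cycles/mm; ``t_s`` (seconds,
    broadcastable to the leading shape) is the acquisition time of each
    sample, applying per-object T2* decay and off-resonance phase
    ``exp(2 pi i df t)`` at the per-sample time, not per-spoke average.
    """
    d = kcoords.shape[-1]
    out = np.zeros(kcoords.shape[:-1], dtype=complex)
    for e in phantom.ellipsoids:
        if len(e.center) != d or len(e.semi_axes) != d:
            raise ValueError("ellipsoid dimensionality does not match trajectory")
        scaled = kcoords * np.asarray(e.semi_axes)
        u = 2.0 * np.pi * np.linalg.norm(scaled, axis=-1)
        if d == 3:
            vol = 4.0 / 3.0 * np.pi * np.prod(e.semi_axes)
            shape = _ball_ft(u)
        elif d == 2:
            vol = np.pi * np.prod(e.semi_axes)
            shape = _disc_ft(u)
        else:
            raise ValueError("only 2D and 3D phantoms are supported")
        phase = np.exp(-2j * np.pi * (kcoords @ np.asarray(e.center)))
        decay = np.exp(-t_s * 1e3 / e.t2_star) if np.isfinite(e.t2_star) else 1.0
        offres = np.exp(2j * np.pi * e.delta_f * t_s)
        out += e.amplitude * vol * shape * phase * decay * offres
    return out


def simulate_radial_kspace(
    phantom: EllipsoidPhantom,
    traj,
    noise: NoiseModel | None = None,
    n_channels: int = 1,
    channel_sensitivities=None,
    with_noise_scan: bool = False,
):
    """Radial UTE k-space of an ellipsoid phantom, plus optional noise scan.

    The analytic ellipsoid Fourier transform is evaluated at every trajectory
    sample, multiplied by per-object ``exp(-t/T2*)`` and off-resonance phase
    at the sample time ``TE + (j-1) t_d``, weighted by per-channel
    sensitivities (uniform by default; a callable is evaluated at each
    ellipsoid center, a piecewise-constant surface-coil approximation), and
    corrupted by correlated complex channel noise.  An empty phantom yields
    noise only.  Returns a :class:`fluormr.imaging.KSpaceData`.
    """
    from .imaging import KSpaceData  # local import to avoid a cycle

    kc = traj.kcoords()  # (spokes, points, d)
    t_s = traj.sample_times()[None, :]  # s

    if channel_sensitivities is None:
        gains = [np.ones(len(phantom.ellipsoids) or 1)] * n_channels
    elif callable(channel_sensitivities):
        centers = [e.center for e in phantom.ellipsoids] or [(0.0,) * kc.shape[-1]]
        gains = [np.asarray([channel_sensitivities(c, ch) for c in centers]) for ch in range(n_channels)]
    else:
        gains = np.asarray(channel_sensitivities, dtype=complex)
        if gains.shape[0] != n_channels:
            raise ValueError(f"got {gains.shape[0]} channel sensitivities for {n_channels} channels")
        gains = [np.full(len(phantom.ellipsoids) or 1, g) for g in gains]

    samples = np.zeros((n_channels, kc.shape[0], kc.shape[1]), dtype=complex)
    for ch in range(n_channels):
        if phantom.ellipsoids:
            weighted = EllipsoidPhantom(
                [Ellipsoid(e.center, e.semi_axes, e.amplitude * abs(g), e.t2_star, e.delta_f)
                 for e, g in zip(phantom.ellipsoids, gains[ch])]
            )
            samples[ch] = ellipsoid_kspace(weighted, kc, t_s)

    noise_scan = None
    if noise is not None:
        if noise.n_channels != n_channels:
            raise ValueError(f"noise model has {noise.n_channels} channels, data has {n_channels}")
        rng = np.random.default_rng(noise.seed)
        n_total = kc.shape[0] * kc.shape[1]
        samples = samples + noise.sample(n_total, rng).reshape(n_channels, kc.shape[0], kc.shape[1])
        if with_noise_scan:
            noise_scan = noise.sample(n_total, rng).reshape(n_channels, kc.shape[0], kc.shape[1])

    return KSpaceData(samples=samples, trajectory=traj, noise_scan=noise_scan)


# ---------------------------------------------------------------------------
# coil-artifact model
# ---------------------------------------------------------------------------

def coil_artifact_stats(channel: int) -> dict[str, tuple[float, float]]:
    """Means and sds of the coupled two-line coil-contaminant model."""
    if channel not in COIL_ARTIFACT_STATS:
        raise ValueError(f"channel must be 1 or 2, got {channel}")
    return dict(COIL_ARTIFACT_STATS[channel])


def coil_artifact_model(
    channel: int,
    amplitude: float = 1.0,
    sample: bool = False,
    rng: np.random.Generator | None = None,
) -> SpectralModel:
    """Coupled two-peak model of the coil-intrinsic contaminant lines.

    With ``sample=False`` the peaks sit at the characterised mean parameters;
    with ``sample=True`` each parameter is drawn from its Gaussian
    between-scan distribution (mixing/ratio clipped to [0, 1], widths kept
    positive), which is how synthetic empty-coil control spectra are made.
    The two amplitudes are coupled as ``r*a`` and ``(1-r)*a``.
    """
    stats = coil_artifact_stats(channel)
    if sample:
        if rng is None:
            rng = np.random.default_rng()
        draw = {k: rng.normal(mu, sd) for k, (mu, sd) in stats.items()}
        draw["r"] = float(np.clip(draw["r"], 0.0, 1.0))
        for k in ("m1", "m2"):
            draw[k] = float(np.clip(draw[k], 0.0, 1.0))
        for k in ("w1", "w2"):
            draw[k] = max(draw[k], 0.5)
    else:
        draw = {k: mu for k, (mu, sd) in stats.items()}
    p1 = VoigtPeak(1.0, draw["v1"], draw["w1"], draw["m1"], 0.0)
    p2 = VoigtPeak(1.0, draw["v2"], draw["w2"], draw["m2"], 0.0)
    return SpectralModel.coupled_pair(amplitude, draw["r"], p1, p2)
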
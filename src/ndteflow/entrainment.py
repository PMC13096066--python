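"""Spectral and phase measures of cue-related neural entrainment.

Post-cue entrainment is quantified three ways: Welch power spectral density
averaged inside a frequency band and normalized by a baseline interval;
inter-trial phase clustering (ITPC) from complex Morlet wavelet
coefficients, ITPC = |mean over trials of e^{iφ}| per channel, frequency and
time; and the phase-locking value (PLV) between channel pairs from
Hilbert-transform instantaneous phases,

    PLV = | 1/T Σ_t e^{i(φ_a(t) − φ_b(t))} |,

averaged over all unordered channel pairs to a whole-head scalar per epoch.
Condition contrasts of these scalars use a paired sign-flip permutation
test; multiple channels/bands are corrected with the same
Benjamini–Hochberg routine the flow inference uses.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .epochs import EpochSet, bandpass, highpass
from .exceptions import ValidationError

__all__ = [
    "welch_bandpower",
    "morlet_itpc",
    "itpc_band_average",
    "plv_from_phases",
    "hilbert_plv",
    "permutation_test_scalar",
]

#: Frequency bands of interest (Hz).
BANDS = {"delta": (0.5, 4.0), "broad": (0.5, 80.0)}


def welch_bandpower(
    epochs: EpochSet,
    band: tuple[float, float],
    overlap: float = 0.5,
    bin_spacing_hz: float = 0.12,
    baseline: EpochSet | None = None,
    nperseg: int | None = None,
) -> np.ndarray:
    """Per-channel Welch band power, optionally baseline-normalized.

    Hann-windowed Welch PSD with the given segment overlap; the FFT is
    zero-padded so that bin spacing equals ``bin_spacing_hz`` (an epoch of
    1.2 s cannot natively resolve 0.12 Hz, so the fine spacing is
    interpolation, not added resolution). Power is averaged over bins inside
    ``band`` and over trials. With ``baseline`` given, returns the ratio
    post/baseline per channel.
    """
    lo, hi = band
    nyq = epochs.fs_hz / 2.0
    if not 0 < lo < hi <= nyq:
        raise ValidationError(f"band {band} outside (0, Nyquist={nyq}]")
    if nperseg is None:
        nperseg = epochs.n_samples
    nfft = max(nperseg, int(np.ceil(epochs.fs_hz / bin_spacing_hz)))
    freqs, psd = sps.welch(
        epochs.data,
        fs=epochs.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        nfft=nfft,
        axis=2,
        detrend="constant",
    )
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValidationError("no frequency bins inside the requested band")
    power = psd[:, :, sel].mean(axis=2).mean(axis=0)  # trials then bins -> channels
    if baseline is not None:
        base = welch_bandpower(baseline, band, overlap, bin_spacing_hz, None, None)
        return power / base
    return power


def _morlet_wavelet(f0: float, fs: float, n_cycles: float) -> np.ndarray:
    sd_t = n_cycles / (2 * np.pi * f0)
    half = int(np.ceil(3.5 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * f0 * t) * np.exp(-(t ** 2) / (2 * sd_t ** 2))
    return wav / np.abs(wav).sum()


def morlet_itpc(
    epochs: EpochSet,
    f_min: float = 0.5,
    f_max: float = 80.0,
    n_freqs: int = 20,
    n_cycles: float = 7.0,
    trim_edges: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-trial phase clustering from complex Morlet convolution.

    Center frequencies are log-spaced between ``f_min`` and ``f_max``
    (``n_freqs`` of them). Returns ``(itpc, freqs)`` with ``itpc`` of shape
    ``(channels, freqs, samples)`` in [0, 1]. With ``trim_edges`` the first
    and last 3 wavelet standard deviations are set to NaN (convolution edge
    artifacts).
    """
    if epochs.n_trials < 2:
        raise ValidationError("ITPC needs at least 2 trials")
    if f_max >= epochs.fs_hz / 2:
        raise ValidationError(f"f_max={f_max} Hz at or above Nyquist")
    if not 0 < f_min < f_max:
        raise ValidationError("need 0 < f_min < f_max")
    freqs = np.geomspace(f_min, f_max, n_freqs)
    out = np.empty((epochs.n_regions, n_freqs, epochs.n_samples))
    flat = epochs.data.reshape(-1, epochs.n_samples)
    for fi, f0 in enumerate(freqs):
        wav = _morlet_wavelet(f0, epochs.fs_hz, n_cycles)
        coef = sps.fftconvolve(flat, wav[None, :], mode="same", axes=1)
        mag = np.abs(coef)
        unit = np.where(mag > 0, coef / np.where(mag > 0, mag, 1.0), 0.0)
        unit = unit.reshape(epochs.n_trials, epochs.n_regions, -1)
        itpc = np.abs(unit.mean(axis=0))
        if trim_edges:
            sd_samples = int(np.ceil(3 * n_cycles / (2 * np.pi * f0) * epochs.fs_hz))
            edge = min(sd_samples, epochs.n_samples // 2)
            itpc[:, :edge] = np.nan
            itpc[:, epochs.n_samples - edge :] = np.nan
        out[:, fi, :] = itpc
    return out, freqs


def itpc_band_average(itpc: np.ndarray, freqs: np.ndarray,
                      band: tuple[float, float]) -> np.ndarray:
    """Average ITPC over in-band frequencies -> (channels, samples)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError("no ITPC frequencies inside the requested band")
    return np.nanmean(itpc[:, sel, :], axis=1)


def plv_from_phases(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """PLV of two instantaneous-phase series: |mean_t e^{i(φa−φb)}|."""
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape or phi_a.ndim != 1 or len(phi_a) < 1:
        raise ValidationError("phase series must be 1-D and of equal length")
    return float(np.abs(np.exp(1j * (phi_a - phi_b)).mean()))


def hilbert_plv(
    epochs: EpochSet,
    band: tuple[float, float] | None = None,
    highpass_hz: float | None = None,
) -> np.ndarray:
    """Whole-head phase-locking value per epoch.

    Instantaneous phases come from the FFT-based analytic signal after mean
    removal (optionally preceded by band-pass or high-pass filtering, e.g.
    0.85 Hz for 1.2 s epochs). PLV is computed per unordered channel pair
    over time and averaged over pairs; the participant-level value is the
    mean of the returned per-epoch values.
    """
    if epochs.n_regions < 2:
        raise ValidationError("PLV needs at least 2 channels")
    if band is not None:
        epochs = bandpass(epochs, band[0], band[1])
    elif highpass_hz is not None:
        epochs = highpass(epochs, highpass_hz)
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    analytic = sps.hilbert(data, axis=2)
    mag = np.abs(analytic)
    unit = analytic / np.where(mag > 0, mag, 1.0)
    # G[trial, a, b] = mean_t u_a conj(u_b); |G| is the pairwise PLV matrix
    G = np.einsum("tcs,tds->tcd", unit, unit.conj()) / epochs.n_samples
    plv = np.abs(G)
    iu = np.triu_indices(epochs.n_regions, k=1)
    return plv[:, iu[0], iu[1]].mean(axis=1)


def permutation_test_scalar(
    valsA: np.ndarray,
    valsB: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided paired sign-flip permutation test on the mean difference.

    When ``n_perm`` covers the full sign-flip group (``n_perm >= 2**n - 1``)
    the test enumerates all ``2**n`` patterns exactly and returns
    ``#{|null| >= |observed|} / 2**n``; otherwise random flips with the
    add-one Monte-Carlo convention.
    """
    a = np.asarray(valsA, dtype=float)
    b = np.asarray(valsB, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("need paired 1-D vectors with n >= 2")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d = a - b
    n = len(d)
    obs = abs(d.mean())
    if n <= 20 and n_perm >= 2 ** n - 1:
        bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1) * 2.0 - 1.0
        null = np.abs(bits @ d) / n
        return float((null >= obs - 1e-12).sum() / 2 ** n)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs(signs @ d) / n
    return float((1 + (null >= obs - 1e-12).sum()) / (n_perm + 1))
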
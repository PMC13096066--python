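"""Epoch container and epoch-level operations.

The :class:`EpochSet` is the pipeline's universal currency: a
``(trials, regions, samples)`` array of signal values with sampling rate,
epoch onset time relative to the cue, region labels and per-trial condition
labels. All downstream stages (difference waveforms, directed-flow
estimation, spectral measures) consume and return this container.

Operations follow the epoch-level steps of a cued target-detection EEG
study: peak-to-peak amplitude rejection, per-participant equalization of
epoch counts between conditions, random cross-condition pairing with
difference-waveform construction, analysis-window extraction and zero-phase
FIR filtering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError

__all__ = [
    "EpochSet",
    "DifferenceEpochSet",
    "read_epochs",
    "write_epochs",
    "reject_amplitude",
    "equalize_epoch_counts",
    "pair_and_difference",
    "extract_window",
    "highpass",
    "lowpass",
    "bandpass",
]


@dataclass
class EpochSet:
    """Epoched multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(trials, regions, samples)`` in signal units
        (microvolts for channel data, source units for ROI data).
    fs_hz
        Sampling rate in Hz.
    t0_ms
        Time of the first sample relative to cue onset, in milliseconds.
    region_labels
        Unique region (or channel) names, one per second array dimension.
    condition
        Optional per-trial condition labels (length = number of trials).
    participant_id
        Optional participant identifier.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    region_labels: list[str]
    condition: np.ndarray | None = None
    participant_id: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"epoch data must be (trials, regions, samples); got ndim={self.data.ndim}"
            )
        self.region_labels = [str(x) for x in self.region_labels]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.region_labels)} region labels for {self.data.shape[1]} regions"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValidationError("region labels must be unique")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if self.condition is not None:
            self.condition = np.asarray(self.condition)
            if len(self.condition) != self.data.shape[0]:
                raise ValidationError("condition must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to cue onset."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def select_trials(self, idx) -> "EpochSet":
        """Return a copy restricted to the given trial indices (order kept)."""
        idx = np.asarray(idx)
        cond = self.condition[idx] if self.condition is not None else None
        return replace(self, data=self.data[idx], condition=cond)


@dataclass
class DifferenceEpochSet(EpochSet):
    """Per-trial condition-difference waveforms (50% − 80% convention).

    ``pair_map`` records, per difference trial, the source trial indices
    ``(index in the 50% set, index in the 80% set)``.
    """

    pair_map: list[tuple[int, int]] = field(default_factory=list)
    sign_convention: str = "50-80"


# ---------------------------------------------------------------------------
# container I/O: raw little-endian float32 + JSON sidecar, or TSV text fallback
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, prefix: str | Path, fmt: str = "binary") -> Path:
    """Write an :class:`EpochSet` as ``<prefix>.bin``/``.tsv`` + ``<prefix>.json``.

    The binary payload is raw little-endian float32 in C order; the text
    fallback is one tab-delimited row per (trial, region). Round-trip is
    lossless at float32 precision.
    """
    prefix = Path(prefix)
    meta = {
        "shape": list(epochs.data.shape),
        "fs_hz": epochs.fs_hz,
        "t0_ms": epochs.t0_ms,
        "region_labels": epochs.region_labels,
        "condition": None if epochs.condition is None else [str(c) for c in epochs.condition],
        "participant_id": epochs.participant_id,
        "format": fmt,
    }
    payload = epochs.data.astype("<f4")
    if fmt == "binary":
        payload.tofile(prefix.with_suffix(".bin"))
    elif fmt == "text":
        flat = payload.reshape(-1, epochs.n_samples)
        np.savetxt(prefix.with_suffix(".tsv"), flat, delimiter="\t", fmt="%.9g")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return prefix


def read_epochs(prefix: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    shape = tuple(meta["shape"])
    if meta.get("format", "binary") == "binary":
        data = np.fromfile(prefix.with_suffix(".bin"), dtype="<f4").reshape(shape)
    else:
        data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        data = data.astype("<f4").reshape(shape)
    cond = meta["condition"]
    return EpochSet(
        data=np.asarray(data, dtype=float),
        fs_hz=meta["fs_hz"],
        t0_ms=meta["t0_ms"],
        region_labels=meta["region_labels"],
        condition=None if cond is None else np.asarray(cond),
        participant_id=meta["participant_id"],
    )


# ---------------------------------------------------------------------------
# epoch-level operations
# ---------------------------------------------------------------------------

def reject_amplitude(epochs: EpochSet, threshold: float) -> tuple[EpochSet, float]:
    """Reject epochs whose within-region peak-to-peak amplitude reaches ``threshold``.

    An epoch is removed iff max − min within any single region's trace is
    ``>= threshold`` (per-region peak-to-peak, the standard reading of an
    "amplitude change" criterion). Returns the surviving epochs and the
    rejected fraction.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, regions)
    bad = (ptp >= threshold).any(axis=1)
    frac = float(bad.mean()) if epochs.n_trials else 0.0
    if bad.all() and epochs.n_trials:
        warnings.warn("all epochs rejected by amplitude criterion", RuntimeWarning)
    return epochs.select_trials(np.flatnonzero(~bad)), frac


def equalize_epoch_counts(larger: EpochSet, smaller: EpochSet, seed: int) -> EpochSet:
    """Randomly drop trials from ``larger`` until it matches ``smaller``'s count.

    The retained subset is drawn uniformly without replacement (seeded);
    original trial order is preserved. Mirrors within-participant epoch-count
    equalization between the two early-target conditions.
    """
    if larger.n_trials < smaller.n_trials:
        raise ValidationError(
            f"'larger' has {larger.n_trials} trials < 'smaller' {smaller.n_trials}; "
            "arguments swapped?"
        )
    if larger.n_trials == smaller.n_trials:
        return larger
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(larger.n_trials, size=smaller.n_trials, replace=False))
    return larger.select_trials(keep)


def pair_and_difference(set50: EpochSet, set80: EpochSet, seed: int) -> DifferenceEpochSet:
    """Randomly pair trials across conditions and form 50% − 80% differences.

    A seeded random bijection matches each 50%-condition trial with one
    80%-condition trial; each difference trace is ``trace(50%) − trace(80%)``
    per region and sample. Counts must already be equal (run
    :func:`equalize_epoch_counts` first).
    """
    if set50.n_trials != set80.n_trials:
        raise ValidationError(
            f"trial counts differ ({set50.n_trials} vs {set80.n_trials}); equalize first"
        )
    if set50.region_labels != set80.region_labels:
        raise ValidationError("region labels differ between condition sets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(set50.n_trials)
    diff = set50.data - set80.data[perm]
    return DifferenceEpochSet(
        data=diff,
        fs_hz=set50.fs_hz,
        t0_ms=set50.t0_ms,
        region_labels=list(set50.region_labels),
        condition=np.asarray(["difference"] * set50.n_trials),
        participant_id=set50.participant_id,
        pair_map=[(int(i), int(perm[i])) for i in range(set50.n_trials)],
    )


def extract_window(epochs: EpochSet, start_ms: float, end_ms: float) -> EpochSet:
    """Extract the half-open analysis window ``[start_ms, end_ms)``.

    Times are relative to cue onset; sample indices are resolved on the
    sample grid, so a 400 ms window at 1 kHz yields exactly 400 samples.
    """
    if start_ms >= end_ms:
        raise ValidationError("window start must precede end")
    span_lo = epochs.t0_ms
    span_hi = epochs.t0_ms + epochs.n_samples * 1000.0 / epochs.fs_hz
    if start_ms < span_lo - 1e-9 or end_ms > span_hi + 1e-9:
        raise ValidationError(
            f"window [{start_ms}, {end_ms}) ms outside epoch span [{span_lo}, {span_hi}) ms"
        )
    i0 = int(round((start_ms - epochs.t0_ms) * epochs.fs_hz / 1000.0))
    i1 = int(round((end_ms - epochs.t0_ms) * epochs.fs_hz / 1000.0))
    out = replace(epochs, data=epochs.data[:, :, i0:i1])
    out.t0_ms = epochs.t0_ms + i0 * 1000.0 / epochs.fs_hz
    return out


def _fir_filtfilt(epochs: EpochSet, cutoff, btype: str, order: int | None) -> EpochSet:
    fs = epochs.fs_hz
    nyq = fs / 2.0
    edges = np.atleast_1d(cutoff).astype(float)
    if np.any(edges <= 0) or np.any(edges >= nyq):
        raise ValidationError(f"cutoff {cutoff} Hz outside (0, Nyquist={nyq} Hz)")
    if order is None:
        # default length: 3 periods of the lowest edge, clamped so
        # forward-backward filtering stays valid for the epoch length
        order = int(round(3 * fs / edges.min()))
    max_taps = max((epochs.n_samples - 1) // 3, 5)
    numtaps = min(order, max_taps)
    if numtaps < order:
        warnings.warn(
            f"filter length reduced from {order} to {numtaps} taps to fit "
            f"{epochs.n_samples}-sample epochs",
            RuntimeWarning,
        )
    if numtaps % 2 == 0:
        numtaps += 1
    taps = sps.firwin(numtaps, edges, pass_zero=btype, fs=fs)
    out = sps.filtfilt(taps, [1.0], epochs.data, axis=2, padlen=min(3 * numtaps, epochs.n_samples - 1))
    return replace(epochs, data=out)


def highpass(epochs: EpochSet, cutoff_hz: float, order: int | None = None) -> EpochSet:
    """Zero-phase FIR high-pass (forward-backward); DC removed, length preserved."""
    return _fir_filtfilt(epochs, cutoff_hz, "highpass", order)


def lowpass(epochs: EpochSet, cutoff_hz: float, order: int | None = None) -> EpochSet:
    """Zero-phase FIR low-pass."""
    return _fir_filtfilt(epochs, cutoff_hz, "lowpass", order)


def bandpass(epochs: EpochSet, low_hz: float, high_hz: float, order: int | None = None) -> EpochSet:
    """Zero-phase FIR band-pass between ``low_hz`` and ``high_hz``."""
    if low_hz >= high_hz:
        raise ValidationError("band edges must satisfy low < high")
    return _fir_filtfilt(epochs, (low_hz, high_hz), "bandpass", order)
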
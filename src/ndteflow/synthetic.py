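"""Synthetic data for the cued auditory target-detection design.

Every downstream stage of the pipeline is testable without recorded EEG:
this module generates (a) trial sequences matching the temporal-prediction
design — a predictive cue followed by an early target on 80% of trials, a
non-predictive cue on 50%, cue duration 100 ms, cue-target interval
1200/2400 ms (cue offset to target onset), inter-trial interval uniform on
200–1000 ms, 3 blocks of 50 trials per condition; (b) ROI time series from
stationary vector-autoregressive (VAR) networks whose directed couplings can
differ by condition inside a configurable time window, giving a known
directed-flow ground truth; (c) connectivity matrices with a planted
rich-club hub structure; (d) reaction times with a condition effect; and
(e) phase-locked sinusoidal epochs for phase-measure oracles.

Innovations are Gaussian i.i.d.: the directed-flow estimator downstream is a
Gaussian-entropy estimator, so a linear-Gaussian network is the faithful
test bed for it. Condition effects are coupling-coefficient changes, not
amplitude changes, so the planted ground truth is a directed-flow
difference — exactly what flow estimation on difference waveforms is meant
to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .exceptions import StationarityError, ValidationError

__all__ = [
    "GroundTruthSpec",
    "simulate_trial_sequence",
    "generate_var_epochs",
    "plant_rich_club",
    "generate_rt_table",
    "generate_phase_locked_epochs",
    "companion_spectral_radius",
]

PREDICTIVE = "predictive_80"
NONPREDICTIVE = "nonpredictive_50"

#: Design constants of the emulated study.
CUE_DURATION_MS = 100
EARLY_INTERVAL_MS = 1200
LATE_INTERVAL_MS = 2400
ITI_RANGE_MS = (200, 1000)


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of VAR coefficients ``(R, R, p)``."""
    coeffs = np.asarray(coeffs, dtype=float)
    r, r2, p = coeffs.shape
    if r != r2:
        raise ValidationError("coupling matrices must be square")
    comp = np.zeros((r * p, r * p))
    for lag in range(p):
        comp[:r, lag * r : (lag + 1) * r] = coeffs[:, :, lag]
    if p > 1:
        comp[r:, :-r] = np.eye(r * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass
class GroundTruthSpec:
    """Ground truth for VAR epoch simulation.

    ``base_coupling[i, j, l]`` is the coefficient with which region ``j`` at
    lag ``l+1`` drives region ``i`` (same source→target orientation as the
    flow matrices downstream). ``condition_delta`` is added to the coupling
    for predictive-condition trials inside ``effect_window_ms`` (relative to
    cue onset). Both coefficient sets must be stationary.
    """

    n_rois: int
    fs_hz: float
    var_order: int
    base_coupling: np.ndarray
    condition_delta: np.ndarray
    effect_window_ms: tuple[float, float]
    noise_sd: float = 1.0
    planted_club: frozenset = field(default_factory=frozenset)
    seed: int = 0
    burn_in: int = 100

    def __post_init__(self):
        self.base_coupling = np.asarray(self.base_coupling, dtype=float)
        self.condition_delta = np.asarray(self.condition_delta, dtype=float)
        expected = (self.n_rois, self.n_rois, self.var_order)
        if self.base_coupling.shape != expected or self.condition_delta.shape != expected:
            raise ValidationError(f"coupling arrays must have shape {expected}")
        if not set(self.planted_club) <= set(range(self.n_rois)):
            raise ValidationError("planted_club must be a subset of ROI indices")
        for name, coeffs in (
            ("base", self.base_coupling),
            ("base+delta", self.base_coupling + self.condition_delta),
        ):
            rho = companion_spectral_radius(coeffs)
            if rho >= 1.0:
                raise StationarityError(rho, which=name)


def simulate_trial_sequence(
    n_participants: int,
    blocks_per_condition: int,
    trials_per_block: int,
    p_early_predictive: float = 0.8,
    p_early_nonpredictive: float = 0.5,
    seed: int = 0,
    cue_duration_ms: float = CUE_DURATION_MS,
) -> pd.DataFrame:
    """Simulate the trial design as a tidy trial table.

    Each participant completes ``blocks_per_condition`` blocks of
    ``trials_per_block`` trials per condition (predictive / non-predictive
    cue). Within each stratum, early targets (cue-target interval 1200 ms)
    are drawn independently with the condition's probability; late targets
    get the 2400 ms interval. Trial order is randomized per participant.
    Identical seeds reproduce the table exactly.
    """
    for name, p in (("p_early_predictive", p_early_predictive),
                    ("p_early_nonpredictive", p_early_nonpredictive)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name}={p} is not a probability")
    for name, c in (("n_participants", n_participants),
                    ("blocks_per_condition", blocks_per_condition),
                    ("trials_per_block", trials_per_block)):
        if int(c) < 1:
            raise ValidationError(f"{name} must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_participants):
        recs = []
        for cond, p_early in ((PREDICTIVE, p_early_predictive),
                              (NONPREDICTIVE, p_early_nonpredictive)):
            for block in range(blocks_per_condition):
                early = rng.random(trials_per_block) < p_early
                for e in early:
                    recs.append((cond, block, bool(e)))
        order = rng.permutation(len(recs))
        t_cursor = 0.0
        for k, idx in enumerate(order):
            cond, block, early = recs[idx]
            iti = float(rng.uniform(*ITI_RANGE_MS))
            interval = EARLY_INTERVAL_MS if early else LATE_INTERVAL_MS
            cue_onset = t_cursor + iti
            rows.append(
                dict(
                    trial_id=k,
                    participant_id=pid,
                    block=block,
                    condition=cond,
                    cue_onset_ms=cue_onset,
                    cue_duration_ms=cue_duration_ms,
                    target_latency="early" if early else "late",
                    cue_target_interval_ms=interval,
                    iti_ms=iti,
                    rt_ms=np.nan,
                )
            )
            t_cursor = cue_onset + cue_duration_ms + interval + CUE_DURATION_MS
    return pd.DataFrame(rows)


def generate_var_epochs(
    spec: GroundTruthSpec,
    trials: pd.DataFrame,
    epoch_window_ms: tuple[float, float] = (-500.0, 4500.0),
) -> EpochSet:
    """Simulate one VAR epoch per trial of a single participant.

    Outside ``spec.effect_window_ms`` every trial follows ``base_coupling``;
    inside it, predictive-condition trials follow ``base + condition_delta``.
    Each epoch is preceded by a burn-in (``spec.burn_in`` samples, default
    100) under the base coupling to remove start-up transients. Innovations
    are Gaussian(0, ``noise_sd``²), seeded from ``spec.seed`` so identical
    specs reproduce identical epochs.
    """
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValidationError(
            "generate_var_epochs simulates one participant at a time; "
            f"got participants {sorted(pids)}"
        )
    start_ms, end_ms = epoch_window_ms
    if start_ms >= end_ms:
        raise ValidationError("epoch window start must precede end")
    fs = spec.fs_hz
    n_samples = int(round((end_ms - start_ms) * fs / 1000.0))
    n_trials = len(trials)
    R, p = spec.n_rois, spec.var_order
    rng = np.random.default_rng(spec.seed)

    total = spec.burn_in + n_samples
    # sample times relative to cue onset; effect window resolved on this grid
    t_ms = start_ms + (np.arange(total) - spec.burn_in) * 1000.0 / fs
    in_effect = (t_ms >= spec.effect_window_ms[0]) & (t_ms < spec.effect_window_ms[1])
    predictive = (trials["condition"] == PREDICTIVE).to_numpy()

    A = spec.base_coupling
    B = spec.base_coupling + spec.condition_delta
    eps = rng.normal(0.0, spec.noise_sd, size=(n_trials, R, total))
    y = np.zeros((n_trials, R, total))
    for t in range(total):
        drive = eps[:, :, t].copy()
        for lag in range(1, min(p, t) + 1):
            past = y[:, :, t - lag]  # (trials, R)
            base_part = past @ A[:, :, lag - 1].T
            if in_effect[t] and predictive.any():
                delta_part = past @ B[:, :, lag - 1].T
                drive += np.where(predictive[:, None], delta_part, base_part)
            else:
                drive += base_part
        y[:, :, t] = drive
    return EpochSet(
        data=y[:, :, spec.burn_in :],
        fs_hz=fs,
        t0_ms=start_ms,
        region_labels=[f"roi{i:02d}" for i in range(R)],
        condition=trials["condition"].to_numpy(),
        participant_id=int(pids[0]),
    )


def plant_rich_club(
    n_rois: int,
    club: set,
    in_weight: float,
    out_weight: float,
    background: float,
    seed: int = 0,
    jitter_scale: float = 0.01,
) -> np.ndarray:
    """Connectivity matrix with a planted rich club.

    Orientation ``M[i, j]`` = flow from source ``j`` into target ``i``.
    Rows of club members (within-club and into-club flow) sit near
    ``in_weight``; entries leaving the club toward non-members near
    ``out_weight``; all other entries near ``background``. Seeded uniform
    jitter on ``(0, jitter_scale * background)`` breaks ties; the diagonal
    is zero (no self-flow).
    """
    club = set(club)
    if not club <= set(range(n_rois)):
        raise ValidationError("club must be a subset of {0..n_rois-1}")
    if not (in_weight > background > 0):
        raise ValidationError("require in_weight > background > 0")
    if not out_weight < in_weight:
        raise ValidationError("require out_weight < in_weight")
    rng = np.random.default_rng(seed)
    member = np.zeros(n_rois, dtype=bool)
    member[list(club)] = True
    M = np.full((n_rois, n_rois), background, dtype=float)
    M[member, :] = in_weight                 # into-club and within-club rows
    M[np.ix_(~member, member)] = out_weight  # club -> outside
    M += rng.uniform(0.0, jitter_scale * background, size=M.shape)
    np.fill_diagonal(M, 0.0)
    return M


def generate_rt_table(
    trials: pd.DataFrame,
    mean_80: float = 330.0,
    mean_50: float = 360.0,
    within_sd: float = 40.0,
    between_sd: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill ``rt_ms`` with participant-offset + condition-mean + trial-noise RTs.

    ``rt = offset(participant) + mean(condition) + noise(trial)``, with the
    participant offset Gaussian(0, ``between_sd``²) and trial noise
    Gaussian(0, ``within_sd``²), truncated at 50 ms. The default means put
    the non-predictive (50%) condition 30 ms slower, a realistic cueing
    effect for this design.
    """
    for name, v in (("mean_80", mean_80), ("mean_50", mean_50),
                    ("within_sd", within_sd), ("between_sd", between_sd)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    pids = out["participant_id"].unique()
    offsets = dict(zip(pids, rng.normal(0.0, between_sd, size=len(pids))))
    cond_mean = out["condition"].map({PREDICTIVE: mean_80, NONPREDICTIVE: mean_50})
    rt = (
        out["participant_id"].map(offsets).to_numpy()
        + cond_mean.to_numpy()
        + rng.normal(0.0, within_sd, size=len(out))
    )
    out["rt_ms"] = np.maximum(rt, 50.0)
    return out


def generate_phase_locked_epochs(
    n_trials: int,
    fs: float,
    f0: float,
    phase_jitter_sd: float,
    seed: int = 0,
    duration_s: float = 1.2,
    noise_sd: float = 0.0,
    n_channels: int = 1,
) -> EpochSet:
    """Sinusoidal epochs at ``f0`` with Gaussian per-trial phase jitter.

    With ``phase_jitter_sd = 0`` every trial has identical phase (perfect
    inter-trial locking); for Gaussian jitter of SD σ the population phase
    clustering at ``f0`` is ``exp(-σ²/2)``. Optional white noise is added on
    top. Channels share the trial phase.
    """
    if f0 >= fs / 2:
        raise ValidationError(f"f0={f0} Hz aliases at fs={fs} Hz (Nyquist {fs/2})")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phases = rng.normal(0.0, phase_jitter_sd, size=n_trials)
    data = np.cos(2 * np.pi * f0 * t[None, None, :] + phases[:, None, None])
    data = np.broadcast_to(data, (n_trials, n_channels, n)).copy()
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return EpochSet(
        data=data,
        fs_hz=fs,
        t0_ms=0.0,
        region_labels=[f"ch{i:02d}" for i in range(n_channels)],
        condition=None,
    )
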
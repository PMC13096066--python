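"""Surrogate-based inference for NDTE flows.

Circular time-shifted surrogates preserve each signal's amplitude and
autocorrelation spectrum while reducing the cross-correlation between the
pair to chance, giving a per-pair null distribution for the observed flow.
Per-trial surrogate p-values are aggregated with Stouffer's method across
trials within a participant and then across participants; one
Benjamini–Hochberg FDR mask over all ordered region pairs is shared by all
participants; and significant flows are standardized against the surrogate
mean and standard deviation.

The *source* series is shifted (the target's future is preserved exactly),
and shift offsets are restricted to the middle half of the epoch so no
surrogate is close to the identity. Monte-Carlo p-values follow the add-one
rule p = (1 + #{surrogate >= observed}) / (n_surrogates + 1) and therefore
never reach zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .ndte import ModelOrder, RawFlowMatrix, _embed_past, _ndte_from_cov

__all__ = [
    "SurrogateStats",
    "NDTEMatrix",
    "circular_shift",
    "surrogate_pvalues",
    "stouffer_combine",
    "bh_fdr",
    "standardize_and_mask",
]

_P_CLIP = 1e-15


@dataclass
class SurrogateStats:
    """Per-pair surrogate summaries for one trial."""

    surrogate_mean: np.ndarray  # (R, R)
    surrogate_sd: np.ndarray    # (R, R)
    p_trial: np.ndarray         # (R, R)
    n_surrogates: int


@dataclass
class NDTEMatrix:
    """Standardized, masked flow matrices (orientation: Z[i,j] = flow j -> i)."""

    Z: np.ndarray                 # group-mean standardized flows, 0 outside mask
    per_participant_Z: np.ndarray  # (participants, R, R)
    mask: np.ndarray              # boolean, shared across participants
    p_group: np.ndarray           # Stouffer-aggregated p per pair
    region_labels: list[str] | None = None

    def save(self, prefix, provenance: dict | None = None) -> None:
        """Write Z, p_group and mask as TSVs plus a JSON provenance sidecar."""
        from .ndte import write_flow_matrix

        labels = self.region_labels or [f"roi{i:02d}" for i in range(self.Z.shape[0])]
        write_flow_matrix(f"{prefix}_Z.tsv", self.Z, labels)
        write_flow_matrix(f"{prefix}_pgroup.tsv", self.p_group, labels)
        write_flow_matrix(f"{prefix}_mask.tsv", self.mask.astype(float), labels)
        with open(f"{prefix}_provenance.json", "w") as fh:
            json.dump(provenance or {}, fh, indent=1)


def _draw_offsets(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    lo, hi = n // 4, 3 * n // 4
    return rng.integers(lo, hi + 1, size=size)


def circular_shift(x: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rotate ``x`` by a seeded uniform offset in [L/4, 3L/4].

    The multiset of values (hence the amplitude spectrum) is preserved; the
    offset range keeps the surrogate away from the identity rotation.
    """
    x = np.asarray(x)
    if len(x) < 4:
        raise ValidationError("series too short to shift (need length >= 4)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.roll(x, int(_draw_offsets(rng, len(x), 1)[0]))


def _surrogate_flows(x: np.ndarray, y: np.ndarray, T: int,
                     offsets: np.ndarray) -> np.ndarray:
    """NDTE of (rotated x -> y) for a batch of rotation offsets, vectorized."""
    n = len(x)
    m = n - T
    S = len(offsets)
    yf = y[T:] - y[T:].mean()
    Yp = _embed_past(y, T)
    Yp = Yp - Yp.mean(axis=1, keepdims=True)
    tgt = np.vstack([yf, Yp])                              # (T+1, m)

    rolled = x[(np.arange(n)[None, :] - offsets[:, None]) % n]  # (S, n)
    Xp = np.stack([rolled[:, T - l : n - l] for l in range(1, T + 1)], axis=1)
    Xp = Xp - Xp.mean(axis=2, keepdims=True)               # (S, T, m)

    cov = np.empty((S, 2 * T + 1, 2 * T + 1))
    cov[:, : T + 1, : T + 1] = tgt @ tgt.T / m
    cross = np.einsum("stm,km->stk", Xp, tgt) / m          # (S, T, T+1)
    cov[:, T + 1 :, : T + 1] = cross
    cov[:, : T + 1, T + 1 :] = cross.transpose(0, 2, 1)
    cov[:, T + 1 :, T + 1 :] = np.einsum("stm,sum->stu", Xp, Xp) / m
    return np.array([_ndte_from_cov(c, T) for c in cov])


def surrogate_pvalues(
    epoch: np.ndarray,
    lag: ModelOrder | int,
    n_surrogates: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[RawFlowMatrix, SurrogateStats]:
    """Observed NDTE matrix of one epoch plus circular-shift surrogate stats.

    For every ordered pair the source series is rotated ``n_surrogates``
    times and the flow recomputed; ``p_trial`` follows the add-one rule.
    """
    from .ndte import ndte_matrix

    if n_surrogates < 19:
        raise ValidationError("n_surrogates must be >= 19 for a usable null")
    data = np.asarray(epoch, dtype=float)
    T = lag.lag_samples if isinstance(lag, ModelOrder) else int(lag)
    R, n = data.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = ndte_matrix(data, lag)
    mean = np.zeros((R, R))
    sd = np.zeros((R, R))
    p = np.ones((R, R))
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            offsets = _draw_offsets(rng, n, n_surrogates)
            null = _surrogate_flows(data[j], data[i], T, offsets)
            mean[i, j] = null.mean()
            sd[i, j] = null.std(ddof=0)
            p[i, j] = (1 + int((null >= observed.F[i, j]).sum())) / (n_surrogates + 1)
    return observed, SurrogateStats(mean, sd, p, n_surrogates)


def stouffer_combine(pvals) -> float:
    """One-sided Stouffer combination: z_i = Φ⁻¹(1−p_i), p = 1−Φ(Σz/√n)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(p <= 0) or np.any(p >= 1):
        warnings.warn("p-values clipped away from 0/1 for Stouffer", RuntimeWarning)
        p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))


def bh_fdr(pvals, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def standardize_and_mask(
    flows: list[np.ndarray],
    stats_list: list[list[SurrogateStats]],
    q: float = 0.05,
    region_labels: list[str] | None = None,
) -> NDTEMatrix:
    """Aggregate, mask and standardize per-trial flows across participants.

    Parameters
    ----------
    flows
        One ``(trials, R, R)`` array of raw NDTE matrices per participant.
    stats_list
        Matching per-participant lists of per-trial :class:`SurrogateStats`.
    q
        FDR level for the shared Benjamini–Hochberg mask.

    Per-trial p-values are Stouffer-combined across trials within each
    participant, then across participants; the BH mask is computed once on
    the group p matrix (all off-diagonal ordered pairs jointly) and shared
    by every participant. Each trial's flow is standardized against its own
    surrogate mean/SD; per-participant matrices are trial means, the group
    matrix their participant mean, zeroed outside the mask. Pairs with zero
    surrogate SD in a trial are dropped from that trial's average with a
    warning.
    """
    n_participants = len(flows)
    if n_participants == 0 or len(stats_list) != n_participants:
        raise ValidationError("flows and stats_list must align per participant")
    R = flows[0].shape[1]
    offdiag = ~np.eye(R, dtype=bool)

    p_participant = np.ones((n_participants, R, R))
    z_participant = np.zeros((n_participants, R, R))
    for k, (F, st) in enumerate(zip(flows, stats_list)):
        p_trials = np.stack([s.p_trial for s in st])           # (trials, R, R)
        for i in range(R):
            for j in range(R):
                if i != j:
                    p_participant[k, i, j] = stouffer_combine(p_trials[:, i, j])
        means = np.stack([s.surrogate_mean for s in st])
        sds = np.stack([s.surrogate_sd for s in st])
        valid = sds > 0
        if not valid[:, offdiag].all():
            warnings.warn("pairs with zero surrogate SD dropped from averaging",
                          RuntimeWarning)
        zt = np.where(valid, (F - means) / np.where(valid, sds, 1.0), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z_participant[k] = np.nanmean(zt, axis=0)
        z_participant[k][~np.isfinite(z_participant[k])] = 0.0

    p_group = np.ones((R, R))
    for i in range(R):
        for j in range(R):
            if i != j:
                p_group[i, j] = stouffer_combine(p_participant[:, i, j])

    mask = np.zeros((R, R), dtype=bool)
    mask[offdiag] = bh_fdr(p_group[offdiag], q)
    z_participant *= mask
    return NDTEMatrix(
        Z=z_participant.mean(axis=0),
        per_participant_Z=z_participant,
        mask=mask,
        p_group=p_group,
        region_labels=region_labels,
    )
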
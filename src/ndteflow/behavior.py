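"""Linking directed connectivity to behaviour.

Per-participant reaction-time condition differences (non-predictive 50% −
predictive 80%, after excluding over-cutoff responses) are correlated with
the strongest inflow connections of the condition-effect flow matrix using
Pearson's r, with Benjamini–Hochberg correction across the selected
connections.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .surrogates import NDTEMatrix, bh_fdr
from .synthetic import NONPREDICTIVE, PREDICTIVE

__all__ = [
    "rt_condition_difference",
    "top_k_connections",
    "correlate_rt_fc",
]

RT_CUTOFF_MS = 1000.0


def rt_condition_difference(
    behavior: pd.DataFrame, cutoff_ms: float = RT_CUTOFF_MS
) -> pd.Series:
    """Per-participant ΔRT = mean RT(50%) − mean RT(80%).

    Trials with ``rt_ms > cutoff_ms`` (or missing RT) are excluded before
    averaging. Participants missing either condition after exclusion are
    dropped with a warning.
    """
    if cutoff_ms <= 0:
        raise ValidationError("cutoff must be positive")
    df = behavior.dropna(subset=["rt_ms"])
    df = df[df["rt_ms"] <= cutoff_ms]
    out = {}
    for pid, grp in df.groupby("participant_id"):
        m50 = grp.loc[grp["condition"] == NONPREDICTIVE, "rt_ms"]
        m80 = grp.loc[grp["condition"] == PREDICTIVE, "rt_ms"]
        if m50.empty or m80.empty:
            warnings.warn(f"participant {pid} missing a condition; excluded",
                          RuntimeWarning)
            continue
        out[pid] = float(m50.mean() - m80.mean())
    return pd.Series(out, name="delta_rt_ms").rename_axis("participant_id")


def top_k_connections(result: NDTEMatrix, k: int) -> list[tuple[str, str, float]]:
    """The k strongest masked inflow connections, ``(target, source, Z)``.

    Pairs are sorted by group Z descending with a deterministic tie-break on
    (target label, source label).
    """
    R = result.Z.shape[0]
    labels = result.region_labels or [f"roi{i:02d}" for i in range(R)]
    pairs = [
        (labels[i], labels[j], float(result.Z[i, j]), i, j)
        for i in range(R)
        for j in range(R)
        if i != j and result.mask[i, j]
    ]
    if k > len(pairs):
        raise ValidationError(f"k={k} exceeds {len(pairs)} masked pairs")
    if k < 1:
        raise ValidationError("k must be >= 1")
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return [(t, s, z) for t, s, z, _, _ in pairs[:k]]


def correlate_rt_fc(
    deltas: pd.Series,
    connections: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of ΔRT with each connection across participants.

    Parameters
    ----------
    deltas
        Per-participant ΔRT, indexed by participant.
    connections
        Per-participant connection strengths (participants × connections);
        column names identify the connections, index must match ``deltas``.
    q
        FDR level for the Benjamini–Hochberg correction across connections.

    Returns a frame with ``r``, ``p_raw`` and ``p_corrected`` per connection;
    zero-variance inputs yield missing (NaN) correlations that are excluded
    from the correction.
    """
    common = deltas.index.intersection(connections.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 participants with both measures")
    x = deltas.loc[common].to_numpy(dtype=float)
    rows = []
    for col in connections.columns:
        y = connections.loc[common, col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((col, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((col, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["connection", "r", "p_raw"]).set_index("connection")
    valid = out["p_raw"].notna()
    out["p_corrected"] = np.nan
    if valid.any():
        out.loc[valid, "p_corrected"] = _bh_adjust(out.loc[valid, "p_raw"].to_numpy(), q)
    return out


def _bh_adjust(pvals: np.ndarray, q: float) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up); rejection at level q matches bh_fdr."""
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    # consistency with the shared mask routine
    assert np.array_equal(reject, bh_fdr(pvals, q))
    return p_adj
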
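"""Functional rich-club (FRIC) hub detection on directed flow matrices.

The functional rich club is the core set of regions that are more densely
connected among themselves and receive more inflow than they send outflow.
Its score for a candidate club is

    FRIC(club) = within-club flow + inflow from non-members − outflow to non-members,

which, with the orientation convention ``M[i, j]`` = flow j → i, equals
``Σ inflow(club) − Σ outflow(club) + Σ within-club``. The detected club is
grown along the total-inflow ranking, one region at a time, and each size k
is kept only while a Monte-Carlo comparison against surrogate clubs (same
k−1 members plus one random other region) stays below the alpha level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "FRICResult",
    "total_inflow",
    "total_outflow",
    "fric_value",
    "club_pvalue",
    "find_fric",
]


@dataclass
class FRICResult:
    """Detected functional rich club.

    ``ranking`` lists all region labels by total inflow (descending,
    ties broken by label order); ``club`` is the accepted prefix of that
    ranking; ``fric_values`` / ``p_values`` record every tested size k.
    ``significant`` is False when even the first tested size failed, in
    which case ``club`` falls back to the single top-inflow region.
    """

    ranking: list[str]
    club: list[str]
    fric_values: dict[int, float] = field(default_factory=dict)
    p_values: dict[int, float] = field(default_factory=dict)
    n_mc: int = 0
    alpha: float = 0.05
    significant: bool = True

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ranking": self.ranking,
                    "club": self.club,
                    "fric_values": {str(k): v for k, v in self.fric_values.items()},
                    "p_values": {str(k): v for k, v in self.p_values.items()},
                    "n_mc": self.n_mc,
                    "alpha": self.alpha,
                    "significant": self.significant,
                },
                fh,
                indent=1,
            )


def _check_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError("flow matrix must be square")
    return M


def total_inflow(M: np.ndarray) -> np.ndarray:
    """Total inflow per region: row sums under M[i, j] = flow j -> i."""
    return _check_square(M).sum(axis=1)


def total_outflow(M: np.ndarray) -> np.ndarray:
    """Total outflow per region: column sums under M[i, j] = flow j -> i."""
    return _check_square(M).sum(axis=0)


def _club_indices(club, n: int, labels: list[str] | None) -> np.ndarray:
    if labels is not None:
        lookup = {lab: i for i, lab in enumerate(labels)}
        try:
            idx = np.array([lookup[c] if isinstance(c, str) else int(c) for c in club])
        except KeyError as err:
            raise ValidationError(f"unknown region {err.args[0]!r} in club") from err
    else:
        idx = np.array([int(c) for c in club])
    if len(idx) == 0:
        raise ValidationError("club must be non-empty")
    if idx.min() < 0 or idx.max() >= n or len(set(idx.tolist())) != len(idx):
        raise ValidationError("club contains invalid or duplicate regions")
    return idx


def fric_value(M: np.ndarray, club, labels: list[str] | None = None) -> float:
    """FRIC score of a club: within + inflow-from-outside − outflow-to-outside."""
    M = _check_square(M)
    idx = _club_indices(club, M.shape[0], labels)
    within = M[np.ix_(idx, idx)].sum()
    return float(total_inflow(M)[idx].sum() - total_outflow(M)[idx].sum() + within)


def club_pvalue(
    M: np.ndarray,
    club,
    n_mc: int,
    seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
) -> float:
    """Monte-Carlo p-value of a club of size k against surrogate clubs.

    Each surrogate keeps the first k−1 members and swaps the k-th for a
    uniformly random non-member (the k-th member itself excluded);
    p = (1 + #{surrogate FRIC ≥ observed FRIC}) / (n_mc + 1).
    """
    M = _check_square(M)
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    idx = _club_indices(club, M.shape[0], labels)
    if len(idx) < 2:
        raise ValidationError("club must have at least 2 members for a surrogate test")
    fixed, last = idx[:-1], idx[-1]
    n = M.shape[0]
    candidates = np.setdiff1d(np.arange(n), idx)
    if candidates.size == 0:
        raise DegenerateInputError("no eligible replacement member for surrogate clubs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    inflow, outflow = total_inflow(M), total_outflow(M)
    w_fixed = M[np.ix_(fixed, fixed)].sum()
    base = inflow[fixed].sum() - outflow[fixed].sum() + w_fixed
    # candidate r completes the surrogate: add its net flow and cross terms
    cand_vals = (
        base
        + inflow[candidates] - outflow[candidates]
        + M[np.ix_(candidates, fixed)].sum(axis=1)
        + M[np.ix_(fixed, candidates)].sum(axis=0)
    )
    observed = base + inflow[last] - outflow[last] + M[last, fixed].sum() + M[fixed, last].sum()
    draws = cand_vals[rng.integers(0, candidates.size, size=n_mc)]
    return (1 + int((draws >= observed).sum())) / (n_mc + 1)


def find_fric(
    M: np.ndarray,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
    labels: list[str] | None = None,
) -> FRICResult:
    """Grow the functional rich club along the inflow ranking.

    Starting from the two highest-inflow regions, the club is extended by the
    next-ranked region as long as :func:`club_pvalue` stays below ``alpha``;
    the first non-significant size stops the search. If even size 2 fails,
    the singleton top-inflow region is returned flagged non-significant.
    """
    M = _check_square(M)
    n = M.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 regions for FRIC detection")
    if labels is None:
        labels = [f"roi{i:02d}" for i in range(n)]
    inflow = total_inflow(M)
    # descending inflow, ties broken by label order (stable sort on labels first)
    order = np.lexsort((np.argsort(np.argsort(labels)), -inflow))
    ranking = [labels[i] for i in order]
    rng = np.random.default_rng(seed)

    fric_values: dict[int, float] = {}
    p_values: dict[int, float] = {}
    accepted = 0
    for k in range(2, n):
        club_idx = order[:k]
        fric_values[k] = fric_value(M, club_idx)
        p_values[k] = club_pvalue(M, club_idx, n_mc=n_mc, seed=rng)
        if p_values[k] < alpha:
            accepted = k
        else:
            break
    if accepted == 0:
        return FRICResult(
            ranking=ranking,
            club=[ranking[0]],
            fric_values=fric_values,
            p_values=p_values,
            n_mc=n_mc,
            alpha=alpha,
            significant=False,
        )
    return FRICResult(
        ranking=ranking,
        club=ranking[:accepted],
        fric_values=fric_values,
        p_values=p_values,
        n_mc=n_mc,
        alpha=alpha,
        significant=True,
    )
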
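"""Normalized directed transfer entropy (NDTE) between region pairs.

NDTE measures the directed information flow from a source time series X to a
target Y as the conditional mutual information between X's past and Y's
next sample given Y's own past,

    F(X -> Y) = I(Y_t ; X_past | Y_past) / I(Y_t ; X_past, Y_past),

normalized by the total information the joint past carries about Y's
future, which bounds F in [0, 1] and makes flows comparable across pairs.
All (conditional) mutual informations are differences of Gaussian entropies
H = n/2·ln(2πe) + ½·ln det Σ computed from empirical covariance matrices of
lag-embedded vectors. The embedding length (model order) is taken from the
first minimum of the sample autocorrelation function, averaged over regions
and trials.

Orientation convention everywhere: ``M[i, j]`` is the flow from source
region ``j`` into target region ``i`` (inflow along rows, outflow along
columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "ModelOrder",
    "RawFlowMatrix",
    "estimate_model_order",
    "gaussian_entropy",
    "ndte_pair",
    "ndte_matrix",
    "write_flow_matrix",
]

LN_2PIE = float(np.log(2 * np.pi * np.e))
_DENOM_FLOOR = 1e-12
_JITTER = 1e-10


@dataclass
class ModelOrder:
    """Embedding length for the NDTE past, in samples and milliseconds."""

    lag_samples: int
    lag_ms: float
    per_unit_decays: list[int]

    def __post_init__(self):
        if self.lag_samples < 1:
            raise ValidationError("lag_samples must be >= 1")


@dataclass
class RawFlowMatrix:
    """Unstandardized NDTE flows; ``F[i, j]`` = flow j -> i, zero diagonal."""

    F: np.ndarray
    lag: ModelOrder
    region_labels: list[str] | None = None


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom <= 0:
        raise DegenerateInputError("constant trace: autocorrelation undefined")
    n = len(x)
    return np.array([x[: n - k] @ x[k:] / denom for k in range(max_lag + 2)])


def _first_minimum(acf: np.ndarray, max_lag: int) -> int:
    """First local minimum of the ACF; 1/e crossing as fallback."""
    descended = False
    for tau in range(1, max_lag):
        if acf[tau] <= acf[tau - 1]:
            descended = True
        if descended and acf[tau] < acf[tau + 1]:
            return tau
    below = np.flatnonzero(acf[1 : max_lag + 1] < 1.0 / np.e)
    if below.size:
        return int(below[0]) + 1
    return max_lag


def estimate_model_order(epochs: EpochSet, max_lag: int) -> ModelOrder:
    """Model order from the autocorrelation first minimum.

    Per region and trial the first local minimum of the sample ACF is found
    (falling back to the 1/e crossing when the ACF decays monotonically);
    the rounded mean over regions and trials is returned. At pipeline level
    the same averaging extends over conditions and participants by pooling
    epochs before calling this.
    """
    if max_lag >= epochs.n_samples // 2:
        raise ValidationError(
            f"max_lag={max_lag} too large for {epochs.n_samples}-sample epochs"
        )
    decays = []
    for trial in epochs.data:
        for trace in trial:
            decays.append(_first_minimum(_acf(trace, max_lag), max_lag))
    lag = max(1, int(round(float(np.mean(decays)))))
    return ModelOrder(
        lag_samples=lag,
        lag_ms=lag * 1000.0 / epochs.fs_hz,
        per_unit_decays=decays,
    )


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy (nats) of a Gaussian with covariance ``cov``.

    H = n/2·ln(2πe) + ½·ln det Σ, with the determinant from a stable
    factorization after adding a relative jitter floor to the diagonal.
    Small negative eigenvalues (within -1e-10) are tolerated via the jitter.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValidationError("covariance must be a square matrix")
    n = cov.shape[0]
    jitter = _JITTER * max(np.trace(cov), 1.0)
    sign, logdet = np.linalg.slogdet(cov + jitter * np.eye(n))
    if sign <= 0:
        raise DegenerateInputError("covariance is not positive definite")
    return n / 2.0 * LN_2PIE + 0.5 * float(logdet)


def _embed_past(x: np.ndarray, lag: int) -> np.ndarray:
    """Rows l=1..lag of x_{t-l} aligned to future index t = lag..n-1."""
    n = len(x)
    return np.stack([x[lag - l : n - l] for l in range(1, lag + 1)])


def _entropy_from_cov(cov: np.ndarray, idx: np.ndarray) -> float:
    sub = cov[np.ix_(idx, idx)]
    jitter = _JITTER * max(np.trace(sub), 1.0)
    sign, logdet = np.linalg.slogdet(sub + jitter * np.eye(len(idx)))
    return len(idx) / 2.0 * LN_2PIE + 0.5 * logdet


def _ndte_from_cov(cov: np.ndarray, T: int) -> float:
    """NDTE from the covariance of the stacked vector [y_t, Y_past, X_past]."""
    i_f = np.array([0])
    i_yp = np.arange(1, T + 1)
    i_xp = np.arange(T + 1, 2 * T + 1)
    h_f = _entropy_from_cov(cov, i_f)
    h_yp = _entropy_from_cov(cov, i_yp)
    h_f_yp = _entropy_from_cov(cov, np.concatenate([i_f, i_yp]))
    h_xp_yp = _entropy_from_cov(cov, np.concatenate([i_yp, i_xp]))
    h_all = _entropy_from_cov(cov, np.arange(2 * T + 1))
    numerator = h_f_yp + h_xp_yp - h_yp - h_all
    denominator = h_f + h_xp_yp - h_all
    if denominator < _DENOM_FLOOR:
        return 0.0
    return float(np.clip(numerator / denominator, 0.0, 1.0))


def ndte_pair(x: np.ndarray, y: np.ndarray, lag: ModelOrder | int) -> float:
    """NDTE flow from source ``x`` into target ``y``.

    Both pasts are embedded over ``lag`` samples, the future horizon is one
    sample. Covariances use biased (1/n) normalization over the within-epoch
    time dimension. Returns a value in [0, 1]; 0 when the joint past carries
    no information about the target's future.
    """
    T = lag.lag_samples if isinstance(lag, ModelOrder) else int(lag)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D series of equal length")
    if len(x) <= 3 * T:
        raise ValidationError(f"series length {len(x)} too short for lag {T}")
    Z = np.vstack([y[T:], _embed_past(y, T), _embed_past(x, T)])
    Zc = Z - Z.mean(axis=1, keepdims=True)
    cov = Zc @ Zc.T / Z.shape[1]
    return _ndte_from_cov(cov, T)


def _stack_embeddings(data: np.ndarray, T: int) -> np.ndarray:
    """Stack [future_r]*R then [past_r]*R for all regions; shape (R(1+T), m)."""
    R = data.shape[0]
    futures = data[:, T:]
    pasts = [_embed_past(data[r], T) for r in range(R)]
    return np.vstack([futures] + pasts)


def ndte_matrix(epoch: np.ndarray | EpochSet, lag: ModelOrder | int,
                trial: int | None = None) -> RawFlowMatrix:
    """NDTE between all ordered region pairs of a single epoch.

    ``epoch`` is a ``(regions, samples)`` array, or an :class:`EpochSet`
    with ``trial`` selecting the epoch. All pairwise flows are read off a
    single joint covariance of every region's future and lag-embedded past,
    which is numerically identical to calling :func:`ndte_pair` per pair.
    """
    labels = None
    if isinstance(epoch, EpochSet):
        if trial is None:
            raise ValidationError("pass trial index when giving an EpochSet")
        labels = list(epoch.region_labels)
        data = epoch.data[trial]
    else:
        data = np.asarray(epoch, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValidationError("epoch must be (regions >= 2, samples)")
    T = lag.lag_samples if isinstance(lag, ModelOrder) else int(lag)
    R, n = data.shape
    if n <= 3 * T:
        raise ValidationError(f"series length {n} too short for lag {T}")
    Z = _stack_embeddings(data, T)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    cov = Zc @ Zc.T / Z.shape[1]

    def block(r):  # indices of region r's [future, past] inside the joint cov
        fut = r
        past = R + r * T + np.arange(T)
        return fut, past

    F = np.zeros((R, R))
    for i in range(R):          # target
        fi, pi = block(i)
        for j in range(R):      # source
            if i == j:
                continue
            _, pj = block(j)
            idx = np.concatenate([[fi], pi, pj])
            sub = cov[np.ix_(idx, idx)]
            F[i, j] = _ndte_from_cov(sub, T)
    mo = lag if isinstance(lag, ModelOrder) else ModelOrder(T, float("nan"), [])
    return RawFlowMatrix(F=F, lag=mo, region_labels=labels)


def write_flow_matrix(path, matrix: np.ndarray, region_labels: list[str]) -> None:
    """Write a flow matrix as TSV with labels and the orientation convention."""
    with open(path, "w") as fh:
        fh.write("# M[i,j] = flow j -> i\n")
        fh.write("\t" + "\t".join(region_labels) + "\n")
        for label, row in zip(region_labels, matrix):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
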
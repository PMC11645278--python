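"""Gaussian-copula O-information connectivity.

The O-information of a multivariate system quantifies whether its
interdependencies are dominated by redundancy (shared randomness, positive
values) or synergy (collective constraints, negative values). For three
blocks x, y, z it reads

    O(x, y, z) = H(x,y,z) - H(x,y) - H(x,z) - H(y,z) + H(x) + H(y) + H(z)

and for n variables

    O(X) = (n - 2) H(X) + sum_j [ H(X_j) - H(X_{-j}) ].

Entropies are estimated under the Gaussian-copula approximation: each
margin is rank-transformed to a standard-normal margin and the differential
entropy is the closed-form Gaussian entropy of the covariance of the
transformed data, H = 1/2 ln((2 pi e)^k det Sigma). This makes every
O-information value invariant to strictly monotone per-region transforms.

The per-subject connectivity matrix assigns to the pair (i, j) the
three-block O-information of ({i}, {j}, all remaining regions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ContractError, DegenerateInputError
from .synthetic import RegionTimeSeries

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))
_RIDGE = 1e-8


@dataclass
class OmegaMatrix:
    """R x R symmetric O-information connectivity matrix (zero diagonal)."""

    subject_id: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractError("omega values must be a square matrix")
        if not np.allclose(v, v.T, atol=0, rtol=0, equal_nan=True):
            raise ContractError("omega matrix must be exactly symmetric")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def copula_transform(X: np.ndarray) -> np.ndarray:
    """Rank-Gaussianize each column: Phi^{-1}(rank / (T + 1)), average ties."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = X.shape[0]
    if T < 3:
        raise ContractError(f"need at least 3 samples, got {T}")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0 or not np.all(np.isfinite(col)):
            raise DegenerateInputError(
                f"column {j} is constant or non-finite; cannot copula-transform"
            )
        out[:, j] = stats.norm.ppf(stats.rankdata(col, method="average") / (T + 1))
    return out


def _gaussian_entropy_from_cov(cov: np.ndarray) -> float:
    """H = 1/2 ln((2 pi e)^k det Sigma) via Cholesky log-determinant."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = cov.shape[0]
    cov = cov + _RIDGE * np.eye(k)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("covariance not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return 0.5 * (k * _LN_2PIE + logdet)


def gaussian_entropy(cov: np.ndarray, idx=None) -> float:
    """Closed-form Gaussian entropy of (a sub-block of) a covariance matrix."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if idx is not None:
        idx = np.asarray(idx, dtype=int)
        cov = cov[np.ix_(idx, idx)]
    return _gaussian_entropy_from_cov(cov)


def gaussian_copula_entropy(X: np.ndarray, transformed: bool = False) -> float:
    """Gaussian-copula differential entropy (nats) of the joint columns of X."""
    Z = np.asarray(X, dtype=float) if transformed else copula_transform(X)
    if Z.ndim == 1:
        Z = Z[:, None]
    cov = np.cov(Z, rowvar=False, ddof=1)
    return _gaussian_entropy_from_cov(np.atleast_2d(cov))


def o_information_from_cov(cov: np.ndarray, blocks) -> float:
    """O-information of column blocks, from a (copula-)covariance matrix.

    For exactly three blocks this evaluates the three-block expansion; for
    more it uses the general (n-2) H(X) + sum_j [H(X_j) - H(X_{-j})] form
    with blocks treated as single variables.
    """
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    if len(blocks) < 3:
        raise ContractError("o_information needs at least 3 blocks")
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = len(blocks)
    H = lambda ix: gaussian_entropy(cov, ix)  # noqa: E731
    if n == 3:
        x, y, z = blocks
        return (
            H(np.concatenate([x, y, z]))
            - H(np.concatenate([x, y]))
            - H(np.concatenate([x, z]))
            - H(np.concatenate([y, z]))
            + H(x)
            + H(y)
            + H(z)
        )
    full = np.concatenate(blocks)
    total = (n - 2) * H(full)
    for j in range(n):
        rest = np.concatenate([blocks[q] for q in range(n) if q != j])
        total += H(blocks[j]) - H(rest)
    return total


def o_information(X: np.ndarray, blocks=None) -> float:
    """Gaussian-copula O-information of the column blocks of data matrix X."""
    X = np.asarray(X, dtype=float)
    if blocks is None:
        blocks = [[j] for j in range(X.shape[1])]
    Z = copula_transform(X)
    cov = np.cov(Z, rowvar=False, ddof=1)
    return o_information_from_cov(cov, blocks)


def omega_matrix_from_cov(
    cov: np.ndarray, subject_id: str = "cov"
) -> OmegaMatrix:
    """Pairwise-conditioned O-information matrix from a covariance matrix.

    Entry (i, j) is the three-block O-information of ({i}, {j}, all other
    regions). Single-variable and leave-one-out entropies are computed once
    and reused across pairs; the pair-specific terms H(i, j) and
    H(all-but-{i, j}) are evaluated per pair.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    R = cov.shape[0]
    if R < 3:
        raise ContractError("need at least 3 regions")
    all_idx = np.arange(R)
    H_full = gaussian_entropy(cov)
    H_single = np.array([gaussian_entropy(cov, [i]) for i in range(R)])
    H_loo = np.array(
        [gaussian_entropy(cov, np.delete(all_idx, i)) for i in range(R)]
    )
    out = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            rest = np.delete(all_idx, [i, j])
            # H(x,y,z)=H_full; H(x,z)=H_loo[j]; H(y,z)=H_loo[i]
            om = (
                H_full
                - gaussian_entropy(cov, [i, j])
                - H_loo[j]
                - H_loo[i]
                + H_single[i]
                + H_single[j]
                + gaussian_entropy(cov, rest)
            )
            out[i, j] = out[j, i] = om
    return OmegaMatrix(subject_id=subject_id, values=out, normalized=False)


def omega_matrix(ts: RegionTimeSeries) -> OmegaMatrix:
    """Per-subject R x R O-information connectivity matrix (nats)."""
    if ts.n_regions < 3:
        raise ContractError("need at least 3 regions")
    Z = copula_transform(ts.data)
    cov = np.cov(Z, rowvar=False, ddof=1)
    return omega_matrix_from_cov(cov, subject_id=ts.subject_id)


def normalize_omega(m: OmegaMatrix) -> OmegaMatrix:
    """Scale by the maximum absolute off-diagonal entry, into [-1, 1].

    The sign of every entry is preserved; an all-zero matrix is returned
    unchanged (flagged normalized). Idempotent.
    """
    v = m.values.copy()
    off = np.abs(v[~np.eye(v.shape[0], dtype=bool)])
    peak = off.max() if off.size else 0.0
    if peak > 0:
        v = v / peak
    return replace(m, values=v, normalized=True)
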
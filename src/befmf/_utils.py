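"""Shared numeric helpers: seeded random streams and fast OLS primitives."""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, *labels: str) -> np.random.Generator:
    """Return an independent random generator for a named stream.

    Every stream is derived from the single run seed plus a stable hash of
    the label path, so adding a new stream never perturbs draws made by
    existing ones, and identical (seed, labels) always reproduce the same
    sequence.
    """
    spawn_key = tuple(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def derive_seed(seed: int, *labels: str) -> int:
    """A 31-bit child seed for APIs that want a plain integer."""
    ss = np.random.SeedSequence(
        seed, spawn_key=tuple(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def ols_rss(
    y: np.ndarray, X: np.ndarray, intercept: bool = True, allow_rank_deficient: bool = False
) -> float:
    """Residual sum of squares of an OLS fit (intercept added by default)."""
    y = np.asarray(y, dtype=float)
    M = add_intercept(as_2d(X)) if intercept else as_2d(X)
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < M.shape[1] and not allow_rank_deficient:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {M.shape[1]} columns)"
        )
    resid = y - M @ beta
    return float(resid @ resid)


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Plain coefficient of determination of OLS with intercept."""
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("response is constant; R^2 undefined")
    return 1.0 - ols_rss(y, X) / tss


def zscore(x, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-score a constant column")
    return (x - x.mean()) / sd
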
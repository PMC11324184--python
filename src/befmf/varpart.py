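"""Variation partitioning of adjusted R² among 2-4 predictor groups.

For predictor groups G1..Gk the adjusted R² (Ezekiel) of every non-empty
subset model is computed and decomposed by inclusion-exclusion into the
unique fraction of each group and the fractions shared by every
combination of groups, so that all fractions sum exactly to the adjusted
R² of the full model. Adjusted R² fractions can legitimately be negative;
both the raw and the zero-truncated values are reported.

Unique fractions are tested with a Freedman-Lane permutation test: the
residuals of the reduced model (conditioning groups only) are permuted,
re-attached to the reduced-model fit, and the pseudo-F of the focal
group's partial contribution is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import as_2d, ols_rss, stream_rng, zscore

__all__ = ["adjusted_r2", "VariancePartition", "VarPartResult", "test_unique_fraction"]


def adjusted_r2(y, X) -> float:
    """Ezekiel-adjusted R² of OLS with intercept.

    R²adj = 1 - (1 - R²) (n - 1) / (n - p - 1). Requires n > p + 1.
    """
    y = np.asarray(y, dtype=float)
    X = as_2d(X)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant response")
    r2 = 1.0 - ols_rss(y, X) / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _subset_key(names: tuple[str, ...]) -> str:
    return "+".join(names)


@dataclass
class VarPartResult:
    """Unique/shared adjusted-R² fractions for named predictor groups."""

    group_names: list[str]
    r2adj_subsets: dict[str, float]  # subset key -> adjusted R²
    fractions: dict[str, float]  # combination key -> raw fraction
    fractions_truncated: dict[str, float]
    residual: float
    n: int
    p_unique: dict[str, float] | None = None

    @property
    def full_r2adj(self) -> float:
        return self.r2adj_subsets[_subset_key(tuple(sorted(self.group_names)))]

    def unique(self, group: str) -> float:
        return self.fractions[group]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.fractions:
            rows.append(
                {
                    "fraction": key,
                    "raw": self.fractions[key],
                    "truncated": self.fractions_truncated[key],
                    "p": (self.p_unique or {}).get(key, np.nan),
                }
            )
        rows.append(
            {"fraction": "residual", "raw": self.residual, "truncated": self.residual, "p": np.nan}
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Variation partitioning (adjusted R²)",
            f"  groups: {', '.join(self.group_names)}   n = {self.n}",
            f"  full-model R²adj = {self.full_r2adj:.4f}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class VariancePartition:
    """Partition the variance of ``y`` among named groups of predictors.

    Parameters
    ----------
    y : array-like
        Univariate response.
    groups : dict[str, array-like]
        2-4 named predictor groups; each value is a column or matrix.
    standardize : bool
        z-score all predictor columns first (default; R² is unaffected
        but conditioning improves).
    """

    def __init__(self, y, groups: dict, standardize: bool = True):
        if not 2 <= len(groups) <= 4:
            raise ValueError(f"need 2-4 predictor groups, got {len(groups)}")
        self.y = np.asarray(y, dtype=float)
        self.group_names = sorted(groups)
        self.groups = {}
        for name in self.group_names:
            X = as_2d(groups[name])
            if len(X) != len(self.y):
                raise ValueError(f"group {name!r} has {len(X)} rows, response has {len(self.y)}")
            if standardize:
                X = np.column_stack([zscore(X[:, j]) for j in range(X.shape[1])])
            self.groups[name] = X

    def _design(self, names) -> np.ndarray:
        return np.column_stack([self.groups[n] for n in names])

    def fit(self) -> VarPartResult:
        names = tuple(self.group_names)
        k = len(names)
        r2adj: dict[tuple[str, ...], float] = {}
        for r in range(1, k + 1):
            for subset in combinations(names, r):
                r2adj[subset] = adjusted_r2(self.y, self._design(subset))

        # Fraction attributable to exactly the combination T (its members
        # jointly, beyond everything else): Möbius inclusion-exclusion
        #   f(T) = sum_{S subset of T} (-1)^{|S|+1} R²adj(S u (G \ T))
        # For k=2 this reduces to the familiar identities
        #   unique(A) = R(AB) - R(B); shared(AB) = R(A) + R(B) - R(AB).
        fractions: dict[str, float] = {}
        for r in range(1, k + 1):
            for T in combinations(names, r):
                rest = tuple(n for n in names if n not in T)
                val = 0.0
                for s in range(0, len(T) + 1):
                    for S in combinations(T, s):
                        joint = tuple(sorted(S + rest))
                        term = r2adj[joint] if joint else 0.0
                        val += ((-1) ** (len(S) + 1)) * term
                fractions["+".join(T)] = val

        subsets_by_key = {_subset_key(s): v for s, v in r2adj.items()}
        full = r2adj[names]
        truncated = {key: max(0.0, v) for key, v in fractions.items()}
        return VarPartResult(
            group_names=list(names),
            r2adj_subsets=subsets_by_key,
            fractions=fractions,
            fractions_truncated=truncated,
            residual=1.0 - full,
            n=len(self.y),
        )

    def fit_with_tests(self, n_perm: int = 999, seed: int = 17) -> VarPartResult:
        """Fit and attach Freedman-Lane permutation p-values for each unique fraction."""
        res = self.fit()
        res.p_unique = {}
        for name in self.group_names:
            others = [n for n in self.group_names if n != name]
            res.p_unique[name] = test_unique_fraction(
                self.y,
                self.groups[name],
                self._design(others),
                n_perm=n_perm,
                seed=seed,
            )
        return res


def test_unique_fraction(y, focal, conditioning, n_perm: int = 999, seed: int = 17) -> float:
    """Freedman-Lane permutation p-value for a group's unique contribution.

    Fits the reduced model (conditioning predictors only), permutes its
    residuals, adds them back to the reduced fit and recomputes the
    pseudo-F of the focal block. p = (#{F* >= F} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float)
    Xf = as_2d(focal)
    Xc = as_2d(conditioning)
    n = len(y)
    m = Xf.shape[1]
    p_full = Xf.shape[1] + Xc.shape[1]
    if n <= p_full + 1:
        raise ValueError("too few observations for the full model")

    def pseudo_f(resp):
        # a focal block collinear with the conditioning block legitimately
        # contributes nothing, so rank deficiency is tolerated here
        rss_red = ols_rss(resp, Xc)
        rss_full = ols_rss(resp, np.column_stack([Xc, Xf]), allow_rank_deficient=True)
        gain = rss_red - rss_full
        if gain <= 1e-12 * max(rss_red, 1e-300):  # numerically zero contribution
            return 0.0
        denom = rss_full / (n - p_full - 1)
        if denom <= 0:
            return np.inf
        return (gain / m) / denom

    f_obs = pseudo_f(y)
    # reduced-model fit and residuals (Freedman–Lane)
    Xc1 = np.column_stack([np.ones(n), Xc])
    beta, *_ = np.linalg.lstsq(Xc1, y, rcond=None)
    fitted = Xc1 @ beta
    resid = y - fitted
    rng = stream_rng(seed, "freedman-lane")
    hits = 0
    for _ in range(n_perm):
        y_star = fitted + rng.permutation(resid)
        if pseudo_f(y_star) >= f_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)
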
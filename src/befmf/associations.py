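"""Correlation and regression inference used across both study designs.

Covers Spearman rank correlations (with exact small-sample p-values),
partial correlations via the residual method, the small-sample corrected
Akaike information criterion, all-subsets AICc model averaging with
predictor-importance percentages, and a restricted-maximum-likelihood
linear mixed model with a single random intercept (the plant-combination
effect in the microcosm design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._utils import as_2d, zscore

__all__ = [
    "AssociationResult",
    "spearman",
    "partial_correlation",
    "aicc",
    "ModelAveraging",
    "ModelAveragingResult",
    "fit_mixed",
    "MixedModelFit",
]


@dataclass
class AssociationResult:
    pair: tuple[str, str]
    coefficient: float
    p: float
    n: int
    kind: str  # "spearman" | "partial-pearson"
    controls: list[str] = field(default_factory=list)

    def __iter__(self):  # allows `rho, p = spearman(...)` style unpacking
        yield self.coefficient
        yield self.p


def _spearman_exact_p(rho_obs: float, ranks_x: np.ndarray, ranks_y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all rank permutations (n <= 9)."""
    n = len(ranks_x)
    rx = ranks_x - ranks_x.mean()
    denom = np.sqrt((rx @ rx)) if rx.any() else 0.0
    count = 0
    total = factorial(n)
    ry0 = ranks_y - ranks_y.mean()
    denom_y = np.sqrt(ry0 @ ry0)
    target = abs(rho_obs) - 1e-12
    for perm in permutations(ranks_y):
        ry = np.asarray(perm, dtype=float) - ranks_y.mean()
        rho = (rx @ ry) / (denom * denom_y)
        if abs(rho) >= target:
            count += 1
    return count / total


def spearman(x, y, names: tuple[str, str] = ("x", "y")) -> AssociationResult:
    """Spearman rank correlation with midrank ties.

    The two-sided p-value uses the t approximation, except for n <= 9
    with untied data, where the exact permutation distribution is
    enumerated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties and np.isfinite(rho):
        p = _spearman_exact_p(rho, stats.rankdata(x), stats.rankdata(y))
    return AssociationResult(names, float(rho), float(p), n, "spearman")


def partial_correlation(x, y, controls=None, names: tuple[str, str] = ("x", "y")) -> AssociationResult:
    """Partial Pearson correlation of x and y given control variables.

    Computed as the Pearson correlation of the OLS residuals of x and y
    on the controls; p from a t distribution with n - k - 2 degrees of
    freedom where k is the number of controls. With no controls this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        Z = np.empty((n, 0))
        control_names: list[str] = []
    else:
        if isinstance(controls, pd.DataFrame):
            control_names = list(controls.columns)
            Z = controls.to_numpy(dtype=float)
        else:
            Z = as_2d(controls)
            control_names = [f"z{i}" for i in range(Z.shape[1])]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > #controls + 2 (n={n}, controls={k})")
    M = np.column_stack([np.ones(n), Z])
    rx = x - M @ np.linalg.lstsq(M, x, rcond=None)[0]
    ry = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    if sx < 1e-12 * np.abs(x).max() or sy < 1e-12 * max(np.abs(y).max(), 1e-300):
        raise ValueError("controls are collinear with x or y (no residual variance)")
    r = float((rx @ ry) / (sx * sy))
    df = n - k - 2
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clamped * np.sqrt(df / (1 - r_clamped**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(names, r, p, n, "partial-pearson", control_names)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n <= k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelAveragingResult:
    """All-subsets AICc averaging output."""

    predictors: list[str]
    model_table: pd.DataFrame  # per-model: terms, k, aicc, delta, weight, r2adj
    coefficients: pd.Series  # model-averaged standardized coefficients
    coefficient_se: pd.Series  # unconditional (model-averaging) SEs
    importance_pct: pd.Series
    r2adj_averaged: float

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.coefficients - z * self.coefficient_se
        hi = self.coefficients + z * self.coefficient_se
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "beta_avg": self.coefficients,
                "se": self.coefficient_se,
                "importance_%": self.importance_pct,
            }
        )
        return (
            "AICc model averaging over all predictor subsets\n"
            f"  models: {len(self.model_table)}   "
            f"averaged R2adj: {self.r2adj_averaged:.4f}\n\n"
            + tab.to_string(float_format=lambda v: f"{v:.4f}")
        )


class ModelAveraging:
    """All-subsets OLS with AICc weights and importance percentages.

    The response and every predictor are z-scored internally so the
    averaged coefficients are standardized effect sizes. Every subset of
    the predictors (including the intercept-only model) is fitted by OLS;
    Akaike weights w_m = exp(-delta_m / 2) normalised over models; the
    averaged coefficient of predictor j uses zero-method (full) averaging
    (beta = 0 in models excluding j), and its importance is
    100 |beta_j| / sum_j' |beta_j'|. The weighted mean of the per-model
    adjusted R² serves as the variance-explained companion figure.

    The intercept-only model is excluded from the candidate set, so with a
    single predictor the averaged coefficient reproduces that model's OLS
    estimate exactly.
    """

    MAX_PREDICTORS = 12

    def __init__(self, y, X: pd.DataFrame, averaging: str = "zero"):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        if X.shape[1] > self.MAX_PREDICTORS:
            raise ValueError(f"all-subsets averaging limited to {self.MAX_PREDICTORS} predictors")
        if averaging not in ("zero", "natural"):
            raise ValueError("averaging must be 'zero' or 'natural'")
        self.averaging = averaging
        self.names = list(X.columns)
        self.y = zscore(np.asarray(y, dtype=float))
        self.X = np.column_stack([zscore(X[c].to_numpy(dtype=float)) for c in self.names])
        cond = np.linalg.cond(np.corrcoef(self.X, rowvar=False)) if X.shape[1] > 1 else 1.0
        if cond > 1e8:
            raise ValueError("predictors are (near-)collinear; condition number guard tripped")

    def fit(self) -> ModelAveragingResult:
        n, p = self.X.shape
        rows = []
        betas, ses, terms_list = [], [], []
        for r in range(1, p + 1):
            for terms in combinations(range(p), r):
                M = sm.add_constant(self.X[:, terms])
                fit = sm.OLS(self.y, M).fit()
                k = len(terms) + 2  # slopes + intercept + residual variance
                rows.append(
                    {
                        "terms": "+".join(self.names[j] for j in terms) or "(null)",
                        "k": k,
                        "aicc": aicc(float(fit.llf), k, n),
                        "r2adj": float(fit.rsquared_adj) if terms else 0.0,
                    }
                )
                b = np.zeros(p)
                s = np.zeros(p)
                if terms:
                    b[list(terms)] = fit.params[1:]
                    s[list(terms)] = fit.bse[1:]
                betas.append(b)
                ses.append(s)
                terms_list.append(terms)
        table = pd.DataFrame(rows)
        table["delta"] = table["aicc"] - table["aicc"].min()
        w = np.exp(-table["delta"].to_numpy() / 2)
        w = w / w.sum()
        table["weight"] = w

        B = np.asarray(betas)
        S = np.asarray(ses)
        if self.averaging == "zero":
            beta_avg = w @ B
            # Burnham–Anderson unconditional SE, with beta=0, se=0 outside a model
            se_avg = np.array(
                [
                    np.sum(w * np.sqrt(S[:, j] ** 2 + (B[:, j] - beta_avg[j]) ** 2))
                    for j in range(p)
                ]
            )
        else:  # natural averaging: only over models containing the predictor
            beta_avg = np.empty(p)
            se_avg = np.empty(p)
            for j in range(p):
                inc = np.array([j in t for t in terms_list])
                wj = w[inc] / w[inc].sum()
                beta_avg[j] = wj @ B[inc, j]
                se_avg[j] = np.sum(
                    wj * np.sqrt(S[inc, j] ** 2 + (B[inc, j] - beta_avg[j]) ** 2)
                )
        abs_sum = np.abs(beta_avg).sum()
        importance = (
            100.0 * np.abs(beta_avg) / abs_sum
            if abs_sum > 0
            else np.full(p, 100.0 / p)
        )
        return ModelAveragingResult(
            predictors=self.names,
            model_table=table.sort_values("aicc").reset_index(drop=True),
            coefficients=pd.Series(beta_avg, index=self.names, name="beta_avg"),
            coefficient_se=pd.Series(se_avg, index=self.names, name="se"),
            importance_pct=pd.Series(importance, index=self.names, name="importance_pct"),
            r2adj_averaged=float(w @ table["r2adj"].to_numpy()),
        )


@dataclass
class MixedModelFit:
    """REML linear mixed model with one random intercept."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fvalues: pd.Series
    conf_int: pd.DataFrame
    group_var: float
    resid_var: float
    r2adj: float
    n: int
    n_groups: int
    ols_fallback: bool = False
    converged: bool = True

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "F": self.fvalues, "p": self.pvalues}
        )
        head = (
            f"Linear mixed model (REML), n = {self.n}, groups = {self.n_groups}\n"
            f"  random-intercept variance = {self.group_var:.4f}, "
            f"residual variance = {self.resid_var:.4f}, R2adj = {self.r2adj:.4f}"
        )
        if self.ols_fallback:
            head += "\n  [single grouping level: ordinary least squares fallback]"
        return head + "\n\n" + tab.to_string(float_format=lambda v: f"{v:.4f}")


def fit_mixed(y, X: pd.DataFrame, groups, reml: bool = True) -> MixedModelFit:
    """Fit ``y ~ X`` with a random intercept for ``groups`` by REML.

    Fixed-effect inference is Wald-based (F = t² per coefficient). When
    the grouping factor has a single level the model degenerates and an
    OLS fit is returned with ``ols_fallback`` set; when the true group
    variance is zero the REML estimate collapses towards zero and the
    fixed effects converge to OLS.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(as_2d(X), columns=[f"x{i}" for i in range(as_2d(X).shape[1])])
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n = len(y)
    names = list(X.columns)
    n_groups = len(np.unique(groups))

    if n_groups < 2:
        fit = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
        idx = ["Intercept"] + names
        ci = fit.conf_int()
        return MixedModelFit(
            params=pd.Series(np.asarray(fit.params), index=idx),
            bse=pd.Series(np.asarray(fit.bse), index=idx),
            pvalues=pd.Series(np.asarray(fit.pvalues), index=idx),
            fvalues=pd.Series(np.asarray(fit.tvalues) ** 2, index=idx),
            conf_int=pd.DataFrame(np.asarray(ci), index=idx, columns=["lower", "upper"]),
            group_var=0.0,
            resid_var=float(fit.mse_resid),
            r2adj=float(fit.rsquared_adj),
            n=n,
            n_groups=n_groups,
            ols_fallback=True,
        )

    data = X.copy()
    data["__y"] = y
    data["__g"] = groups
    formula = "__y ~ " + (" + ".join(f"Q('{c}')" for c in names) if names else "1")
    model = smf.mixedlm(formula, data, groups=data["__g"])
    try:
        fit = model.fit(reml=reml)
    except np.linalg.LinAlgError:
        # gradient-based optimisers can hit singular working matrices when
        # the group variance collapses; fall back to derivative-free search
        fit = model.fit(reml=reml, method="powell")
    fe = fit.fe_params
    idx = ["Intercept"] + names
    params = pd.Series(np.asarray(fe), index=idx)
    bse = pd.Series(np.asarray(fit.bse_fe), index=idx)
    if not np.isfinite(bse).all():
        # the observed-information SEs can degenerate numerically; fall back
        # to the model-based GLS covariance at the REML variance estimates
        Xm = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        g_idx = pd.factorize(groups)[0]
        Z = np.zeros((n, g_idx.max() + 1))
        Z[np.arange(n), g_idx] = 1.0
        V = fit.scale * np.eye(n) + float(np.asarray(fit.cov_re)[0, 0]) * (Z @ Z.T)
        cov = np.linalg.inv(Xm.T @ np.linalg.solve(V, Xm))
        bse = pd.Series(np.sqrt(np.diag(cov)), index=idx)
    tv = params / bse
    pv = pd.Series(
        2 * stats.norm.sf(np.abs(tv.to_numpy())), index=idx
    )
    z975 = stats.norm.ppf(0.975)
    ci = pd.DataFrame(
        {"lower": params - z975 * bse, "upper": params + z975 * bse}
    )
    # marginal pseudo-R2adj: squared correlation of fixed-effect prediction
    # with the response, Ezekiel-adjusted
    yhat = np.asarray(model.exog @ fe)
    r2 = 0.0 if np.std(yhat) == 0 else np.corrcoef(yhat, y)[0, 1] ** 2
    p_fixed = len(names)
    r2adj = 1 - (1 - r2) * (n - 1) / (n - p_fixed - 1) if n > p_fixed + 1 else np.nan
    return MixedModelFit(
        params=params,
        bse=bse,
        pvalues=pv,
        fvalues=tv**2,
        conf_int=pd.DataFrame(
            np.asarray(ci), index=idx, columns=["lower", "upper"]
        ),
        group_var=float(np.asarray(fit.cov_re)[0, 0]),
        resid_var=float(fit.scale),
        r2adj=float(r2adj),
        n=n,
        n_groups=n_groups,
        converged=bool(fit.converged),
    )
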
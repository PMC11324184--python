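"""Piecewise structural equation modelling over a user-declared DAG.

Each endogenous variable is fitted by its own linear model (OLS, or the
single-random-intercept mixed model when a grouping factor is declared
for that equation). Overall consistency of the causal structure with the
data is assessed by directed separation: every non-adjacent ordered pair
of variables yields an independence claim, tested by the partial
regression p-value of the earlier variable in the later variable's
equation augmented with it, and the claim p-values are combined into
Fisher's C = -2 sum(ln p_i), which is chi-square distributed with 2k
degrees of freedom when the structure is correct. The model is
conventionally retained when p(C) > 0.05.

Composite variables (e.g. a soil microbial richness block built from
bacterial and fungal richness) are collapsed to a single standardized
score using the indicator weights fitted from the composite's first
child equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .associations import fit_mixed

__all__ = ["SEMSpec", "SEMFit", "basis_set", "fishers_c", "PiecewiseSEM", "fit_sem"]


@dataclass
class SEMSpec:
    """Directed-acyclic structural specification.

    ``edges`` are (cause, effect) pairs over observed variables (binary
    treatments enter as numeric 0/1 regressors). ``groups`` optionally
    maps an endogenous variable to the name of a grouping column, turning
    that equation into a random-intercept mixed model. ``composites``
    maps a composite name to the list of indicator columns it summarises.
    """

    edges: list[tuple[str, str]]
    groups: dict[str, str] = field(default_factory=dict)
    composites: dict[str, list[str]] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structural specification contains a cycle")
        return g

    @property
    def nodes(self) -> list[str]:
        return list(self.graph().nodes)

    @classmethod
    def from_dict(cls, d: dict) -> "SEMSpec":
        return cls(
            edges=[tuple(e) for e in d["edges"]],
            groups=dict(d.get("groups", {})),
            composites={k: list(v) for k, v in d.get("composites", {}).items()},
        )


def _topological_rank(g: nx.DiGraph) -> dict[str, int]:
    """Stable variable ordering: topological generations, ties lexicographic."""
    rank = {}
    i = 0
    for gen in nx.topological_generations(g):
        for node in sorted(gen):
            rank[node] = i
            i += 1
    return rank


def basis_set(spec: SEMSpec) -> list[tuple[str, str, tuple[str, ...]]]:
    """Directed-separation claims (u, v, conditioning set).

    For each non-adjacent pair, with v the later variable in a
    topological order, the claim is independence of u and v given the
    union of the parents of both, following the basis set used with
    piecewise SEM. The claim list is deterministic (topological
    generations with lexicographic tie-breaks).
    """
    g = spec.graph()
    rank = _topological_rank(g)
    claims = []
    for a, b in combinations(sorted(g.nodes, key=rank.get), 2):
        if g.has_edge(a, b) or g.has_edge(b, a):
            continue
        u, v = (a, b) if rank[a] <= rank[b] else (b, a)
        cond = (set(g.predecessors(v)) | set(g.predecessors(u))) - {u, v}
        claims.append((u, v, tuple(sorted(cond))))
    return claims


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C statistic over independence-claim p-values.

    C = -2 sum(ln p_i) ~ chi-square with df = 2k under the causal
    structure. An empty claim set is a saturated model: (0, 0, 1).
    Any p_i = 0 yields C = +inf with p(C) = 0.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("claim p-values must lie in (0, 1]")
    if np.any(p == 0):
        return float("inf"), 2 * p.size, 0.0
    c = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return c, df, float(stats.chi2.sf(c, df))


@dataclass
class SEMFit:
    """Fitted piecewise SEM."""

    paths: pd.DataFrame  # one row per edge: estimate, std_estimate, se, p
    r2: dict[str, float]
    claims: pd.DataFrame  # one row per independence claim with its p
    C: float
    df: int
    p_C: float
    aic: float
    n_params: int
    saturated: bool

    def standardized_coefficient(self, cause: str, effect: str) -> float:
        row = self.paths[(self.paths["from"] == cause) & (self.paths["to"] == effect)]
        if row.empty:
            raise KeyError(f"no path {cause} -> {effect}")
        return float(row["std_estimate"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Piecewise structural equation model",
            f"  Fisher's C = {self.C:.3f}, df = {self.df}, p = {self.p_C:.4f}"
            + ("  [saturated]" if self.saturated else ""),
            f"  AIC (C + 2K) = {self.aic:.3f}   K = {self.n_params}",
            "  R² per equation: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.r2.items()),
            "",
            self.paths.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if len(self.claims):
            lines += ["", "Independence claims:", self.claims.to_string(index=False)]
        return "\n".join(lines)


class PiecewiseSEM:
    """Model object: fit a :class:`SEMSpec` to a data frame."""

    def __init__(self, spec: SEMSpec, data: pd.DataFrame):
        self.spec = spec
        g = spec.graph()
        needed = (set(g.nodes) - set(spec.composites)) | {
            i for inds in spec.composites.values() for i in inds
        }
        missing = sorted(needed - set(data.columns))
        if missing:
            raise KeyError(f"variables missing from data: {missing}")
        self.data = data.copy()
        self._build_composites(g)

    def _build_composites(self, g: nx.DiGraph) -> None:
        # composite score = fitted linear combination of its indicators,
        # with weights taken from the first child equation, then z-scored
        for comp, indicators in self.spec.composites.items():
            children = sorted(g.successors(comp))
            if not children:
                raise ValueError(f"composite {comp!r} has no downstream equation")
            target = self.data[children[0]].to_numpy(dtype=float)
            X = sm.add_constant(self.data[indicators].to_numpy(dtype=float))
            w = sm.OLS(target, X).fit().params[1:]
            score = self.data[indicators].to_numpy(dtype=float) @ w
            sd = score.std(ddof=1)
            if sd == 0:
                raise ValueError(f"composite {comp!r} collapsed to a constant")
            self.data[comp] = (score - score.mean()) / sd

    def _equation_p(self, response: str, predictors: list[str], focal: str) -> float:
        """p-value of `focal` in the regression of response on predictors."""
        y = self.data[response].to_numpy(dtype=float)
        X = self.data[predictors]
        if response in self.spec.groups:
            fit = fit_mixed(y, X, self.data[self.spec.groups[response]].to_numpy())
            return float(fit.pvalues[focal])
        m = sm.OLS(y, sm.add_constant(X.to_numpy(dtype=float))).fit()
        return float(m.pvalues[1 + predictors.index(focal)])

    def fit(self) -> SEMFit:
        g = self.spec.graph()
        endogenous = [n for n in g.nodes if g.in_degree(n) > 0]
        n = len(self.data)
        max_eq = max((g.in_degree(v) for v in endogenous), default=0)
        if n <= max_eq + 2:
            raise ValueError("too few observations for the largest equation")

        path_rows = []
        r2: dict[str, float] = {}
        n_params = 0
        for v in sorted(endogenous, key=_topological_rank(g).get):
            parents = sorted(g.predecessors(v))
            y = self.data[v].to_numpy(dtype=float)
            sd_y = y.std(ddof=1)
            if v in self.spec.groups:
                fit = fit_mixed(y, self.data[parents], self.data[self.spec.groups[v]].to_numpy())
                params, bse, pvals = fit.params, fit.bse, fit.pvalues
                r2[v] = fit.r2adj
                n_params += len(parents) + 1
            else:
                X = sm.add_constant(self.data[parents].to_numpy(dtype=float))
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    raise np.linalg.LinAlgError(f"equation for {v!r} is rank deficient")
                m = sm.OLS(y, X).fit()
                idx = ["Intercept"] + parents
                params = pd.Series(np.asarray(m.params), index=idx)
                bse = pd.Series(np.asarray(m.bse), index=idx)
                pvals = pd.Series(np.asarray(m.pvalues), index=idx)
                r2[v] = float(m.rsquared)
                n_params += len(parents) + 1
            for u in parents:
                sd_x = self.data[u].to_numpy(dtype=float).std(ddof=1)
                path_rows.append(
                    {
                        "from": u,
                        "to": v,
                        "estimate": float(params[u]),
                        "std_estimate": float(params[u] * sd_x / sd_y),
                        "se": float(bse[u]),
                        "p": float(pvals[u]),
                    }
                )
        paths = pd.DataFrame(path_rows)

        claim_rows = []
        for u, v, cond in basis_set(self.spec):
            preds = sorted(set(cond) | {u})
            # ensure the focal variable enters last conceptually; order of
            # columns does not affect its partial p-value
            p = self._equation_p(v, preds, u)
            claim_rows.append({"u": u, "v": v, "conditioning": ",".join(cond), "p": p})
        claims = pd.DataFrame(claim_rows, columns=["u", "v", "conditioning", "p"])
        c, df, p_c = fishers_c(claims["p"]) if len(claims) else (0.0, 0, 1.0)
        return SEMFit(
            paths=paths,
            r2=r2,
            claims=claims,
            C=c,
            df=df,
            p_C=p_c,
            aic=c + 2 * n_params,
            n_params=n_params,
            saturated=len(claims) == 0,
        )

    def effects(self, fit: SEMFit, cause: str, effect: str) -> dict[str, float]:
        """Direct, indirect and total standardized effects of cause on effect.

        The indirect effect along a directed path is the product of its
        standardized path coefficients; the total effect sums the direct
        path and all indirect paths.
        """
        g = self.spec.graph()
        direct = 0.0
        indirect = 0.0
        for path in nx.all_simple_paths(g, cause, effect):
            coef = 1.0
            for a, b in zip(path, path[1:]):
                coef *= fit.standardized_coefficient(a, b)
            if len(path) == 2:
                direct += coef
            else:
                indirect += coef
        return {"direct": direct, "indirect": indirect, "total": direct + indirect}


def fit_sem(spec: SEMSpec, data: pd.DataFrame) -> SEMFit:
    """Convenience wrapper: ``PiecewiseSEM(spec, data).fit()``."""
    return PiecewiseSEM(spec, data).fit()
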
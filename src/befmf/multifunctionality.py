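"""Ecosystem multifunctionality (EMF) indices.

Functions measured in heterogeneous native units are brought onto a common
unit interval by min-max standardization (optionally after a log or sqrt
transform), grouped into named ecosystem services, and summarised per
sample as either

* ``emf_weighted`` — the mean of service-level means, so every *service*
  contributes equally regardless of how many functions it contains, or
* ``emf_averaged`` — the flat mean over all standardized functions.

The multi-threshold profile counts, for each sample and threshold ``t``,
how many functions exceed ``t`` percent of the maximum value that function
attains anywhere in the analysed sample set; regressing those counts on a
diversity metric across a grid of thresholds yields the slope-vs-threshold
curve that characterises whether diversity supports high or low levels of
functioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "standardize_function",
    "standardize_matrix",
    "weighted_emf",
    "averaged_emf",
    "composite_richness",
    "multithreshold_counts",
    "threshold_slope_curve",
    "best_fit_regression",
    "validate_service_map",
    "Multifunctionality",
    "MultifunctionalityResult",
    "ThresholdProfile",
    "PRIMARY_THRESHOLDS",
    "THRESHOLD_GRID",
]

#: headline thresholds (percent of maximum observed function value)
PRIMARY_THRESHOLDS = (10, 25, 50, 75, 90)
#: dense grid for slope-vs-threshold curves
THRESHOLD_GRID = tuple(range(5, 100))

_TRANSFORMS = {
    "none": lambda v: v,
    "log": np.log10,
    "sqrt": np.sqrt,
}


class DegenerateColumnError(ValueError):
    """A column is constant (or otherwise carries no usable variation)."""


def _apply_transform(values: np.ndarray, transform: str, name: str = "column") -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected none|log|sqrt")
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if transform == "log" and np.any(finite <= 0):
        raise ValueError(f"log transform requires strictly positive values in {name}")
    if transform == "sqrt" and np.any(finite < 0):
        raise ValueError(f"sqrt transform requires non-negative values in {name}")
    out = v.copy()
    mask = np.isfinite(v)
    out[mask] = _TRANSFORMS[transform](v[mask])
    return out


def standardize_function(raw, transform: str = "none") -> np.ndarray:
    """Min-max standardize one function column to [0, 1].

    ``(x - min(x)) / (max(x) - min(x))`` after the optional transform;
    missing values are ignored for min/max and propagated. Raises
    :class:`DegenerateColumnError` when fewer than two distinct finite
    values remain.
    """
    v = _apply_transform(np.asarray(raw, dtype=float), transform)
    finite = v[np.isfinite(v)]
    if finite.size < 2 or np.nanmin(finite) == np.nanmax(finite):
        raise DegenerateColumnError(
            "function column is constant or has <2 finite values; "
            "min-max standardization is undefined"
        )
    lo, hi = float(finite.min()), float(finite.max())
    return (v - lo) / (hi - lo)


def validate_service_map(service_map: dict[str, list[str]], function_names) -> None:
    """Check the service map partitions the function set."""
    if not service_map:
        raise ValueError("service map is empty")
    names = list(function_names)
    seen: dict[str, str] = {}
    for service, members in service_map.items():
        if not members:
            raise ValueError(f"service {service!r} has no member functions")
        for f in members:
            if f not in names:
                raise KeyError(f"service {service!r} maps unknown function {f!r}")
            if f in seen:
                raise ValueError(
                    f"function {f!r} appears in services {seen[f]!r} and {service!r}"
                )
            seen[f] = service
    missing = [f for f in names if f not in seen]
    if missing:
        raise ValueError(f"functions not assigned to any service: {missing}")


def standardize_matrix(
    functions: pd.DataFrame, transform_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Standardize every function column to [0, 1] (see :func:`standardize_function`)."""
    transform_map = transform_map or {}
    out = {}
    for col in functions.columns:
        out[col] = standardize_function(
            functions[col].to_numpy(), transform_map.get(col, "none")
        )
    return pd.DataFrame(out, index=functions.index)


def weighted_emf(
    standardized: pd.DataFrame, service_map: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    """Service means and the service-weighted EMF.

    Each service mean is the unweighted mean of its member functions;
    the index is the unweighted mean over services, so services of
    different sizes still contribute equally. Missing function values are
    excluded pairwise; a sample whose service has no observed member at
    all yields NaN for that service and is flagged by the caller.
    """
    validate_service_map(service_map, standardized.columns)
    arr = standardized.to_numpy(dtype=float)
    if np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12:
        raise ValueError("standardized matrix must lie in [0, 1]")
    service_means = pd.DataFrame(
        {s: standardized[m].mean(axis=1) for s, m in service_map.items()},
        index=standardized.index,
    )
    return service_means, service_means.mean(axis=1).rename("emf_weighted")


def averaged_emf(standardized: pd.DataFrame) -> pd.Series:
    """Flat mean over all standardized functions."""
    if standardized.shape[1] == 0:
        raise ValueError("empty function matrix")
    return standardized.mean(axis=1).rename("emf_averaged")


def composite_richness(richness: pd.DataFrame) -> pd.Series:
    """Equal-weight composite of min-max standardized richness columns.

    Used for the microbial composite (bacteria + fungi) and the
    multitrophic composite (plants + microbes): each group is scaled to
    [0, 1] so that groups with very different richness magnitudes (e.g.
    thousands of bacterial zOTUs vs a handful of plant species)
    contribute equally.
    """
    if richness.shape[1] < 1:
        raise ValueError("need at least one richness group")
    cols = {c: standardize_function(richness[c].to_numpy()) for c in richness.columns}
    return pd.DataFrame(cols, index=richness.index).mean(axis=1).rename("composite")


def multithreshold_counts(
    functions: pd.DataFrame,
    thresholds=PRIMARY_THRESHOLDS,
    transform_map: dict[str, str] | None = None,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Per-sample counts of functions exceeding each threshold.

    ``counts[s, t] = #{f : x[s, f] > (t/100) * max_s x[s, f]}`` on the
    (optionally transformed) scale. Exceedance is strict by default;
    ``inclusive=True`` switches to ``>=``. Thresholds are percentages in
    (0, 100) and are relative to the maximum observed in the analysed
    sample set, so subsetting samples changes the reference maxima.
    """
    thresholds = list(thresholds)
    if any(not 0 < t < 100 for t in thresholds):
        raise ValueError("thresholds must lie strictly between 0 and 100")
    transform_map = transform_map or {}
    vals = np.column_stack(
        [
            _apply_transform(functions[c].to_numpy(dtype=float), transform_map.get(c, "none"), c)
            for c in functions.columns
        ]
    )
    maxima = np.nanmax(vals, axis=0)
    counts = np.empty((len(functions), len(thresholds)), dtype=int)
    for j, t in enumerate(thresholds):
        cut = (t / 100.0) * maxima
        exceeds = vals >= cut if inclusive else vals > cut
        counts[:, j] = np.nansum(exceeds & np.isfinite(vals), axis=1)
    return pd.DataFrame(counts, index=functions.index, columns=thresholds)


@dataclass
class ThresholdProfile:
    """Slope of counts-vs-diversity at each threshold."""

    thresholds: list[int]
    counts: pd.DataFrame
    slopes: pd.DataFrame  # columns: slope, se, adj_r2, p, fit

    def summary(self) -> pd.DataFrame:
        return self.slopes


def best_fit_regression(x, y) -> dict:
    """Fit y~x and y~x+x^2; keep whichever has the larger adjusted R².

    Ties (including the exact-line case, where the quadratic term buys
    nothing and the adjustment penalises it) resolve to the linear fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 observations")
    if np.ptp(x) == 0:
        raise DegenerateColumnError("predictor is constant")
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    if quad.rsquared_adj > lin.rsquared_adj + 1e-12:
        chosen, kind = quad, "quadratic"
    else:
        chosen, kind = lin, "linear"
    return {
        "fit": kind,
        "coefficients": np.asarray(chosen.params),
        "adj_r2": float(chosen.rsquared_adj),
        "r2": float(chosen.rsquared),
        "p": float(chosen.f_pvalue) if chosen.df_model > 0 else np.nan,
    }


def threshold_slope_curve(
    diversity, counts: pd.DataFrame, quadratic: bool = False
) -> ThresholdProfile:
    """OLS slope of threshold counts on a diversity metric, per threshold."""
    d = np.asarray(diversity, dtype=float)
    if np.unique(d[np.isfinite(d)]).size < 3:
        raise DegenerateColumnError("diversity metric needs >= 3 distinct values")
    rows = []
    for t in counts.columns:
        y = counts[t].to_numpy(dtype=float)
        if quadratic:
            res = best_fit_regression(d, y)
            fit_kind, slope = res["fit"], res["coefficients"][1]
            # SE of the linear term from the chosen model
            X = sm.add_constant(
                d if fit_kind == "linear" else np.column_stack([d, d**2])
            )
            m = sm.OLS(y, X).fit()
            se, adj, p = float(m.bse[1]), res["adj_r2"], res["p"]
        else:
            m = sm.OLS(y, sm.add_constant(d)).fit()
            fit_kind = "linear"
            slope, se = float(m.params[1]), float(m.bse[1])
            adj, p = float(m.rsquared_adj), float(m.pvalues[1])
        rows.append(
            {"threshold": t, "slope": float(slope), "se": se, "adj_r2": adj, "p": p, "fit": fit_kind}
        )
    slopes = pd.DataFrame(rows).set_index("threshold")
    return ThresholdProfile(list(counts.columns), counts, slopes)


@dataclass
class MultifunctionalityResult:
    """Standardized functions, service means and both EMF indices."""

    standardized: pd.DataFrame
    service_means: pd.DataFrame
    emf_weighted: pd.Series
    emf_averaged: pd.Series
    incomplete_samples: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.service_means.copy()
        out["emf_weighted"] = self.emf_weighted
        out["emf_averaged"] = self.emf_averaged
        return out

    def summary(self) -> pd.DataFrame:
        return self.to_frame().describe().T


class Multifunctionality:
    """Model-style entry point for the EMF computation.

    Parameters
    ----------
    functions : DataFrame
        Samples x functions, native units.
    service_map : dict
        Service name -> member function names; must partition the columns.
    transform_map : dict, optional
        Per-function transform in {none, log, sqrt}, applied before
        min-max standardization.
    """

    def __init__(
        self,
        functions: pd.DataFrame,
        service_map: dict[str, list[str]],
        transform_map: dict[str, str] | None = None,
    ):
        validate_service_map(service_map, functions.columns)
        self.functions = functions
        self.service_map = service_map
        self.transform_map = transform_map or {}

    def fit(self) -> MultifunctionalityResult:
        standardized = standardize_matrix(self.functions, self.transform_map)
        service_means, emf_w = weighted_emf(standardized, self.service_map)
        emf_a = averaged_emf(standardized)
        incomplete = list(service_means.index[service_means.isna().any(axis=1)])
        return MultifunctionalityResult(standardized, service_means, emf_w, emf_a, incomplete)

    def threshold_profile(
        self,
        diversity,
        thresholds=THRESHOLD_GRID,
        inclusive: bool = False,
        use_transforms: bool = False,
    ) -> ThresholdProfile:
        # counts default to the raw measurement scale; use_transforms applies
        # the configured per-function transforms before thresholding
        counts = multithreshold_counts(
            self.functions,
            thresholds,
            self.transform_map if use_transforms else None,
            inclusive,
        )
        return threshold_slope_curve(diversity, counts)
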
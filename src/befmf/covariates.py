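"""Site covariates: aridity, ordination axes, and Shannon diversity.

The aridity index AI = MAP / PET (mean annual precipitation over potential
evapotranspiration, both mm/yr) with the UNEP (1992) dryland categories:
hyperarid AI < 0.05, arid 0.05 <= AI < 0.2, semiarid 0.2 <= AI < 0.5,
dry subhumid 0.5 <= AI < 0.65 and humid AI >= 0.65.

Composite covariates reduce a block of correlated site properties to a
single standardized axis: a correlation-matrix PCA for continuous
environmental variables and a Jaccard-distance principal coordinates
analysis (classical scaling) for presence/absence community composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

__all__ = [
    "ARIDITY_BREAKPOINTS",
    "ARIDITY_CLASSES",
    "aridity_index",
    "classify_aridity",
    "pca_first_axis",
    "jaccard_pcoa_axis",
    "shannon_index",
    "CompositionAxis",
]

# lower bound of each class, scanned from wettest to driest;
# lower bounds inclusive, upper bounds exclusive
ARIDITY_BREAKPOINTS = (0.65, 0.5, 0.2, 0.05)
ARIDITY_CLASSES = ("humid", "dry subhumid", "semiarid", "arid", "hyperarid")


def aridity_index(map_mm, pet_mm):
    """AI = MAP / PET. PET must be positive; MAP non-negative."""
    map_mm = np.asarray(map_mm, dtype=float)
    pet_mm = np.asarray(pet_mm, dtype=float)
    if np.any(pet_mm <= 0):
        raise ValueError("potential evapotranspiration must be > 0")
    if np.any(map_mm < 0):
        raise ValueError("precipitation must be >= 0")
    out = map_mm / pet_mm
    return float(out) if out.ndim == 0 else out


def classify_aridity(ai):
    """UNEP aridity class for an aridity index value (scalar or array)."""
    arr = np.asarray(ai, dtype=float)
    if np.any(arr < 0):
        raise ValueError("aridity index must be >= 0")
    idx = np.select(
        [arr >= 0.65, arr >= 0.5, arr >= 0.2, arr >= 0.05],
        [0, 1, 2, 3],
        default=4,
    )
    classes = np.asarray(ARIDITY_CLASSES, dtype=object)[idx]
    return str(classes) if arr.ndim == 0 else classes


@dataclass
class CompositionAxis:
    """Leading ordination axis used as a single composite covariate."""

    scores: pd.Series  # standardized, mean 0, sd 1
    variance_explained: float
    method: str  # "PCA" or "PCoA-Jaccard"
    eigenvalues: np.ndarray | None = None
    note: str = ""


def pca_first_axis(table: pd.DataFrame) -> CompositionAxis:
    """Scores on the first principal component of z-scored columns.

    Columns are z-scored first (the inputs mix units: pH, degC, %, mm),
    so this is PCA of the correlation matrix. The axis sign is fixed so
    the loading of the first input column is non-negative, and the scores
    are re-standardized to mean 0 / SD 1 for use as a regression covariate.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("PCA needs >= 2 columns and >= 3 rows")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant columns cannot enter the PCA: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        raise ValueError("input matrix has no variance structure (rank 0)")
    lead = evecs[:, 0]
    if lead[0] < 0:
        lead = -lead
    scores = Z @ lead
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return CompositionAxis(
        scores=pd.Series(scores, index=table.index, name="pc1"),
        variance_explained=float(evals[0] / evals.sum()),
        method="PCA",
        eigenvalues=evals,
    )


def jaccard_pcoa_axis(presence: pd.DataFrame) -> CompositionAxis:
    """Leading principal-coordinates axis of Jaccard distances.

    Input is a samples x taxa presence/absence matrix. Jaccard distance
    d(A, B) = 1 - |A & B| / |A | B| is undefined when both rows are empty,
    which is reported as an error naming the rows. Classical scaling
    (double-centered Gower matrix) is used; negative eigenvalues, if any,
    are reported untouched rather than corrected.
    """
    X = presence.to_numpy()
    uniq = np.unique(X[np.isfinite(X.astype(float))])
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("presence/absence matrix must contain only 0/1")
    if X.shape[0] < 3:
        raise ValueError("PCoA needs >= 3 samples")
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    if empty.size >= 2:
        rows = list(presence.index[empty])
        raise ValueError(f"Jaccard distance undefined between all-zero rows: {rows}")
    dist = squareform(pdist(X.astype(bool), metric="jaccard"))
    ord_res = _skbio_pcoa(dist, method="eigh", number_of_dimensions=0)
    scores = ord_res.samples.iloc[:, 0].to_numpy()
    eigvals = ord_res.eigvals.to_numpy()
    if scores[0] < 0:  # deterministic sign, anchored to the first sample
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    total = np.abs(eigvals).sum()
    return CompositionAxis(
        scores=pd.Series(scores, index=presence.index, name="pcoa1"),
        variance_explained=float(eigvals[0] / total) if total > 0 else 0.0,
        method="PCoA-Jaccard",
        eigenvalues=eigvals,
        note="composition axis via Jaccard PCoA (ordination substitute for NMDS)",
    )


def shannon_index(abundances) -> float:
    """Shannon-Wiener H' = -sum(p ln p) over positive entries."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())
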
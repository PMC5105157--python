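"""Ordination and fossil-record correlation.

Layer profiles are compared by Bray–Curtis dissimilarity and embedded in
two dimensions by non-metric multidimensional scaling (Kruskal stress-1,
best of several random restarts), so layers with similar faunal
composition cluster together. DNA read counts are correlated (Pearson)
against zooarchaeological quantities — raw bone counts (NISP) or expected
biomass — and MNI counts from a partial excavation are scaled to the full
deposit by the reciprocal of the excavated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import braycurtis
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "CorrelationResult",
    "OrdinationResult",
    "bray_curtis",
    "dissimilarity_matrix",
    "kruskal_stress",
    "nmds",
    "pearson",
    "scale_mni",
    "correlate_profiles",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    excluded: tuple = ()


@dataclass(frozen=True)
class OrdinationResult:
    coords: np.ndarray  # (n_layers, dims)
    stress: float  # Kruskal stress-1
    seed: int
    n_restarts: int
    labels: tuple = ()


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity 1 − 2Σmin(u,v)/(Σu+Σv), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be nonnegative")
    if u.sum() + v.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(u, v))


def dissimilarity_matrix(vectors: Sequence[Sequence[float]]) -> np.ndarray:
    vecs = [np.asarray(v, dtype=float) for v in vectors]
    n = len(vecs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(vecs[i], vecs[j])
    return d


def kruskal_stress(diss: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1: sqrt(Σ(d − d̂)² / Σd²) with d̂ the isotonic (monotone)
    regression of embedded distances on the input dissimilarities."""
    iu = np.triu_indices_from(diss, k=1)
    delta = diss[iu]
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    order = np.argsort(delta, kind="stable")
    dhat = np.empty_like(dist)
    dhat[order] = IsotonicRegression().fit_transform(
        np.arange(len(order)), dist[order]
    )
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _classical_mds(diss: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering solution, used as a metric start."""
    n = diss.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (diss**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    comp = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return comp


def nmds(
    diss: np.ndarray,
    dims: int = 2,
    seed: int = 0,
    restarts: int = 20,
    labels: Sequence | None = (),
) -> OrdinationResult:
    """Non-metric MDS of a symmetric dissimilarity matrix.

    Best (lowest Kruskal stress-1) of ``restarts`` random initializations;
    ties in the isotonic regression are handled as primary (tied input
    dissimilarities are free to embed at different distances).
    """
    diss = np.asarray(diss, dtype=float)
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(diss, diss.T) or not np.allclose(np.diag(diss), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    n = diss.shape[0]
    if n < 3:
        raise ValueError("NMDS needs at least 3 profiles")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    candidates: list[tuple[float, float, np.ndarray]] = []
    for start in range(restarts):
        # first restart from the classical (metric) MDS solution: when the
        # rank information leaves the configuration underdetermined (stress
        # near zero), the metric start keeps the embedding faithful to the
        # dissimilarity magnitudes instead of an arbitrary order-preserving
        # layout
        init = _classical_mds(diss, dims) if start == 0 else rng.normal(size=(n, dims))
        coords, _ = smacof(
            diss,
            metric=False,
            n_components=dims,
            init=init,
            n_init=1,
            max_iter=500,
            eps=1e-9,
            normalized_stress=True,
        )
        s = kruskal_stress(diss, coords)
        dist = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )[iu]
        if dist.std() > 0 and diss[iu].std() > 0:
            fit = float(np.corrcoef(diss[iu], dist)[0, 1])
        else:
            fit = 0.0
        candidates.append((s, fit, coords))
    best_stress = min(c[0] for c in candidates)
    tie_window = max(1e-4, 0.01 * best_stress)
    tied = [c for c in candidates if c[0] <= best_stress + tie_window]
    # among (near-)equal-stress solutions keep the one whose Shepard plot is
    # most linear — breaks the zero-stress degeneracy of tightly clustered data
    s, _, coords = max(tied, key=lambda c: c[1])
    return OrdinationResult(
        coords=coords,
        stress=s,
        seed=seed,
        n_restarts=restarts,
        labels=tuple(labels or ()),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-based p-value
    (t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom; |r| = 1 → p = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    return CorrelationResult(rho=float(r), p_two_sided=float(p), n=n)


def scale_mni(
    mni: Mapping[str, float] | float, excavated_fraction: float
) -> tuple[Mapping[str, float] | float, float]:
    """Scale MNI counts from a partial excavation to the whole deposit.

    The factor is 1/excavated_fraction rounded to one decimal (an 8.7%
    sample scales by 11.5). Returns (scaled, factor).
    """
    if not 0 < excavated_fraction <= 1:
        raise ValueError("excavated_fraction must be in (0, 1]")
    factor = round(1.0 / excavated_fraction, 1)
    if isinstance(mni, Mapping):
        return {k: v * factor for k, v in mni.items()}, factor
    return mni * factor, factor


def correlate_profiles(
    counts: Mapping[str, float], reference: Mapping[str, float]
) -> CorrelationResult:
    """Pearson correlation of DNA read counts against a zooarchaeological
    column (NISP or expected biomass), over the shared species.

    Species present on only one side are excluded and reported in the
    result; fewer than 3 shared species is an error.
    """
    shared = sorted(set(counts) & set(reference))
    excluded = tuple(sorted(set(counts) ^ set(reference)))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared species; need at least 3"
        )
    res = pearson(
        [counts[s] for s in shared], [reference[s] for s in shared]
    )
    return CorrelationResult(
        rho=res.rho, p_two_sided=res.p_two_sided, n=res.n, excluded=excluded
    )
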
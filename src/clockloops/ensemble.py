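"""Ensemble statistics over collections of fitted models.

Once many independent fits per tissue exist, their loop reports and
parameter vectors are aggregated: frequencies of essential loop families
per tissue, Venn-style counts of minimal-oscillator compositions, PCA/LDA
projections of the 34-dimensional parameter sets, circular phase
statistics, and rank-based score comparisons.  All aggregations are pure
functions of the ensemble and invariant to the order of fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .clamping import FAMILIES, LoopReport
from .pso import FitResult


@dataclass
class Ensemble:
    fits: list[FitResult]
    reports: list[LoopReport]

    def __post_init__(self):
        if len(self.fits) != len(self.reports):
            raise ValueError("fits and reports must align")
        ids = [f.fit_id for f in self.fits]
        if len(set(ids)) != len(ids):
            raise ValueError("fit ids must be unique")

    @property
    def tissues(self) -> list[str]:
        return sorted({f.tissue for f in self.fits})

    def parameter_matrix(self) -> np.ndarray:
        return np.vstack([f.params.vector for f in self.fits])

    def scores(self) -> np.ndarray:
        return np.array([float(f.score) for f in self.fits])


def loop_frequency_table(
    ensemble: Ensemble, threshold: float = 10.0
) -> pd.DataFrame:
    """Fraction of good fits per tissue in which each core family is essential."""
    if not ensemble.reports:
        raise ValueError("empty ensemble")
    rows = {}
    for tissue in ensemble.tissues:
        good = [
            r
            for f, r in zip(ensemble.fits, ensemble.reports)
            if f.tissue == tissue and float(f.score) < threshold
        ]
        n = len(good)
        rows[tissue] = {
            fam: (sum(fam in r.essential_families for r in good) / n if n else 0.0)
            for fam in FAMILIES
        }
    return pd.DataFrame(rows)  # families x tissues


def oscillator_venn(ensemble: Ensemble, tissue: str) -> dict[tuple[str, ...], int]:
    """Counts of fits by the family composition of their minimal oscillators.

    Each fit is assigned the union of families over its minimal
    oscillators; counts over all family subsets partition the fit set.
    """
    counts: dict[tuple[str, ...], int] = {
        subset: 0
        for k in range(len(FAMILIES) + 1)
        for subset in itertools.combinations(FAMILIES, k)
    }
    for f, r in zip(ensemble.fits, ensemble.reports):
        if f.tissue != tissue:
            continue
        key = r.oscillator_family_union()
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class Projection:
    coordinates: np.ndarray  # (n_fits, 2)
    loadings: np.ndarray  # (n_params, 2)
    kind: str
    explained: np.ndarray  # variance ratios or discriminant-eigenvalue ratios
    parameter_names: list[str] = field(default_factory=list)
    top_loadings: list[int] = field(default_factory=list)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def pca_project(ensemble: Ensemble) -> Projection:
    """First two principal components of the standardized parameter vectors."""
    X = ensemble.parameter_matrix()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 fits for PCA")
    Z = _standardize(X)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :2] * s[:2]
    var = s**2 / np.sum(s**2)
    names = ensemble.fits[0].params.names()
    loadings = Vt[:2].T
    mags = np.linalg.norm(loadings, axis=1)
    return Projection(
        coordinates=coords,
        loadings=loadings,
        kind="PCA",
        explained=var[:2],
        parameter_names=names,
        top_loadings=list(np.argsort(mags)[::-1][:3]),
    )


def lda_project(ensemble: Ensemble, ridge: float = 1e-6) -> Projection:
    """Two-discriminant linear discriminant projection separating tissues.

    Solves the generalized eigenproblem S_b w = lambda (S_w + ridge I) w on
    standardized parameters; the ridge keeps the within-class scatter
    invertible when fits per tissue are fewer than the 34 dimensions.
    """
    labels = np.array([f.tissue for f in ensemble.fits])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 tissues for LDA")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"tissue {c!r} has fewer than 2 fits")
    X = _standardize(ensemble.parameter_matrix())
    dim = X.shape[1]
    mean = X.mean(axis=0)
    Sw = np.zeros((dim, dim))
    Sb = np.zeros((dim, dim))
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        D = Xc - mc
        Sw += D.T @ D
        dm = (mc - mean)[:, None]
        Sb += len(Xc) * (dm @ dm.T)
    Sw_reg = Sw + ridge * np.eye(dim)
    evals, evecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1]
    W = evecs[:, order[:2]]
    # sign convention: largest-magnitude loading positive per axis
    for k in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, k])))
        if W[i, k] < 0:
            W[:, k] = -W[:, k]
    coords = X @ W
    lam = np.clip(evals[order[:2]], 0, None)
    total = np.sum(np.clip(evals, 0, None))
    mags = np.linalg.norm(W, axis=1)
    return Projection(
        coordinates=coords,
        loadings=W,
        kind="LDA",
        explained=lam / total if total > 0 else lam,
        parameter_names=ensemble.fits[0].params.names(),
        top_loadings=list(np.argsort(mags)[::-1][:4]),
    )


# ---------------------------------------------------------------------------
# Rank and circular statistics
# ---------------------------------------------------------------------------

def _rankdata(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def ranksum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum statistic (sum of x's ranks) and its p-value.

    ``alternative`` is "two-sided" (default), "less" (x tends smaller) or
    "greater".  Exact by enumeration of all rank assignments when
    min(n) <= 8 (ties handled by enumerating the actual pooled values),
    otherwise a normal approximation with tie correction.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    w = float(np.sum(ranks[:nx]))
    if min(nx, ny) <= 8:
        import itertools as it

        sums = np.array(
            [sum(c) for c in it.combinations(ranks, nx)]
        )
        p_le = float(np.mean(sums <= w + 1e-9))
        p_ge = float(np.mean(sums >= w - 1e-9))
        if alternative == "less":
            return w, p_le
        if alternative == "greater":
            return w, p_ge
        return w, float(min(1.0, 2.0 * min(p_le, p_ge)))
    n = nx + ny
    mu = nx * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var = nx * ny / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    if var <= 0:
        return w, 1.0
    z = (w - mu) / np.sqrt(var)
    from scipy.stats import norm

    if alternative == "less":
        return w, float(norm.cdf(z))
    if alternative == "greater":
        return w, float(norm.sf(z))
    return w, float(2.0 * norm.sf(abs(z)))


def circular_mean(phases, period: float = 24.0) -> tuple[float, float]:
    """Mean phase as the angle of the resultant vector; returns (mean, R).

    R is the mean resultant length in [0, 1]; when R is numerically zero
    (antipodal or uniform phases) the mean is undefined and NaN is returned.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    ang = 2.0 * np.pi * np.asarray(phases, dtype=float) / period
    z = np.mean(np.exp(1j * ang))
    R = float(np.abs(z))
    if R < 1e-12:
        return float("nan"), 0.0
    mean = (float(np.angle(z)) % (2.0 * np.pi)) * period / (2.0 * np.pi)
    return mean % period, R


def invert_repressor_phases(
    phases: dict[str, float], roles: dict[str, str], period: float = 24.0
) -> dict[str, float]:
    """Shift repressor phases by half a cycle to compare with activators."""
    out = {}
    for g, p in phases.items():
        if roles.get(g) == "repressor":
            out[g] = (p + period / 2.0) % period
        else:
            out[g] = p % period
    return out


def score_loop_association(ensemble: Ensemble) -> dict:
    """Do better-scoring fits involve more essential loops?

    Splits fits at the median score (ties to the lower half), compares
    essential-loop counts across the halves by rank sum, and reports the
    mean score of fits with vs without each core family.
    """
    scores = ensemble.scores()
    if len(scores) < 4:
        raise ValueError("need at least 4 fits")
    counts = np.array([len(r.essential_members) for r in ensemble.reports])
    med = float(np.median(scores))
    low = counts[scores <= med]
    high = counts[scores > med]
    if len(high) == 0:  # all scores at the median
        w, p = float(np.sum(_rankdata(counts)[: len(low)])), 1.0
    else:
        w, p = ranksum(low, high)
    by_family = {}
    for fam in FAMILIES:
        has = np.array([fam in r.essential_families for r in ensemble.reports])
        by_family[fam] = {
            "mean_score_with": float(scores[has].mean()) if has.any() else float("nan"),
            "mean_score_without": float(scores[~has].mean())
            if (~has).any()
            else float("nan"),
            "n_with": int(has.sum()),
        }
    return {
        "median_score": med,
        "n_low": int(len(low)),
        "n_high": int(len(high)),
        "mean_loops_low": float(low.mean()) if len(low) else float("nan"),
        "mean_loops_high": float(high.mean()) if len(high) else float("nan"),
        "ranksum_stat": w,
        "ranksum_p": p,
        "by_family": by_family,
    }
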
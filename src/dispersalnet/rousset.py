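"""Rousset's individual-based dispersal estimator (the comparison baseline).

Under two-dimensional isolation by distance, the regression of an
individual-pair genetic differentiation statistic â on the natural log of
geographic distance has slope 1/(4 pi D sigma^2) = 1/Nb, where D is
population density and Nb Wright's neighborhood size.  Given D, the slope b
converts to a dispersal estimate sigma = sqrt(1 / (4 pi D b)); a
non-positive fitted slope leaves sigma undefined (returned as NaN and
excluded from downstream error metrics, with the count reported).

The â statistic used here is the individual-level analogue of
F_ST/(1 - F_ST): per pair (i, j), â = sum_l (Qw_l - Qb_l(i,j)) /
sum_l (1 - Qw_l), where Qb_l(i,j) is the probability that one gene drawn
from i and one from j are identical at locus l, and Qw_l is the average
within-individual gene identity over the whole sample.  This is the
convention conventionally paired with the ln(d) regression in 2-D habitats;
the exact estimator variant is a declared choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, LocationTable

__all__ = [
    "RoussetFit",
    "genetic_distance_pairs",
    "rousset_regression",
    "sigma_from_slope",
    "fit_rousset",
    "RoussetDispersal",
]


@dataclass
class RoussetFit:
    """Result of one Rousset regression on a single dataset."""

    slope: float
    intercept: float
    sigma_hat: float  # NaN when the slope is non-positive (undefined)
    density_used: float
    n_pairs_used: int

    @property
    def neighborhood_size(self) -> float:
        return 1.0 / self.slope if self.slope > 0 else math.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.sigma_hat)


def genetic_distance_pairs(G: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of the pairwise â statistic, zero diagonal.

    Works on the unphased dosage coding; â is invariant to which allele is
    labelled minor and to SNP order (it is a per-site ratio of sums).
    """
    if G.phased:
        raise ValueError("â is computed from unphased dosages; collapse haplotypes first")
    vals = G.values
    if vals.shape[1] < 2:
        raise ValueError("need at least two individuals")
    p = vals.T.astype(float) / 2.0  # (n, m) within-individual allele frequency
    qb = p @ p.T + (1 - p) @ (1 - p).T  # sum over loci of Qb(i, j)
    hom = (vals != 1).mean(axis=1)  # per-locus within-individual identity, averaged over inds
    qw_sum = float(hom.sum())
    m = vals.shape[0]
    denom = m - qw_sum
    if denom <= 0:
        raise ValueError("no within-individual heterozygosity; â undefined")
    a = (qw_sum - qb) / denom
    np.fill_diagonal(a, 0.0)
    return a


def rousset_regression(a_matrix: np.ndarray, locations: LocationTable) -> tuple[float, float, int]:
    """OLS of â on ln(distance) over pairs with positive distance.

    Returns (slope, intercept, n_pairs_used); co-located pairs are excluded
    (ln 0 undefined) and do not count toward ``n_pairs_used``.
    """
    coords = locations.coords
    n = coords.shape[0]
    iu = np.triu_indices(n, k=1)
    d = np.hypot(*(coords[iu[0]] - coords[iu[1]]).T)
    a = np.asarray(a_matrix)[iu]
    keep = d > 0
    if keep.sum() < 2:
        raise ValueError("need at least two pairs at distinct positive distances")
    x = np.log(d[keep])
    if np.ptp(x) == 0:
        raise ValueError("all pair distances identical; slope undefined")
    res = stats.linregress(x, a[keep])
    return float(res.slope), float(res.intercept), int(keep.sum())


def sigma_from_slope(slope: float, density: float) -> float:
    """Dispersal rate from the regression slope and known density.

    sigma = sqrt(1 / (4 pi D b)); NaN (undefined, not an exception) when the
    slope is non-positive, as happens under weak isolation by distance.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if slope <= 0 or not np.isfinite(slope):
        return math.nan
    return math.sqrt(1.0 / (4.0 * math.pi * density * slope))


def fit_rousset(G: GenotypeMatrix, L: LocationTable, density: float) -> RoussetFit:
    """Full baseline on one dataset: â matrix, regression, σ conversion."""
    a = genetic_distance_pairs(G)
    slope, intercept, used = rousset_regression(a, L)
    return RoussetFit(
        slope=slope,
        intercept=intercept,
        sigma_hat=sigma_from_slope(slope, density),
        density_used=density,
        n_pairs_used=used,
    )


class RoussetDispersal(BaseEstimator):
    """Scikit-learn style wrapper: per-dataset Rousset dispersal estimates.

    There is nothing to train; ``fit`` is a no-op kept for pipeline
    compatibility.  ``predict`` returns one σ̂ per dataset, NaN where the
    fitted slope was non-positive.
    """

    def __init__(self, density: float = 1.0):
        self.density = density

    def fit(self, X=None, y=None):
        if self.density <= 0:
            raise ValueError("density must be positive")
        self.fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        from .estimator import _coerce_datasets

        geno, locs, phased, _ = _coerce_datasets(X, None)
        if phased:
            raise ValueError("baseline expects unphased dosages")
        out = np.empty(geno.shape[0])
        for k in range(geno.shape[0]):
            gm = GenotypeMatrix(
                values=geno[k].astype(np.int16),
                positions=np.arange(1, geno.shape[1] + 1, dtype=float),
            )
            try:
                out[k] = fit_rousset(gm, LocationTable(coords=locs[k]), self.density).sigma_hat
            except ValueError:
                out[k] = math.nan
        return out
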
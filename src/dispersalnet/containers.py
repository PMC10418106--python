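"""Core in-memory containers shared across the package.

A :class:`GenotypeMatrix` holds minor-allele counts for ``m`` SNPs ordered by
genomic position; a :class:`LocationTable` holds the planar coordinates of the
sampled individuals, row-aligned with the genotype columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "LocationTable",
    "PairSet",
    "SimulationResult",
]


@dataclass
class GenotypeMatrix:
    """Minor-allele-count matrix, SNPs x samples.

    Unphased entries are diploid dosages in {0, 1, 2} with one column per
    individual; phased entries are haploid {0, 1} with two adjacent columns
    per individual (columns 2i, 2i+1 belong to individual i).

    Parameters
    ----------
    values
        Integer matrix of shape (m, n) unphased or (m, 2n) phased.
    positions
        Base-pair coordinate of each SNP, strictly increasing.
    phased
        Whether columns are haplotypes rather than diploid dosages.
    """

    values: np.ndarray
    positions: np.ndarray
    phased: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if self.positions.shape != (self.values.shape[0],):
            raise ValueError("positions must have one entry per SNP row")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("SNP positions must be strictly increasing")
        hi = 1 if self.phased else 2
        if self.values.size and (self.values.min() < 0 or self.values.max() > hi):
            raise ValueError(
                f"genotype entries must lie in [0, {hi}] "
                f"({'phased' if self.phased else 'unphased'} coding)"
            )

    @property
    def m_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        ncol = self.values.shape[1]
        return ncol // 2 if self.phased else ncol


@dataclass
class LocationTable:
    """Planar (x, y) coordinates per sample, in map units or kilometres.

    ``latlon`` optionally retains the original geographic coordinates
    (latitude, longitude in degrees) before projection.
    """

    coords: np.ndarray
    latlon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coordinates must be an (n, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.latlon is not None:
            self.latlon = np.asarray(self.latlon, dtype=float)
            if self.latlon.shape != self.coords.shape:
                raise ValueError("latlon must match coords shape")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class PairSet:
    """Ordered list of sample-index pairs (i, j), i < j, lexicographic."""

    pairs: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if self.pairs.size and not np.all(self.pairs[:, 0] < self.pairs[:, 1]):
            raise ValueError("each pair must satisfy i < j")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.pairs))


@dataclass
class SimulationResult:
    """One training/validation dataset: genotypes, locations and the true σ."""

    genotypes: GenotypeMatrix
    locations: LocationTable
    sigma_f_true: float
    sigma_true: float
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotypes.n_samples != self.locations.n:
            raise ValueError(
                "genotype columns and location rows describe different sample counts"
            )
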
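"""Turn empirical or simulated inputs into the tensors the network consumes.

Covers VCF + coordinate-table ingestion, minor-allele coding, equirectangular
projection of latitude/longitude, matching of simulated individuals to the
empirical sampling scheme, pair enumeration, and the packed binary training
cache.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LocationTable, PairSet, SimulationResult

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "code_minor_alleles",
    "read_genotypes",
    "read_locations",
    "project_coordinates",
    "match_sampling",
    "enumerate_pairs",
    "pairwise_distance",
    "pack_training_set",
    "load_training_set",
    "PackedTrainingSet",
    "subset_evenly",
]


# ---------------------------------------------------------------------------
# genotype coding


def code_minor_alleles(alt_counts: np.ndarray, ploidy_per_column: int = 2) -> np.ndarray:
    """Re-code ALT-allele counts as minor-allele counts, row by row.

    The minor allele at a site is the one whose sample frequency is < 0.5;
    at an exact tie (frequency 0.5) the currently counted allele is kept, the
    only tie rule that is both deterministic and idempotent (re-coding an
    already coded matrix is a no-op).
    """
    g = np.asarray(alt_counts)
    total = g.shape[1] * ploidy_per_column
    alt = g.sum(axis=1)
    flip = 2 * alt > total  # ALT is strictly major -> count REF instead
    out = g.copy()
    out[flip] = ploidy_per_column - g[flip]
    return out


def subset_evenly(n_available: int, n_wanted: int) -> np.ndarray:
    """Deterministic subset of row ranks, evenly spaced along the genome."""
    if n_wanted > n_available:
        raise ValueError(
            f"requested {n_wanted} SNPs but only {n_available} usable sites are available"
        )
    if n_wanted == n_available:
        return np.arange(n_available)
    idx = np.floor(np.linspace(0, n_available - 1, n_wanted)).astype(np.int64)
    return np.unique(idx)


def read_genotypes(vcf_path: str | Path, phased: bool = False, m_snps: int | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a minor-allele-coded matrix.

    Multiallelic and monomorphic sites are excluded.  Missing genotypes are
    rejected rather than imputed.  When more than ``m_snps`` usable sites are
    present, an evenly spaced (by rank along the genome) subset is taken.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gts = np.array(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in var.genotypes], dtype=np.int16)
        if (alleles < 0).any():
            raise ValueError(
                f"missing genotype at {var.CHROM}:{var.POS}; pre-filter or drop the site"
            )
        if phased:
            if not all(g[2] for g in gts):
                raise ValueError(
                    f"unphased genotype at {var.CHROM}:{var.POS} but phased output requested"
                )
            row = alleles.reshape(-1)
        else:
            row = alleles.sum(axis=1)
        if row.min() == row.max():
            continue  # monomorphic in this sample
        rows.append(row)
        positions.append(var.POS)
    vcf.close()

    if not rows:
        raise ValueError("no usable biallelic segregating SNPs in VCF")
    values = np.asarray(rows, dtype=np.int16)
    pos = np.asarray(positions, dtype=float)
    ploidy = 1 if phased else 2
    values = code_minor_alleles(values, ploidy_per_column=ploidy)
    # recheck segregation after coding (coding cannot fix a monomorphic row)
    keep = values.max(axis=1) > 0
    values, pos = values[keep], pos[keep]
    if m_snps is not None:
        if values.shape[0] < m_snps:
            raise ValueError(
                f"VCF has {values.shape[0]} usable SNPs, fewer than the requested {m_snps}"
            )
        sel = subset_evenly(values.shape[0], m_snps)
        values, pos = values[sel], pos[sel]
    return GenotypeMatrix(values=values, positions=pos, phased=phased)


# ---------------------------------------------------------------------------
# locations


def read_locations(table_path: str | Path, n_expected: int | None = None) -> LocationTable:
    """Read a per-sample coordinate table (CSV or TSV).

    Expected columns: ``sample_id, latitude, longitude`` or just two numeric
    columns (latitude, longitude).  A header row is auto-detected and skipped.
    Row order must match the VCF sample order.
    """
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    # header detection: first row fails numeric parse in the coordinate columns
    first = df.iloc[0, -2:]
    try:
        first.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 2:
        raise ValueError("coordinate table needs at least two columns (lat, lon)")
    try:
        latlon = df.iloc[:, -2:].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric coordinate field in {path}: {exc}") from exc
    if n_expected is not None and latlon.shape[0] != n_expected:
        raise ValueError(
            f"coordinate table has {latlon.shape[0]} rows but {n_expected} samples expected"
        )
    return LocationTable(coords=latlon.copy(), latlon=latlon)


def project_coordinates(latlon_table: LocationTable) -> LocationTable:
    """Project latitude/longitude onto a plane (x, y in kilometres).

    Equirectangular projection about the sample centroid on a spherical Earth
    (R = 6371 km): adequate at the regional scales where isolation by
    distance is measured.  Distances between nearby points approximate
    great-circle distances.
    """
    latlon = latlon_table.latlon if latlon_table.latlon is not None else latlon_table.coords
    lat, lon = latlon[:, 0], latlon[:, 1]
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of range [-180, 180]")
    lat0, lon0 = lat.mean(), lon.mean()
    x = np.deg2rad(lon - lon0) * EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(lat - lat0) * EARTH_RADIUS_KM
    return LocationTable(coords=np.column_stack([x, y]), latlon=latlon)


def rescale_to_cloud(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map one point cloud onto another's scale by centroid + width matching.

    Width is the larger bounding-box extent.  Used to place empirical
    localities on the simulated habitat before nearest-individual matching.
    """
    points = np.asarray(points, float)
    target = np.asarray(target, float)
    span_p = np.ptp(points, axis=0).max()
    span_t = np.ptp(target, axis=0).max()
    scale = 1.0 if span_p == 0 else span_t / span_p
    return (points - points.mean(axis=0)) * scale + target.mean(axis=0)


def match_sampling(
    sim_locations: LocationTable,
    empirical_locations: LocationTable,
    rescale: bool = True,
) -> np.ndarray:
    """Pick, per empirical locality, the nearest unchosen simulated individual.

    Greedy without replacement, localities processed in input order, Euclidean
    metric.  When ``rescale`` is set the empirical cloud is first mapped onto
    the simulated cloud's centroid and width.
    """
    sim = sim_locations.coords
    emp = empirical_locations.coords
    if sim.shape[0] < emp.shape[0]:
        raise ValueError(
            f"simulated census {sim.shape[0]} smaller than locality count {emp.shape[0]}"
        )
    if rescale:
        emp = rescale_to_cloud(emp, sim)
    chosen = np.empty(emp.shape[0], dtype=np.int64)
    taken = np.zeros(sim.shape[0], dtype=bool)
    for k, p in enumerate(emp):
        d2 = np.sum((sim - p) ** 2, axis=1)
        d2[taken] = np.inf
        idx = int(np.argmin(d2))
        chosen[k] = idx
        taken[idx] = True
    return chosen


# ---------------------------------------------------------------------------
# pairs


def enumerate_pairs(n: int) -> PairSet:
    """All n(n-1)/2 index pairs (i, j), i < j, in lexicographic order."""
    if n < 2:
        raise ValueError("need at least two samples to form pairs")
    i, j = np.triu_indices(n, k=1)
    return PairSet(pairs=np.column_stack([i, j]))


def pairwise_distance(a, b) -> float:
    """Euclidean distance between two planar points."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.hypot(*(a - b)))


def pair_distances(locations: LocationTable, pairs: PairSet) -> np.ndarray:
    """Euclidean distance for every pair, in pair order."""
    c = locations.coords
    d = c[pairs.pairs[:, 0]] - c[pairs.pairs[:, 1]]
    return np.hypot(d[:, 0], d[:, 1])


# ---------------------------------------------------------------------------
# tree-sequence input


def read_tree_sequence(
    ts_path: str | Path,
    sample_individuals: np.ndarray | int | None = None,
    m_snps: int | None = None,
    phased: bool = False,
    locations: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, LocationTable]:
    """Genotypes + locations from a tree-sequence file (.trees).

    An alternative genotype source for training data produced by external
    spatial simulators.  ``sample_individuals`` may be explicit individual
    ids, a count to sample uniformly at random (requires ``rng``), or None
    for all individuals.  Locations are taken from the individuals' location
    metadata (first two coordinates) unless supplied explicitly.  Coding
    follows the same rules as the internal extractor: biallelic sites only,
    segregating in the sample, minor-allele counts, evenly spaced subset
    when more than ``m_snps`` sites are available.
    """
    import tskit

    ts = tskit.load(str(ts_path))
    n_ind = ts.num_individuals
    if n_ind == 0:
        raise ValueError("tree sequence has no individuals")
    if sample_individuals is None:
        ids = np.arange(n_ind)
    elif np.isscalar(sample_individuals):
        if rng is None:
            raise ValueError("sampling a count of individuals requires an rng")
        ids = rng.choice(n_ind, size=int(sample_individuals), replace=False)
    else:
        ids = np.asarray(sample_individuals, dtype=np.int64)

    node_ids = np.concatenate([ts.individual(int(i)).nodes for i in ids])
    gm = ts.genotype_matrix()
    sites = ts.sites_position
    biallelic = np.array([len(v.alleles) == 2 for v in ts.variants()])
    gm, sites = gm[biallelic], sites[biallelic]
    sub = gm[:, node_ids]  # (S, 2k) haplotypes in sample order
    k = ids.size
    counts = sub.sum(axis=1)
    seg = (counts > 0) & (counts < 2 * k)
    sub, sites, counts = sub[seg], sites[seg], counts[seg]
    if m_snps is not None and sub.shape[0] < m_snps:
        raise ValueError(f"only {sub.shape[0]} usable sites, need {m_snps}")
    flip = 2 * counts > 2 * k
    sub = np.where(flip[:, None], 1 - sub, sub)
    if m_snps is not None:
        sel = subset_evenly(sub.shape[0], m_snps)
        sub, sites = sub[sel], sites[sel]
    if phased:
        values = sub.astype(np.int16)
    else:
        values = (sub[:, 0::2] + sub[:, 1::2]).astype(np.int16)

    if locations is None:
        locs = []
        for i in ids:
            loc = ts.individual(int(i)).location
            if loc is None or len(loc) < 2:
                raise ValueError(
                    "tree sequence individuals carry no location metadata; "
                    "pass locations= explicitly"
                )
            locs.append(loc[:2])
        locations = np.asarray(locs, dtype=float)
    else:
        locations = np.asarray(locations, dtype=float)[ids] if len(locations) == n_ind else np.asarray(locations, dtype=float)
    return (
        GenotypeMatrix(values=values, positions=sites.astype(float), phased=phased),
        LocationTable(coords=locations),
    )


# ---------------------------------------------------------------------------
# packed training cache


class PackedTrainingSet:
    """In-memory view of a packed cache: genotype/location/σ arrays + manifest."""

    def __init__(self, genotypes, locations, sigmas, sigma_fs, phased, manifest=None):
        self.genotypes = genotypes  # (D, m, ncol) uint8
        self.locations = locations  # (D, n, 2) float64
        self.sigmas = sigmas  # (D,)
        self.sigma_fs = sigma_fs  # (D,)
        self.phased = bool(phased)
        self.manifest = manifest or {}

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    def dataset(self, k: int) -> tuple[GenotypeMatrix, LocationTable]:
        m = self.genotypes.shape[1]
        g = GenotypeMatrix(
            values=self.genotypes[k].astype(np.int16),
            positions=np.arange(1, m + 1, dtype=float),
            phased=self.phased,
        )
        return g, LocationTable(coords=self.locations[k])

    def as_list(self) -> list[tuple[GenotypeMatrix, LocationTable]]:
        return [self.dataset(k) for k in range(len(self))]


def pack_training_set(results: list[SimulationResult], out_dir: str | Path) -> dict:
    """Write simulation results to a binary cache with a JSON manifest.

    All results must share the genotype-matrix dimensions.  The manifest
    records dataset count, dimensions, the σ targets and the normalization
    statistics (mean/std of log σ) used at training time.
    """
    if not results:
        raise ValueError("no results to pack")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shapes = {r.genotypes.values.shape for r in results}
    ns = {r.locations.n for r in results}
    if len(shapes) != 1 or len(ns) != 1:
        raise ValueError(f"dimension mismatch across results: shapes={shapes}, n={ns}")
    phased = results[0].genotypes.phased
    G = np.stack([r.genotypes.values for r in results]).astype(np.uint8)
    L = np.stack([r.locations.coords for r in results])
    sig = np.array([r.sigma_true for r in results], dtype=float)
    sig_f = np.array([r.sigma_f_true for r in results], dtype=float)
    np.save(out / "genotypes.npy", G)
    np.save(out / "locations.npy", L)
    np.save(out / "sigma.npy", sig)
    np.save(out / "sigma_f.npy", sig_f)
    log_sig = np.log(sig)
    manifest = {
        "n_datasets": len(results),
        "m_snps": int(G.shape[1]),
        "n_samples": int(ns.pop()),
        "phased": phased,
        "sigma_min": float(sig.min()),
        "sigma_max": float(sig.max()),
        "log_sigma_mean": float(log_sig.mean()),
        "log_sigma_std": float(log_sig.std()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_training_set(cache_dir: str | Path) -> PackedTrainingSet:
    """Load a cache written by :func:`pack_training_set`, bit-exactly."""
    d = Path(cache_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    return PackedTrainingSet(
        genotypes=np.load(d / "genotypes.npy"),
        locations=np.load(d / "locations.npy"),
        sigmas=np.load(d / "sigma.npy"),
        sigma_fs=np.load(d / "sigma_f.npy"),
        phased=manifest["phased"],
        manifest=manifest,
    )
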
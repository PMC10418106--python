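"""Continuous-space individual-based forward simulator.

Generates the training and validation data for dispersal inference: a
population of diploid hermaphrodites lives on a square habitat, and the
mother-offspring dispersal kernel, the mate-search kernel and the competition
kernel are all Gaussian with the same scale ``sigma_f``.  Local density
regulates fecundity so the census fluctuates around carrying capacity times
habitat area.  Initial standing variation is seeded from a neutral coalescent
sample (msprime), then the population evolves forward with recombination and
mutation for a configurable number of generations.

The quantity of interest is the effective dispersal rate sigma — the RMS
per-axis displacement between a child and a randomly chosen parent — which
combines the mother-offspring kernel (variance sigma_f^2) and the
father-child displacement (mating plus dispersal, variance 2 sigma_f^2),
giving sigma = sigma_f * sqrt(3/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from ._neighbors import build_grid, density_and_mates
from .containers import GenotypeMatrix, LocationTable, SimulationResult
from .preprocess import subset_evenly

__all__ = [
    "SimParams",
    "PopulationState",
    "ExtinctionError",
    "effective_sigma",
    "init_population",
    "step_generation",
    "run_simulation",
    "extract_genotype_matrix",
    "simulate_training_data",
    "write_vcf",
]

# fraction of a 2-D Gaussian's mass inside the 3-sigma truncation radius
_TRUNC_MASS = 1.0 - math.exp(-4.5)


class ExtinctionError(RuntimeError):
    """The population died out; retry with another seed or milder settings."""


@dataclass(frozen=True)
class SimParams:
    """Simulation settings.

    Parameters
    ----------
    habitat_width
        Side of the square habitat, map units.
    carrying_capacity
        Target density K, individuals per square map unit.
    sigma_f
        Shared scale (map units) of the dispersal, mating and competition
        kernels; the training prior draws it from U(0.2, 3).
    genome_length, recomb_rate, mut_rate
        Genome size in bp and per-bp per-generation crossover/mutation rates.
    founder_recomb_rate
        Recombination rate of the coalescent that seeds standing variation.
        The deep (pre-spatial) genealogy carries no dispersal signal, so a
        shorter founder map is a pure speed choice; forward generations
        always use ``recomb_rate``.
    n_generations
        Forward generations run after coalescent seeding.
    sigma_factor
        Multiplier converting sigma_f to the effective dispersal rate sigma;
        sqrt(3/2) under equal dispersal and mating kernels.
    max_fecundity
        Expected offspring per mother as local density approaches zero;
        regulation is lambda = max_fecundity / (1 + (max_fecundity - 1) rho/K).
    """

    habitat_width: float = 15.0
    carrying_capacity: float = 5.0
    sigma_f: float = 1.0
    genome_length: float = 1e6
    recomb_rate: float = 1e-6
    founder_recomb_rate: float = 2e-7
    mut_rate: float = 2.5e-8
    n_generations: int = 100
    seed: int = 0
    sigma_factor: float = math.sqrt(1.5)
    max_fecundity: float = 2.0

    def __post_init__(self) -> None:
        if self.habitat_width <= 0:
            raise ValueError("habitat_width must be positive")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.recomb_rate < 0 or self.mut_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be positive")
        if self.max_fecundity <= 1:
            raise ValueError("max_fecundity must exceed 1 for a stable population")


@dataclass
class PopulationState:
    """Positions, haplotypes and segregating-site coordinates at one generation."""

    positions: np.ndarray  # (N, 2) float
    haplotypes: np.ndarray  # (N, 2, S) uint8
    site_positions: np.ndarray  # (S,) float, strictly increasing bp coords
    generation: int = 0
    displacements: list = field(default_factory=list)  # recorded pre-reflection

    @property
    def census(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]


def effective_sigma(sigma_f: float, sigma_factor: float = math.sqrt(1.5)) -> float:
    """Effective dispersal rate to a randomly chosen parent."""
    if sigma_f <= 0 or sigma_factor <= 0:
        raise ValueError("sigma_f and sigma_factor must be positive")
    return sigma_f * sigma_factor


def init_population(params: SimParams) -> PopulationState:
    """Place ~K*area individuals uniformly; seed variation from a coalescent.

    The coalescent sample (population size = census, with recombination and
    mutation) provides standing variation without a long forward burn-in.
    """
    import msprime

    n0 = int(round(params.carrying_capacity * params.habitat_width**2))
    if n0 < 2:
        raise ValueError("carrying_capacity x area must allow at least 2 individuals")
    ss = np.random.SeedSequence(params.seed)
    s_pos, s_anc, s_mut = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(3))
    rng = np.random.default_rng(s_pos)
    positions = rng.uniform(0, params.habitat_width, size=(n0, 2))
    ts = msprime.sim_ancestry(
        samples=n0,
        population_size=n0,
        sequence_length=params.genome_length,
        recombination_rate=params.founder_recomb_rate,
        random_seed=s_anc,
    )
    ts = msprime.sim_mutations(
        ts, rate=params.mut_rate, random_seed=s_mut, model=msprime.BinaryMutationModel()
    )
    gm = ts.genotype_matrix()  # (S, 2*n0) in {0,1}
    site_pos = ts.sites_position.astype(float)
    # keep polymorphic sites only (recurrent mutation can re-fix a site)
    counts = gm.sum(axis=1)
    keep = (counts > 0) & (counts < 2 * n0)
    gm, site_pos = gm[keep], site_pos[keep]
    haps = np.ascontiguousarray(gm.T.reshape(n0, 2, -1)).astype(np.uint8)
    return PopulationState(positions=positions, haplotypes=haps, site_positions=site_pos)


def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Reflect coordinates into [0, width] (period-2W folding)."""
    y = np.mod(x, 2 * width)
    over = y > width
    y[over] = 2 * width - y[over]
    return y


def _edge_coverage(pos: np.ndarray, width: float, sigma: float) -> np.ndarray:
    """Fraction of each individual's Gaussian kernel mass inside the habitat."""
    cov_x = ndtr((width - pos[:, 0]) / sigma) - ndtr(-pos[:, 0] / sigma)
    cov_y = ndtr((width - pos[:, 1]) / sigma) - ndtr(-pos[:, 1] / sigma)
    return cov_x * cov_y


def _make_gametes(haps, site_pos, parent_idx, rng, recomb_rate, genome_length):
    """One recombinant gamete per requested parent.

    Crossover count per gamete is Poisson(recomb_rate * genome_length) with
    breakpoints uniform on the bp map; the gamete alternates between the
    parent's two haplotypes across breakpoints.  Vectorized over gametes by
    looping over crossover ranks (few) instead of gametes (many).
    """
    m = parent_idx.size
    hsel = rng.integers(0, 2, size=m)
    gam = haps[parent_idx, hsel, :].copy()
    ncx = rng.poisson(recomb_rate * genome_length, size=m)
    with_cx = np.flatnonzero(ncx)
    if with_cx.size == 0:
        return gam
    # parity[g, s] = (number of breakpoints left of site s) mod 2
    parity = np.zeros((with_cx.size, site_pos.size), dtype=bool)
    for _ in range(int(ncx.max())):
        active = ncx[with_cx] > 0
        cuts = rng.uniform(0, genome_length, size=int(active.sum()))
        parity[active] ^= site_pos[None, :] >= cuts[:, None]
        ncx[with_cx[active]] -= 1
    other = haps[parent_idx[with_cx], 1 - hsel[with_cx], :]
    sub = gam[with_cx]
    sub[parity] = other[parity]
    gam[with_cx] = sub
    return gam


def step_generation(
    state: PopulationState,
    params: SimParams,
    rng: np.random.Generator,
    record_displacements: bool = False,
) -> PopulationState:
    """Advance one non-overlapping generation.

    Every individual acts as a mother: she samples a mate with Gaussian
    weights truncated at 3*sigma_f (no candidate in range -> no offspring),
    produces Poisson-many offspring with mean set by logistic local-density
    regulation, and each offspring lands at the mother's position plus an
    isotropic Gaussian displacement of scale sigma_f, reflected at the
    habitat edges.  Displacements are recorded before reflection.
    """
    n = state.census
    if n == 0:
        raise ExtinctionError("population is extinct")
    sigma = params.sigma_f
    w = params.habitat_width
    pos = state.positions

    order, cell_start, ncell, cellw = build_grid(pos, w, sigma)
    u_mate = rng.random(n)
    wsum, mate = density_and_mates(pos, sigma, u_mate, order, cell_start, ncell, cellw)

    coverage = _edge_coverage(pos, w, sigma)
    density = wsum / (2 * math.pi * sigma**2 * _TRUNC_MASS * np.maximum(coverage, 1e-12))
    lam_max = params.max_fecundity
    lam = lam_max / (1.0 + (lam_max - 1.0) * density / params.carrying_capacity)
    lam[mate < 0] = 0.0
    n_off = rng.poisson(lam)
    total = int(n_off.sum())
    if total == 0:
        raise ExtinctionError(f"no offspring produced at generation {state.generation + 1}")

    mothers = np.repeat(np.arange(n), n_off)
    fathers = mate[mothers]
    disp = rng.normal(0.0, sigma, size=(total, 2))
    child_pos = _reflect(pos[mothers] + disp, w)

    mat_gam = _make_gametes(
        state.haplotypes, state.site_positions, mothers, rng, params.recomb_rate, params.genome_length
    )
    pat_gam = _make_gametes(
        state.haplotypes, state.site_positions, fathers, rng, params.recomb_rate, params.genome_length
    )
    child_haps = np.stack([mat_gam, pat_gam], axis=1)
    site_pos = state.site_positions

    # new mutations: Poisson(mut_rate * L) per gamete, uniform bp positions
    mu_total = rng.poisson(params.mut_rate * params.genome_length * 2 * total)
    if mu_total > 0:
        new_pos = rng.uniform(0, params.genome_length, size=mu_total)
        new_pos = new_pos[~np.isin(new_pos, site_pos)]
        gamete_of = rng.integers(0, 2 * total, size=new_pos.size)
        new_cols = np.zeros((total, 2, new_pos.size), dtype=np.uint8)
        new_cols[gamete_of % total, gamete_of // total, np.arange(new_pos.size)] = 1
        child_haps = np.concatenate([child_haps, new_cols], axis=2)
        site_pos = np.concatenate([site_pos, new_pos])

    # drop sites fixed or lost in the new generation and restore position
    # order (new mutation columns were appended at the end) in one re-index
    colsum = child_haps.sum(axis=(0, 1), dtype=np.int64)
    keep = np.flatnonzero((colsum > 0) & (colsum < 2 * total))
    keep = keep[np.argsort(site_pos[keep], kind="stable")]
    child_haps = child_haps[:, :, keep]
    site_pos = site_pos[keep]

    new_state = PopulationState(
        positions=child_pos,
        haplotypes=child_haps,
        site_positions=site_pos,
        generation=state.generation + 1,
        displacements=state.displacements,
    )
    if record_displacements:
        new_state.displacements.append(disp)
    return new_state


def extract_genotype_matrix(
    state: PopulationState,
    sample_ids: np.ndarray,
    m_snps: int | None = None,
    phased: bool = False,
) -> tuple[GenotypeMatrix, LocationTable]:
    """Genotypes and locations of a sample, minor-allele coded.

    Sites monomorphic within the sample are dropped; when more than
    ``m_snps`` segregating sites remain, an evenly spaced (by rank along the
    genome) subset of exactly ``m_snps`` is returned.
    """
    sample_ids = np.asarray(sample_ids, dtype=np.int64)
    haps = state.haplotypes[sample_ids]  # (k, 2, S)
    k = sample_ids.size
    counts = haps.sum(axis=(0, 1))
    seg = (counts > 0) & (counts < 2 * k)
    if m_snps is not None and int(seg.sum()) < m_snps:
        raise ValueError(
            f"only {int(seg.sum())} segregating sites in the sample, need {m_snps}"
        )
    haps = haps[:, :, seg]
    pos = state.site_positions[seg]
    counts = counts[seg]
    # minor coding: flip when the derived allele is strictly major (ties keep
    # the derived allele, matching the idempotent coding rule)
    flip = 2 * counts > (2 * k)
    haps = np.where(flip[None, None, :], 1 - haps, haps)
    if m_snps is not None:
        sel = subset_evenly(pos.size, m_snps)
        haps, pos = haps[:, :, sel], pos[sel]
    if phased:
        values = haps.reshape(k * 2, -1).T.astype(np.int16)  # columns 2i, 2i+1
    else:
        values = haps.sum(axis=1).T.astype(np.int16)
    gm = GenotypeMatrix(values=values, positions=pos, phased=phased)
    loc = LocationTable(coords=state.positions[sample_ids].copy())
    return gm, loc


def run_simulation(
    params: SimParams,
    sample_n: int,
    draws: int = 1,
    m_snps: int | None = None,
    phased: bool = False,
) -> list[SimulationResult]:
    """Run a full simulation and take ``draws`` independent samples.

    Each draw samples ``sample_n`` individuals uniformly at random without
    replacement from the final generation; all draws share the same true σ.
    """
    state = init_population(params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    for _ in range(params.n_generations):
        state = step_generation(state, params, rng)
    if sample_n > state.census:
        raise ValueError(
            f"sample_n={sample_n} exceeds final census {state.census}"
        )
    sigma = effective_sigma(params.sigma_f, params.sigma_factor)
    results = []
    for _ in range(draws):
        ids = rng.choice(state.census, size=sample_n, replace=False)
        gm, loc = extract_genotype_matrix(state, ids, m_snps=m_snps, phased=phased)
        results.append(
            SimulationResult(
                genotypes=gm,
                locations=loc,
                sigma_f_true=params.sigma_f,
                sigma_true=sigma,
                seed=params.seed,
            )
        )
    return results


def simulate_training_data(
    n_sims: int,
    draws_per_sim: int,
    sample_n: int,
    m_snps: int,
    seed: int,
    sigma_f_range: tuple[float, float] = (0.2, 3.0),
    params_template: SimParams | None = None,
    phased: bool = False,
    max_retries: int = 3,
) -> list[SimulationResult]:
    """Simulate across the training prior: sigma_f ~ U(0.2, 3) per simulation.

    Each simulation is sampled ``draws_per_sim`` times; an extinct run is
    retried with a fresh seed up to ``max_retries`` times.
    """
    template = params_template or SimParams()
    ss = np.random.SeedSequence(seed)
    prior_rng = np.random.default_rng(ss.spawn(1)[0])
    sim_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_sims * (max_retries + 1))]
    results: list[SimulationResult] = []
    seed_iter = iter(sim_seeds)
    for _ in range(n_sims):
        sf = float(prior_rng.uniform(*sigma_f_range))
        for attempt in range(max_retries + 1):
            params = replace(template, sigma_f=sf, seed=next(seed_iter))
            try:
                results.extend(
                    run_simulation(params, sample_n, draws=draws_per_sim, m_snps=m_snps, phased=phased)
                )
                break
            except (ExtinctionError, ValueError):
                if attempt == max_retries:
                    raise
    return results


def write_vcf(gm: GenotypeMatrix, path, chrom: str = "1", sample_names=None) -> None:
    """Export a genotype matrix as a plain-text VCF 4.2 file (GT field only)."""
    n = gm.n_samples
    names = sample_names or [f"ind{i}" for i in range(n)]
    sep = "|" if gm.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        last_pos = 0
        for r in range(gm.m_snps):
            pos = max(int(round(gm.positions[r])), last_pos + 1)
            last_pos = pos
            gts = []
            for i in range(n):
                if gm.phased:
                    a, b = gm.values[r, 2 * i], gm.values[r, 2 * i + 1]
                else:
                    g = gm.values[r, i]
                    a, b = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
                gts.append(f"{a}{sep}{b}")
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
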
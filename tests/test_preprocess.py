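import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispersalnet.containers import GenotypeMatrix, LocationTable
from dispersalnet.preprocess import (
    code_minor_alleles,
    enumerate_pairs,
    match_sampling,
    pack_training_set,
    load_training_set,
    pair_distances,
    pairwise_distance,
    project_coordinates,
    read_genotypes,
    read_locations,
    subset_evenly,
)
from dispersalnet.simulate import write_vcf


# ---------------------------------------------------------------------------
# pair enumeration


@pytest.mark.parametrize("n,expected", [(2, 1), (10, 45), (100, 4950)])
def test_enumerate_pairs_counts(n, expected):
    ps = enumerate_pairs(n)
    assert len(ps) == expected


def test_enumerate_pairs_matches_brute_force():
    for n in (2, 3, 7, 50, 200):
        brute = [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert list(enumerate_pairs(n)) == brute


def test_enumerate_pairs_rejects_singletons():
    with pytest.raises(ValueError):
        enumerate_pairs(1)


# ---------------------------------------------------------------------------
# distances and projection


def test_pairwise_distance_345_triangle():
    assert pairwise_distance((0, 0), (3, 4)) == 5.0
    assert pairwise_distance((1, 1), (1, 1)) == 0.0


@given(
    st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
    st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_pairwise_distance_symmetric(a, b):
    assert pairwise_distance(a, b) == pytest.approx(pairwise_distance(b, a))


def test_projection_one_degree_longitude_at_equator():
    # one degree of longitude on a 6371-km sphere: pi*R/180 = 111.19 km
    table = LocationTable(coords=np.array([[0.0, 0.0], [0.0, 1.0]]), latlon=np.array([[0.0, 0.0], [0.0, 1.0]]))
    planar = project_coordinates(table)
    d = pairwise_distance(planar.coords[0], planar.coords[1])
    assert d == pytest.approx(111.19, abs=0.01)


def test_projection_identical_points_and_centering():
    table = LocationTable(coords=np.array([[45.0, 10.0], [45.0, 10.0]]))
    planar = project_coordinates(table)
    assert pairwise_distance(planar.coords[0], planar.coords[1]) == 0.0
    single = project_coordinates(LocationTable(coords=np.array([[12.0, 30.0]])))
    assert np.allclose(single.coords, 0.0)


def test_projection_rejects_out_of_range():
    with pytest.raises(ValueError):
        project_coordinates(LocationTable(coords=np.array([[95.0, 0.0]])))


def test_projection_preserves_local_distance_ratios():
    # a cluster spanning < 2 degrees: ratios preserved to within 1%
    rng = np.random.default_rng(3)
    latlon = np.column_stack([40 + rng.uniform(0, 1.5, 20), -120 + rng.uniform(0, 1.5, 20)])
    planar = project_coordinates(LocationTable(coords=latlon))
    # haversine reference
    lat = np.deg2rad(latlon[:, 0])
    lon = np.deg2rad(latlon[:, 1])
    ratios = []
    for i, j in [(0, 1), (2, 5), (7, 19), (3, 11)]:
        dlat, dlon = lat[j] - lat[i], lon[j] - lon[i]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat[i]) * np.cos(lat[j]) * np.sin(dlon / 2) ** 2
        gc = 2 * 6371.0 * np.arcsin(np.sqrt(h))
        pl = pairwise_distance(planar.coords[i], planar.coords[j])
        ratios.append(pl / gc)
    assert np.ptp(ratios) < 0.01


# ---------------------------------------------------------------------------
# genotype coding


def test_minor_allele_coding_idempotent():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(50, 11)).astype(np.int16)
    coded = code_minor_alleles(g)
    assert np.array_equal(code_minor_alleles(coded), coded)
    freqs = coded.sum(axis=1) / (2 * coded.shape[1])
    assert np.all(freqs <= 0.5)


def test_minor_allele_tie_keeps_current_coding():
    # all-het site: frequency exactly 0.5 either way, row stays all ones
    g = np.ones((1, 4), dtype=np.int16)
    assert np.array_equal(code_minor_alleles(g), g)
    # 2,2,0,0: frequency exactly 0.5 -> tie -> left unchanged (idempotent)
    g2 = np.array([[2, 2, 0, 0]], dtype=np.int16)
    assert np.array_equal(code_minor_alleles(g2), g2)
    # strict majority flips
    g3 = np.array([[2, 2, 1, 0]], dtype=np.int16)
    assert np.array_equal(code_minor_alleles(g3), np.array([[0, 0, 1, 2]]))


def test_subset_evenly_deterministic_and_bounded():
    idx = subset_evenly(6000, 5000)
    assert idx.size == 5000
    assert idx[0] == 0 and idx[-1] == 5999
    with pytest.raises(ValueError):
        subset_evenly(100, 200)


# ---------------------------------------------------------------------------
# VCF + coordinate-table I/O


def test_vcf_round_trip_unphased(tmp_path, quick_sim):
    gm = quick_sim[0].genotypes
    vcf_path = tmp_path / "sim.vcf"
    write_vcf(gm, vcf_path)
    back = read_genotypes(vcf_path, phased=False)
    assert np.array_equal(back.values, gm.values)
    assert np.all(np.diff(back.positions) > 0)


def test_vcf_phased_has_twice_the_columns(tmp_path, quick_sim):
    from dispersalnet.simulate import SimParams, run_simulation

    res = run_simulation(
        SimParams(habitat_width=6, sigma_f=0.8, n_generations=10, seed=9),
        sample_n=10,
        draws=1,
        m_snps=50,
        phased=True,
    )[0]
    vcf_path = tmp_path / "phased.vcf"
    write_vcf(res.genotypes, vcf_path)
    phased = read_genotypes(vcf_path, phased=True)
    unphased = read_genotypes(vcf_path, phased=False)
    assert phased.values.shape[1] == 2 * unphased.values.shape[1]
    assert set(np.unique(phased.values)) <= {0, 1}


def test_read_genotypes_m_snps_subsetting(tmp_path, quick_sim):
    gm = quick_sim[0].genotypes
    vcf_path = tmp_path / "sim.vcf"
    write_vcf(gm, vcf_path)
    sub = read_genotypes(vcf_path, m_snps=60)
    assert sub.values.shape[0] == 60
    assert np.all(np.diff(sub.positions) > 0)
    with pytest.raises(ValueError, match="fewer"):
        read_genotypes(vcf_path, m_snps=10_000)


def test_read_locations_header_and_mismatch(tmp_path):
    p = tmp_path / "coords.csv"
    p.write_text("sample,latitude,longitude\na,1.5,2.5\nb,3.0,4.0\n")
    loc = read_locations(p)
    assert loc.n == 2
    assert loc.latlon[0, 0] == 1.5
    with pytest.raises(ValueError, match="rows"):
        read_locations(p, n_expected=3)
    bad = tmp_path / "bad.csv"
    bad.write_text("a,1.0,2.0\nb,oops,4.0\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_locations(bad)


# ---------------------------------------------------------------------------
# sampling-scheme matching


def test_match_sampling_identity_and_injectivity():
    rng = np.random.default_rng(5)
    sim = LocationTable(coords=rng.uniform(0, 50, size=(200, 2)))
    emp = LocationTable(coords=sim.coords[[3, 17, 99, 42]].copy())
    idx = match_sampling(sim, emp, rescale=False)
    assert list(idx) == [3, 17, 99, 42]
    assert len(set(idx)) == len(idx)


def test_match_sampling_conflict_goes_to_next_nearest():
    sim = LocationTable(coords=np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]]))
    emp = LocationTable(coords=np.array([[0.1, 0.0], [0.0, 0.1]]))
    idx = match_sampling(sim, emp, rescale=False)
    assert idx[0] == 0  # first locality takes the nearest
    assert idx[1] == 1  # second must take its next-nearest
    with pytest.raises(ValueError):
        match_sampling(LocationTable(coords=np.zeros((1, 2))), emp, rescale=False)


# ---------------------------------------------------------------------------
# packed cache


def test_pack_round_trip(tmp_path, quick_sim):
    manifest = pack_training_set(quick_sim, tmp_path / "cache")
    assert manifest["n_datasets"] == len(quick_sim)
    packed = load_training_set(tmp_path / "cache")
    assert len(packed) == len(quick_sim)
    for k, r in enumerate(quick_sim):
        G, L = packed.dataset(k)
        assert np.array_equal(G.values, r.genotypes.values)
        assert np.array_equal(L.coords, r.locations.coords)
        assert packed.sigmas[k] == r.sigma_true


def test_pack_rejects_dimension_mismatch(tmp_path, quick_sim):
    import dataclasses

    small = dataclasses.replace(
        quick_sim[0],
        genotypes=GenotypeMatrix(
            values=quick_sim[0].genotypes.values[:50],
            positions=quick_sim[0].genotypes.positions[:50],
        ),
    )
    with pytest.raises(ValueError, match="mismatch"):
        pack_training_set([quick_sim[0], small], tmp_path / "bad")


def test_pair_distances_match_scalar_function(quick_sim):
    loc = quick_sim[0].locations
    ps = enumerate_pairs(5)
    vec = pair_distances(loc, ps)
    for k, (i, j) in enumerate(ps):
        assert vec[k] == pytest.approx(pairwise_distance(loc.coords[i], loc.coords[j]))


def test_read_tree_sequence_matches_direct_coding(tmp_path):
    import msprime
    from dispersalnet.preprocess import read_tree_sequence

    ts = msprime.sim_ancestry(samples=12, population_size=50, sequence_length=1e5,
                              recombination_rate=1e-7, random_seed=4)
    ts = msprime.sim_mutations(ts, rate=5e-7, random_seed=5,
                               model=msprime.BinaryMutationModel())
    path = tmp_path / "sim.trees"
    ts.dump(path)
    locs = np.random.default_rng(0).uniform(0, 10, size=(12, 2))
    G, L = read_tree_sequence(path, m_snps=20, locations=locs)
    assert G.values.shape == (20, 12)
    assert set(np.unique(G.values)) <= {0, 1, 2}
    freqs = G.values.sum(axis=1) / 24
    assert np.all(freqs > 0) and np.all(freqs <= 0.5)
    # phased output has twice the columns and collapses back to dosages
    Gp, _ = read_tree_sequence(path, m_snps=20, locations=locs, phased=True)
    assert np.array_equal(Gp.values[:, 0::2] + Gp.values[:, 1::2], G.values)
    # sampling a subset requires an rng and yields matching shapes
    Gs, Ls = read_tree_sequence(path, sample_individuals=5, m_snps=10,
                                locations=locs, rng=np.random.default_rng(1))
    assert G.values.shape[1] == 12 and Gs.values.shape == (10, 5)
    assert Ls.coords.shape == (5, 2)
    with pytest.raises(ValueError, match="location"):
        read_tree_sequence(path, m_snps=5)
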
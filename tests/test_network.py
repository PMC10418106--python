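import numpy as np
import pytest

from dispersalnet.containers import PairSet
from dispersalnet.network import (
    ModelSpec,
    assemble_pair_tensors,
    build_model,
    extract_pair_features,
    batch_forward,
    forward,
    forward_gated,
    load_weights,
    loss_and_grads,
    save_weights,
)
from dispersalnet.preprocess import enumerate_pairs


def test_spec_shape_arithmetic():
    spec = ModelSpec(m_snps=5000, n_samples=100)
    (lc1, lp1), (lc2, lp2) = spec.block_lengths()
    assert lc1 == 4999  # valid-padding conv with kernel 2
    assert lp1 == 499  # average pool window 10, remainder dropped
    assert lc2 == 498 and lp2 == 49
    assert spec.n_pairs == 4950


def test_spec_rejects_small_m():
    with pytest.raises(ValueError, match="minimum"):
        ModelSpec(m_snps=40, n_samples=4)  # two blocks need m >= 111
    ModelSpec(m_snps=111, n_samples=4)  # boundary is valid


def test_head_outputs_scalar(toy_weights, toy_dataset):
    G, L = toy_dataset
    sigma_hat = forward(G, L, toy_weights)
    assert np.isscalar(sigma_hat)
    assert np.isfinite(sigma_hat)


def test_extractor_parameter_count_independent_of_n():
    s4 = ModelSpec(m_snps=200, n_samples=4)
    s40 = ModelSpec(m_snps=200, n_samples=40)
    w4, w40 = build_model(s4), build_model(s40)
    for name in w4.extractor_param_names():
        assert w4.params[name].shape == w40.params[name].shape
    assert w40.params["head_W"].size > w4.params["head_W"].size


def test_weight_sharing_identical_blocks_give_identical_features(toy_weights):
    rng = np.random.default_rng(0)
    block = rng.integers(0, 3, size=(2, 40)).astype(float)
    f1 = extract_pair_features(block, 1.5, toy_weights)
    f2 = extract_pair_features(block.copy(), 1.5, toy_weights)
    assert np.array_equal(f1, f2)
    # distance enters the feature path
    f3 = extract_pair_features(block, 3.0, toy_weights)
    assert not np.array_equal(f1, f3)


def test_zero_inputs_zero_weights_give_zero_features():
    spec = ModelSpec(m_snps=40, n_samples=4, filters_per_block=(6,), pair_dense_units=8)
    ws = build_model(spec)
    for k in ws.params:
        ws.params[k] = np.zeros_like(ws.params[k])
    f = extract_pair_features(np.zeros((2, 40)), 0.0, ws)
    assert np.array_equal(f, np.zeros(8))


def test_forward_deterministic_and_denormalized(toy_weights, toy_dataset):
    G, L = toy_dataset
    a = forward(G, L, toy_weights)
    b = forward(G, L, toy_weights)
    assert a == b
    # log-z transform changes the output scale
    ws2 = toy_weights.copy()
    ws2.target_log = True
    ws2.target_mean, ws2.target_std = 0.3, 0.5
    assert forward(G, L, ws2) == pytest.approx(np.exp(0.3 + 0.5 * a))


def test_forward_gated_prediction_identical(toy_weights, toy_dataset):
    G, L = toy_dataset
    pairs = enumerate_pairs(4)
    full = forward(G, L, toy_weights, pairs)
    for k in range(1, 7):
        sub = PairSet(pairs=pairs.pairs[:k])
        assert forward_gated(G, L, toy_weights, pairs, sub) == full
    with pytest.raises(ValueError, match="subset"):
        forward_gated(G, L, toy_weights, pairs, PairSet(pairs=np.array([[0, 5]])))


def test_gated_full_mask_matches_ungated_gradients(toy_weights, toy_dataset):
    G, L = toy_dataset
    x, dist = assemble_pair_tensors(G, L)
    y = np.array([0.7])
    loss_a, _, grads_a = loss_and_grads(toy_weights, x[None], dist[None], y, None)
    mask = np.ones(6, dtype=bool)
    loss_b, _, grads_b = loss_and_grads(toy_weights, x[None], dist[None], y, mask)
    assert loss_a == loss_b
    for k in grads_a:
        assert np.allclose(grads_a[k], grads_b[k], rtol=1e-12, atol=0)


def test_gating_zeroes_only_extractor_gradients(toy_weights, toy_dataset):
    G, L = toy_dataset
    x, dist = assemble_pair_tensors(G, L)
    y = np.array([0.7])
    mask = np.zeros(6, dtype=bool)
    mask[2] = True  # single pair carries extractor gradients
    _, _, gated = loss_and_grads(toy_weights, x[None], dist[None], y, mask)
    _, _, full = loss_and_grads(toy_weights, x[None], dist[None], y, None)
    # head gradients unaffected by gating
    assert np.allclose(gated["head_W"], full["head_W"])
    assert np.allclose(gated["head_b"], full["head_b"])
    # extractor gradient equals the selected pair's contribution alone:
    # summing single-pair masks over all pairs reproduces the ungated gradient
    acc = {k: np.zeros_like(v) for k, v in full.items() if k.startswith(("conv", "dense"))}
    for p in range(6):
        m = np.zeros(6, dtype=bool)
        m[p] = True
        _, _, g = loss_and_grads(toy_weights, x[None], dist[None], y, m)
        for k in acc:
            acc[k] += g[k]
    for k in acc:
        assert np.allclose(acc[k], full[k], rtol=1e-9, atol=1e-12)


def test_gradients_match_finite_differences(toy_weights, toy_dataset):
    G, L = toy_dataset
    x, dist = assemble_pair_tensors(G, L)
    y = np.array([0.4])
    _, _, grads = loss_and_grads(toy_weights, x[None], dist[None], y, None)
    rng = np.random.default_rng(17)
    eps = 1e-6
    for name, g in grads.items():
        p = toy_weights.params[name]
        flat = p.reshape(-1) if p.ndim else None
        idxs = [None] if p.ndim == 0 else rng.choice(flat.size, size=min(4, flat.size), replace=False)
        for i in idxs:
            if p.ndim == 0:
                orig = float(p)
                toy_weights.params[name] = np.asarray(orig + eps)
                lp, _, _ = loss_and_grads(toy_weights, x[None], dist[None], y, None)
                toy_weights.params[name] = np.asarray(orig - eps)
                lm, _, _ = loss_and_grads(toy_weights, x[None], dist[None], y, None)
                toy_weights.params[name] = np.asarray(orig)
                ana = float(g)
            else:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = loss_and_grads(toy_weights, x[None], dist[None], y, None)
                flat[i] = orig - eps
                lm, _, _ = loss_and_grads(toy_weights, x[None], dist[None], y, None)
                flat[i] = orig
                ana = g.reshape(-1)[i]
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(ana, rel=1e-5, abs=1e-10)


def test_label_permutation_consistency(toy_weights, toy_dataset):
    """Permuting sample labels (and locations identically) leaves the pair
    multiset unchanged up to pair-row order; with a head that sums symmetric
    contributions the prediction shift comes only from pair ordering."""
    G, L = toy_dataset
    base = forward(G, L, toy_weights)
    # swap samples 2 and 3: pair set unchanged as a set; features permute
    perm = [0, 1, 3, 2]
    import dataclasses

    G2 = dataclasses.replace(G, values=G.values[:, perm])
    L2 = dataclasses.replace(L, coords=L.coords[perm])
    x1, d1 = assemble_pair_tensors(G, L)
    x2, d2 = assemble_pair_tensors(G2, L2)
    # multisets of ({pair member rows}, distance) agree even though pair order
    # and within-pair row order differ (the block layout is order-sensitive,
    # which is why a canonical i<j order is imposed everywhere)
    def keys(x, d):
        return sorted(
            (min(x[k][0].tobytes(), x[k][1].tobytes()),
             max(x[k][0].tobytes(), x[k][1].tobytes()),
             round(d[k], 12))
            for k in range(6)
        )

    assert keys(x1, d1) == keys(x2, d2)
    assert np.isfinite(forward(G2, L2, toy_weights)) and np.isfinite(base)


def test_batch_forward_handles_zero_distance(toy_weights, toy_dataset):
    G, L = toy_dataset
    import dataclasses

    L0 = dataclasses.replace(L, coords=np.zeros_like(L.coords))
    assert np.isfinite(forward(G, L0, toy_weights))


def test_weight_serialization_round_trip(tmp_path, toy_weights, toy_dataset):
    G, L = toy_dataset
    path = tmp_path / "w.npz"
    save_weights(toy_weights, path)
    back = load_weights(path)
    assert back.spec == toy_weights.spec
    for k, v in toy_weights.params.items():
        assert np.array_equal(back.params[k], v)
    assert forward(G, L, back) == forward(G, L, toy_weights)


def test_forward_rejects_pair_count_mismatch(toy_weights, toy_dataset):
    G, L = toy_dataset
    with pytest.raises(ValueError, match="pairs"):
        forward(G, L, toy_weights, PairSet(pairs=np.array([[0, 1], [0, 2]])))


def test_extract_pair_features_rejects_bad_shape(toy_weights):
    with pytest.raises(ValueError, match="block"):
        extract_pair_features(np.zeros((3, 40)), 1.0, toy_weights)
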
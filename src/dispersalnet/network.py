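"""The pairwise convolutional network, in plain numpy.

The extractor runs independently on every pair of individuals: the pair's
stacked genotype rows (2 rows unphased, 4 phased) pass through repeated
[convolution (kernel spanning 2 SNPs, stride 1, no padding) -> average
pooling (window 10, non-overlapping, remainder dropped)] blocks, the output
is flattened, the pair's (scaled) Euclidean distance is concatenated, and a
fully connected layer with rectified-linear activation yields the pair's
feature vector.  Extractor weights are shared across all pairs.  The head
stacks every pair's features and applies a single fully connected unit with
linear activation to produce the dispersal estimate.

Gradient gating: during optimization only a random subset of k_extract pairs
contributes gradients to the shared extractor weights, while the forward
pass — and the head's gradients — always use the full pair set.  This leaves
the prediction identical and only reroutes gradient flow.

Forward and backward passes are hand-written; all arrays are float64, so
gradients can be validated against finite differences to tight tolerance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .containers import GenotypeMatrix, LocationTable, PairSet
from .preprocess import enumerate_pairs, pair_distances

__all__ = [
    "ModelSpec",
    "WeightSet",
    "build_model",
    "extract_pair_features",
    "forward",
    "forward_gated",
    "assemble_pair_tensors",
    "batch_forward",
    "loss_and_grads",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    The convolution kernel width (2 SNPs) and pooling window (10 SNPs,
    averaged) are fixed; block count, filter counts and the dense width are
    configurable.  ``distance_scale`` divides pair distances before they are
    concatenated with the convolved genotypes, keeping that feature of order
    one for samples spread across a habitat of that width.  With
    ``distance_transform="log"`` (default) the feature is the natural log of
    the scaled distance (floored at 1e-3 of the scale) — the transform under
    which two-dimensional isolation by distance is linear; ``"linear"``
    passes the scaled distance through unchanged.
    """

    m_snps: int
    n_samples: int
    phased: bool = False
    conv_kernel_snps: int = 2
    pool_window: int = 10
    filters_per_block: tuple[int, ...] = (32, 64)
    pair_dense_units: int = 128
    distance_scale: float = 1.0
    distance_transform: str = "log"
    k_extract: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_kernel_snps != 2 or self.pool_window != 10:
            raise ValueError("conv kernel is fixed at 2 SNPs and pooling at 10")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples to form pairs")
        if min(self.filters_per_block) < 1 or self.pair_dense_units < 1:
            raise ValueError("layer sizes must be positive")
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if self.distance_transform not in ("linear", "log"):
            raise ValueError("distance_transform must be 'linear' or 'log'")
        n_pairs = self.n_samples * (self.n_samples - 1) // 2
        if self.k_extract is not None and not (1 <= self.k_extract <= n_pairs):
            raise ValueError(f"k_extract must be in [1, {n_pairs}]")
        m_min = self.min_m_snps()
        if self.m_snps < m_min:
            raise ValueError(
                f"m_snps={self.m_snps} too small for {len(self.filters_per_block)} "
                f"conv/pool blocks; minimum is {m_min}"
            )

    @property
    def channels(self) -> int:
        return 4 if self.phased else 2

    @property
    def n_pairs(self) -> int:
        return self.n_samples * (self.n_samples - 1) // 2

    def min_m_snps(self) -> int:
        need = 1
        for _ in self.filters_per_block:
            need = need * self.pool_window + self.conv_kernel_snps - 1
        return need

    def block_lengths(self) -> list[tuple[int, int]]:
        """(post-conv, post-pool) sequence length after each block."""
        out = []
        length = self.m_snps
        for _ in self.filters_per_block:
            lc = length - self.conv_kernel_snps + 1
            lp = lc // self.pool_window
            out.append((lc, lp))
            length = lp
        return out

    @property
    def flat_features(self) -> int:
        return self.filters_per_block[-1] * self.block_lengths()[-1][1]


@dataclass
class WeightSet:
    """Trainable parameters plus the target transform used at prediction time.

    The extractor's parameter count is independent of the sample size; only
    the head grows with the number of pairs.  With ``target_log`` the network
    is trained on z-scores of log σ and predictions are back-transformed.
    """

    spec: ModelSpec
    params: dict[str, np.ndarray]
    target_mean: float = 0.0
    target_std: float = 1.0
    target_log: bool = False

    def copy(self) -> "WeightSet":
        return WeightSet(
            spec=self.spec,
            params={k: v.copy() for k, v in self.params.items()},
            target_mean=self.target_mean,
            target_std=self.target_std,
            target_log=self.target_log,
        )

    def denormalize(self, z: np.ndarray | float):
        y = self.target_mean + self.target_std * np.asarray(z, dtype=float)
        return np.exp(y) if self.target_log else y

    def extractor_param_names(self) -> list[str]:
        return [k for k in self.params if not k.startswith("head_")]


def build_model(spec: ModelSpec) -> WeightSet:
    """He-initialized weights for the given architecture, seeded."""
    rng = np.random.default_rng(spec.seed)
    params: dict[str, np.ndarray] = {}
    c_in = spec.channels
    for b, f_out in enumerate(spec.filters_per_block):
        fan_in = c_in * spec.conv_kernel_snps
        params[f"conv{b}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(f_out, fan_in))
        params[f"conv{b}_b"] = np.zeros(f_out)
        c_in = f_out
    fan_in = spec.flat_features + 1
    params["dense_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(spec.pair_dense_units, fan_in))
    params["dense_b"] = np.zeros(spec.pair_dense_units)
    head_in = spec.n_pairs * spec.pair_dense_units
    params["head_W"] = rng.normal(0.0, np.sqrt(1.0 / head_in), size=head_in)
    params["head_b"] = np.zeros(())
    return WeightSet(spec=spec, params=params)


# ---------------------------------------------------------------------------
# forward / backward


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, C*k, L-k+1); channel block t holds x shifted by t."""
    L = x.shape[2]
    return np.concatenate([x[:, :, t : L - k + 1 + t] for t in range(k)], axis=1)


def _forward_pairs(params, spec: ModelSpec, x: np.ndarray, dist: np.ndarray, want_cache: bool):
    """Extractor + head on (B, P, C, m) genotypes and (B, P) scaled distances."""
    nb, npairs = x.shape[0], x.shape[1]
    a = x.reshape(nb * npairs, spec.channels, spec.m_snps).astype(np.float64)
    cache = {"blocks": [], "x_shape": x.shape}
    k = spec.conv_kernel_snps
    w = spec.pool_window
    for b in range(len(spec.filters_per_block)):
        z = _im2col(a, k)
        pre = np.tensordot(z, params[f"conv{b}_W"], axes=([1], [1])).transpose(0, 2, 1)
        pre += params[f"conv{b}_b"][None, :, None]
        act = np.maximum(pre, 0.0)
        q = act.shape[2] // w
        pooled = act[:, :, : q * w].reshape(act.shape[0], act.shape[1], q, w).mean(axis=3)
        if want_cache:
            cache["blocks"].append({"z": z, "pre": pre, "q": q})
        a = pooled
    flat = a.reshape(a.shape[0], -1)
    d_in = np.concatenate([flat, dist.reshape(-1, 1)], axis=1)
    h_pre = d_in @ params["dense_W"].T + params["dense_b"]
    h = np.maximum(h_pre, 0.0)
    feats = h.reshape(nb, npairs * spec.pair_dense_units)
    y = feats @ params["head_W"] + params["head_b"]
    if want_cache:
        cache.update({"d_in": d_in, "h_pre": h_pre, "feats": feats})
        return y, cache
    return y, None


def batch_forward(weights: WeightSet, x: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Normalized-scale predictions for a batch; no caches kept."""
    y, _ = _forward_pairs(weights.params, weights.spec, x, dist, want_cache=False)
    return y


def loss_and_grads(
    weights: WeightSet,
    x: np.ndarray,
    dist: np.ndarray,
    y_true: np.ndarray,
    extract_mask: np.ndarray | None = None,
):
    """Mean-squared-error loss and parameter gradients for one batch.

    ``extract_mask`` is a boolean vector over pairs; pairs outside the mask
    still shape the forward pass and the head's gradients, but contribute no
    gradient to the shared extractor weights (the k_extract strategy).
    """
    spec = weights.spec
    params = weights.params
    y, cache = _forward_pairs(params, spec, x, dist, want_cache=True)
    nb, npairs = x.shape[0], x.shape[1]
    resid = y - y_true
    loss = float(np.mean(resid**2))
    dy = 2.0 * resid / nb

    grads: dict[str, np.ndarray] = {}
    feats = cache["feats"]
    grads["head_W"] = feats.T @ dy
    grads["head_b"] = np.asarray(dy.sum())
    dfeats = np.outer(dy, params["head_W"])
    dh = dfeats.reshape(nb * npairs, spec.pair_dense_units)
    if extract_mask is not None:
        mask = np.asarray(extract_mask, dtype=bool)
        if mask.shape != (npairs,):
            raise ValueError("extract_mask must have one flag per pair")
        dh = dh * np.tile(mask, nb)[:, None]
    dpre = dh * (cache["h_pre"] > 0)
    grads["dense_W"] = dpre.T @ cache["d_in"]
    grads["dense_b"] = dpre.sum(axis=0)
    dd_in = dpre @ params["dense_W"]
    dflat = dd_in[:, :-1]

    k = spec.conv_kernel_snps
    w = spec.pool_window
    lengths = spec.block_lengths()
    f_last = spec.filters_per_block[-1]
    da = dflat.reshape(-1, f_last, lengths[-1][1])
    for b in reversed(range(len(spec.filters_per_block))):
        blk = cache["blocks"][b]
        lc = lengths[b][0]
        q = blk["q"]
        dact = np.zeros((da.shape[0], da.shape[1], lc))
        dact[:, :, : q * w] = np.repeat(da / w, w, axis=2)
        dconv = dact * (blk["pre"] > 0)
        grads[f"conv{b}_W"] = np.tensordot(dconv, blk["z"], axes=([0, 2], [0, 2]))
        grads[f"conv{b}_b"] = dconv.sum(axis=(0, 2))
        if b > 0:
            dz = np.tensordot(dconv, params[f"conv{b}_W"], axes=([1], [0]))  # (B, L, CK)
            dz = dz.transpose(0, 2, 1)
            c_in = spec.filters_per_block[b - 1]
            l_in = lengths[b - 1][1]
            da_next = np.zeros((dz.shape[0], c_in, l_in))
            for t in range(k):
                da_next[:, :, t : l_in - k + 1 + t] += dz[:, t * c_in : (t + 1) * c_in, :]
            da = da_next
    return loss, y, grads


# ---------------------------------------------------------------------------
# spec-surface operations on single datasets


def transform_distances(dist: np.ndarray, distance_scale: float, distance_transform: str = "log"):
    """Scale raw pair distances into the network's distance feature."""
    scaled = np.asarray(dist, dtype=np.float64) / distance_scale
    if distance_transform == "log":
        return np.log(np.maximum(scaled, 1e-3))
    return scaled


def assemble_pair_tensors(
    G: GenotypeMatrix,
    L: LocationTable,
    pairs: PairSet | None = None,
    distance_scale: float = 1.0,
    distance_transform: str = "log",
):
    """Stack each pair's genotype rows and compute its distance feature.

    Returns ``x`` of shape (P, C, m) — individual i's row(s) above j's — and
    the matching (transformed) distance vector.
    """
    n = G.n_samples
    if pairs is None:
        pairs = enumerate_pairs(n)
    cols = G.values.T  # (ncol, m)
    pr = pairs.pairs
    if G.phased:
        idx = np.column_stack([2 * pr[:, 0], 2 * pr[:, 0] + 1, 2 * pr[:, 1], 2 * pr[:, 1] + 1])
    else:
        idx = pr
    x = cols[idx].astype(np.float64)  # (P, C, m)
    dist = transform_distances(pair_distances(L, pairs), distance_scale, distance_transform)
    return x, dist


def extract_pair_features(genotype_block: np.ndarray, pair_distance: float, weights: WeightSet) -> np.ndarray:
    """Feature vector for one pair (same shared weights as every other pair)."""
    spec = weights.spec
    block = np.asarray(genotype_block, dtype=np.float64)
    if block.shape != (spec.channels, spec.m_snps):
        raise ValueError(
            f"genotype block must be ({spec.channels}, {spec.m_snps}), got {block.shape}"
        )
    if pair_distance < 0:
        raise ValueError("pair distance must be non-negative")
    params = weights.params
    a = block[None]
    k, w = spec.conv_kernel_snps, spec.pool_window
    for b in range(len(spec.filters_per_block)):
        z = _im2col(a, k)
        pre = np.tensordot(z, params[f"conv{b}_W"], axes=([1], [1])).transpose(0, 2, 1)
        pre += params[f"conv{b}_b"][None, :, None]
        act = np.maximum(pre, 0.0)
        q = act.shape[2] // w
        a = act[:, :, : q * w].reshape(1, act.shape[1], q, w).mean(axis=3)
    flat = a.reshape(1, -1)
    feat = transform_distances(np.array([pair_distance]), spec.distance_scale, spec.distance_transform)
    d_in = np.concatenate([flat, feat[:, None]], axis=1)
    h = np.maximum(d_in @ params["dense_W"].T + params["dense_b"], 0.0)
    return h[0]


def forward(G: GenotypeMatrix, L: LocationTable, weights: WeightSet, pairs: PairSet | None = None) -> float:
    """Scalar dispersal estimate for one dataset, on the de-normalized scale."""
    spec = weights.spec
    if pairs is None:
        pairs = enumerate_pairs(G.n_samples)
    if len(pairs) != spec.n_pairs:
        raise ValueError(f"model expects {spec.n_pairs} pairs, got {len(pairs)}")
    x, dist = assemble_pair_tensors(G, L, pairs, spec.distance_scale, spec.distance_transform)
    z = batch_forward(weights, x[None], dist[None])[0]
    return float(weights.denormalize(z))


def forward_gated(
    G: GenotypeMatrix,
    L: LocationTable,
    weights: WeightSet,
    pairs: PairSet | None = None,
    extract_pairs: PairSet | None = None,
) -> float:
    """Prediction under gradient gating — identical to :func:`forward`.

    Gating reroutes gradients only; the forward pass always uses the full
    pair set.  ``extract_pairs`` must be a subset of ``pairs``.
    """
    if pairs is None:
        pairs = enumerate_pairs(G.n_samples)
    if extract_pairs is not None:
        all_set = {tuple(p) for p in pairs.pairs}
        sub = {tuple(p) for p in extract_pairs.pairs}
        if not sub <= all_set:
            raise ValueError("extract_pairs must be a subset of pairs")
    return forward(G, L, weights, pairs)


# ---------------------------------------------------------------------------
# serialization


def save_weights(weights: WeightSet, path: str | Path) -> None:
    """Single-archive serialization with the spec embedded; reloads bit-exactly."""
    meta = {
        "spec": asdict(weights.spec),
        "target_mean": weights.target_mean,
        "target_std": weights.target_std,
        "target_log": weights.target_log,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **weights.params,
    )


def load_weights(path: str | Path) -> WeightSet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {k: archive[k].copy() for k in archive.files if k != "__meta__"}
    sd = meta["spec"]
    sd["filters_per_block"] = tuple(sd["filters_per_block"])
    spec = ModelSpec(**sd)
    return WeightSet(
        spec=spec,
        params=params,
        target_mean=meta["target_mean"],
        target_std=meta["target_std"],
        target_log=meta["target_log"],
    )
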
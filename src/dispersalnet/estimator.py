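"""Training: a scikit-learn style regressor around the pairwise network.

``PairwiseDispersalRegressor.fit`` consumes a collection of simulated
datasets (genotype matrix + locations) with their true dispersal rates,
optimizes the network with mean-squared-error loss and the Adam optimizer at
learning rate 1e-4 on z-scored log σ targets, and supports the k_extract
gradient-gating strategy: each batch, a fresh random subset of pairs carries
gradients into the shared extractor while every pair feeds the forward pass
and the head.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import GenotypeMatrix, LocationTable, PairSet, SimulationResult
from .network import (
    ModelSpec,
    WeightSet,
    batch_forward,
    build_model,
    loss_and_grads,
)
from .preprocess import PackedTrainingSet, enumerate_pairs

__all__ = [
    "PairwiseDispersalRegressor",
    "loss_mse",
    "select_kextract_pairs",
]


def loss_mse(pred, true) -> float:
    """Mean squared error on the (normalized) target scale."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("pred and true must be non-empty and equally long")
    return float(np.mean((pred - true) ** 2))


def select_kextract_pairs(pairs: PairSet, k: int, rng: np.random.Generator) -> PairSet:
    """Uniform random subset of k pairs without replacement, order preserved."""
    n = len(pairs)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return PairSet(pairs=pairs.pairs[idx])


def _coerce_datasets(X, y):
    """Accept a PackedTrainingSet, SimulationResults, or (G, L) tuples."""
    if isinstance(X, PackedTrainingSet):
        geno = X.genotypes
        locs = X.locations
        phased = X.phased
        if y is None:
            y = X.sigmas
    else:
        items = list(X)
        if items and isinstance(items[0], SimulationResult):
            if y is None:
                y = np.array([r.sigma_true for r in items])
            items = [(r.genotypes, r.locations) for r in items]
        gs = [g.values for g, _ in items]
        shapes = {g.shape for g in gs}
        if len(shapes) != 1:
            raise ValueError(f"all datasets must share dimensions, got {shapes}")
        phased = items[0][0].phased
        geno = np.stack(gs)
        locs = np.stack([loc.coords for _, loc in items])
    return np.asarray(geno), np.asarray(locs), bool(phased), None if y is None else np.asarray(y, float)


def _pair_column_index(pairs: np.ndarray, phased: bool) -> np.ndarray:
    if phased:
        i, j = pairs[:, 0], pairs[:, 1]
        return np.column_stack([2 * i, 2 * i + 1, 2 * j, 2 * j + 1])
    return pairs


class PairwiseDispersalRegressor(BaseEstimator, RegressorMixin):
    """Estimate per-generation dispersal distance σ from genotypes + locations.

    Parameters
    ----------
    filters_per_block
        Filter counts of the conv/pool blocks (kernel 2 SNPs, average pool 10).
    pair_dense_units
        Width of the per-pair fully connected layer.
    k_extract
        Pairs carrying extractor gradients per batch; ``None`` uses all pairs.
    learning_rate, batch_size, epochs
        Adam settings; loss is MSE on z-scores of log σ.
    lr_schedule
        ``"constant"`` keeps the learning rate fixed; ``"cosine"`` decays it
        along a half-cosine to 10% of the initial value over ``epochs``,
        which settles the weights into a flatter solution and reduces
        run-to-run variance of the final model.
    validation_fraction, patience
        Held-out fraction for early stopping on validation loss; the best
        checkpoint is retained.  ``patience=None`` disables early stopping.
        When ``fit`` receives ``groups`` (e.g. the simulation each dataset
        was drawn from), the split is made at group level so that no
        simulation contributes to both training and validation.
    augment_permute
        Randomly relabel each dataset's individuals every training batch.
        A dataset's dispersal rate is invariant to sample order, but the
        stacked pair features are not; presenting every ordering teaches the
        head that pair slots are exchangeable and curbs memorization.
    predict_permutations
        Number of random relabelings averaged at prediction time (test-time
        counterpart of ``augment_permute``); 0 predicts once on the input
        ordering.  Averaging over orderings removes the arbitrary-labelling
        component of prediction variance.  Deterministic given random_state.
    n_ensemble
        Number of independently initialized networks trained on the same
        data; predictions average the members on the normalized (log)
        scale.  A small ensemble reduces the initialization/batch-order
        component of prediction variance.
    calibrate
        After training, fit a linear map from the ensemble's validation
        predictions to the true normalized targets and apply it at predict
        time.  MSE training shrinks estimates toward the prior mean; this
        regression adjustment, fitted on held-out simulations only, undoes
        the shrinkage.  Ignored when the validation split is empty.
    distance_scale
        Divisor for pair distances; inferred from the training point clouds
        when ``None``.
    random_state
        Seeds initialization, the train/validation split, batch order and
        pair subsampling.

    Attributes
    ----------
    weights_ : WeightSet
        Best-validation-loss parameters.
    history_ : pandas.DataFrame
        Per-epoch train/validation loss.
    target_mean_, target_std_ : float
        Normalization statistics of log σ over the training split.
    """

    def __init__(
        self,
        filters_per_block=(32, 64),
        pair_dense_units=128,
        k_extract=None,
        learning_rate=1e-4,
        lr_schedule="constant",
        batch_size=16,
        epochs=50,
        validation_fraction=0.1,
        patience=20,
        augment_permute=True,
        predict_permutations=8,
        n_ensemble=1,
        calibrate=True,
        distance_scale=None,
        distance_transform="log",
        random_state=0,
    ):
        self.filters_per_block = filters_per_block
        self.pair_dense_units = pair_dense_units
        self.k_extract = k_extract
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.augment_permute = augment_permute
        self.predict_permutations = predict_permutations
        self.n_ensemble = n_ensemble
        self.calibrate = calibrate
        self.distance_scale = distance_scale
        self.distance_transform = distance_transform
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _tensors(self, geno, locs, pair_cols, pairs):
        """Pair tensors for a block of datasets: (D, P, C, m) and (D, P)."""
        from .network import transform_distances

        cols = geno.transpose(0, 2, 1)  # (D, ncol, m)
        x = cols[:, pair_cols].astype(np.float64)
        d = locs[:, pairs[:, 0]] - locs[:, pairs[:, 1]]
        dist = transform_distances(
            np.hypot(d[..., 0], d[..., 1]), self.distance_scale_, self.distance_transform
        )
        return x, dist

    def fit(self, X, y=None, groups=None):
        geno, locs, phased, y = _coerce_datasets(X, y)
        if y is None or len(y) != geno.shape[0]:
            raise ValueError("y (true σ per dataset) is required and must match X")
        if np.any(y <= 0):
            raise ValueError("true σ must be positive")
        n_data, m, ncol = geno.shape
        n = ncol // 2 if phased else ncol

        n_members = max(1, int(self.n_ensemble))
        ss = np.random.SeedSequence(int(self.random_state))
        member_seeds = ss.spawn(n_members + 1)
        rng = np.random.default_rng(member_seeds[0])  # split + shared choices
        if self.distance_scale is None:
            self.distance_scale_ = float(max(np.ptp(locs[..., 0]), np.ptp(locs[..., 1]), 1e-12))
        else:
            self.distance_scale_ = float(self.distance_scale)

        pairset = enumerate_pairs(n)
        pairs = pairset.pairs
        pair_cols = _pair_column_index(pairs, phased)
        n_pairs = len(pairset)
        k = self.k_extract
        if k is not None and not 1 <= k <= n_pairs:
            raise ValueError(f"k_extract must be in [1, {n_pairs}]")

        # train/validation split, at group (simulation) level when known
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape != (n_data,):
                raise ValueError("groups must have one label per dataset")
            uniq = rng.permutation(np.unique(groups))
            n_vg = max(1, int(round(self.validation_fraction * uniq.size))) if uniq.size > 2 else 0
            val_mask = np.isin(groups, uniq[:n_vg])
            val_idx = np.flatnonzero(val_mask)
            train_idx = rng.permutation(np.flatnonzero(~val_mask))
        else:
            perm = rng.permutation(n_data)
            n_val = max(1, int(round(self.validation_fraction * n_data))) if n_data > 2 else 0
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ValueError("not enough datasets to train")

        log_y = np.log(y)
        self.target_mean_ = float(log_y[train_idx].mean())
        self.target_std_ = float(log_y[train_idx].std()) or 1.0
        z = (log_y - self.target_mean_) / self.target_std_

        def val_loss(ws):
            losses = []
            for lo in range(0, val_idx.size, self.batch_size):
                idx = val_idx[lo : lo + self.batch_size]
                xb, db = self._tensors(geno[idx], locs[idx], pair_cols, pairs)
                pred = batch_forward(ws, xb, db)
                losses.append(np.sum((pred - z[idx]) ** 2))
            return float(np.sum(losses) / val_idx.size) if val_idx.size else np.nan

        def fit_member(member_rng):
            spec = ModelSpec(
                m_snps=m,
                n_samples=n,
                phased=phased,
                filters_per_block=tuple(self.filters_per_block),
                pair_dense_units=self.pair_dense_units,
                distance_scale=self.distance_scale_,
                distance_transform=self.distance_transform,
                k_extract=k,
                seed=int(member_rng.integers(2**31 - 1)),
            )
            weights = build_model(spec)
            weights.target_mean = self.target_mean_
            weights.target_std = self.target_std_
            weights.target_log = True
            mom = {kk: np.zeros_like(v) for kk, v in weights.params.items()}
            vel = {kk: np.zeros_like(v) for kk, v in weights.params.items()}
            beta1, beta2, eps = 0.9, 0.999, 1e-8
            t = 0
            history = []
            best = weights.copy()
            best_val = np.inf
            stale = 0
            for epoch in range(self.epochs):
                if self.lr_schedule == "cosine":
                    frac = epoch / max(1, self.epochs - 1)
                    lr_epoch = self.learning_rate * (0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
                elif self.lr_schedule == "constant":
                    lr_epoch = self.learning_rate
                else:
                    raise ValueError("lr_schedule must be 'constant' or 'cosine'")
                order = member_rng.permutation(train_idx)
                epoch_losses = []
                for lo in range(0, order.size, self.batch_size):
                    idx = order[lo : lo + self.batch_size]
                    gb, lb = geno[idx], locs[idx]
                    if self.augment_permute:
                        gb, lb = gb.copy(), lb.copy()
                        for d in range(gb.shape[0]):
                            pm = member_rng.permutation(n)
                            if phased:
                                hap_pm = np.column_stack([2 * pm, 2 * pm + 1]).reshape(-1)
                                gb[d] = gb[d][:, hap_pm]
                            else:
                                gb[d] = gb[d][:, pm]
                            lb[d] = lb[d][pm]
                    xb, db = self._tensors(gb, lb, pair_cols, pairs)
                    if k is not None and k < n_pairs:
                        sel = member_rng.choice(n_pairs, size=k, replace=False)
                        mask = np.zeros(n_pairs, dtype=bool)
                        mask[sel] = True
                    else:
                        mask = None
                    loss, _, grads = loss_and_grads(weights, xb, db, z[idx], mask)
                    if not np.isfinite(loss):
                        raise FloatingPointError(
                            f"training diverged (non-finite loss) at epoch {epoch}"
                        )
                    t += 1
                    lr_t = lr_epoch * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                    for kk, g in grads.items():
                        mom[kk] = beta1 * mom[kk] + (1 - beta1) * g
                        vel[kk] = beta2 * vel[kk] + (1 - beta2) * g * g
                        weights.params[kk] -= lr_t * mom[kk] / (np.sqrt(vel[kk]) + eps)
                    epoch_losses.append(loss * idx.size)
                train_loss = float(np.sum(epoch_losses) / order.size)
                vloss = val_loss(weights)
                history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": vloss})
                monitored = vloss if np.isfinite(vloss) else train_loss
                if monitored < best_val - 1e-12:
                    best_val = monitored
                    best = weights.copy()
                    stale = 0
                else:
                    stale += 1
                    if self.patience is not None and stale >= self.patience:
                        break
            return best, pd.DataFrame(history)

        # A member occasionally fails to train at all (its validation loss
        # never beats the trivial constant predictor, loss ~ 1 on z-scored
        # targets): reject it and retrain with a fresh init, a bounded
        # number of times, keeping the best attempt otherwise.
        self.members_ = []
        self.histories_ = []
        for mseed in member_seeds[1:]:
            attempts = mseed.spawn(3)
            best, history = None, None
            for aseed in attempts:
                cand, hist = fit_member(np.random.default_rng(aseed))
                if best is None or hist["val_loss"].min() < history["val_loss"].min():
                    best, history = cand, hist
                if np.nanmin(hist["val_loss"].to_numpy()) < 0.8 or val_idx.size == 0:
                    break
            self.members_.append(best)
            self.histories_.append(history)
        self.weights_ = self.members_[0]
        self.spec_ = self.weights_.spec
        self.history_ = self.histories_[0]
        self.n_pairs_ = n_pairs

        # regression adjustment on the validation split: undo shrinkage of
        # the MSE-trained predictions toward the prior mean
        self.calibration_ = (0.0, 1.0)
        if self.calibrate and val_idx.size >= 3:
            z_hat = self._predict_z(geno[val_idx], locs[val_idx], phased, n)
            if np.std(z_hat) > 1e-9:
                b, a = np.polyfit(z_hat, z[val_idx], 1)
                self.calibration_ = (float(a), float(b))
        return self

    def _predict_z(self, geno, locs, phased, n):
        """Normalized-scale ensemble prediction with permutation averaging."""
        pairs = enumerate_pairs(n).pairs
        pair_cols = _pair_column_index(pairs, phased)
        members = getattr(self, "members_", [self.weights_])

        def _predict_once(g, l):
            acc = None
            for ws in members:
                preds = []
                for lo in range(0, g.shape[0], self.batch_size):
                    xb, db = self._tensors(g[lo : lo + self.batch_size], l[lo : lo + self.batch_size], pair_cols, pairs)
                    preds.append(batch_forward(ws, xb, db))
                zm = np.concatenate(preds)
                acc = zm if acc is None else acc + zm
            return acc / len(members)

        n_perm = int(self.predict_permutations or 0)
        if n_perm <= 0:
            return _predict_once(geno, locs)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.random_state), 1]))
        acc = np.zeros(geno.shape[0])
        for _ in range(n_perm):
            gp, lp = geno.copy(), locs.copy()
            for d in range(gp.shape[0]):
                pm = rng.permutation(n)
                if phased:
                    hap_pm = np.column_stack([2 * pm, 2 * pm + 1]).reshape(-1)
                    gp[d] = gp[d][:, hap_pm]
                else:
                    gp[d] = gp[d][:, pm]
                lp[d] = lp[d][pm]
            acc += _predict_once(gp, lp)
        return acc / n_perm

    def predict(self, X):
        """De-normalized σ̂ (map units of the training simulations) per dataset."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("estimator is not fitted")
        geno, locs, phased, _ = _coerce_datasets(X, None)
        spec = self.weights_.spec
        if phased != spec.phased or geno.shape[1] != spec.m_snps:
            raise ValueError(
                f"input shape {geno.shape[1:]} (phased={phased}) does not match the "
                f"trained spec (m={spec.m_snps}, phased={spec.phased})"
            )
        n = geno.shape[2] // 2 if phased else geno.shape[2]
        if n != spec.n_samples:
            raise ValueError(f"model was trained for n={spec.n_samples}, got n={n}")
        z = self._predict_z(geno, locs, phased, n)
        a, b = getattr(self, "calibration_", (0.0, 1.0))
        return self.weights_.denormalize(a + b * z)

    def predict_dataset(self, G: GenotypeMatrix, L: LocationTable) -> float:
        """σ̂ for a single dataset."""
        return float(self.predict([(G, L)])[0])
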
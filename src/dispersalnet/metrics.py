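"""Validation harness: error metrics and method-comparison reports.

Three metrics summarize recovery of the true dispersal rate on held-out
simulations: mean relative absolute error (MRAE), root mean squared error
(RMSE) on the natural σ scale, and the squared Pearson correlation (r²)
between true and predicted values.  Undefined baseline estimates (NaN) are
excluded from a method's metrics and their count reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "mrae",
    "rmse",
    "r_squared",
    "mrae_reduction",
    "prior_mean_mrae",
    "run_benchmark",
    "relative_error_quantiles",
]


def _check(pred, true, allow_any_true=False):
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("pred and true must be non-empty, equal-length vectors")
    if not allow_any_true and np.any(true <= 0):
        raise ValueError("true values must be positive for relative error")
    return pred, true


def mrae(pred, true) -> float:
    """Mean relative absolute error: mean of |pred - true| / true."""
    pred, true = _check(pred, true)
    return float(np.mean(np.abs(pred - true) / true))


def rmse(pred, true) -> float:
    """Root mean squared error on the natural σ scale."""
    pred, true = _check(pred, true, allow_any_true=True)
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def r_squared(pred, true) -> float:
    """Squared Pearson correlation between true and predicted values."""
    pred, true = _check(pred, true, allow_any_true=True)
    if pred.size < 2 or np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("r² needs >= 2 points with nonzero variance in both vectors")
    return float(stats.pearsonr(pred, true)[0] ** 2)


def mrae_reduction(mrae_ref: float, mrae_new: float) -> float:
    """Relative MRAE reduction of a new method: (ref - new) / ref."""
    if mrae_ref <= 0:
        raise ValueError("reference MRAE must be positive")
    return (mrae_ref - mrae_new) / mrae_ref


def prior_mean_mrae(a: float, b: float) -> float:
    """MRAE of the constant prior-mean predictor under σ ~ U(a, b).

    The no-information reference line: predicting c = (a+b)/2 always gives
    E|c - σ|/σ, evaluated by 1-D numerical integration.
    """
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    c = 0.5 * (a + b)
    val, _ = integrate.quad(lambda s: abs(c - s) / s / (b - a), a, b, points=[c])
    return float(val)


def relative_error_quantiles(
    predictions: dict, true_sigma, qs=(0.05, 0.25, 0.5, 0.75, 0.95)
) -> pd.DataFrame:
    """Box-plot-style summary: quantiles of σ̂/σ per method, as a table.

    ``predictions`` maps method name to a σ̂ vector; NaN (undefined)
    predictions are dropped per method before taking quantiles.
    """
    true_sigma = np.asarray(true_sigma, dtype=float)
    rows = {}
    for name, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        ok = np.isfinite(pred)
        ratio = pred[ok] / true_sigma[ok]
        rows[name] = {f"q{int(100 * q):02d}": float(np.quantile(ratio, q)) for q in qs}
    return pd.DataFrame(rows).T


def run_benchmark(methods: dict, test_sets, true_sigma=None) -> pd.DataFrame:
    """Apply each method to the held-out datasets and tabulate the metrics.

    ``methods`` maps a name to either a fitted estimator with ``predict`` or
    a callable returning one σ̂ per dataset.  NaN predictions (undefined
    fits) are excluded from that method's metrics; their count is reported
    in ``n_undefined_excluded``.
    """
    test_sets = list(test_sets)
    if not test_sets:
        raise ValueError("empty test set")
    if true_sigma is None:
        true_sigma = np.array([r.sigma_true for r in test_sets])
    true_sigma = np.asarray(true_sigma, dtype=float)
    rows = []
    for name, method in methods.items():
        pred = method.predict(test_sets) if hasattr(method, "predict") else method(test_sets)
        pred = np.asarray(pred, dtype=float)
        ok = np.isfinite(pred)
        n_bad = int((~ok).sum())
        if ok.sum() < 2:
            row = dict(method=name, mrae=np.nan, rmse=np.nan, r2=np.nan)
        else:
            p, t = pred[ok], true_sigma[ok]
            try:
                r2 = r_squared(p, t)
            except ValueError:  # zero variance (e.g. a constant predictor)
                r2 = np.nan
            row = dict(method=name, mrae=mrae(p, t), rmse=rmse(p, t), r2=r2)
        row["n_test"] = int(ok.sum())
        row["n_undefined_excluded"] = n_bad
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
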
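"""Empirical-Bayes location/scale batch adjustment (ComBat-style).

Each gene is standardized by its pooled mean and variance; per
gene x batch location (gamma) and scale (delta^2) effects are estimated
and — in the parametric mode — shrunk toward a normal prior on gamma
and an inverse-gamma prior on delta^2, both fitted across genes by
moments and solved by the standard iterative update.  Adjusted values
restore the pooled scale and mean:

    x* = (z - gamma*) / delta* . pooled_sd + pooled_mean.

Covariates are not modeled.  Negative log2 values produced by the
adjustment are conventionally clamped to zero afterwards
(:func:`clamp_negative`); clamping is a separate explicit step so the
unclamped matrix remains inspectable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DataError, as_frame

__all__ = ["combat_adjust", "clamp_negative"]


def _moments_priors(delta2_hat: np.ndarray) -> tuple[float, float]:
    """Inverse-gamma prior (a, b) for the scale effects, by moments."""
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1) if delta2_hat.size > 1 else 0.0
    if s2 <= 0:
        return np.inf, np.inf  # degenerate prior: no shrinkage applied
    a = (2 * s2 + m * m) / s2
    b = (m * s2 + m ** 3) / s2
    return a, b


def combat_adjust(matrix, design, parametric_shrinkage: bool = True, *,
                  conv_tol: float = 1e-4, max_iter: int = 100) -> pd.DataFrame:
    """Remove known-batch location/scale effects from a log2 matrix.

    Parameters
    ----------
    matrix:
        log2 genes x samples matrix.
    design:
        Mapping or Series sample id -> batch label covering every column.
    parametric_shrinkage:
        Shrink batch effects toward parametric priors (normal /
        inverse-gamma) fitted across genes; with ``False`` the raw
        per-gene estimates are used, which removes a pure location
        shift exactly.

    Genes with zero pooled variance cannot be standardized and are
    passed through unadjusted with a warning.
    """
    df = as_frame(matrix)
    design = pd.Series(design)
    missing = df.columns.difference(design.index)
    if len(missing):
        raise DataError(f"samples missing from batch design: {list(missing)}")
    labels = design.loc[df.columns]
    batches = labels.unique()
    if len(batches) < 2:
        raise DataError("combat_adjust requires at least 2 batches")
    batch_cols = {b: np.flatnonzero((labels == b).to_numpy()) for b in batches}
    for b, cols in batch_cols.items():
        if cols.size < 2:
            raise DataError(f"batch {b!r} has fewer than 2 samples; variance not estimable")

    x = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("matrix contains non-finite values")
    n_total = x.shape[1]
    sizes = np.array([batch_cols[b].size for b in batches], dtype=float)

    batch_means = np.column_stack([x[:, batch_cols[b]].mean(axis=1) for b in batches])
    grand_mean = batch_means @ (sizes / n_total)
    fitted = np.zeros_like(x)
    for j, b in enumerate(batches):
        fitted[:, batch_cols[b]] = batch_means[:, [j]]
    var_pooled = ((x - fitted) ** 2).mean(axis=1)

    ok = var_pooled > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-variance gene(s) passed through unadjusted")
    sd = np.sqrt(var_pooled[ok])
    z = (x[ok] - grand_mean[ok, None]) / sd[:, None]

    adjusted_z = np.empty_like(z)
    for j, b in enumerate(batches):
        cols = batch_cols[b]
        zb = z[:, cols]
        n_b = cols.size
        gamma_hat = zb.mean(axis=1)
        delta2_hat = zb.var(axis=1, ddof=1)
        delta2_hat = np.maximum(delta2_hat, 1e-12)
        if parametric_shrinkage:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
            a_prior, b_prior = _moments_priors(delta2_hat)
            gamma_star = gamma_hat.copy()
            delta2_star = delta2_hat.copy()
            if tau2 > 0 and np.isfinite(a_prior):
                for _ in range(max_iter):
                    g_new = (n_b * tau2 * gamma_hat + delta2_star * gamma_bar) / (n_b * tau2 + delta2_star)
                    sum2 = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                    d_new = (b_prior + 0.5 * sum2) / (n_b / 2.0 + a_prior - 1.0)
                    change = max(
                        np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-8)),
                        np.max(np.abs(d_new - delta2_star) / np.maximum(np.abs(delta2_star), 1e-8)),
                    )
                    gamma_star, delta2_star = g_new, d_new
                    if change < conv_tol:
                        break
        else:
            gamma_star, delta2_star = gamma_hat, delta2_hat
        adjusted_z[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta2_star)[:, None]

    out = x.copy()
    out[ok] = adjusted_z * sd[:, None] + grand_mean[ok, None]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def clamp_negative(matrix) -> pd.DataFrame:
    """Replace negative entries (artifacts of batch adjustment) by 0."""
    df = as_frame(matrix)
    return df.clip(lower=0.0)
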
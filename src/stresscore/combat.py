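"""Parametric empirical-Bayes location/scale batch correction.

This is the standard ComBat algorithm with batch as the only design
variable and no covariates: genes are standardized against the
batch-design fit, per-(batch, gene) location (gamma) and scale (delta^2)
estimates are shrunk toward batch-level parametric priors — normal for
gamma, inverse-gamma for delta^2, hyperparameters by method of moments —
via the usual iterative EB solution, and the data are adjusted and
de-standardized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative EB solution for one batch (genes vectorized)."""
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = np.nansum((sdat - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(min=1e-30)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(min=1e-30)),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat(data: pd.DataFrame, batch: pd.Series, conv: float = 1e-4) -> pd.DataFrame:
    """Adjust ``data`` (genes x samples) for the batch labels in ``batch``.

    Genes with zero pooled variance cannot be standardized and are passed
    through unchanged.  Requires >= 2 batches with >= 2 samples each.
    """
    batch = batch.loc[data.columns]
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        raise ValueError("combat requires at least two batches")
    counts = batch.value_counts()
    small = sorted(counts[counts < 2].index)
    if small:
        raise ValueError(
            f"batches with fewer than 2 samples (variance inestimable): {small}"
        )

    Y = data.to_numpy(dtype=float)
    n_array = Y.shape[1]
    masks = {b: (batch == b).to_numpy() for b in levels}
    n_batches = np.array([masks[b].sum() for b in levels], dtype=float)

    # batch-design least squares fit and pooled variance
    batch_means = np.column_stack([Y[:, masks[b]].mean(axis=1) for b in levels])
    grand_mean = batch_means @ (n_batches / n_array)
    fitted = np.zeros_like(Y)
    for j, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[:, [j]]
    var_pooled = ((Y - fitted) ** 2).mean(axis=1)

    ok = var_pooled > 0
    sd = np.sqrt(var_pooled[ok])
    s_data = (Y[ok] - grand_mean[ok, None]) / sd[:, None]

    adjusted = np.empty_like(s_data)
    for j, b in enumerate(levels):
        m = masks[b]
        sub = s_data[:, m]
        g_hat = sub.mean(axis=1)
        d_hat = sub.var(axis=1, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        # inverse-gamma hyperparameters by method of moments
        dm = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        if s2 > 0:
            a = (2 * s2 + dm**2) / s2
            b_prior = (dm * s2 + dm**3) / s2
            g_star, d_star = _it_sol(sub, g_hat, d_hat, g_bar, t2, a, b_prior, conv)
        else:  # degenerate: all genes share one scale estimate, nothing to shrink
            g_star, d_star = g_hat, d_hat
        adjusted[:, m] = (sub - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = Y.copy()
    out[ok] = adjusted * sd[:, None] + grand_mean[ok, None]
    return pd.DataFrame(out, index=data.index, columns=data.columns)
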
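"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def holm_sidak(pvalues, alpha=0.05):
    """Holm-Sidak step-down adjusted p-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    with np.errstate(divide="ignore"):  # p == 1 is valid input
        reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return p_adj, reject


def bootstrap_ci(values, statistic=np.median, n_boot=1000, ci=95.0, rng=None):
    """Percentile bootstrap confidence interval for a statistic."""
    rng = np.random.default_rng(rng)
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap CI undefined for fewer than 2 observations")
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    stats = np.array([statistic(values[row]) for row in idx])
    lo, hi = np.percentile(stats, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(statistic(values)), (float(lo), float(hi))


def smote_oversample(X, y, rng=None, k_neighbors=5):
    """Minority oversampling by interpolation between nearest neighbours.

    Synthesises minority-class points on segments joining each minority
    sample to one of its k nearest minority neighbours until classes are
    balanced.  Binary labels only.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects binary labels")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) == 1:
        # Degenerate: replicate the single sample.
        Xs = np.repeat(Xm, n_needed, axis=0)
    else:
        k = min(k_neighbors, len(Xm) - 1)
        d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k]
        base = rng.integers(0, len(Xm), size=n_needed)
        pick = nn[base, rng.integers(0, k, size=n_needed)]
        gap = rng.random(n_needed)[:, None]
        Xs = Xm[base] + gap * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, Xs])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
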
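"""Statistical machinery: concordance correlation, rank tests, bootstraps.

The concordance correlation coefficient (CCC) measures agreement with
the identity line: ``rho_c = 2 cov(x, y) / (var(x) + var(y) +
(mean(x) - mean(y))^2)``, with population (1/n) moments, the convention
of the imaging-agreement literature.  When each subject contributes a
distribution rather than a point (posterior predictive samples), the
CCC is resampled: one draw per subject per axis per iteration, the CCC
of each draw, and the mean and SD over draws.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu, pearsonr


def ccc(x, y, sample_moments: bool = False) -> float:
    """Concordance correlation coefficient (population moments by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    ddof = 1 if sample_moments else 0
    vx, vy = np.var(x, ddof=ddof), np.var(y, ddof=ddof)
    cov = np.cov(x, y, ddof=ddof)[0, 1]
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return float("nan")
    return float(2.0 * cov / denom)


def resampled_ccc(
    x_dists: list[np.ndarray],
    y_dists: list[np.ndarray],
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the CCC over random per-subject draws.

    Each subject contributes one distribution per axis; every iteration
    draws one value per subject per axis and computes the CCC.
    """
    if len(x_dists) != len(y_dists) or len(x_dists) < 2:
        raise ValueError("need matched distributions for >= 2 subjects")
    if any(np.asarray(d).size == 0 for d in list(x_dists) + list(y_dists)):
        raise ValueError("empty per-subject distribution")
    rng = np.random.default_rng(seed)
    n = len(x_dists)
    xs = np.column_stack([rng.choice(np.asarray(d, dtype=float), size=n_draws) for d in x_dists])
    ys = np.column_stack([rng.choice(np.asarray(d, dtype=float), size=n_draws) for d in y_dists])
    # vectorized population-moment CCC per draw
    mx, my = xs.mean(axis=1), ys.mean(axis=1)
    vx = ((xs - mx[:, None]) ** 2).mean(axis=1)
    vy = ((ys - my[:, None]) ** 2).mean(axis=1)
    cov = ((xs - mx[:, None]) * (ys - my[:, None])).mean(axis=1)
    vals = 2.0 * cov / (vx + vy + (mx - my) ** 2)
    return float(vals.mean()), float(vals.std())


def mann_whitney_u(a, b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U-test p-value.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(mannwhitneyu(a, b, alternative=alternative, method="auto").pvalue)


def bootstrap_pearson(
    x_dists: list[np.ndarray],
    y_dists: list[np.ndarray],
    n_draws: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Bootstrap Pearson correlation over per-subject distributions.

    Returns ``(mean r, percentile CI, median per-draw p-value)``.
    """
    if len(x_dists) != len(y_dists):
        raise ValueError("subjects must be paired")
    if len(x_dists) < 3:
        raise ValueError("need at least three subjects")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_draws)
    ps = np.empty(n_draws)
    xcols = [np.asarray(d, dtype=float) for d in x_dists]
    ycols = [np.asarray(d, dtype=float) for d in y_dists]
    xs = np.column_stack([rng.choice(d, size=n_draws) for d in xcols])
    ys = np.column_stack([rng.choice(d, size=n_draws) for d in ycols])
    for i in range(n_draws):
        if np.ptp(xs[i]) == 0 or np.ptp(ys[i]) == 0:
            rs[i], ps[i] = np.nan, 1.0
            continue
        r, p = pearsonr(xs[i], ys[i])
        rs[i], ps[i] = r, p
    lo, hi = np.nanpercentile(rs, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    return float(np.nanmean(rs)), (float(lo), float(hi)), float(np.nanmedian(ps))


def percent_change(old: float, new: float) -> float:
    """Signed percent change of ``new`` relative to ``old``."""
    if old == 0:
        return 0.0 if new == 0 else float("inf")
    return 100.0 * (new - old) / old
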
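"""Shared statistical primitives.

Small, brute-force-verifiable building blocks used throughout the
co-localization pipeline: Spearman and partial Spearman correlation,
the Fisher variance-stabilizing transform, Benjamini-Hochberg FDR,
exact permutation p-values (the "+1" convention), pooled-variance
two-sample t from summary statistics, Pearson chi-square on a 2x2
table, and the Mann-Whitney formulation of the ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FISHER_CLIP",
    "PermutationNull",
    "spearman_rho",
    "partial_spearman",
    "fisher_z",
    "fisher_z_inv",
    "bh_fdr",
    "exact_perm_pvalue",
    "pooled_t_from_summary",
    "chi_square_2x2",
    "auc_mann_whitney",
]

#: correlations are clipped to +/- (1 - FISHER_CLIP) before atanh so that
#: degenerate (perfectly monotone) synthetic inputs stay finite.
FISHER_CLIP = 1e-6


def _pairwise_complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(a, dtype=float).ravel() for a in arrays)
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("inputs must have equal length")
    keep = np.ones(n, dtype=bool)
    for a in arrays:
        keep &= np.isfinite(a)
    return tuple(a[keep] for a in arrays)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Pairs with a missing (non-finite) value in either vector are dropped.
    Returns NaN when either vector is constant after deletion or fewer
    than 3 complete pairs remain.
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def partial_spearman(x, y, covariate) -> float:
    """Spearman correlation of ``x`` and ``y`` controlling for ``covariate``.

    All three vectors are converted to average ranks; the partial
    coefficient is the Pearson correlation of the OLS residuals of the
    x-ranks and y-ranks on the covariate ranks (plus intercept). Returns
    NaN when a residual vector is degenerate (zero variance).
    """
    x, y, z = _pairwise_complete(x, y, covariate)
    if x.size < 4:
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = sps.rankdata(z)
    design = np.column_stack([np.ones_like(rz), rz])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    sx = float(np.sqrt(ex @ ex))
    sy = float(np.sqrt(ey @ ey))
    # residuals indistinguishable from zero => the partial is undefined
    tol = 1e-8 * x.size
    if sx <= tol or sy <= tol:
        return float("nan")
    return float((ex @ ey) / (sx * sy))


def fisher_z(r) -> np.ndarray | float:
    """Fisher variance-stabilizing transform atanh(r), clipped near +/-1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValueError("correlation coefficients must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z) -> np.ndarray | float:
    """Inverse Fisher transform tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (independence variant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def exact_perm_pvalue(observed: float, null_draws, alternative: str = "two-sided") -> float:
    """Permutation p-value with the add-one convention.

    p = (1 + #{null draws at least as extreme as observed}) / (1 + n_perm),
    so p is never 0 and never below 1/(n_perm + 1).
    """
    null = np.asarray(null_draws, dtype=float).ravel()
    if null.size < 1:
        raise ValueError("need at least one permutation draw")
    if alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    elif alternative == "greater":
        hits = np.sum(null >= observed)
    elif alternative == "less":
        hits = np.sum(null <= observed)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float((1 + hits) / (1 + null.size))


@dataclass
class PermutationNull:
    """Observed statistic plus its permutation null distribution."""

    observed: float
    null_draws: np.ndarray
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return int(np.asarray(self.null_draws).size)

    def pvalue(self, alternative: str = "two-sided") -> float:
        return exact_perm_pvalue(self.observed, self.null_draws, alternative)


def pooled_t_from_summary(m1, s1, n1, m2, s2, n2, welch: bool = False):
    """Two-sample t statistic from group means, SDs and sizes.

    By default uses the pooled-variance formulation with
    df = n1 + n2 - 2; ``welch=True`` switches to the Welch-Satterthwaite
    unequal-variance form. Both SDs zero with equal means gives t = 0;
    both zero with unequal means gives a signed infinity.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    diff = m1 - m2
    if s1 == 0 and s2 == 0:
        if diff == 0:
            return 0.0, float(n1 + n2 - 2)
        return float(np.sign(diff) * np.inf), float(n1 + n2 - 2)
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        t = diff / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        return float(t), float(df)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(n1 + n2 - 2)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square on a 2x2 contingency table, no continuity correction.

    Table layout is ``[[a, b], [c, d]]``.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, _, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2)


def auc_mann_whitney(positives, negatives) -> float:
    """ROC AUC as the Mann-Whitney pair-ordering probability.

    Fraction of (positive, negative) pairs with positive > negative,
    counting ties as 1/2. Identical to the area under the empirical ROC
    curve of the score.
    """
    pos = np.asarray(positives, dtype=float).ravel()
    neg = np.asarray(negatives, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))
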
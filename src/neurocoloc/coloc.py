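"""Cross-modal spatial co-localization with template density maps.

The core analysis: each patient's regional map is z-scored against the
control group, correlated (Spearman, optionally partial with respect to
regional gray-matter probability) with every template density map, and
the correlation is Fisher-z transformed. The per-template group
statistic is the mean Fisher z over patients, tested against zero with
an exact permutation test that randomly reassigns subjects to the
patient/control roles (group sizes preserved) and recomputes the whole
z-scoring + correlation chain per permutation. Benjamini-Hochberg FDR
corrects across the template set. Discriminability of the profiles is
summarized per template by the ROC AUC of patients versus leave-one-out
control z-map profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging import Atlas, ScalarMap, extract_regional_means
from .stats import (
    FISHER_CLIP,
    auc_mann_whitney,
    bh_fdr,
    fisher_z,
    fisher_z_inv,
    partial_spearman,
    spearman_rho,
)

__all__ = [
    "ColocTestResult",
    "ROCResult",
    "regional_data_matrix",
    "zscore_vs_controls",
    "loo_control_zscores",
    "coloc_profile",
    "coloc_profiles",
    "coloc_group_test",
    "coloc_roc",
]


def regional_data_matrix(maps: list[ScalarMap], atlas: Atlas) -> pd.DataFrame:
    """Subjects x regions matrix of regional means."""
    return pd.DataFrame([extract_regional_means(m, atlas) for m in maps]).reset_index(
        drop=True
    )


def zscore_vs_controls(patient_rv: pd.Series, control_rvs: pd.DataFrame) -> pd.Series:
    """Per-region z of a patient's values relative to the control group.

    ``(patient - mean(controls)) / sd(controls)`` with the sample (n-1)
    SD; regions with zero control SD are missing (NaN), never zero.
    """
    if len(control_rvs) < 2:
        raise ValueError("need at least 2 controls")
    patient_rv = patient_rv.reindex(control_rvs.columns)
    mu = control_rvs.mean(axis=0)
    sd = control_rvs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (patient_rv - mu) / sd
    z[sd == 0] = np.nan
    return z


def loo_control_zscores(control_rvs: pd.DataFrame) -> pd.DataFrame:
    """Each control z-scored against the remaining controls (leave-one-out)."""
    if len(control_rvs) < 3:
        raise ValueError("need at least 3 controls for leave-one-out z-maps")
    rows = []
    for i in range(len(control_rvs)):
        rest = control_rvs.drop(index=control_rvs.index[i])
        rows.append(zscore_vs_controls(control_rvs.iloc[i], rest))
    return pd.DataFrame(rows, index=control_rvs.index)


def coloc_profile(
    zmap: pd.Series,
    template_rv: pd.Series,
    gm_rv: pd.Series | None = None,
    adjust_gm: bool = False,
) -> float:
    """Fisher-z Spearman correlation of a z-map with one template.

    Computed over the jointly non-missing regions (pairwise deletion);
    with ``adjust_gm`` the partial Spearman controlling for regional GM
    probability is used. The correlation is clipped before the Fisher
    transform so degenerate (perfectly monotone) inputs stay finite.
    """
    z = zmap.to_numpy(dtype=float)
    t = template_rv.reindex(zmap.index).to_numpy(dtype=float)
    joint = np.isfinite(z) & np.isfinite(t)
    if adjust_gm:
        if gm_rv is None:
            raise ValueError("adjust_gm requires a GM probability vector")
        g = gm_rv.reindex(zmap.index).to_numpy(dtype=float)
        joint &= np.isfinite(g)
        if joint.sum() < 4:
            raise ValueError("fewer than 4 jointly non-missing regions")
        rho = partial_spearman(z[joint], t[joint], g[joint])
    else:
        if joint.sum() < 4:
            raise ValueError("fewer than 4 jointly non-missing regions")
        rho = spearman_rho(z[joint], t[joint])
    return float(fisher_z(rho)) if np.isfinite(rho) else float("nan")


def coloc_profiles(
    zmaps: pd.DataFrame,
    templates: pd.DataFrame,
    gm_rv: pd.Series | None = None,
    adjust_gm: bool = False,
) -> pd.DataFrame:
    """Subjects x templates matrix of Fisher-z coefficients."""
    out = pd.DataFrame(
        index=zmaps.index, columns=templates.columns, dtype=float
    )
    for tname in templates.columns:
        for idx in zmaps.index:
            out.loc[idx, tname] = coloc_profile(
                zmaps.loc[idx], templates[tname], gm_rv, adjust_gm
            )
    return out


@dataclass
class ColocTestResult:
    """Per-template permutation test of the mean Fisher-z coefficient."""

    table: pd.DataFrame  # template, mean_z, mean_r, p, q, significant
    profiles: pd.DataFrame  # patients x templates Fisher z
    n_perm: int
    seed: int


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, axis=-1)


def _row_corr_with_templates(z_ranks: np.ndarray, t_ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of z_ranks with each column pattern.

    z_ranks: (..., R); t_ranks: (R, K). Returns (..., K).
    """
    zc = z_ranks - z_ranks.mean(axis=-1, keepdims=True)
    zn = np.sqrt((zc**2).sum(axis=-1, keepdims=True))
    tc = t_ranks - t_ranks.mean(axis=0, keepdims=True)
    tn = np.sqrt((tc**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (zc @ tc) / (zn * tn)
    return corr


def _fisher_profiles_fast(
    X_pat: np.ndarray,
    X_ctl: np.ndarray,
    t_ranks: np.ndarray,
    g_ranks: np.ndarray | None,
) -> np.ndarray:
    """Patients x templates Fisher-z profiles, complete data only.

    ``X_pat``/``X_ctl`` may carry leading batch dimensions (permutations);
    z-scoring, ranking, correlation (optionally partial for GM ranks via
    the single-covariate recursion) and the Fisher transform are all
    vectorized.
    """
    mu = X_ctl.mean(axis=-2, keepdims=True)
    sd = X_ctl.std(axis=-2, ddof=1, keepdims=True)
    z = (X_pat - mu) / sd
    z_ranks = _rank_rows(z)
    r_zt = _row_corr_with_templates(z_ranks, t_ranks)
    if g_ranks is not None:
        r_zg = _row_corr_with_templates(z_ranks, g_ranks[:, None])  # (..., 1)
        r_tg = _row_corr_with_templates(t_ranks.T, g_ranks[:, None]).reshape(1, -1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_zt = (r_zt - r_zg * r_tg) / np.sqrt((1 - r_zg**2) * (1 - r_tg**2))
    return np.arctanh(np.clip(r_zt, -1 + FISHER_CLIP, 1 - FISHER_CLIP))


def coloc_group_test(
    patient_rvs: pd.DataFrame,
    control_rvs: pd.DataFrame,
    templates: pd.DataFrame,
    gm_rv: pd.Series | None = None,
    adjust_gm: bool = False,
    n_perm: int = 10000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> ColocTestResult:
    """Permutation test of group-level co-localization, per template.

    The observed statistic is the mean over patients of the Fisher-z
    Spearman coefficient between patient z-maps (vs controls) and each
    template. The null reassigns subjects at random to patient/control
    roles of the original sizes and recomputes z-maps and profiles; the
    two-sided p uses the add-one convention. When the number of distinct
    role assignments does not exceed ``n_perm`` the null enumerates all
    of them (an exact test). Mean r is the back-transformed mean Fisher z.
    """
    if len(patient_rvs) == 0 or len(control_rvs) == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    regions = patient_rvs.columns
    if not regions.equals(control_rvs.columns):
        raise ValueError("patient and control regional vectors are not aligned")
    templates = templates.loc[regions]
    X = np.vstack([patient_rvs.to_numpy(float), control_rvs.to_numpy(float)])
    n_pat, n_ctl = len(patient_rvs), len(control_rvs)
    n = n_pat + n_ctl
    t_vals = templates.to_numpy(float)
    g_vals = gm_rv.reindex(regions).to_numpy(float) if gm_rv is not None else None
    if adjust_gm and g_vals is None:
        raise ValueError("adjust_gm requires a GM probability vector")
    complete = (
        np.all(np.isfinite(X))
        and np.all(np.isfinite(t_vals))
        and (not adjust_gm or np.all(np.isfinite(g_vals)))
    )
    if not complete:
        return _coloc_group_test_general(
            patient_rvs, control_rvs, templates, gm_rv, adjust_gm, n_perm, seed, fdr_q
        )

    t_ranks = _rank_rows(t_vals.T).T  # rank template values across regions
    g_ranks = _rank_rows(g_vals) if adjust_gm else None

    profiles = _fisher_profiles_fast(X[:n_pat], X[n_pat:], t_ranks, g_ranks)
    observed = profiles.mean(axis=0)

    total = comb(n, n_pat)
    rng = np.random.default_rng(seed)
    if total - 1 <= n_perm:
        # enumerate every distinct role assignment except the observed one
        observed_set = frozenset(range(n_pat))
        assignments = [
            np.array(c)
            for c in combinations(range(n), n_pat)
            if frozenset(c) != observed_set
        ]
        perm_idx = np.stack(
            [np.concatenate([a, np.setdiff1d(np.arange(n), a)]) for a in assignments]
        )
    else:
        perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null_means = np.empty((len(perm_idx), t_vals.shape[1]))
    chunk = max(1, int(2e7 // (n_pat * len(regions))))
    for start in range(0, len(perm_idx), chunk):
        idx = perm_idx[start : start + chunk]
        Xp = X[idx[:, :n_pat]]  # (B, n_pat, R)
        Xc = X[idx[:, n_pat:]]
        prof = _fisher_profiles_fast(Xp, Xc, t_ranks, g_ranks)
        null_means[start : start + len(idx)] = prof.mean(axis=1)

    n_eff = len(perm_idx)
    p = (1 + np.sum(np.abs(null_means) >= np.abs(observed)[None, :], axis=0)) / (1 + n_eff)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "template": templates.columns,
            "mean_z": observed,
            "mean_r": fisher_z_inv(observed),
            "p": p,
            "q": q,
            "significant": q < fdr_q,
        }
    )
    profile_frame = pd.DataFrame(
        profiles, index=patient_rvs.index, columns=templates.columns
    )
    return ColocTestResult(table=table, profiles=profile_frame, n_perm=n_eff, seed=seed)


def _coloc_group_test_general(
    patient_rvs, control_rvs, templates, gm_rv, adjust_gm, n_perm, seed, fdr_q
) -> ColocTestResult:
    """Missing-data path: pairwise deletion per subject-template pair."""

    def mean_profiles(pat: pd.DataFrame, ctl: pd.DataFrame) -> np.ndarray:
        zmaps = pd.DataFrame([zscore_vs_controls(pat.iloc[i], ctl) for i in range(len(pat))])
        prof = coloc_profiles(zmaps, templates, gm_rv, adjust_gm)
        return prof.to_numpy(float)

    all_rvs = pd.concat([patient_rvs, control_rvs], ignore_index=True)
    n_pat = len(patient_rvs)
    profiles = mean_profiles(patient_rvs, control_rvs)
    observed = np.nanmean(profiles, axis=0)
    rng = np.random.default_rng(seed)
    null_means = np.empty((n_perm, templates.shape[1]))
    for b in range(n_perm):
        idx = rng.permutation(len(all_rvs))
        pat = all_rvs.iloc[idx[:n_pat]].reset_index(drop=True)
        ctl = all_rvs.iloc[idx[n_pat:]].reset_index(drop=True)
        null_means[b] = np.nanmean(mean_profiles(pat, ctl), axis=0)
    p = (1 + np.sum(np.abs(null_means) >= np.abs(observed)[None, :], axis=0)) / (1 + n_perm)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "template": templates.columns,
            "mean_z": observed,
            "mean_r": fisher_z_inv(observed),
            "p": p,
            "q": q,
            "significant": q < fdr_q,
        }
    )
    profile_frame = pd.DataFrame(
        profiles, index=patient_rvs.index, columns=templates.columns
    )
    return ColocTestResult(table=table, profiles=profile_frame, n_perm=n_perm, seed=seed)


@dataclass
class ROCResult:
    """Per-template discrimination of patients from controls by Fisher-z profile."""

    table: pd.DataFrame  # template, auc, flipped
    curves: dict  # template -> (fpr, tpr) arrays


def coloc_roc(
    patient_profiles: pd.DataFrame, control_profiles: pd.DataFrame
) -> ROCResult:
    """ROC AUC per template for patient vs (leave-one-out) control profiles.

    The AUC is the Mann-Whitney pair-ordering probability; orientation
    is chosen so the reported AUC is >= 0.5, with a ``flipped`` flag
    recording when low scores indicate patients.
    """
    if len(patient_profiles) == 0 or len(control_profiles) == 0:
        raise ValueError("both profile sets must be nonempty")
    from sklearn.metrics import roc_curve

    rows, curves = [], {}
    for tname in patient_profiles.columns:
        pos = patient_profiles[tname].to_numpy(float)
        neg = control_profiles[tname].to_numpy(float)
        auc_raw = auc_mann_whitney(pos, neg)
        flipped = auc_raw < 0.5
        auc = 1 - auc_raw if flipped else auc_raw
        scores = np.concatenate([pos, neg])
        if flipped:
            scores = -scores
        labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
        fpr, tpr, _ = roc_curve(labels, scores)
        rows.append({"template": tname, "auc": auc, "auc_raw": auc_raw, "flipped": flipped})
        curves[tname] = (fpr, tpr)
    return ROCResult(table=pd.DataFrame(rows), curves=curves)
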
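"""Structural and clinical follow-up analyses.

Answers three questions about a set of co-localization profiles: how
much of the functional co-localization is explained by gray-matter
atrophy (the median-squared correlation between fALFF and GMV profiles
per patient), whether co-localization strength tracks clinical scores
(Spearman with BH-FDR over the tested family), and whether profiles
differ across acquisition sites (Kruskal-Wallis).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, spearman_rho

__all__ = [
    "variance_explained",
    "clinical_association",
    "site_homogeneity_test",
]


def variance_explained(
    falff_profiles: pd.DataFrame, gmv_profiles: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Share of co-localization variance attributable to structure.

    Per patient, the Spearman correlation across templates between the
    functional (fALFF) and structural (GMV) Fisher-z profiles; the
    squared median of these correlations is the reported fraction.
    Squaring discards the sign: perfectly anti-correlated profiles also
    yield fraction 1.
    """
    if falff_profiles.shape[1] < 3:
        raise ValueError("need at least 3 templates")
    if not falff_profiles.columns.equals(gmv_profiles.columns) or len(
        falff_profiles
    ) != len(gmv_profiles):
        raise ValueError("profiles are not aligned by patient and template")
    rhos = pd.Series(
        [
            spearman_rho(falff_profiles.iloc[i], gmv_profiles.iloc[i])
            for i in range(len(falff_profiles))
        ],
        index=falff_profiles.index,
        name="rho",
    )
    fraction = float(np.nanmedian(rhos.to_numpy()) ** 2)
    return rhos, fraction


def clinical_association(
    profiles: pd.DataFrame,
    subject_table: pd.DataFrame,
    score_names: list[str],
    min_n: int = 5,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Spearman association of per-patient profiles with clinical scores.

    One test per (template, score) pair with pairwise-complete deletion
    of missing scores; BH-FDR is applied over all tests of the call
    (the correction family is the call). Scores that are entirely
    missing are excluded with a warning.
    """
    patients = subject_table.loc[subject_table["group"] == "patient"]
    rows = []
    for score in score_names:
        values = patients[score].to_numpy(dtype=float)
        if not np.isfinite(values).any():
            warnings.warn(f"score {score!r} is entirely missing; excluded")
            continue
        for tname in profiles.columns:
            prof = profiles[tname].to_numpy(dtype=float)
            joint = np.isfinite(prof) & np.isfinite(values)
            n = int(joint.sum())
            if n < min_n:
                raise ValueError(
                    f"fewer than {min_n} complete pairs for ({tname}, {score})"
                )
            rho, p = sps.spearmanr(prof[joint], values[joint])
            rows.append(
                {"template": tname, "score": score, "rho": float(rho), "p": float(p), "n": n}
            )
    table = pd.DataFrame(rows, columns=["template", "score", "rho", "p", "n"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["q"] < fdr_q
    return table


def site_homogeneity_test(
    values: pd.Series, subject_table: pd.DataFrame
) -> tuple[float, int, float]:
    """Kruskal-Wallis test of profile differences across acquisition sites.

    Returns (H, df, p) with the tie-corrected H statistic and a
    chi-square p on df = (#sites with data) - 1. When every value is
    tied the statistic is 0 and p is 1 (the tie-correction convention).
    """
    sites = subject_table.loc[values.index, "site"]
    groups = [
        g.dropna().to_numpy(dtype=float)
        for _, g in values.groupby(sites)
        if g.dropna().size > 0
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 sites with data")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)
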
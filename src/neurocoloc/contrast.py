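"""Voxel-wise two-group GLM with permutation-based cluster inference.

Each voxel is fit by OLS on group plus covariates; the group contrast
is converted to a t statistic with the pooled residual variance at that
voxel. Cluster-level inference thresholds the t-map at an uncorrected
voxel p (one-sided, per contrast direction), finds connected
components, and compares each observed cluster's size against the null
distribution of the *maximum* cluster size obtained by re-running the
fit under random permutations of the group labels. Covariate rows stay
attached to their subjects during permutation (only the group labels
are shuffled), which is a literal reading of label-permutation and a
documented approximation when covariates correlate with group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .imaging import ScalarMap, build_design_matrix

__all__ = [
    "TMap",
    "fit_voxelwise_glm",
    "permutation_cluster_inference",
    "cluster_mask_from_table",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class TMap:
    """Voxel-wise t statistics for one group contrast."""

    t: np.ndarray  # 3D, NaN outside the analysis mask
    df: int
    contrast: str


def _group_indicator(subject_table: pd.DataFrame) -> np.ndarray:
    group = subject_table["group"].astype(str)
    levels = set(group.unique())
    if not levels <= {"patient", "control"}:
        raise ValueError(f"unknown group levels: {sorted(levels)}")
    return (group == "patient").to_numpy(dtype=float)


def _contrast_sign(contrast: str) -> float:
    # positive t = evidence for the stated direction
    if contrast == "patient>control":
        return 1.0
    if contrast == "control>patient":
        return -1.0
    raise ValueError(f"contrast must be 'patient>control' or 'control>patient': {contrast!r}")


def _design_with_group(
    subject_table: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, int]:
    design = build_design_matrix(subject_table, covariates)
    X = np.column_stack([design.to_numpy(float), _group_indicator(subject_table)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design with group indicator is rank deficient")
    return X, X.shape[1] - 1  # index of the group column


def _glm_t(X: np.ndarray, Y: np.ndarray, col: int, sign: float) -> tuple[np.ndarray, int]:
    """t statistics for one design column, vectorized over voxels (columns of Y)."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[col, col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = sign * beta[col] / se
    t[se == 0] = 0.0
    return t, df


def _stack_maps(maps: list[ScalarMap]) -> tuple[np.ndarray, np.ndarray, tuple]:
    shape = maps[0].grid_shape
    Y = np.stack([m.data.ravel() for m in maps])
    valid = np.all(np.isfinite(Y), axis=0)
    return Y, valid, shape


def fit_voxelwise_glm(
    maps: list[ScalarMap],
    subject_table: pd.DataFrame,
    covariates: list[str],
    contrast: str = "control>patient",
) -> TMap:
    """Per-voxel OLS of map value on group + covariates; group-contrast t-map."""
    if len(maps) != len(subject_table):
        raise ValueError("need one map per subject")
    Y, valid, shape = _stack_maps(maps)
    X, group_col = _design_with_group(subject_table, covariates)
    t_flat, df = _glm_t(X, Y[:, valid], group_col, _contrast_sign(contrast))
    t = np.full(Y.shape[1], np.nan)
    t[valid] = t_flat
    return TMap(t.reshape(shape), df, contrast)


def _clusters(
    t3d: np.ndarray, t_crit: float, connectivity: int
) -> tuple[np.ndarray, list[dict]]:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    above = np.nan_to_num(t3d, nan=-np.inf) > t_crit
    labels, n_clusters = ndimage.label(above, structure=structure)
    info = []
    for cid in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == cid)
        tvals = t3d[tuple(voxels.T)]
        peak = voxels[np.argmax(tvals)]
        info.append(
            {
                "cluster_id": cid,
                "size": len(voxels),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "peak_t": float(tvals.max()),
            }
        )
    return labels, info


def permutation_cluster_inference(
    maps: list[ScalarMap],
    subject_table: pd.DataFrame,
    covariates: list[str],
    contrast: str = "control>patient",
    n_perm: int = 1000,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    seed: int = 0,
    connectivity: int = 18,
) -> pd.DataFrame:
    """Cluster table with permutation-based cluster-level p-values.

    The observed t-map is thresholded at the one-sided critical t for
    ``voxel_p`` (Student, residual df); connected components (18-
    connectivity by default) form clusters. The null of the maximum
    cluster size is built from ``n_perm`` random permutations of the
    group labels; each observed cluster gets
    ``p = (1 + #{perm max size >= size}) / (1 + n_perm)`` and a
    ``significant`` flag at ``cluster_p``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    Y, valid, shape = _stack_maps(maps)
    columns = [
        "cluster_id", "size", "peak_x", "peak_y", "peak_z", "peak_t", "p", "significant",
    ]
    if not valid.any():
        import warnings

        warnings.warn("no in-mask voxels; returning empty cluster table")
        return pd.DataFrame(columns=columns)
    Yv = Y[:, valid]
    sign = _contrast_sign(contrast)
    X, group_col = _design_with_group(subject_table, covariates)
    t_obs, df = _glm_t(X, Yv, group_col, sign)
    t_crit = float(sps.t.isf(voxel_p, df))

    t3d = np.full(Y.shape[1], np.nan)
    t3d[valid] = t_obs
    t3d = t3d.reshape(shape)
    _, observed = _clusters(t3d, t_crit, connectivity)

    rng = np.random.default_rng(seed)
    group = _group_indicator(subject_table)
    null_max = np.empty(n_perm)
    Xp = X.copy()
    for b in range(n_perm):
        Xp[:, group_col] = rng.permutation(group)
        t_b, _ = _glm_t(Xp, Yv, group_col, sign)
        flat = np.full(Y.shape[1], np.nan)
        flat[valid] = t_b
        _, info = _clusters(flat.reshape(shape), t_crit, connectivity)
        null_max[b] = max((c["size"] for c in info), default=0)

    rows = []
    for c in observed:
        p = (1 + int(np.sum(null_max >= c["size"]))) / (1 + n_perm)
        rows.append({**c, "p": p, "significant": p < cluster_p})
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values("size", ascending=False).reset_index(drop=True)


def cluster_mask_from_table(
    maps: list[ScalarMap],
    subject_table: pd.DataFrame,
    covariates: list[str],
    contrast: str,
    voxel_p: float,
    cluster_table: pd.DataFrame,
    cluster_id: int | None = None,
    connectivity: int = 18,
) -> np.ndarray:
    """Boolean mask of one reported cluster (largest by default)."""
    tmap = fit_voxelwise_glm(maps, subject_table, covariates, contrast)
    t_crit = float(sps.t.isf(voxel_p, tmap.df))
    labels, info = _clusters(tmap.t, t_crit, connectivity)
    if cluster_id is None:
        if not info:
            raise ValueError("no suprathreshold clusters")
        cluster_id = max(info, key=lambda c: c["size"])["cluster_id"]
    return labels == cluster_id
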
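"""Volumetric data model.

A :class:`ScalarMap` is a 3D scalar field (fALFF, gray-matter volume, a
neurotransmitter density template) on a fixed voxel grid with NaN as the
missing marker outside the gray-matter mask. An :class:`Atlas` is an
integer label volume with a region table. All downstream statistics work
on regional summaries (:func:`extract_regional_means`), so no world
coordinate math is performed; NIfTI affines are passed through on IO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "ScalarMap",
    "Atlas",
    "SubjectRecord",
    "apply_gm_mask",
    "build_design_matrix",
    "regress_confounds_images",
    "extract_regional_means",
    "extract_eigenvariate",
]


@dataclass
class ScalarMap:
    """A 3D scalar field; NaN marks missing (out-of-mask) voxels."""

    data: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap data must be 3-dimensional")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of non-missing voxels."""
        return np.isfinite(self.data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float64), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ScalarMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), img.affine)


@dataclass
class Atlas:
    """Integer-labeled parcellation; labels 1..R partition the mask, 0 = background."""

    labels: np.ndarray
    region_table: pd.DataFrame  # columns: region_id, name
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-dimensional")
        present = np.unique(self.labels)
        present = present[present > 0]
        expected = np.arange(1, self.n_regions + 1)
        if not np.array_equal(np.sort(self.region_table["region_id"].to_numpy()), expected):
            raise ValueError("region table ids must be contiguous 1..R")
        if present.size and not np.isin(present, expected).all():
            raise ValueError("label volume contains ids missing from the region table")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def region_ids(self) -> np.ndarray:
        return np.sort(self.region_table["region_id"].to_numpy())

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def save(self, label_path, table_path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(label_path))
        self.region_table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, label_path, table_path) -> "Atlas":
        img = nib.load(str(label_path))
        labels = np.asarray(img.get_fdata()).astype(np.int32)
        table = pd.read_csv(table_path, sep="\t")
        return cls(labels, table, img.affine)


@dataclass
class SubjectRecord:
    """One row of the subject table."""

    id: str
    group: str  # "patient" | "control"
    age: float
    sex: str
    site: str
    tiv: float | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValueError("group must be 'patient' or 'control'")


def apply_gm_mask(scalar_map: ScalarMap, mask: np.ndarray) -> ScalarMap:
    """Restrict a map to a gray-matter mask: out-of-mask voxels become missing."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scalar_map.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {scalar_map.grid_shape}"
        )
    out = scalar_map.data.copy()
    out[~mask] = np.nan
    return ScalarMap(out, scalar_map.affine)


def build_design_matrix(
    subject_table: pd.DataFrame,
    covariate_names: list[str],
    include_intercept: bool = True,
) -> pd.DataFrame:
    """Dummy-code covariates into a numeric design matrix.

    Categorical (non-numeric) covariates get one indicator per
    non-reference level; the reference level is the lexicographically
    first. Raises if the resulting design is rank deficient, naming the
    collinear columns.
    """
    cols: dict[str, np.ndarray] = {}
    if include_intercept:
        cols["intercept"] = np.ones(len(subject_table))
    for name in covariate_names:
        col = subject_table[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols[name] = col.to_numpy(dtype=float)
        elif pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # lexicographically first level = reference
                cols[f"{name}[{level}]"] = (col.astype(str) == level).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=subject_table.index)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns past the rank are the dependent ones
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = [design.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def regress_confounds_images(
    maps: list[ScalarMap],
    subject_table: pd.DataFrame,
    covariate_names: list[str],
) -> list[ScalarMap]:
    """Regress confounds out of a stack of subject maps, voxel-wise.

    Per voxel, the values across subjects are OLS-fit on an intercept
    plus the dummy-coded covariates; the returned maps are the residuals
    plus the fitted intercept, so the grand mean is preserved. Voxels
    missing in any subject are missing in every output map (the
    cross-subject fit is undefined there).
    """
    if len(maps) != len(subject_table):
        raise ValueError("need exactly one map per subject-table row")
    design = build_design_matrix(subject_table, covariate_names)
    X = design.to_numpy(dtype=float)
    X[:, 1:] -= X[:, 1:].mean(axis=0)  # centered covariates: intercept = grand mean
    Y = np.stack([m.data.ravel() for m in maps])  # subjects x voxels
    valid = np.all(np.isfinite(Y), axis=0)
    beta = np.zeros((X.shape[1], Y.shape[1]))
    beta[:, valid] = np.linalg.lstsq(X, Y[:, valid], rcond=None)[0]
    resid = np.full_like(Y, np.nan)
    resid[:, valid] = Y[:, valid] - X @ beta[:, valid]
    resid[:, valid] += beta[0, valid]  # restore the fitted grand mean
    shape = maps[0].grid_shape
    return [ScalarMap(row.reshape(shape), maps[0].affine) for row in resid]


def extract_regional_means(scalar_map: ScalarMap, atlas: Atlas) -> pd.Series:
    """Mean map value per atlas region, over non-missing voxels.

    Returns a Series indexed by region id; a region with no eligible
    voxel is NaN (flagged missing, never silently dropped or zero-filled).
    """
    if scalar_map.grid_shape != atlas.labels.shape:
        raise ValueError("map grid does not match atlas grid")
    labels = atlas.labels.ravel()
    values = scalar_map.data.ravel()
    ok = (labels > 0) & np.isfinite(values)
    n_regions = atlas.n_regions
    sums = np.bincount(labels[ok], weights=values[ok], minlength=n_regions + 1)
    counts = np.bincount(labels[ok], minlength=n_regions + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums[1:] / counts[1:]
    means[counts[1:] == 0] = np.nan
    return pd.Series(means, index=pd.Index(np.arange(1, n_regions + 1), name="region_id"))


def extract_eigenvariate(maps: list[ScalarMap], cluster_mask: np.ndarray) -> np.ndarray:
    """First singular component of the subject x cluster-voxel matrix.

    The matrix is column-centered (each voxel demeaned across subjects)
    before the SVD; the left singular vector is rescaled to unit sample
    variance and its sign fixed so that it correlates nonnegatively with
    the per-subject cluster-mean signal. One score per subject.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    if len(maps) < 2:
        raise ValueError("need at least two subjects")
    M = np.stack([m.data[cluster_mask] for m in maps])  # subjects x voxels
    if not np.all(np.isfinite(M)):
        raise ValueError("cluster contains missing voxels in some subject")
    cluster_mean = M.mean(axis=1)
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    scores = U[:, 0]
    sd = scores.std(ddof=1)
    if sd > 0:
        scores = scores / sd
    centered_mean = cluster_mean - cluster_mean.mean()
    if scores @ centered_mean < 0:
        scores = -scores
    return scores
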
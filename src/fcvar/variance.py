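"""Voxel-wise homogeneity-of-variance testing and variability-ratio maps.

The core statistic is the Brown-Forsythe test: a one-way ANOVA on absolute
deviations from each group's median.  Median centering (instead of Levene's
mean centering) keeps the type-I error near nominal for skewed data, which
matters because Fisher-z connectivity values need not be symmetric across
subjects.  Nuisance covariates (age, task accuracy, reaction time, ...) are
removed by least squares before the test, with covariate slopes estimated
jointly with group intercepts so that group-correlated covariates do not
absorb group effects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .nifti_io import Mask

__all__ = [
    "GroupDesign",
    "StatMap",
    "RatioMap",
    "residualize",
    "brown_forsythe_map",
    "variability_ratio_map",
]


@dataclasses.dataclass
class GroupDesign:
    """Subject-level design: group factor plus nuisance covariates.

    ``covariates`` is a subject x covariate DataFrame (may be empty).  Every
    group must have at least 3 subjects, and no covariate may be constant.
    """

    subject_ids: list[str]
    group_labels: np.ndarray  # (n,) array of labels
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels)
        n = len(self.subject_ids)
        if self.group_labels.shape != (n,):
            raise ValueError("group_labels must align with subject_ids")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(n))
        if len(self.covariates) != n:
            raise ValueError("covariates must have one row per subject")
        levels, counts = np.unique(self.group_labels, return_counts=True)
        if len(levels) < 2:
            raise ValueError("need at least 2 groups")
        if np.any(counts < 3):
            small = levels[counts < 3]
            raise ValueError(f"groups {list(small)} have fewer than 3 subjects")
        cov = self.covariates.to_numpy(dtype=float) if self.covariates.shape[1] else None
        if cov is not None:
            if not np.all(np.isfinite(cov)):
                raise ValueError("covariates contain non-finite values")
            const = self.covariates.columns[np.ptp(cov, axis=0) == 0]
            if len(const):
                raise ValueError(f"constant covariate columns: {list(const)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.group_labels)

    def group_dummies(self) -> np.ndarray:
        """One indicator column per group (cell-means coding, full rank)."""
        return (self.group_labels[:, None] == self.levels[None, :]).astype(float)


@dataclasses.dataclass
class StatMap:
    """Voxel-wise statistic + p-value image (Brown-Forsythe F, ANOVA F, t or r)."""

    mask: Mask
    statistic: np.ndarray
    p: np.ndarray
    df: tuple
    kind: str
    degenerate: np.ndarray | None = None  # per-voxel flag

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        n = self.mask.n_voxels
        if self.statistic.shape != (n,) or self.p.shape != (n,):
            raise ValueError("statistic/p must have one entry per mask voxel")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")
        if self.degenerate is None:
            self.degenerate = np.zeros(n, dtype=bool)


@dataclasses.dataclass
class RatioMap:
    """Voxel-wise ratio of across-subject spread between two groups."""

    mask: Mask
    ratio: np.ndarray  # NaN where undefined / outside restriction
    spread_kind: str  # "sd" or "variance"
    numerator_group: str
    denominator_group: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.ratio)


def residualize(fc: np.ndarray, design: GroupDesign) -> np.ndarray:
    """Remove covariate effects from subject x voxel FC, keeping group intercepts.

    Per voxel the model  y = group intercepts + covariate slopes  is fitted by
    least squares on mean-centered covariates; the returned values are
    y minus the covariate component only, so between-group location structure
    survives for downstream mean comparisons while covariate-driven variance
    is gone.
    """
    fc = np.asarray(fc, dtype=np.float64)
    if fc.shape[0] != design.n_subjects:
        raise ValueError(
            f"fc has {fc.shape[0]} rows but design has {design.n_subjects} subjects"
        )
    if design.covariates.shape[1] == 0:
        return fc.copy()
    g = design.group_dummies()
    c = design.covariates.to_numpy(dtype=float)
    c = c - c.mean(axis=0)
    x = np.column_stack([g, c])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = list(design.covariates.columns)
        raise ValueError(
            "rank-deficient design: group indicators plus covariates "
            f"{names} are collinear (rank {rank} < {x.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(x, fc, rcond=None)
    beta_cov = beta[g.shape[1]:]
    return fc - c @ beta_cov


def brown_forsythe_map(
    residuals: np.ndarray,
    groups: np.ndarray,
    mask: Mask | None = None,
    center: str = "median",
) -> StatMap:
    """Brown-Forsythe homogeneity-of-variance F at every voxel.

    Per voxel: d_ij = |y_ij - center(group j)|, then one-way ANOVA F on d
    across groups with df (k-1, N-k); the upper-tail F p-value tests equal
    spread.  ``center='mean'`` gives the classical Levene variant.  Voxels
    where every deviation is zero are flagged degenerate with F=0, p=1.
    """
    y = np.asarray(residuals, dtype=np.float64)
    groups = np.asarray(groups)
    if y.shape[0] != groups.shape[0]:
        raise ValueError("residual rows must align with group labels")
    levels = np.unique(groups)
    k = len(levels)
    n_total = y.shape[0]
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.array([(groups == g).sum() for g in levels])
    if np.any(counts < 3):
        raise ValueError("every group needs at least 3 subjects")

    d = np.empty_like(y)
    for g in levels:
        sel = groups == g
        if center == "median":
            loc = np.median(y[sel], axis=0)
        elif center == "mean":
            loc = y[sel].mean(axis=0)
        else:
            raise ValueError("center must be 'median' or 'mean'")
        d[sel] = np.abs(y[sel] - loc)

    grand = d.mean(axis=0)
    ss_between = np.zeros(y.shape[1])
    ss_within = np.zeros(y.shape[1])
    for g, n_g in zip(levels, counts):
        sel = groups == g
        gm = d[sel].mean(axis=0)
        ss_between += n_g * (gm - grand) ** 2
        ss_within += ((d[sel] - gm) ** 2).sum(axis=0)

    df1, df2 = k - 1, n_total - k
    degenerate = ss_within <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[degenerate] = 0.0
    p = stats.f.sf(f, df1, df2)
    p[degenerate] = 1.0
    if mask is None:
        mask = _dummy_mask(y.shape[1])
    return StatMap(
        mask=mask, statistic=f, p=p, df=(df1, df2),
        kind=f"brown-forsythe-F ({center}-centered)", degenerate=degenerate,
    )


def variability_ratio_map(
    residuals: np.ndarray,
    groups: np.ndarray,
    numerator_group,
    denominator_group,
    restrict_to: np.ndarray | None = None,
    mask: Mask | None = None,
    spread: str = "sd",
) -> RatioMap:
    """Ratio of across-subject spread (SD by default) between two groups.

    ``restrict_to`` is a per-voxel boolean flag (e.g. significant + cluster
    vetted Brown-Forsythe voxels); outside it, and wherever the denominator
    spread is zero, the ratio is NaN.
    """
    y = np.asarray(residuals, dtype=np.float64)
    groups = np.asarray(groups)
    if spread not in ("sd", "variance"):
        raise ValueError("spread must be 'sd' or 'variance'")
    sel_num = groups == numerator_group
    sel_den = groups == denominator_group
    if sel_num.sum() < 2 or sel_den.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    num = y[sel_num].std(axis=0, ddof=1)
    den = y[sel_den].std(axis=0, ddof=1)
    if spread == "variance":
        num, den = num**2, den**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, dtype=bool)
        if restrict_to.shape != ratio.shape:
            raise ValueError("restrict_to must align with voxels")
        if not restrict_to.any():
            raise ValueError("restriction selects no voxels")
        ratio = np.where(restrict_to, ratio, np.nan)
    if mask is None:
        mask = _dummy_mask(y.shape[1])
    return RatioMap(
        mask=mask, ratio=ratio, spread_kind=spread,
        numerator_group=str(numerator_group),
        denominator_group=str(denominator_group),
    )


def _dummy_mask(n_voxels: int) -> Mask:
    """A flat 1 x 1 x n grid mask for matrix-only workflows without geometry."""
    from .nifti_io import VoxelGrid

    grid = VoxelGrid(
        shape=(1, 1, n_voxels), voxel_size=(1.0, 1.0, 1.0), affine=np.eye(4)
    )
    idx = np.column_stack(
        [np.zeros(n_voxels, dtype=int), np.zeros(n_voxels, dtype=int), np.arange(n_voxels)]
    )
    return Mask(grid=grid, indices=idx)
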
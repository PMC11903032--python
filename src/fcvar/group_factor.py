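"""Group mean comparisons of FC, and whole-brain / ROI correlations with
continuous subject factors (e.g. age of first hearing-aid use, duration of
hearing-aid use, hearing threshold in dB).

All analyses operate on covariate-residualized Fisher-z FC values (see
``fcvar.variance.residualize``).  ROI-level correlations are corrected
across the ROI x factor family with Benjamini-Hochberg; uncorrected p and q
are both reported.
"""

from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clusters import ClusterSet
from .nifti_io import Mask
from .variance import GroupDesign, StatMap

__all__ = [
    "FactorTable",
    "RoiSet",
    "group_mean_map",
    "factor_correlation_map",
    "roi_factor_correlation",
    "extract_rois",
]


@dataclasses.dataclass
class FactorTable:
    """Per-subject continuous factors; NaN marks missing (listwise-dropped)."""

    subject_ids: list[str]
    factors: pd.DataFrame  # subject x factor, NaN = missing

    def __post_init__(self) -> None:
        if len(self.factors) != len(self.subject_ids):
            raise ValueError("factors must have one row per subject")
        for col in self.factors.columns:
            if self.factors[col].notna().sum() < 3:
                raise ValueError(f"factor {col!r} has fewer than 3 non-missing subjects")


@dataclasses.dataclass
class RoiSet:
    rois: list[tuple[str, Mask]]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.rois:
            warnings.warn("empty ROI set", RuntimeWarning)


def group_mean_map(
    fc: np.ndarray,
    design: GroupDesign,
    mask: Mask | None = None,
    welch: bool = False,
) -> tuple[StatMap, dict[tuple[str, str], StatMap]]:
    """One-way ANOVA F across groups per voxel, plus post hoc pairwise t maps.

    ``fc`` should already be covariate-residualized.  The post hoc t is a
    pooled-variance two-sample t (sign convention group1 - group2), matching
    the ANOVA's equal-variance model; ``welch=True`` switches to the
    unequal-variance form.
    """
    y = np.asarray(fc, dtype=np.float64)
    groups = design.group_labels
    levels = list(design.levels)
    k = len(levels)
    n_total = y.shape[0]
    if mask is None:
        from .variance import _dummy_mask

        mask = _dummy_mask(y.shape[1])

    grand = y.mean(axis=0)
    ss_between = np.zeros(y.shape[1])
    ss_within = np.zeros(y.shape[1])
    for g in levels:
        sel = groups == g
        gm = y[sel].mean(axis=0)
        ss_between += sel.sum() * (gm - grand) ** 2
        ss_within += ((y[sel] - gm) ** 2).sum(axis=0)
    df1, df2 = k - 1, n_total - k
    degenerate = ss_within <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[degenerate] = 0.0
    p = stats.f.sf(f, df1, df2)
    p[degenerate] = 1.0
    anova = StatMap(mask=mask, statistic=f, p=p, df=(df1, df2),
                    kind="anova-F", degenerate=degenerate)

    posthoc: dict[tuple[str, str], StatMap] = {}
    for g1, g2 in combinations(levels, 2):
        y1, y2 = y[groups == g1], y[groups == g2]
        n1, n2 = y1.shape[0], y2.shape[0]
        m1, m2 = y1.mean(axis=0), y2.mean(axis=0)
        v1, v2 = y1.var(axis=0, ddof=1), y2.var(axis=0, ddof=1)
        if welch:
            se2 = v1 / n1 + v2 / n2
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m1 - m2) / np.sqrt(se2)
                df_t = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            deg = se2 <= 0
            df_rep: tuple = ("welch",)
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df_t = np.full(y.shape[1], n1 + n2 - 2, dtype=float)
            deg = sp2 <= 0
            df_rep = (n1 + n2 - 2,)
        t = np.where(deg, 0.0, t)
        p_t = 2.0 * stats.t.sf(np.abs(t), df_t)
        p_t = np.where(deg, 1.0, np.minimum(p_t, 1.0))
        posthoc[(str(g1), str(g2))] = StatMap(
            mask=mask, statistic=t, p=p_t, df=df_rep,
            kind=f"t ({g1} - {g2})", degenerate=deg,
        )
    return anova, posthoc


def _partial_corr(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None):
    """Pearson r of covariate-residualized y (columns) vs residualized x.

    Returns (r, q) where q = number of covariates removed.
    """
    n = x.shape[0]
    if covariates is not None and covariates.shape[1] > 0:
        c = np.column_stack([np.ones(n), covariates - covariates.mean(axis=0)])
        q_mat, _ = np.linalg.qr(c)
        y = y - q_mat @ (q_mat.T @ y)
        x = x - q_mat @ (q_mat.T @ x)
        q = covariates.shape[1]
    else:
        y = y - y.mean(axis=0)
        x = x - x.mean()
        q = 0
    sx = np.linalg.norm(x)
    sy = np.linalg.norm(y, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ y) / (sx * sy)
    return r, q


def factor_correlation_map(
    fc: np.ndarray,
    factor: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: Mask | None = None,
) -> StatMap:
    """Per-voxel Pearson correlation between FC and a subject factor.

    Missing factor values are dropped listwise.  Covariates, if given, are
    residualized out of both sides; p comes from the t transform with
    df = n - 2 - q.
    """
    y = np.asarray(fc, dtype=np.float64)
    x = np.asarray(factor, dtype=np.float64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("factor must align with fc rows")
    keep = np.isfinite(x)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != y.shape[0]:
            raise ValueError("covariates must align with fc rows")
        keep &= np.all(np.isfinite(covariates), axis=1)
    n = int(keep.sum())
    if n < 5:
        raise ValueError("need at least 5 non-missing subjects")
    x = x[keep]
    if x.std(ddof=0) == 0:
        raise ValueError("constant factor")
    y = y[keep]
    cov = covariates[keep] if covariates is not None else None

    r, q = _partial_corr(y, x, cov)
    df = n - 2 - q
    degenerate = ~np.isfinite(r)
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, np.minimum(p, 1.0))
    if mask is None:
        from .variance import _dummy_mask

        mask = _dummy_mask(y.shape[1])
    return StatMap(mask=mask, statistic=r, p=p, df=(df,), kind="pearson-r",
                   degenerate=degenerate)


def roi_factor_correlation(
    fc: np.ndarray,
    rois: RoiSet,
    table: FactorTable,
    covariates: np.ndarray | None = None,
    analysis_mask: Mask | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate mean ROI FC with each factor; BH-correct over ROI x factor.

    Returns (results, subject_values): ``results`` has one row per ROI x
    factor cell with n, r, uncorrected p and BH q; ``subject_values`` carries
    the per-subject ROI means for scatter plots.
    """
    from .denoise import _subset_columns

    y = np.asarray(fc, dtype=np.float64)
    if y.shape[0] != len(table.subject_ids):
        raise ValueError("fc rows must align with factor table subjects")
    roi_means = {}
    for label, roi_mask in rois.rois:
        if analysis_mask is not None:
            cols = _subset_columns(analysis_mask, roi_mask)
        else:
            cols = np.arange(roi_mask.n_voxels)
            if y.shape[1] < roi_mask.n_voxels:
                raise ValueError(f"ROI {label!r} larger than FC matrix")
        if cols.size == 0:
            raise ValueError(f"ROI {label!r} has no in-mask voxels")
        roi_means[label] = y[:, cols].mean(axis=1)
    subject_values = pd.DataFrame(roi_means, index=table.subject_ids)

    rows = []
    for label in roi_means:
        for factor_name in table.factors.columns:
            x_full = table.factors[factor_name].to_numpy(dtype=float)
            yv = roi_means[label]
            keep = np.isfinite(x_full)
            cov = None
            if covariates is not None:
                cov_full = np.atleast_2d(np.asarray(covariates, dtype=float))
                keep &= np.all(np.isfinite(cov_full), axis=1)
                cov = cov_full[keep]
            x = x_full[keep]
            v = yv[keep]
            n = int(keep.sum())
            if n < 5 or x.std(ddof=0) == 0 or v.std(ddof=0) == 0:
                rows.append(dict(roi=label, factor=factor_name, n=n,
                                 r=np.nan, p=np.nan,
                                 note="undefined (constant values or n < 5)"))
                continue
            r, q = _partial_corr(v[:, None], x, cov)
            r = float(np.clip(r[0], -1, 1))
            df = n - 2 - q
            t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf
            p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
            rows.append(dict(roi=label, factor=factor_name, n=n, r=r, p=p, note=""))
    results = pd.DataFrame(rows)
    valid = results["p"].notna()
    results["q"] = np.nan
    if valid.any():
        results.loc[valid, "q"] = multipletests(
            results.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return results, subject_values


def extract_rois(
    clusters: ClusterSet,
    mask: Mask,
    min_size: int = 0,
    source: str = "",
) -> RoiSet:
    """One ROI per retained cluster, labeled by peak coordinate and size."""
    rois = []
    for cl in clusters.clusters:
        if cl.size < min_size:
            continue
        sel = clusters.labels == cl.id
        roi_mask = Mask(grid=mask.grid, indices=mask.indices[sel])
        label = f"cluster{cl.id}_peak{cl.peak_ijk[0]}-{cl.peak_ijk[1]}-{cl.peak_ijk[2]}_n{cl.size}"
        rois.append((label, roi_mask))
    if not rois:
        warnings.warn("no clusters survive min_size; ROI set is empty", RuntimeWarning)
    return RoiSet(rois=rois, source=source)
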
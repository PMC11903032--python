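"""Confound regression with simultaneous band-pass filtering, and seed FC maps.

Band-pass filtering is realized as regression on a discrete-cosine basis
spanning all out-of-band frequencies, fitted jointly with the confound
columns in a single least-squares projection.  This "simultaneous" strategy
avoids the artifact of sequential filter-then-regress pipelines, where
regressing unfiltered confounds reintroduces out-of-band noise into the
filtered data.

Seed connectivity is plain Pearson correlation between the mean z-scored
seed time course and each voxel's time course, computed on run-concatenated,
per-run standardized residuals, then Fisher-transformed (z = atanh r).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .nifti_io import Mask, TimeSeriesMatrix

__all__ = [
    "ProjectionBasis",
    "FCMap",
    "build_projection",
    "denoise_run",
    "seed_fc_map",
    "CORRELATION_CLAMP",
]

logger = logging.getLogger(__name__)

#: |r| is clamped below 1 by this margin before atanh, keeping maps finite.
CORRELATION_CLAMP = 1.0 - 1e-7


@dataclasses.dataclass
class ProjectionBasis:
    """Regressor matrix whose least-squares residual implements denoising.

    Columns: intercept, confound columns, and discrete-cosine columns for
    every frequency outside the retained band.  Duplicated / collinear
    columns are dropped deterministically (later columns removed first).
    """

    n_volumes: int
    tr: float
    band: tuple[float, float]
    regressors: np.ndarray  # (n_volumes, n_kept) full column rank
    column_names: list[str]

    @property
    def rank(self) -> int:
        return int(self.regressors.shape[1])


def _dct_basis(n_volumes: int, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm DCT-II columns and their frequencies f_k = k / (2 N TR)."""
    t = np.arange(n_volumes)
    k = np.arange(1, n_volumes)
    basis = np.cos(np.pi * np.outer(t + 0.5, k) / n_volumes)
    basis /= np.linalg.norm(basis, axis=0)
    freqs = k / (2.0 * n_volumes * tr)
    return basis, freqs


def build_projection(
    confounds: np.ndarray | None,
    n_volumes: int,
    tr: float,
    band: tuple[float, float],
    confound_names: list[str] | None = None,
) -> ProjectionBasis:
    """Assemble the joint confound + out-of-band cosine regressor matrix.

    ``band`` is the (low, high) pass band in Hz; cosine columns are included
    for frequencies f <= low or f >= high, so that regressing them out removes
    exactly the out-of-band signal.  Requires 0 <= low < high <= Nyquist.
    """
    nyquist = 1.0 / (2.0 * tr)
    low, high = float(band[0]), float(band[1])
    if not (0.0 <= low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band {band} must satisfy 0 <= low < high <= Nyquist ({nyquist:.4g} Hz)"
        )
    cols = [np.ones((n_volumes, 1))]
    names = ["intercept"]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_volumes:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected {n_volumes}"
            )
        cols.append(confounds)
        if confound_names is None:
            confound_names = [f"confound{i}" for i in range(confounds.shape[1])]
        names.extend(confound_names)
    dct, freqs = _dct_basis(n_volumes, tr)
    out_of_band = (freqs <= low) | (freqs >= high)
    if np.any(out_of_band):
        cols.append(dct[:, out_of_band])
        names.extend(f"cos_{f:.6g}Hz" for f in freqs[out_of_band])
    x = np.column_stack(cols)

    # Deterministic de-duplication: QR with column pivoting would reorder, so
    # instead greedily keep each column only if it adds rank.
    keep = _independent_columns(x)
    return ProjectionBasis(
        n_volumes=n_volumes,
        tr=tr,
        band=(low, high),
        regressors=x[:, keep],
        column_names=[names[i] for i in keep],
    )


def _independent_columns(x: np.ndarray, rtol: float = 1e-10) -> list[int]:
    """Indices of a maximal left-to-right set of linearly independent columns."""
    keep: list[int] = []
    q: np.ndarray | None = None
    for j in range(x.shape[1]):
        col = x[:, j]
        scale = np.linalg.norm(col)
        if scale == 0:
            continue
        resid = col - q @ (q.T @ col) if q is not None else col.copy()
        if np.linalg.norm(resid) > rtol * scale:
            resid /= np.linalg.norm(resid)
            q = resid[:, None] if q is None else np.column_stack([q, resid])
            keep.append(j)
    return keep


def denoise_run(run: TimeSeriesMatrix, basis: ProjectionBasis) -> TimeSeriesMatrix:
    """Replace each voxel series by its least-squares residual against the basis.

    A projection: applying it twice equals applying it once, and per-voxel
    output variance never exceeds input variance.
    """
    if run.n_volumes != basis.n_volumes:
        raise ValueError(
            f"run has {run.n_volumes} volumes, basis expects {basis.n_volumes}"
        )
    q, _ = np.linalg.qr(basis.regressors)
    resid = run.data - q @ (q.T @ run.data)
    return TimeSeriesMatrix(
        grid=run.grid, mask=run.mask, data=resid, tr=run.tr, run_id=run.run_id
    )


def _zscore_columns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; zero-variance columns become 0 (flag returned)."""
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    degenerate = sd <= 0
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (data - mean) / safe_sd
    z[:, degenerate] = 0.0
    return z, degenerate


def seed_fc_map(
    runs: list[TimeSeriesMatrix],
    seed: Mask,
    analysis_mask: Mask | None = None,
    subject_id: str = "",
) -> "FCMap":
    """Fisher-z seed connectivity map from one subject's (denoised) runs.

    Per run, every voxel series is z-scored and the seed time course is the
    mean of the z-scored seed-voxel series; runs are then concatenated and a
    single Pearson correlation per voxel is taken against the seed course.
    Per-run standardization makes the map invariant to run-level affine
    rescaling of the data.
    """
    if not runs:
        raise ValueError("need at least one run")
    data_mask = runs[0].mask
    if analysis_mask is None:
        analysis_mask = data_mask
    for r in runs[1:]:
        if r.mask.n_voxels != data_mask.n_voxels or not np.array_equal(
            r.mask.indices, data_mask.indices
        ):
            raise ValueError("all runs must share the same mask")

    seed_cols = _subset_columns(data_mask, seed)
    out_cols = _subset_columns(data_mask, analysis_mask)

    seed_parts = []
    voxel_parts = []
    any_degenerate = np.zeros(len(out_cols), dtype=bool)
    for run in runs:
        z, degenerate = _zscore_columns(run.data)
        seed_z = z[:, seed_cols]
        if np.all(degenerate[seed_cols]):
            raise ValueError(f"seed has zero variance in run {run.run_id!r}")
        seed_course = seed_z.mean(axis=1)
        sd = seed_course.std(ddof=0)
        if sd <= 0:
            raise ValueError(f"seed time course constant in run {run.run_id!r}")
        seed_parts.append((seed_course - seed_course.mean()) / sd)
        voxel_parts.append(z[:, out_cols])
        any_degenerate |= degenerate[out_cols]

    seed_all = np.concatenate(seed_parts)
    vox_all = np.vstack(voxel_parts)
    t_total = seed_all.shape[0]

    seed_std = (seed_all - seed_all.mean()) / seed_all.std(ddof=0)
    vox_std, vox_degenerate = _zscore_columns(vox_all)
    r = seed_std @ vox_std / t_total
    degenerate = any_degenerate | vox_degenerate
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance voxel series set to z=0",
            RuntimeWarning,
            stacklevel=2,
        )
    r = np.clip(r, -CORRELATION_CLAMP, CORRELATION_CLAMP)
    z_map = np.arctanh(r)
    z_map[degenerate] = 0.0
    return FCMap(subject_id=subject_id, mask=analysis_mask, values=z_map, seed=seed)


def _subset_columns(data_mask: Mask, sub: Mask) -> np.ndarray:
    """Column positions in ``data_mask`` ordering of the voxels of ``sub``."""
    data_mask.grid.require_match(sub.grid, what="sub-mask")
    flat_all = data_mask.flat_index()
    flat_sub = sub.flat_index()
    pos = np.searchsorted(flat_all, flat_sub)
    ok = (pos < flat_all.size) & (flat_all[np.minimum(pos, flat_all.size - 1)] == flat_sub)
    if not np.all(ok):
        raise ValueError("sub-mask contains voxels outside the data mask")
    return pos


@dataclasses.dataclass
class FCMap:
    """Per-subject voxel-wise Fisher-z seed connectivity within a mask."""

    subject_id: str
    mask: Mask
    values: np.ndarray  # (n_voxels,) Fisher z
    seed: Mask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError("values length must equal mask.n_voxels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FC map contains non-finite values")
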
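"""Cluster-extent inference: smoothness estimation, Monte-Carlo size
thresholds, and supra-threshold cluster labeling.

Family-wise error over the analysis mask is controlled with the classic
AlphaSim-style approach: simulate Gaussian noise fields at the smoothness
estimated from the data's residual maps, threshold each at the voxel-forming
level, and take the cluster-size threshold that bounds the chance of any
supra-threshold cluster of that size at the corrected alpha.

Smoothness is expressed as the FWHM of the effective Gaussian spatial
autocorrelation, estimated per axis from the variance of first spatial
differences of residual maps:

    FWHM_a = voxel_size_a * sqrt(-2 ln 2 / ln(1 - var(diff_a) / (2 var)))

which inverts the autocorrelation of Gaussian-smoothed white noise at lag
one voxel.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, stats

from .nifti_io import Mask
from .variance import StatMap

__all__ = [
    "SmoothnessEstimate",
    "Cluster",
    "ClusterSet",
    "estimate_fwhm",
    "monte_carlo_cluster_threshold",
    "label_clusters",
]

_SIGMA_PER_FWHM = 1.0 / np.sqrt(8.0 * np.log(2.0))

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class SmoothnessEstimate:
    """Per-axis Gaussian FWHM (mm) of a map's spatial autocorrelation."""

    fwhm: tuple[float, float, float]
    source: str = ""

    @property
    def fwhm_iso(self) -> float:
        fx, fy, fz = self.fwhm
        return float((fx * fy * fz) ** (1.0 / 3.0))

    def sigma_voxels(self, voxel_size) -> np.ndarray:
        """Equivalent Gaussian kernel sigma per axis, in voxel units."""
        return np.asarray(self.fwhm) * _SIGMA_PER_FWHM / np.asarray(voxel_size)


@dataclasses.dataclass(frozen=True)
class Cluster:
    id: int
    size: int
    peak_stat: float
    peak_ijk: tuple[int, int, int]


@dataclasses.dataclass
class ClusterSet:
    """Vetted supra-threshold clusters plus the per-voxel label vector."""

    labels: np.ndarray  # (n_voxels,) cluster id per mask voxel, 0 = background
    clusters: list[Cluster]
    size_threshold: int
    voxel_p: float
    connectivity: int
    corrected_alpha: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def significant_voxels(self) -> np.ndarray:
        return self.labels > 0


def estimate_fwhm(residual_maps: np.ndarray, mask: Mask, source: str = "") -> SmoothnessEstimate:
    """Estimate per-axis smoothness FWHM (mm) from subject x voxel residual maps.

    Uses only voxel pairs where both neighbors are inside the mask.  Axes
    where the difference variance is degenerate (autocorrelation outside
    (0, 1)) are reported as 0 mm with a warning.
    """
    maps = np.atleast_2d(np.asarray(residual_maps, dtype=np.float64))
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    if maps.shape[1] != mask.n_voxels:
        raise ValueError("map columns must align with mask voxels")
    mask_arr = mask.to_array()
    ijk = tuple(mask.indices.T)
    fwhm_axes = []
    for axis in range(3):
        # in-mask voxels whose +1 neighbor along `axis` is also in-mask
        shifted = np.roll(mask_arr, -1, axis=axis)
        shifted[tuple(-1 if a == axis else slice(None) for a in range(3))] = False
        pair = mask_arr & shifted
        if not pair.any():
            warnings.warn(f"axis {axis}: no in-mask neighbor pairs", RuntimeWarning)
            fwhm_axes.append(0.0)
            continue
        per_map = []
        vol = np.zeros(mask.grid.shape)
        for m in maps:
            vol[ijk] = m
            diff = np.take(vol, np.arange(1, vol.shape[axis]), axis=axis) - np.take(
                vol, np.arange(vol.shape[axis] - 1), axis=axis
            )
            d = diff[np.take(pair, np.arange(pair.shape[axis] - 1), axis=axis)]
            s2 = m.var(ddof=1)
            s2d = d.var(ddof=1) if d.size > 1 else 0.0
            if s2 <= 0:
                continue
            rho = 1.0 - s2d / (2.0 * s2)
            if not (0.0 < rho < 1.0):
                continue
            per_map.append(float(np.sqrt(-2.0 * np.log(2.0) / np.log(rho))))
        if per_map:
            fwhm_axes.append(float(np.mean(per_map)) * mask.grid.voxel_size[axis])
        else:
            warnings.warn(
                f"axis {axis}: smoothness not estimable (degenerate difference "
                "variance); reporting 0",
                RuntimeWarning,
            )
            fwhm_axes.append(0.0)
    return SmoothnessEstimate(fwhm=tuple(fwhm_axes), source=source)


def simulate_null_field(
    mask_arr: np.ndarray,
    sigma_vox: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One standardized smooth Gaussian null map restricted to the mask."""
    noise = rng.standard_normal(mask_arr.shape)
    if np.any(sigma_vox > 0):
        # wrap boundaries keep the null field stationary across the grid
        noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    vals = noise[mask_arr]
    sd = vals.std(ddof=0)
    return (vals - vals.mean()) / (sd if sd > 0 else 1.0)


def monte_carlo_cluster_threshold(
    mask: Mask,
    smoothness: SmoothnessEstimate,
    voxel_p: float = 0.05,
    corrected_alpha: float = 0.05,
    n_iterations: int = 1000,
    connectivity: int = 6,
    rng_seed: int = 0,
) -> int:
    """Cluster-size threshold controlling FWER at ``corrected_alpha``.

    Each iteration fills the grid with white Gaussian noise, convolves it to
    the target smoothness, re-standardizes within the mask, thresholds at the
    two-tailed normal quantile of ``voxel_p`` and records the maximum cluster
    size.  Returns the smallest integer s with
    P(max null cluster size >= s) <= corrected_alpha.
    """
    if not (0.0 < voxel_p < 1.0):
        raise ValueError("voxel_p must be in (0, 1)")
    if n_iterations < 100:
        raise ValueError("need at least 100 iterations")
    structure = _structure(connectivity)
    rng = np.random.default_rng(rng_seed)
    mask_arr = mask.to_array()
    sigma_vox = smoothness.sigma_voxels(mask.grid.voxel_size)
    z_crit = stats.norm.isf(voxel_p / 2.0)
    vol = np.zeros(mask.grid.shape, dtype=bool)
    in_mask = tuple(mask.indices.T)
    max_sizes = np.empty(n_iterations, dtype=np.int64)
    for it in range(n_iterations):
        z = simulate_null_field(mask_arr, sigma_vox, rng)
        vol[...] = False
        vol[in_mask] = np.abs(z) >= z_crit
        labeled, n_lab = ndimage.label(vol, structure=structure)
        if n_lab == 0:
            max_sizes[it] = 0
        else:
            max_sizes[it] = np.bincount(labeled[vol]).max()
    # smallest s with #{max >= s} <= alpha * n: one more than the
    # (floor(alpha n)+1)-th largest max size
    k = int(np.floor(corrected_alpha * n_iterations))
    sorted_desc = np.sort(max_sizes)[::-1]
    return int(sorted_desc[k]) + 1


def label_clusters(
    stat: StatMap,
    voxel_p: float,
    size_threshold: int,
    connectivity: int = 6,
) -> ClusterSet:
    """Connected components of {p < voxel_p}, dropping those below the size
    threshold.  Cluster ids are deterministic: ordered by size descending,
    ties broken by peak coordinate."""
    structure = _structure(connectivity)
    mask = stat.mask
    vol = np.zeros(mask.grid.shape, dtype=bool)
    in_mask = tuple(mask.indices.T)
    vol[in_mask] = stat.p < voxel_p
    labeled, n_lab = ndimage.label(vol, structure=structure)
    comp_labels = labeled[in_mask]  # per mask voxel, 0 where sub-threshold
    stat_vals = stat.statistic

    records = []
    for lab in range(1, n_lab + 1):
        sel = comp_labels == lab
        size = int(sel.sum())
        if size < size_threshold:
            continue
        vox_pos = np.flatnonzero(sel)
        peak_pos = vox_pos[np.argmax(np.abs(stat_vals[vox_pos]))]
        records.append(
            (size, tuple(int(c) for c in mask.indices[peak_pos]),
             float(stat_vals[peak_pos]), lab)
        )
    records.sort(key=lambda r: (-r[0], r[1]))

    labels_out = np.zeros(mask.n_voxels, dtype=np.int32)
    clusters = []
    for new_id, (size, peak_ijk, peak_stat, old_lab) in enumerate(records, start=1):
        labels_out[comp_labels == old_lab] = new_id
        clusters.append(
            Cluster(id=new_id, size=size, peak_stat=peak_stat, peak_ijk=peak_ijk)
        )
    return ClusterSet(
        labels=labels_out,
        clusters=clusters,
        size_threshold=int(size_threshold),
        voxel_p=float(voxel_p),
        connectivity=int(connectivity),
        corrected_alpha=np.nan,
    )


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
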
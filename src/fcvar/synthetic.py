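"""Synthetic multi-subject BOLD cohorts with planted seed connectivity.

The generator emulates the structure of a two/three-group resting-state-style
seed-connectivity study: each subject contributes several runs of volumetric
time series in which designated effect-region voxels are coupled to a latent
seed signal, with the coupling strength chosen per subject so that the ideal
measured correlation equals tanh(z_s), z_s drawn from the subject's group
distribution N(mu_g, sigma_g^2) on the Fisher-z scale.  Across-subject FC
variance therefore differs between groups exactly as planted, which is what
the downstream homogeneity-of-variance mapping must recover.

Voxel noise is white Gaussian, spatially smoothed to a target FWHM and
re-standardized so the per-voxel noise SD stays at ``noise_sd``.  Seed voxels
use an independent noise field from the rest of the volume, so the
seed-target noise covariance is zero by construction and the closed-form
coupling solve stays exact; the seed-mean noise variance is computed from
the actual smoothing kernel (for unsmoothed noise it reduces to
noise_sd^2 / n_seed_voxels).

Linear drift and motion-like nuisance regressors are mixed into every voxel
with subject-specific weights and recorded in per-run confound tables, so
confound regression has something real to remove.  Subject-level covariates
(age, task accuracy, reaction time) are drawn with configurable group means
and optional linear coupling to the subject's planted z.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .nifti_io import Mask, TimeSeriesMatrix, VoxelGrid, write_stat_map

__all__ = [
    "EffectRegion",
    "CovariateSpec",
    "CohortConfig",
    "SyntheticTruth",
    "SubjectData",
    "Cohort",
    "expected_correlation",
    "coupling_for_correlation",
    "simulate_subject",
    "generate_cohort",
    "write_cohort",
    "simulate_fc_cohort",
    "default_config",
]

_SIGMA_PER_FWHM = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclasses.dataclass
class EffectRegion:
    """A mask whose voxels are coupled to the seed, with per-group planted
    Fisher-z mean and across-subject SD."""

    name: str
    mask: Mask
    mu: dict[str, float]  # group label -> mean Fisher z
    sigma: dict[str, float]  # group label -> across-subject SD of Fisher z


@dataclasses.dataclass
class CovariateSpec:
    """Gaussian subject covariate with per-group location/scale and linear
    coupling to the subject's planted z (deviation from the group mean)."""

    name: str
    mean: dict[str, float]
    sd: dict[str, float]
    coupling: float = 0.0


@dataclasses.dataclass
class CohortConfig:
    groups: list[tuple[str, int]]
    n_runs: int
    volumes_per_run: int
    tr: float
    grid: VoxelGrid
    seed_region: Mask
    effect_regions: list[EffectRegion]
    noise_sd: float = 1.0
    spatial_fwhm: float = 0.0  # mm
    drift_amplitude: float = 1.0
    n_motion_regressors: int = 6
    covariate_spec: list[CovariateSpec] = dataclasses.field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for _, n in self.groups) or not self.groups:
            raise ValueError("every group needs at least 1 subject")
        if self.n_runs < 1 or self.volumes_per_run < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.spatial_fwhm < 0:
            raise ValueError("spatial_fwhm must be >= 0")
        seed_flat = set(self.seed_region.flat_index().tolist())
        for reg in self.effect_regions:
            self.grid.require_match(reg.mask.grid, what=f"effect region {reg.name}")
            if seed_flat & set(reg.mask.flat_index().tolist()):
                raise ValueError(f"effect region {reg.name!r} overlaps the seed")
            for label, _ in self.groups:
                if label not in reg.mu or label not in reg.sigma:
                    raise ValueError(f"region {reg.name!r} missing group {label!r}")
                if reg.sigma[label] < 0:
                    raise ValueError("sigma must be >= 0")
        self.grid.require_match(self.seed_region.grid, what="seed region")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth against which recovery is scored."""

    subject_z: pd.DataFrame  # subject x region planted Fisher z
    group_params: dict[str, dict[str, tuple[float, float]]]  # region -> group -> (mu, sigma)
    effect_regions: list[EffectRegion]
    cohort_table: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "subject_z": {
                c: dict(zip(self.subject_z.index, self.subject_z[c]))
                for c in self.subject_z.columns
            },
            "group_params": {
                reg: {g: list(ms) for g, ms in by_group.items()}
                for reg, by_group in self.group_params.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclasses.dataclass
class SubjectData:
    subject_id: str
    group: str
    runs: list[TimeSeriesMatrix]
    confounds: list[pd.DataFrame]  # one table per run, aligned rows


@dataclasses.dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]
    cohort_table: pd.DataFrame
    truth: SyntheticTruth


def expected_correlation(
    w: float, target_noise_sd: float, seed_noise_sd: float, n_seed_voxels: int
) -> float:
    """Ideal seed-target correlation for coupling ``w`` with i.i.d. voxel noise.

    The seed course is the mean of n voxel series g + eta_i (unit-variance
    latent signal g, noise SD ``seed_noise_sd``); the target series is
    w*g + eps with noise SD ``target_noise_sd``:

        r = w / sqrt((1 + seed_sd^2 / n) * (w^2 + target_sd^2))
    """
    if target_noise_sd < 0 or seed_noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    seed_var = 1.0 + seed_noise_sd**2 / n_seed_voxels
    target_var = w**2 + target_noise_sd**2
    if target_var == 0:
        return 0.0
    return float(w / np.sqrt(seed_var * target_var))


def coupling_for_correlation(
    r: float, target_noise_sd: float, seed_mean_noise_var: float
) -> float:
    """Invert ``expected_correlation`` for the coupling weight.

    ``seed_mean_noise_var`` is the variance of the noise in the seed-mean
    course (seed_sd^2/n for i.i.d. noise; larger when the noise is spatially
    smoothed).  Requires r^2 * (1 + seed_mean_noise_var) < 1.
    """
    s = 1.0 + seed_mean_noise_var
    denom = 1.0 - r * r * s
    if denom <= 0:
        raise ValueError(f"correlation {r} infeasible with seed-mean noise var "
                         f"{seed_mean_noise_var}")
    return float(r * target_noise_sd * np.sqrt(s / denom))


def _smoothing_scale(shape: tuple[int, ...], sigma_vox: np.ndarray) -> float:
    """1/||kernel row||_2 of the circulant (wrap-mode) Gaussian filter on
    ``shape``: the factor that restores unit per-voxel variance of smoothed
    white noise."""
    delta = np.zeros(shape)
    delta[tuple(s // 2 for s in shape)] = 1.0
    resp = ndimage.gaussian_filter(delta, sigma=sigma_vox, mode="wrap")
    return 1.0 / np.sqrt(float((resp**2).sum()))


def smoothed_unit_noise(
    shape: tuple[int, ...],
    sigma_vox: np.ndarray,
    rng: np.random.Generator,
    n_volumes: int | None = None,
) -> np.ndarray:
    """White noise smoothed to ``sigma_vox`` with exactly unit per-voxel SD.

    Smoothing uses circular (wrap) boundaries, making the field strictly
    stationary: every voxel, including edge voxels, has the same variance and
    the same local autocorrelation, at the cost of a wrap-around correlation
    between opposite faces of the volume.
    """
    sigma_vox = np.asarray(sigma_vox, dtype=float)
    full = shape if n_volumes is None else shape + (n_volumes,)
    noise = rng.standard_normal(full)
    if not np.any(sigma_vox > 0):
        return noise
    sig = tuple(sigma_vox) if n_volumes is None else tuple(sigma_vox) + (0.0,)
    noise = ndimage.gaussian_filter(noise, sigma=sig, mode="wrap")
    return noise * _smoothing_scale(shape, sigma_vox)


class _NoiseModel:
    """Smoothed, re-standardized noise fields plus exact seed-mean statistics."""

    def __init__(self, config: CohortConfig):
        self.grid = config.grid
        self.noise_sd = config.noise_sd
        vs = np.asarray(config.grid.voxel_size)
        self.sigma_vox = np.where(
            vs > 0, config.spatial_fwhm * _SIGMA_PER_FWHM / vs, 0.0
        )
        self.smooth = bool(np.any(self.sigma_vox > 0))
        self.rescale = (
            _smoothing_scale(config.grid.shape, self.sigma_vox) if self.smooth else 1.0
        )
        # variance of the mean noise over the seed: ||K^T u||^2 for
        # u = indicator/n (K symmetric circulant), times rescale^2 * noise_sd^2
        u = np.zeros(config.grid.shape)
        u[tuple(config.seed_region.indices.T)] = 1.0 / config.seed_region.n_voxels
        ku = (
            ndimage.gaussian_filter(u, sigma=self.sigma_vox, mode="wrap")
            if self.smooth
            else u
        )
        self.seed_mean_noise_var = float(
            (ku**2).sum() * self.rescale**2 * self.noise_sd**2
        )

    def field(self, rng: np.random.Generator, n_volumes: int) -> np.ndarray:
        """(x, y, z, t) noise with per-voxel SD noise_sd, smoothed in space."""
        return (
            smoothed_unit_noise(self.grid.shape, self.sigma_vox, rng, n_volumes)
            * self.noise_sd
        )


def _draw_subject_z(
    config: CohortConfig, rng: np.random.Generator, group: str, noise: _NoiseModel
) -> dict[str, float]:
    """Planted per-region Fisher z, clamped to the feasible correlation range."""
    s = 1.0 + noise.seed_mean_noise_var
    r_max = 0.995 / np.sqrt(s)
    out = {}
    for reg in config.effect_regions:
        z = rng.normal(reg.mu[group], reg.sigma[group])
        r = np.clip(np.tanh(z), -r_max, r_max)
        out[reg.name] = float(np.arctanh(r))
    return out


def simulate_subject(
    config: CohortConfig,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    noise: _NoiseModel | None = None,
    subject_z: dict[str, float] | None = None,
) -> SubjectData:
    """One subject's runs plus confound tables (exact mixed-in regressors)."""
    if noise is None:
        noise = _NoiseModel(config)
    if subject_z is None:
        subject_z = _draw_subject_z(config, rng, group, noise)
    t = config.volumes_per_run
    grid = config.grid
    seed_ijk = tuple(config.seed_region.indices.T)

    couplings = {
        reg.name: coupling_for_correlation(
            np.tanh(subject_z[reg.name]), config.noise_sd, noise.seed_mean_noise_var
        )
        for reg in config.effect_regions
    }
    # subject-specific per-voxel nuisance weights, shared across runs
    n_nuis = 1 + config.n_motion_regressors
    nuis_weights = rng.normal(
        0.0, config.drift_amplitude, size=(n_nuis, grid.shape[0], grid.shape[1], grid.shape[2])
    )

    runs: list[TimeSeriesMatrix] = []
    confounds: list[pd.DataFrame] = []
    full_mask = Mask.from_array(np.ones(grid.shape, bool), grid)
    for run_idx in range(config.n_runs):
        g = rng.standard_normal(t)  # latent seed signal, white unit variance
        vol = noise.field(rng, t)  # background + effect noise
        for reg in config.effect_regions:
            w = couplings[reg.name]
            ijk = tuple(reg.mask.indices.T)
            vol[ijk] = w * g[None, :] + vol[ijk]
        seed_noise = noise.field(rng, t)
        vol[seed_ijk] = g[None, :] + seed_noise[seed_ijk]

        # nuisance regressors: linear drift + motion-like random walks
        regs = [np.linspace(-0.5, 0.5, t)]
        names = ["drift"]
        for m in range(config.n_motion_regressors):
            walk = np.cumsum(rng.standard_normal(t))
            walk = (walk - walk.mean()) / (walk.std(ddof=0) or 1.0)
            regs.append(walk)
            names.append(f"motion{m + 1}")
        for series, weights in zip(regs, nuis_weights):
            vol += weights[..., None] * series[None, None, None, :]

        data = vol[tuple(full_mask.indices.T)].T  # (time, voxel)
        runs.append(
            TimeSeriesMatrix(
                grid=grid, mask=full_mask, data=data, tr=config.tr,
                run_id=f"{subject_id}_run-{run_idx + 1:02d}",
            )
        )
        confounds.append(pd.DataFrame(dict(zip(names, regs))))
    return SubjectData(subject_id=subject_id, group=group, runs=runs, confounds=confounds)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort in memory; deterministic given config.rng_seed."""
    root = np.random.SeedSequence(config.rng_seed)
    noise = _NoiseModel(config)
    subject_rows = []
    z_rows = {}
    subjects = []
    subject_index = 0
    covariate_rng = np.random.default_rng(root.spawn(1)[0])
    for group, n in config.groups:
        for i in range(n):
            sid = f"sub-{subject_index + 1:03d}"
            # fixed substream per subject index: adding groups later never
            # shifts earlier subjects' data
            sub_ss = np.random.SeedSequence(
                entropy=config.rng_seed, spawn_key=(1, subject_index)
            )
            rng = np.random.default_rng(sub_ss)
            z = _draw_subject_z(config, rng, group, noise)
            subjects.append(
                simulate_subject(config, sid, group, rng, noise=noise, subject_z=z)
            )
            z_rows[sid] = z
            row = {"subject": sid, "group": group}
            z_mean_dev = np.mean(
                [z[reg.name] - reg.mu[group] for reg in config.effect_regions]
            )
            for cov in config.covariate_spec:
                row[cov.name] = (
                    cov.mean[group]
                    + cov.coupling * z_mean_dev
                    + covariate_rng.normal(0.0, cov.sd[group])
                )
            subject_rows.append(row)
            subject_index += 1

    cohort_table = pd.DataFrame(subject_rows)
    subject_z = pd.DataFrame(
        {reg.name: {sid: z_rows[sid][reg.name] for sid in z_rows}
         for reg in config.effect_regions}
    )
    truth = SyntheticTruth(
        subject_z=subject_z,
        group_params={
            reg.name: {g: (reg.mu[g], reg.sigma[g]) for g, _ in config.groups}
            for reg in config.effect_regions
        },
        effect_regions=config.effect_regions,
        cohort_table=cohort_table,
    )
    return Cohort(config=config, subjects=subjects, cohort_table=cohort_table, truth=truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Emit the cohort as NIfTI runs + TSV confounds/cohort table + JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cohort.config.grid
    for sub in cohort.subjects:
        sub_dir = out / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        for run_idx, (run, conf) in enumerate(zip(sub.runs, sub.confounds), start=1):
            vol = np.zeros(grid.shape + (run.n_volumes,), dtype=np.float32)
            vol[tuple(run.mask.indices.T)] = run.data.T
            img = nib.Nifti1Image(vol, grid.affine)
            img.header.set_zooms(grid.voxel_size + (cohort.config.tr,))
            nib.save(img, str(sub_dir / f"run-{run_idx:02d}.nii"))
            conf.to_csv(sub_dir / f"run-{run_idx:02d}_confounds.tsv",
                        sep="\t", index=False, float_format="%.10g")
    cohort.cohort_table.to_csv(out / "cohort.tsv", sep="\t", index=False,
                               float_format="%.10g")
    (out / "truth.json").write_text(cohort.truth.to_json())
    write_stat_map(np.ones(cohort.config.seed_region.n_voxels),
                   cohort.config.seed_region, out / "seed.nii")
    for reg in cohort.config.effect_regions:
        write_stat_map(np.ones(reg.mask.n_voxels), reg.mask,
                       out / f"effect-{reg.name}.nii")


def simulate_fc_cohort(
    groups: list[tuple[str, int]],
    mask: Mask,
    effect_regions: list[EffectRegion],
    noise_sd: float = 0.15,
    spatial_fwhm: float = 6.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Subject x voxel Fisher-z maps drawn directly at the map level.

    Shortcut for group-level studies of the variance-mapping and cluster
    stages.  Each subject's map is smooth measurement noise of per-voxel SD
    ``noise_sd`` (roughly the sampling error of z at the study's time-series
    length); inside each effect region the subject additionally carries
    mu_g + sigma_g * f_s(v), where f_s is a subject-specific unit-variance
    field smoothed to ``spatial_fwhm``.  Every region voxel therefore has
    across-subject SD exactly sqrt(sigma_g^2 + noise_sd^2), while nearby
    voxels decorrelate over the smoothing scale -- mirroring the fact that a
    subject's connectivity deviation is spatially smooth but not constant
    over a region.  Returns (fc_matrix, group_labels, subject_z_table) where
    the table records each subject's planted region-mean z.
    """
    rng = np.random.default_rng(rng_seed)
    vs = np.asarray(mask.grid.voxel_size)
    sigma_vox = spatial_fwhm * _SIGMA_PER_FWHM / vs
    region_cols = []
    for reg in effect_regions:
        flat_all = mask.flat_index()
        pos = np.searchsorted(flat_all, reg.mask.flat_index())
        region_cols.append(pos)

    n_total = sum(n for _, n in groups)
    fc = np.empty((n_total, mask.n_voxels))
    labels = np.empty(n_total, dtype=object)
    z_rows = []
    in_mask = tuple(mask.indices.T)
    i = 0
    for group, n in groups:
        for _ in range(n):
            noise = smoothed_unit_noise(mask.grid.shape, sigma_vox, rng)
            row = noise[in_mask] * noise_sd
            z_rec = {"group": group}
            for reg, cols in zip(effect_regions, region_cols):
                field = smoothed_unit_noise(mask.grid.shape, sigma_vox, rng)
                planted = (
                    reg.mu[group]
                    + reg.sigma[group] * field[tuple(reg.mask.indices.T)]
                )
                row[cols] += planted
                z_rec[reg.name] = float(planted.mean())
            fc[i] = row
            labels[i] = group
            z_rows.append(z_rec)
            i += 1
    return fc, np.asarray(labels), pd.DataFrame(z_rows)


def default_config(
    rng_seed: int = 0,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_size_mm: float = 2.0,
    three_groups: bool = False,
    n_runs: int = 10,
    volumes_per_run: int = 180,
) -> CohortConfig:
    """Study-shaped default cohort: groups of 16 (+23) / 33 subjects, 10 runs
    of 180 volumes at TR 2 s, a central seed, one effect region with twice the
    across-subject FC SD in the deaf group, 6 mm smooth noise, and age /
    accuracy / reaction-time covariates with the hearing group younger."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    grid = VoxelGrid(shape=grid_shape, voxel_size=(voxel_size_mm,) * 3, affine=affine)
    cx, cy, cz = (s // 2 for s in grid_shape)
    seed_arr = np.zeros(grid_shape, bool)
    seed_arr[cx - 1 : cx + 2, cy - 1 : cy + 2, cz - 1 : cz + 2] = True
    seed = Mask.from_array(seed_arr, grid)
    eff_arr = np.zeros(grid_shape, bool)
    side = min(5, cx - 1)  # corner block, clear of the central seed
    if side < 2:
        raise ValueError("grid too small to place disjoint seed and effect regions")
    eff_arr[:side, :side, :side] = True
    groups = (
        [("native_deaf", 16), ("delayed_deaf", 23), ("hearing", 33)]
        if three_groups
        else [("deaf", 16), ("hearing", 33)]
    )
    deaf_labels = [g for g, _ in groups if g != "hearing"]
    mu = {g: 0.5 for g, _ in groups}
    sigma = {g: (0.4 if g in deaf_labels else 0.2) for g, _ in groups}
    region = EffectRegion(
        name="effect1", mask=Mask.from_array(eff_arr, grid), mu=mu, sigma=sigma
    )
    covs = [
        CovariateSpec(
            "age",
            mean={**{g: 28.0 for g in deaf_labels}, "hearing": 23.0},
            sd={g: 4.0 for g, _ in groups},
        ),
        CovariateSpec(
            "accuracy",
            mean={**{g: 0.74 for g in deaf_labels}, "hearing": 0.89},
            sd={g: 0.06 for g, _ in groups},
        ),
        CovariateSpec(
            "rt",
            mean={**{g: 1.083 for g in deaf_labels}, "hearing": 1.147},
            sd={g: 0.15 for g, _ in groups},
        ),
    ]
    return CohortConfig(
        groups=groups,
        n_runs=n_runs,
        volumes_per_run=volumes_per_run,
        tr=2.0,
        grid=grid,
        seed_region=seed,
        effect_regions=[region],
        noise_sd=1.0,
        spatial_fwhm=6.0,
        drift_amplitude=1.0,
        n_motion_regressors=6,
        covariate_spec=covs,
        rng_seed=rng_seed,
    )
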
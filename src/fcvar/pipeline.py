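"""End-to-end pipeline: simulate -> fc -> varmap -> cluster -> ratio ->
groupdiff -> spatialcorr -> roicorr, driven by one YAML config.

Every stage reads its inputs from, and writes its outputs to, the run's
output directory, so stages are individually re-runnable and the whole run
is reproducible from the config alone.  A single global seed spawns a fixed
per-stage substream (keyed by stage index, not execution order), so toggling
stages never shifts another stage's randomness.  Stage outputs are cached
keyed by a digest of the stage parameters and input files; a digest mismatch
triggers recomputation with a warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import denoise as dn
from . import group_factor as gf
from . import nifti_io as io
from . import spatial as sp
from . import synthetic as syn
from . import variance as vm

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "ConfigError", "DataError"]

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "fc", "varmap", "cluster", "ratio",
    "groupdiff", "spatialcorr", "roicorr",
]
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent input data (CLI exit code 3)."""


@dataclasses.dataclass
class PipelineConfig:
    out_dir: Path
    rng_seed: int
    stages: list[str]
    params: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        try:
            out_dir = Path(raw["out_dir"])
            rng_seed = int(raw["rng_seed"])
        except KeyError as exc:
            raise ConfigError(f"config missing required key {exc}") from exc
        if base is not None and not out_dir.is_absolute():
            out_dir = base / out_dir
        stages = raw.get("stages", STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return cls(out_dir=out_dir, rng_seed=rng_seed,
                   stages=[s for s in STAGES if s in stages], params=raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(
            entropy=self.rng_seed, spawn_key=(_STAGE_INDEX[stage],)
        )
        return int(ss.generate_state(1)[0] % (2**31))

    def stage_params(self, stage: str) -> dict:
        p = self.params.get(stage, {}) or {}
        if not isinstance(p, dict):
            raise ConfigError(f"stage section {stage!r} must be a mapping")
        return p


@dataclasses.dataclass
class RunReport:
    config_echo: dict
    stages: dict  # stage -> {params, inputs, output_digests, headline, cached}
    timings: dict  # stage -> seconds (excluded from determinism)

    def to_json(self) -> str:
        payload = {"config": _jsonable(self.config_echo), "stages": _jsonable(self.stages)}
        return json.dumps(payload, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(obj), sort_keys=True).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# shared loading helpers

def _load_grid_and_masks(data_dir: Path):
    gm_img = data_dir / "gm.nii"
    seed_img = data_dir / "seed.nii"
    for p in (gm_img, seed_img):
        if not p.exists():
            raise DataError(f"missing mask image: {p}")
    import nibabel as nib

    ref = io.VoxelGrid.from_img(nib.load(str(gm_img)))
    gm = io.load_mask(gm_img, ref)
    seed = io.load_mask(seed_img, ref)
    return ref, gm, seed


def _load_cohort_table(data_dir: Path) -> pd.DataFrame:
    path = data_dir / "cohort.tsv"
    if not path.exists():
        raise DataError(f"missing cohort table: {path}")
    return pd.read_csv(path, sep="\t")


def _load_fc_matrix(cfg: PipelineConfig, table: pd.DataFrame, gm: io.Mask) -> np.ndarray:
    import nibabel as nib

    fc_dir = cfg.out_dir / "fc"
    rows = []
    for sid in table["subject"]:
        path = fc_dir / f"{sid}_z.nii"
        if not path.exists():
            raise DataError(f"missing FC map: {path}")
        arr = np.asanyarray(nib.load(str(path)).dataobj)
        rows.append(arr[tuple(gm.indices.T)].astype(np.float64))
    return np.vstack(rows)


def _varmap_design(cfg: PipelineConfig, table: pd.DataFrame):
    p = cfg.stage_params("varmap")
    groups = p.get("groups")
    if groups:
        table = table[table["group"].isin(groups)].reset_index(drop=True)
        if table.empty:
            raise ConfigError(f"no subjects in groups {groups}")
    cov_names = p.get("covariates", [])
    missing = [c for c in cov_names if c not in table.columns]
    if missing:
        raise ConfigError(f"covariates {missing} not in cohort table")
    design = vm.GroupDesign(
        subject_ids=list(table["subject"]),
        group_labels=table["group"].to_numpy(),
        covariates=table[cov_names].copy() if cov_names else pd.DataFrame(index=table.index),
    )
    return table, design


def _bf_pipeline(cfg: PipelineConfig, gm: io.Mask):
    """Residualized FC + BF map + signed median-centered residual maps."""
    table = _load_cohort_table(cfg.out_dir / "data")
    table, design = _varmap_design(cfg, table)
    fc = _load_fc_matrix(cfg, table, gm)
    resid = vm.residualize(fc, design)
    bf = vm.brown_forsythe_map(resid, design.group_labels, mask=gm)
    centered = np.empty_like(resid)
    for g in design.levels:
        sel = design.group_labels == g
        centered[sel] = resid[sel] - np.median(resid[sel], axis=0)
    return table, design, fc, resid, bf, centered


def _cluster_set(cfg: PipelineConfig, gm: io.Mask, bf, centered) -> tuple[cl.ClusterSet, cl.SmoothnessEstimate, int]:
    p = cfg.stage_params("cluster")
    voxel_p = float(p.get("voxel_p", 0.05))
    alpha = float(p.get("alpha", 0.05))
    iters = int(p.get("iterations", 1000))
    conn = int(p.get("connectivity", 6))
    smooth = cl.estimate_fwhm(centered, gm, source="brown-forsythe residuals")
    size_thr = cl.monte_carlo_cluster_threshold(
        gm, smooth, voxel_p=voxel_p, corrected_alpha=alpha,
        n_iterations=iters, connectivity=conn, rng_seed=cfg.stage_seed("cluster"),
    )
    cs = cl.label_clusters(bf, voxel_p=voxel_p, size_threshold=size_thr, connectivity=conn)
    cs.corrected_alpha = alpha
    return cs, smooth, size_thr


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig) -> dict:
    p = cfg.stage_params("simulate")
    config = syn.default_config(
        rng_seed=cfg.stage_seed("simulate"),
        grid_shape=tuple(p.get("grid_shape", (16, 16, 16))),
        voxel_size_mm=float(p.get("voxel_size_mm", 2.0)),
        three_groups=bool(p.get("three_groups", False)),
        n_runs=int(p.get("n_runs", 2)),
        volumes_per_run=int(p.get("volumes_per_run", 60)),
    )
    if "groups" in p:  # override subject counts for the default group labels
        override = {str(k): int(v) for k, v in dict(p["groups"]).items()}
        unknown = set(override) - {g for g, _ in config.groups}
        if unknown:
            raise ConfigError(f"unknown group labels in simulate.groups: {sorted(unknown)}")
        config = dataclasses.replace(
            config,
            groups=[(g, override.get(g, n)) for g, n in config.groups],
        )
    cohort = syn.generate_cohort(config)
    data_dir = cfg.out_dir / "data"
    syn.write_cohort(cohort, data_dir)
    io.write_stat_map(
        np.ones(config.grid.shape).ravel(),
        io.Mask.from_array(np.ones(config.grid.shape, bool), config.grid),
        data_dir / "gm.nii",
    )
    return {
        "n_subjects": len(cohort.subjects),
        "groups": {g: int(n) for g, n in config.groups},
        "n_runs": config.n_runs,
        "volumes_per_run": config.volumes_per_run,
    }


def _stage_fc(cfg: PipelineConfig) -> dict:
    p = cfg.stage_params("fc")
    band = tuple(p.get("band", (0.01, 0.1)))
    tr = float(p.get("tr", 2.0))
    discard = int(p.get("discard_initial", 0))
    data_dir = cfg.out_dir / "data"
    _, gm, seed = _load_grid_and_masks(data_dir)
    table = _load_cohort_table(data_dir)
    fc_dir = cfg.out_dir / "fc"
    fc_dir.mkdir(parents=True, exist_ok=True)
    report = {}
    for sid in table["subject"]:
        sub_dir = data_dir / sid
        run_paths = sorted(sub_dir.glob("run-*.nii"))
        run_paths = [r for r in run_paths if "confounds" not in r.name]
        if not run_paths:
            raise DataError(f"no runs found for {sid} in {sub_dir}")
        runs = []
        removed = []
        for rp in run_paths:
            run = io.load_volume4d(rp, gm, tr=tr, discard_initial=discard)
            conf_path = rp.with_name(rp.stem + "_confounds.tsv")
            conf = pd.read_csv(conf_path, sep="\t") if conf_path.exists() else None
            basis = dn.build_projection(
                conf.to_numpy() if conf is not None else None,
                run.n_volumes, tr, band,
                confound_names=list(conf.columns) if conf is not None else None,
            )
            den = dn.denoise_run(run, basis)
            var_in = run.data.var(axis=0).mean()
            var_out = den.data.var(axis=0).mean()
            removed.append(1.0 - var_out / var_in if var_in > 0 else 0.0)
            runs.append(den)
        fc_map = dn.seed_fc_map(runs, seed, gm, subject_id=sid)
        io.write_stat_map(fc_map.values, gm, fc_dir / f"{sid}_z.nii")
        report[sid] = {
            "n_runs": len(runs),
            "basis_rank": basis.rank,
            "mean_variance_removed": round(float(np.mean(removed)), 6),
        }
    (fc_dir / "denoise_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True)
    )
    return {"n_subjects": len(report), "band_hz": list(band)}


def _stage_varmap(cfg: PipelineConfig) -> dict:
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    table, design, fc, resid, bf, _ = _bf_pipeline(cfg, gm)
    out = cfg.out_dir / "varmap"
    out.mkdir(parents=True, exist_ok=True)
    io.write_stat_map(bf.statistic, gm, out / "bf_F.nii")
    io.write_stat_map(bf.p, gm, out / "bf_p.nii", background=1.0)
    return {
        "n_subjects": design.n_subjects,
        "groups": {str(g): int((design.group_labels == g).sum()) for g in design.levels},
        "df": list(bf.df),
        "n_voxel_p_lt_05": int((bf.p < 0.05).sum()),
    }


def _stage_cluster(cfg: PipelineConfig) -> dict:
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    _, design, fc, resid, bf, centered = _bf_pipeline(cfg, gm)
    cs, smooth, size_thr = _cluster_set(cfg, gm, bf, centered)
    out = cfg.out_dir / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    io.write_stat_map(cs.labels.astype(float), gm, out / "bf_clusters.nii")
    rows = [
        dict(id=c.id, size=c.size, peak_stat=round(c.peak_stat, 6),
             peak_i=c.peak_ijk[0], peak_j=c.peak_ijk[1], peak_k=c.peak_ijk[2])
        for c in cs.clusters
    ]
    pd.DataFrame(rows, columns=["id", "size", "peak_stat", "peak_i", "peak_j", "peak_k"]).to_csv(
        out / "bf_clusters.tsv", sep="\t", index=False
    )
    return {
        "fwhm_mm": [round(f, 4) for f in smooth.fwhm],
        "size_threshold": size_thr,
        "n_clusters": cs.n_clusters,
        "cluster_sizes": [c.size for c in cs.clusters],
    }


def _stage_ratio(cfg: PipelineConfig) -> dict:
    p = cfg.stage_params("ratio")
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    _, design, fc, resid, bf, centered = _bf_pipeline(cfg, gm)
    cs, _, _ = _cluster_set(cfg, gm, bf, centered)
    levels = list(design.levels)
    num = p.get("numerator", levels[0])
    den = p.get("denominator", levels[-1])
    vetted = cs.significant_voxels()
    out = cfg.out_dir / "ratio"
    out.mkdir(parents=True, exist_ok=True)
    if not vetted.any():
        io.write_stat_map(np.zeros(gm.n_voxels), gm, out / "ratio.nii")
        return {"n_vetted_voxels": 0, "median_ratio": None}
    rmap = vm.variability_ratio_map(
        resid, design.group_labels, num, den,
        restrict_to=vetted, mask=gm, spread=p.get("spread", "sd"),
    )
    vals = np.where(np.isfinite(rmap.ratio), rmap.ratio, 0.0)
    io.write_stat_map(vals, gm, out / "ratio.nii")
    med = float(np.nanmedian(rmap.ratio))
    return {
        "n_vetted_voxels": int(vetted.sum()),
        "median_ratio": round(med, 6),
        "numerator": str(num),
        "denominator": str(den),
    }


def _stage_groupdiff(cfg: PipelineConfig) -> dict:
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    _, design, fc, resid, bf, _ = _bf_pipeline(cfg, gm)
    anova, posthoc = gf.group_mean_map(resid, design, mask=gm)
    out = cfg.out_dir / "groupdiff"
    out.mkdir(parents=True, exist_ok=True)
    io.write_stat_map(anova.statistic, gm, out / "anova_F.nii")
    io.write_stat_map(anova.p, gm, out / "anova_p.nii", background=1.0)
    for (g1, g2), tmap in posthoc.items():
        io.write_stat_map(tmap.statistic, gm, out / f"t_{g1}_vs_{g2}.nii")
    return {
        "df": list(anova.df),
        "n_voxel_p_lt_05": int((anova.p < 0.05).sum()),
        "posthoc_pairs": sorted(f"{a}_vs_{b}" for a, b in posthoc),
    }


def _stage_spatialcorr(cfg: PipelineConfig) -> dict:
    p = cfg.stage_params("spatialcorr")
    iters = int(p.get("iterations", 1000))
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    _, design, fc, resid, bf, centered = _bf_pipeline(cfg, gm)
    anova, _ = gf.group_mean_map(resid, design, mask=gm)
    smooth = cl.estimate_fwhm(centered, gm, source="brown-forsythe residuals")
    result = sp.spatial_permutation_test(
        bf.statistic, anova.statistic, gm, smooth,
        n_iterations=iters, rng_seed=cfg.stage_seed("spatialcorr"),
    )
    out = cfg.out_dir / "spatialcorr"
    out.mkdir(parents=True, exist_ok=True)
    (out / "spatialcorr.json").write_text(
        json.dumps(_jsonable(result.summary()), indent=2, sort_keys=True)
    )
    return result.summary()


def _stage_roicorr(cfg: PipelineConfig) -> dict:
    p = cfg.stage_params("roicorr")
    _, gm, _ = _load_grid_and_masks(cfg.out_dir / "data")
    table, design, fc, resid, bf, centered = _bf_pipeline(cfg, gm)
    cs, _, _ = _cluster_set(cfg, gm, bf, centered)
    out = cfg.out_dir / "roicorr"
    out.mkdir(parents=True, exist_ok=True)
    factor_names = p.get("factors") or [
        c for c in table.columns if c not in ("subject", "group")
    ]
    if not cs.clusters or not factor_names:
        pd.DataFrame(columns=["roi", "factor", "n", "r", "p", "note", "q"]).to_csv(
            out / "roicorr.tsv", sep="\t", index=False
        )
        return {"n_rois": 0, "n_tests": 0}
    rois = gf.extract_rois(cs, gm, source="bf clusters")
    ftab = gf.FactorTable(
        subject_ids=list(table["subject"]),
        factors=table[factor_names].astype(float),
    )
    results, subject_values = gf.roi_factor_correlation(
        resid, rois, ftab, analysis_mask=gm
    )
    results.to_csv(out / "roicorr.tsv", sep="\t", index=False, float_format="%.10g")
    subject_values.to_csv(out / "roi_subject_values.tsv", sep="\t",
                          float_format="%.10g")
    n_sig = int((results["q"] < 0.05).sum())
    return {"n_rois": len(rois.rois), "n_tests": len(results), "n_q_lt_05": n_sig}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fc": _stage_fc,
    "varmap": _stage_varmap,
    "cluster": _stage_cluster,
    "ratio": _stage_ratio,
    "groupdiff": _stage_groupdiff,
    "spatialcorr": _stage_spatialcorr,
    "roicorr": _stage_roicorr,
}

_STAGE_OUTPUT_DIRS = {
    "simulate": "data", "fc": "fc", "varmap": "varmap", "cluster": "cluster",
    "ratio": "ratio", "groupdiff": "groupdiff", "spatialcorr": "spatialcorr",
    "roicorr": "roicorr",
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the enabled stages in dependency order and write report.json."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    cache_path = config.out_dir / ".stage_digests.json"
    cache = {}
    if cache_path.exists():
        try:
            cache = json.loads(cache_path.read_text())
        except json.JSONDecodeError:
            logger.warning("corrupt stage cache; recomputing all stages")
    stages_report = {}
    timings = {}
    for stage in config.stages:
        params = config.stage_params(stage)
        in_digest = _digest_obj(
            {"stage": stage, "params": params, "seed": config.stage_seed(stage)}
        )
        out_sub = config.out_dir / _STAGE_OUTPUT_DIRS[stage]
        cached_entry = cache.get(stage)
        if (
            cached_entry
            and cached_entry.get("input_digest") == in_digest
            and out_sub.exists()
            and _outputs_intact(out_sub, cached_entry.get("output_digests", {}))
        ):
            logger.info("stage %s: cache hit, skipping", stage)
            stages_report[stage] = {**cached_entry, "cached": True}
            continue
        if cached_entry:
            logger.warning("stage %s: stale cache, recomputing", stage)
        logger.info("stage %s: running (params digest %s)", stage, in_digest[:12])
        t0 = time.monotonic()
        try:
            headline = _STAGE_FUNCS[stage](config)
        except (ConfigError, DataError):
            raise
        except Exception as exc:
            raise DataError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.monotonic() - t0, 3)
        out_digests = {
            str(p.relative_to(config.out_dir)): _digest_file(p)
            for p in sorted(out_sub.rglob("*"))
            if p.is_file()
        }
        entry = {
            "params": _jsonable(params),
            "input_digest": in_digest,
            "output_digests": out_digests,
            "headline": _jsonable(headline),
            "cached": False,
        }
        stages_report[stage] = entry
        cache[stage] = entry
        cache_path.write_text(json.dumps(cache, indent=2, sort_keys=True))
    report = RunReport(
        config_echo=config.params, stages=stages_report, timings=timings
    )
    (config.out_dir / "report.json").write_text(report.to_json())
    return report


def _outputs_intact(out_sub: Path, digests: dict) -> bool:
    root = out_sub.parent
    for rel, dig in digests.items():
        p = root / rel
        if not p.exists() or _digest_file(p) != dig:
            return False
    return bool(digests)
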
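import numpy as np
import pytest

import fcvar
from fcvar import (
    CohortConfig,
    EffectRegion,
    Mask,
    coupling_for_correlation,
    expected_correlation,
    generate_cohort,
    seed_fc_map,
    simulate_fc_cohort,
)
from fcvar.denoise import build_projection, denoise_run
from fcvar.synthetic import _NoiseModel, simulate_subject, smoothed_unit_noise
from .conftest import box_mask, make_grid


def _tiny_config(seed=0, **kw):
    cfg = fcvar.default_config(rng_seed=seed, grid_shape=(10, 10, 10),
                               n_runs=kw.pop("n_runs", 1),
                               volumes_per_run=kw.pop("volumes_per_run", 80))
    cfg.groups = kw.pop("groups", [("deaf", 2), ("hearing", 3)])
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestExpectedCorrelation:
    def test_closed_forms(self):
        assert expected_correlation(1.0, 1.0, 0.0, 5) == pytest.approx(1 / np.sqrt(2))
        assert expected_correlation(0.0, 1.0, 1.0, 5) == 0.0

    def test_monte_carlo_oracle(self, rng):
        """Closed form matches brute-force simulation of the generative model."""
        w, t_sd, s_sd, n_seed = 0.75, 1.2, 1.0, 30
        t = 200_000
        g = rng.standard_normal(t)
        seed_mean = g + rng.standard_normal((n_seed, t)).mean(axis=0) * s_sd
        target = w * g + rng.standard_normal(t) * t_sd
        r_emp = np.corrcoef(seed_mean, target)[0, 1]
        assert abs(expected_correlation(w, t_sd, s_sd, n_seed) - r_emp) < 0.005

    def test_inverse_solve_roundtrip(self):
        for r in [0.1, 0.46, 0.8, -0.3]:
            v = 0.04
            w = coupling_for_correlation(r, 1.0, v)
            assert expected_correlation(w, 1.0, np.sqrt(v * 25), 25) == pytest.approx(r)

    def test_infeasible_correlation_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            coupling_for_correlation(0.99, 1.0, 0.5)


class TestSmoothedNoise:
    def test_unit_variance_everywhere_including_edges(self, rng):
        field = smoothed_unit_noise((8, 8, 8), np.array([1.3, 1.3, 1.3]), rng, 4000)
        v = field.var(axis=-1)
        assert abs(v[0, 0, 0] - 1.0) < 0.1  # corner
        assert abs(v[4, 4, 4] - 1.0) < 0.1  # interior
        assert abs(v.mean() - 1.0) < 0.02


class TestGenerateCohort:
    def test_shapes_and_reproducibility(self):
        cfg = _tiny_config(seed=5, n_runs=2, volumes_per_run=30)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        assert len(c1.subjects) == 5
        assert all(len(s.runs) == 2 for s in c1.subjects)
        assert all(r.n_volumes == 30 for s in c1.subjects for r in s.runs)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            for r1, r2 in zip(s1.runs, s2.runs):
                np.testing.assert_array_equal(r1.data, r2.data)
        assert c1.cohort_table.equals(c2.cohort_table)
        assert c1.truth.subject_z.equals(c2.truth.subject_z)

    def test_different_seeds_differ(self):
        c1 = generate_cohort(_tiny_config(seed=1, volumes_per_run=20))
        c2 = generate_cohort(_tiny_config(seed=2, volumes_per_run=20))
        assert not np.array_equal(c1.subjects[0].runs[0].data, c2.subjects[0].runs[0].data)

    def test_overlapping_seed_and_effect_rejected(self):
        cfg = _tiny_config()
        bad = EffectRegion(
            name="bad", mask=cfg.seed_region,
            mu={g: 0.0 for g, _ in cfg.groups}, sigma={g: 0.1 for g, _ in cfg.groups},
        )
        with pytest.raises(ValueError, match="overlaps"):
            CohortConfig(
                groups=cfg.groups, n_runs=1, volumes_per_run=10, tr=2.0,
                grid=cfg.grid, seed_region=cfg.seed_region, effect_regions=[bad],
            )

    def test_covariate_coupling_and_group_offsets(self):
        cfg = _tiny_config(seed=3, groups=[("deaf", 30), ("hearing", 30)],
                           volumes_per_run=5)
        cfg.covariate_spec[0].coupling = 0.0
        tab = generate_cohort(cfg).cohort_table
        # hearing group younger by construction (28 vs 23 planted)
        assert tab.loc[tab.group == "deaf", "age"].mean() > tab.loc[
            tab.group == "hearing", "age"
        ].mean()

    def test_planted_z_calibration(self, rng):
        """Measured per-subject Fisher z matches the planted distribution
        (mu=0.5, sigma=0.3) within 3 standard errors at n=40."""
        mu, sigma, n, t = 0.5, 0.3, 40, 400
        cfg = _tiny_config(seed=11, groups=[("deaf", n)], volumes_per_run=t,
                           spatial_fwhm=0.0, drift_amplitude=0.0,
                           n_motion_regressors=0)
        reg = cfg.effect_regions[0]
        reg.mu = {"deaf": mu}
        reg.sigma = {"deaf": sigma}
        cfg.covariate_spec = []
        cohort = generate_cohort(cfg)
        pos = None
        measured = []
        for sub in cohort.subjects:
            fc = seed_fc_map(sub.runs, cfg.seed_region,
                             analysis_mask=sub.runs[0].mask)
            if pos is None:
                pos = np.searchsorted(
                    sub.runs[0].mask.flat_index(), reg.mask.flat_index()
                )
            measured.append(fc.values[pos].mean())
        measured = np.asarray(measured)
        me_var = 1.0 / (t - 3)  # per-subject measurement variance (approx)
        exp_sd = np.sqrt(sigma**2 + me_var)
        se_mean = exp_sd / np.sqrt(n)
        se_sd = exp_sd / np.sqrt(2 * (n - 1))
        assert abs(measured.mean() - mu) < 3 * se_mean
        assert abs(measured.std(ddof=1) - exp_sd) < 3 * se_sd


class TestSimulateSubject:
    def test_confounds_really_mixed_in_and_removable(self, rng):
        cfg = _tiny_config(volumes_per_run=150, drift_amplitude=5.0,
                           n_motion_regressors=2, spatial_fwhm=0.0)
        reg = cfg.effect_regions[0]
        reg.mu = {g: 0.6 for g, _ in cfg.groups}
        reg.sigma = {g: 0.0 for g, _ in cfg.groups}
        noise = _NoiseModel(cfg)
        sub = simulate_subject(cfg, "s0", "deaf", np.random.default_rng(4), noise=noise)
        pos = np.searchsorted(sub.runs[0].mask.flat_index(), reg.mask.flat_index())

        def measure(runs):
            return seed_fc_map(runs, cfg.seed_region,
                               analysis_mask=runs[0].mask).values[pos].mean()

        naive = measure(sub.runs)
        denoised_runs = []
        for run, conf in zip(sub.runs, sub.confounds):
            basis = build_projection(conf.to_numpy(), run.n_volumes, cfg.tr,
                                     (0.0, 0.25), confound_names=list(conf.columns))
            denoised_runs.append(denoise_run(run, basis))
        clean = measure(denoised_runs)
        # heavy nuisance corrupts the naive estimate; regression restores it
        assert abs(clean - 0.6) < abs(naive - 0.6)
        assert abs(clean - 0.6) < 0.25

    def test_no_nuisance_case_close_without_denoising(self):
        cfg = _tiny_config(volumes_per_run=300, drift_amplitude=0.0,
                           n_motion_regressors=0, spatial_fwhm=0.0)
        reg = cfg.effect_regions[0]
        reg.mu = {g: 0.5 for g, _ in cfg.groups}
        reg.sigma = {g: 0.0 for g, _ in cfg.groups}
        noise = _NoiseModel(cfg)
        sub = simulate_subject(cfg, "s0", "deaf", np.random.default_rng(8), noise=noise)
        pos = np.searchsorted(sub.runs[0].mask.flat_index(), reg.mask.flat_index())
        z = seed_fc_map(sub.runs, cfg.seed_region,
                        analysis_mask=sub.runs[0].mask).values[pos].mean()
        assert abs(z - 0.5) < 4 / np.sqrt(300 - 3)

    def test_different_substreams_different_data(self):
        cfg = _tiny_config(volumes_per_run=20)
        noise = _NoiseModel(cfg)
        s1 = simulate_subject(cfg, "a", "deaf", np.random.default_rng(1), noise=noise)
        s2 = simulate_subject(cfg, "b", "deaf", np.random.default_rng(2), noise=noise)
        assert not np.array_equal(s1.runs[0].data, s2.runs[0].data)


class TestSimulateFcCohort:
    def test_null_cohort_nominal_bf_rejection(self, rng):
        """Equal planted sigma in all groups: the variance test rejects at
        roughly the nominal rate."""
        grid = make_grid(12)
        mask = box_mask(grid)
        fc, groups, _ = simulate_fc_cohort(
            [("deaf", 16), ("hearing", 33)], mask, [], noise_sd=0.15,
            spatial_fwhm=0.0, rng_seed=9,
        )
        from fcvar import brown_forsythe_map

        m = brown_forsythe_map(fc, groups, mask=mask)
        assert 0.01 <= np.mean(m.p < 0.05) <= 0.12

    def test_planted_region_variance_structure(self):
        grid = make_grid(12)
        mask = box_mask(grid)
        eff = np.zeros(grid.shape, bool)
        eff[2:6, 2:6, 2:6] = True
        region = EffectRegion("e", Mask.from_array(eff, grid),
                              mu={"a": 0.5, "b": 0.5},
                              sigma={"a": 0.4, "b": 0.1})
        fc, groups, truth = simulate_fc_cohort(
            [("a", 40), ("b", 40)], mask, [region], noise_sd=0.02,
            spatial_fwhm=0.0, rng_seed=3,
        )
        pos = np.searchsorted(mask.flat_index(), region.mask.flat_index())
        sd_a = fc[groups == "a"][:, pos].mean(axis=1).std(ddof=1)
        sd_b = fc[groups == "b"][:, pos].mean(axis=1).std(ddof=1)
        assert sd_a / sd_b > 2.0
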
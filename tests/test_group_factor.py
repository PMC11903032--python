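import numpy as np
import pandas as pd
import pytest

from fcvar import (
    FactorTable,
    GroupDesign,
    Mask,
    extract_rois,
    factor_correlation_map,
    group_mean_map,
    label_clusters,
    roi_factor_correlation,
)
from fcvar.variance import StatMap
from .conftest import box_mask, make_grid


def _design(groups):
    return GroupDesign(
        subject_ids=[f"s{i}" for i in range(len(groups))],
        group_labels=np.asarray(groups),
        covariates=pd.DataFrame(index=range(len(groups))),
    )


class TestGroupMeanMap:
    def test_f_equals_t_squared_for_two_groups(self, rng):
        y = rng.normal(size=(30, 100))
        design = _design(np.repeat(["a", "b"], 15))
        anova, posthoc = group_mean_map(y, design)
        t = posthoc[("a", "b")].statistic
        np.testing.assert_allclose(anova.statistic, t**2, atol=1e-9)

    def test_sign_convention_group1_minus_group2(self, rng):
        y = rng.normal(size=(20, 10)) * 0.01
        y[:10] += 1.0  # group "a" higher
        _, posthoc = group_mean_map(y, _design(np.repeat(["a", "b"], 10)))
        assert np.all(posthoc[("a", "b")].statistic > 0)

    def test_three_group_pairs(self, rng):
        y = rng.normal(size=(12, 5))
        _, posthoc = group_mean_map(y, _design(np.repeat(["a", "b", "c"], 4)))
        assert set(posthoc) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_degenerate_voxel_flagged(self):
        y = np.zeros((10, 1))
        anova, _ = group_mean_map(y, _design(np.repeat(["a", "b"], 5)))
        assert anova.degenerate[0] and anova.p[0] == 1.0

    def test_welch_option(self, rng):
        y = rng.normal(size=(24, 20))
        y[:8] *= 4.0
        _, pooled = group_mean_map(y, _design(np.repeat(["a", "b"], [8, 16])))
        _, welch = group_mean_map(
            y, _design(np.repeat(["a", "b"], [8, 16])), welch=True
        )
        assert not np.allclose(
            pooled[("a", "b")].p, welch[("a", "b")].p
        )


class TestFactorCorrelationMap:
    def test_self_correlation_limit(self, rng):
        z = rng.normal(0.5, 0.3, size=40)
        fc = z[:, None] + rng.normal(scale=1e-3, size=(40, 50))
        m = factor_correlation_map(fc, z)
        assert m.statistic.mean() > 0.9

    def test_independent_factor_p_uniform(self, rng):
        fc = rng.normal(size=(40, 10_000))
        factor = rng.normal(size=40)
        m = factor_correlation_map(fc, factor)
        assert 0.47 <= m.p.mean() <= 0.53

    def test_planted_coupling_recovered(self, rng):
        n = 39
        z = rng.normal(size=n)
        fc = (z[:, None] + rng.normal(size=(n, 300)) * np.sqrt(3.0)) / 2.0  # rho = 0.5
        m = factor_correlation_map(fc, z)
        assert 0.35 <= m.statistic.mean() <= 0.62

    def test_missing_subjects_dropped_listwise(self, rng):
        fc = rng.normal(size=(20, 5))
        factor = rng.normal(size=20)
        factor[:5] = np.nan
        m = factor_correlation_map(fc, factor)
        assert m.df == (15 - 2,)

    def test_constant_factor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            factor_correlation_map(rng.normal(size=(10, 3)), np.ones(10))

    def test_covariate_residualized_df(self, rng):
        fc = rng.normal(size=(30, 5))
        factor = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        m = factor_correlation_map(fc, factor, covariates=cov)
        assert m.df == (30 - 2 - 2,)


def _cluster_set_on(grid, blobs):
    p = np.ones(grid.shape)
    for blob in blobs:
        p[blob] = 0.001
    mask = box_mask(grid)
    sm = StatMap(mask=mask, statistic=1 - p[tuple(mask.indices.T)],
                 p=p[tuple(mask.indices.T)], df=(1, 8), kind="test")
    return label_clusters(sm, 0.05, 1), mask


class TestRois:
    def test_extract_matches_cluster_sizes(self):
        grid = make_grid(10)
        cs, mask = _cluster_set_on(
            grid,
            [(slice(1, 3), slice(1, 3), slice(1, 3)),
             (slice(6, 9), slice(6, 9), 6),
             (slice(5, 6), 1, 1), (9, 9, slice(0, 2))],
        )
        rois = extract_rois(cs, mask)
        assert len(rois.rois) == cs.n_clusters
        sizes = sorted(m.n_voxels for _, m in rois.rois)
        assert sizes == sorted(c.size for c in cs.clusters)

    def test_min_size_filters_to_empty_with_warning(self):
        grid = make_grid(8)
        cs, mask = _cluster_set_on(grid, [(1, 1, slice(1, 3))])
        with pytest.warns(RuntimeWarning):
            rois = extract_rois(cs, mask, min_size=1000)
        assert rois.rois == []

    def test_labels_deterministic(self):
        grid = make_grid(8)
        cs, mask = _cluster_set_on(grid, [(slice(1, 4), 2, 2), (6, slice(5, 7), 6)])
        r1 = extract_rois(cs, mask)
        r2 = extract_rois(cs, mask)
        assert [l for l, _ in r1.rois] == [l for l, _ in r2.rois]


class TestRoiFactorCorrelation:
    def _setup(self, rng, n=30):
        grid = make_grid(6)
        mask = box_mask(grid)
        roi_a = Mask(grid=grid, indices=mask.indices[:20])
        roi_b = Mask(grid=grid, indices=mask.indices[50:70])
        z = rng.normal(size=n)
        fc = rng.normal(size=(n, mask.n_voxels))
        # plant coupling rho ~ 0.6 in ROI A only
        fc[:, :20] = z[:, None] + rng.normal(size=(n, 20)) * 1.1
        table = FactorTable(
            subject_ids=[f"s{i}" for i in range(n)],
            factors=pd.DataFrame({"f": z + rng.normal(size=n) * 0.3}),
        )
        return fc, mask, roi_a, roi_b, table

    def test_single_voxel_roi_matches_voxelwise(self, rng):
        fc, mask, *_ , table = self._setup(rng)
        single = Mask(grid=mask.grid, indices=mask.indices[:1])
        from fcvar import RoiSet

        res, _ = roi_factor_correlation(
            fc, RoiSet(rois=[("v0", single)]), table, analysis_mask=mask
        )
        vox = factor_correlation_map(fc, table.factors["f"].to_numpy(), mask=mask)
        assert abs(res["r"].iloc[0] - vox.statistic[0]) < 1e-12

    def test_planted_roi_detected_null_roi_not(self, rng):
        from fcvar import RoiSet

        fc, mask, roi_a, roi_b, table = self._setup(rng)
        res, _ = roi_factor_correlation(
            fc, RoiSet(rois=[("A", roi_a), ("B", roi_b)]), table, analysis_mask=mask
        )
        qa = res.loc[res.roi == "A", "q"].iloc[0]
        qb = res.loc[res.roi == "B", "q"].iloc[0]
        assert qa < 0.05 <= qb

    def test_constant_roi_reported_missing(self, rng):
        from fcvar import RoiSet

        fc, mask, roi_a, _, table = self._setup(rng)
        fc[:, :20] = 1.0  # ROI A mean constant across subjects
        res, _ = roi_factor_correlation(
            fc, RoiSet(rois=[("A", roi_a)]), table, analysis_mask=mask
        )
        assert np.isnan(res["r"].iloc[0])
        assert "undefined" in res["note"].iloc[0]

    def test_bh_q_monotone_and_bounded_below_by_p(self, rng):
        from fcvar import RoiSet

        fc, mask, roi_a, roi_b, table = self._setup(rng)
        table.factors["g"] = rng.normal(size=len(table.subject_ids))
        res, _ = roi_factor_correlation(
            fc, RoiSet(rois=[("A", roi_a), ("B", roi_b)]), table, analysis_mask=mask
        )
        valid = res.dropna(subset=["p"])
        srt = valid.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
        assert (valid["q"] >= valid["p"] - 1e-12).all()
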
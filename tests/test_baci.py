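"""BACI contrast engine: formula, controls, p-values, recovery, cancellation."""

import datetime as dt

import numpy as np
import pytest

from pixelbaci import baci as baci_mod
from pixelbaci.baci import BACIInputs, baci_contrast, pixel_pvalue, run_baci, sample_controls
from pixelbaci.rasterdata import Scene, SceneStack
from pixelbaci.scenesel import filter_clouds
from pixelbaci.synthgen import SynthConfig, _solve_bands, generate_landscape
from pixelbaci.trajclust import ClusterMap, build_trajectories, isodata_cluster


def _inputs(mu_ib, mu_ia, mu_cb, mu_ca, n=20):
    return BACIInputs(
        impact_before=[mu_ib] * 3,
        impact_after=[mu_ia] * 3,
        control_before=np.full((n, 3), mu_cb),
        control_after=np.full((n, 3), mu_ca),
    )


class TestContrast:
    def test_no_change_anywhere_is_zero(self):
        assert baci_contrast(_inputs(0.2, 0.2, 0.2, 0.2), "NBR") == 0.0

    def test_impact_improving_more_than_control_is_negative(self):
        # control +0.1, impact +0.2 -> contrast 0.1 - 0.2 = -0.1
        assert baci_contrast(_inputs(0.2, 0.4, 0.2, 0.3), "NBR") == pytest.approx(-0.1)

    def test_bsi_sign_flip(self):
        assert baci_contrast(_inputs(0.2, 0.4, 0.2, 0.3), "BSI") == pytest.approx(0.1)

    def test_empty_side_rejected(self):
        bad = BACIInputs([], [0.2], np.full((2, 1), 0.1), np.full((2, 1), 0.1))
        with pytest.raises(ValueError, match="empty"):
            baci_contrast(bad, "NBR")


class TestPixelPValue:
    def test_impact_identical_to_controls_gives_one(self):
        assert pixel_pvalue(_inputs(0.2, 0.3, 0.2, 0.3)) == 1.0

    def test_extreme_impact_hits_rank_floor(self):
        inp = BACIInputs(
            impact_before=[0.0], impact_after=[5.0],
            control_before=np.random.default_rng(0).normal(0, 0.01, (20, 1)),
            control_after=np.random.default_rng(1).normal(0, 0.01, (20, 1)),
        )
        assert pixel_pvalue(inp) == pytest.approx(2 / 21)

    def test_p_in_unit_interval_and_order_invariant(self):
        rng = np.random.default_rng(4)
        cb, ca = rng.normal(0.2, 0.05, (2, 20, 3))
        inp = BACIInputs([0.2, 0.21, 0.19], [0.3, 0.28, 0.33], cb, ca)
        p = pixel_pvalue(inp)
        assert 0.0 <= p <= 1.0
        perm = rng.permutation(20)
        p2 = pixel_pvalue(BACIInputs(inp.impact_before, inp.impact_after,
                                     cb[perm], ca[perm]))
        assert p2 == p

    def test_welch_alternative(self):
        inp = BACIInputs(
            impact_before=[0.0], impact_after=[5.0],
            control_before=np.random.default_rng(0).normal(0, 0.01, (20, 1)),
            control_after=np.random.default_rng(1).normal(0, 0.01, (20, 1)),
        )
        assert pixel_pvalue(inp, method="welch") < 1e-6

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="2 controls"):
            pixel_pvalue(_inputs(0.2, 0.3, 0.2, 0.3, n=1))


class TestSampleControls:
    def _cluster_map(self, labels):
        k = int(labels.max())
        return ClusterMap(labels=labels, centroids=np.zeros((k, 2)),
                          counts=np.bincount(labels.ravel(), minlength=k + 1)[1:],
                          index="NBR", n_iter=1, converged=True)

    def test_exhaustive_pool_returns_all(self):
        labels = np.ones((5, 5), np.int16)
        eligible = np.ones((5, 5), bool)
        eligible[0, 0] = False  # the impact pixel itself
        valid = np.ones((5, 5), bool)
        valid[4, 4] = False  # 25 - 1 - 1 = 23... shrink pool to exactly 20
        eligible[4, 3] = False
        eligible[4, 2] = False
        ctrl = sample_controls((0, 0), self._cluster_map(labels), eligible, valid, n=20)
        assert len(ctrl) == 20

    def test_shortfall_strict_mode_errors(self):
        labels = np.ones((4, 5), np.int16)
        eligible = np.ones((4, 5), bool)
        eligible[0, 0] = False  # 19 remain
        valid = np.ones((4, 5), bool)
        with pytest.raises(ValueError, match="cluster 1"):
            sample_controls((0, 0), self._cluster_map(labels), eligible, valid, n=20)
        out = sample_controls((0, 0), self._cluster_map(labels), eligible, valid,
                              n=20, allow_fewer=True)
        assert len(out) == 19

    def test_same_seed_reproducible_and_cluster_respected(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(1, 4, (20, 20)).astype(np.int16)
        eligible = np.ones((20, 20), bool)
        valid = np.ones((20, 20), bool)
        cm = self._cluster_map(labels)
        pix = (3, 7)
        a = sample_controls(pix, cm, eligible, valid, n=20, seed=5)
        b = sample_controls(pix, cm, eligible, valid, n=20, seed=5)
        np.testing.assert_array_equal(a, b)
        c = sample_controls(pix, cm, eligible, valid, n=20, seed=6)
        assert not np.array_equal(a, c)
        assert np.all(labels[a[:, 0], a[:, 1]] == labels[pix])
        assert len({tuple(p) for p in a}) == 20  # without replacement

    def test_unclustered_pixel_rejected(self):
        labels = np.zeros((5, 5), np.int16)
        with pytest.raises(ValueError, match="no cluster"):
            sample_controls((0, 0), self._cluster_map(np.ones((5, 5), np.int16) * 0 + 0),
                            np.ones((5, 5), bool), np.ones((5, 5), bool))


def _prepare(stack, sites, seed=3):
    thicket = sites.eligible_control | (sites.labels > 0)
    pre = stack.between(dt.date(1989, 1, 1), dt.date(1990, 12, 31))
    traj = build_trajectories(pre, "NBR", thicket)
    cm = isodata_cluster(traj, k=5, seed=seed, grid_shape=stack.grid.shape)
    filtered = filter_clouds(stack, sites.eligible_control)
    from pixelbaci.scenesel import SceneStack as _SS, build_period_spec

    annual = _SS([s for s in filtered.scenes if s.date.year > 2000], filtered.grid)
    spec = build_period_spec(1, 2012, annual, ["NBR"], area_mask=thicket)
    return filtered, spec, cm


class TestRunBaci:
    def test_effect_recovery_and_accounting(self, small_landscape):
        stack, terrain, sites, truth = small_landscape
        filtered, spec, cm = _prepare(stack, sites)
        res = run_baci(filtered, spec, cm, sites, "NBR", seed=1)
        t = res.table
        n_impact = int((sites.labels == 1).sum())
        reasons = {name: int((res.reason == c).sum())
                   for c, name in baci_mod.REASONS.items()}
        assert reasons["analyzed"] == len(t)
        assert (len(t) + reasons["unclustered"] + reasons["invalid"]
                + reasons["control_shortfall"]) == n_impact
        se = t.contrast.std() / np.sqrt(len(t))
        assert abs(t.contrast.mean() + truth["delta"][1]) < 4 * se + 1e-3

    def test_null_effect_on_static_landscape(self):
        # after-values equal before-values everywhere -> all contrasts 0
        cfg = SynthConfig(n_rows=40, n_cols=40, reveg_cols=(10, 14),
                          exclusion_cols=(25, 29), noise_sd=0.0,
                          year_effect_sd=0.0, seasonal_offsets=(0.0,),
                          delta={1: 0.0, 2: 0.0, 3: 0.0}, seed=2)
        stack, terrain, sites, truth = generate_landscape(cfg)
        filtered, spec, cm = _prepare(stack, sites)
        res = run_baci(filtered, spec, cm, sites, "NBR", seed=0)
        assert len(res.table) > 0
        assert np.nanmax(np.abs(res.contrast)) < 1e-12

    def test_determinism_same_seed(self, small_landscape):
        stack, terrain, sites, truth = small_landscape
        filtered, spec, cm = _prepare(stack, sites)
        r1 = run_baci(filtered, spec, cm, sites, "NBR", seed=7)
        r2 = run_baci(filtered, spec, cm, sites, "NBR", seed=7)
        np.testing.assert_array_equal(r1.contrast, r2.contrast)
        assert r1.table.equals(r2.table)

    def test_year_constant_nuisance_cancels(self, small_landscape):
        stack, terrain, sites, truth = small_landscape
        filtered, spec, cm = _prepare(stack, sites)
        base = run_baci(filtered, spec, cm, sites, "NBR", seed=7)

        offsets = {y: 0.07 * ((i % 3) - 1) for i, y in
                   enumerate(sorted({s.date.year for s in filtered.scenes}))}
        shifted_scenes = []
        for s in filtered.scenes:
            v = (s.bands["NIR"] - s.bands["SWIR2"]) / (s.bands["NIR"] + s.bands["SWIR2"])
            bands = _solve_bands("NBR", v + offsets[s.date.year])
            bands["SWIR1"] = s.bands.get("SWIR1", bands["SWIR1"])
            shifted_scenes.append(Scene(date=s.date, bands=bands,
                                        valid_mask=s.valid_mask))
        shifted = SceneStack(shifted_scenes, filtered.grid)
        res = run_baci(shifted, spec, cm, sites, "NBR", seed=7)
        diff = np.nanmax(np.abs(res.contrast - base.contrast))
        assert diff <= 1e-12

    def test_control_count_robustness(self, small_landscape):
        stack, terrain, sites, truth = small_landscape
        filtered, spec, cm = _prepare(stack, sites)
        r20 = run_baci(filtered, spec, cm, sites, "NBR", n_controls=20, seed=7)
        r100 = run_baci(filtered, spec, cm, sites, "NBR", n_controls=100, seed=7)
        m20, m100 = r20.table.contrast.mean(), r100.table.contrast.mean()
        assert np.sign(m20) == np.sign(m100)
        assert abs(m20 - m100) < 0.01

    def test_relative_contrast_definition_and_floor(self, small_landscape):
        stack, terrain, sites, truth = small_landscape
        filtered, spec, cm = _prepare(stack, sites)
        t = run_baci(filtered, spec, cm, sites, "NBR", seed=7).table
        defined = t.rel_contrast_pct.notna()
        np.testing.assert_allclose(
            t.loc[defined, "rel_contrast_pct"],
            t.loc[defined, "contrast"] / t.loc[defined, "mu_ib"] * 100.0,
            rtol=1e-12,
        )
        assert np.all(np.abs(t.loc[defined, "mu_ib"]) >= baci_mod.REL_CONTRAST_FLOOR)
        assert np.all(np.abs(t.loc[~defined, "mu_ib"]) < baci_mod.REL_CONTRAST_FLOOR)
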
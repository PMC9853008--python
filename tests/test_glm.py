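import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nfasym.glm import (
    DesignError,
    build_design,
    cluster_correct,
    condition_regressor,
    contrast_t,
    fit_glm,
    highpass,
    hrf,
    psc_from_series,
    roi_effect_sizes,
    roi_percent_signal_change,
    smooth,
)
from nfasym.paradigm import UPREGULATION, build_schedule
from nfasym.synth import simulate_voxel_bold


class TestHRFAndDesign:
    def test_hrf_zero_at_onset(self):
        assert hrf(0.0) == 0.0

    def test_hrf_peaks_early_undershoots_late(self):
        t = np.arange(0, 32, 0.1)
        h = hrf(t)
        assert 4.0 < t[np.argmax(h)] < 8.0
        assert h[t > 12].min() < 0

    def test_design_rows_650_and_10_columns(self, default_schedule):
        design = build_design(default_schedule)
        assert design.matrix.shape == (650, 10)

    def test_regressor_plateau_is_one(self, default_schedule):
        reg = condition_regressor(default_schedule, UPREGULATION)
        # late-block volumes sit on the sustained-response plateau
        for _, _, sl in default_schedule.volume_slices(label=UPREGULATION):
            assert reg[sl.stop - 3] == pytest.approx(1.0, abs=0.02)

    def test_motion_shape_mismatch_rejected(self, default_schedule):
        with pytest.raises(DesignError):
            build_design(default_schedule, motion=np.zeros((10, 6)))

    def test_schedule_without_rest_rejected(self):
        from nfasym.paradigm import BlockSpec, ExperimentSchedule

        s = ExperimentSchedule(
            runs=((BlockSpec("View", 40.0), BlockSpec("Upregulation", 60.0)),),
            tr=2.0,
            eeg_rate=250.0,
        )
        with pytest.raises(DesignError, match="Rest"):
            build_design(s)


class TestFitGLM:
    def test_normal_equations_oracle_small_design(self, rng):
        """OLS matches an explicit normal-equations solve to 1e-10."""
        x = np.column_stack([np.ones(20), rng.standard_normal((20, 3))])
        from nfasym.glm import DesignMatrix

        design = DesignMatrix(matrix=x, names=("c0", "c1", "c2", "c3"))
        y = rng.standard_normal((20, 5))
        fit = fit_glm(y, design)
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(fit.betas, oracle, atol=1e-10)
        resid = y - x @ oracle
        assert np.allclose(fit.sigma2, (resid**2).sum(0) / 16, atol=1e-10)

    def test_noiseless_recovery(self, short_schedule, rng):
        design = build_design(short_schedule)
        beta = rng.standard_normal(10)
        beta[3:9] = 0.0  # zero-motion columns carry no signal
        y = design.matrix @ beta
        fit = fit_glm(y, design)
        assert np.allclose((design.matrix @ fit.betas[:, 0]), y, atol=1e-8)

    def test_collinear_columns_named(self, rng):
        from nfasym.glm import DesignMatrix

        a = rng.standard_normal(30)
        x = np.column_stack([np.ones(30), a, 2 * a])
        design = DesignMatrix(matrix=x, names=("intercept", "a", "b"))
        with pytest.raises(DesignError, match="a"):
            fit_glm(rng.standard_normal(30), design)

    def test_pure_noise_calibration(self, short_schedule, rng):
        design = build_design(short_schedule)
        y = rng.standard_normal((short_schedule.n_volumes, 4000))
        fit = fit_glm(y, design)
        t, df = contrast_t(fit, {"Upregulation": 1.0, "View": -1.0})
        crit = sps.t.ppf(0.99, df)
        frac = np.mean(t > crit)
        assert frac == pytest.approx(0.01, abs=0.005)


class TestFilters:
    def test_highpass_removes_dc_exactly(self):
        y = np.full(100, 7.3)
        out = highpass(y, 0.005, tr=2.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_highpass_idempotent(self, rng):
        y = rng.standard_normal(650)
        once = highpass(y, 0.005, tr=2.0)
        twice = highpass(once, 0.005, tr=2.0)
        assert np.allclose(once, twice, atol=1e-10)

    def test_slow_sinusoid_attenuated(self):
        t = np.arange(650) * 2.0
        y = np.sin(2 * np.pi * 0.002 * t)
        out = highpass(y, 0.005, tr=2.0)
        assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(y**2))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(np.zeros(100), 0.3, tr=2.0)

    def test_smooth_impulse_fwhm(self):
        vol = np.zeros((31, 31, 31, 1))
        vol[15, 15, 15, 0] = 1.0
        out = smooth(vol, fwhm_vox=4.0)
        profile = out[:, 15, 15, 0]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        measured_fwhm = above[-1] - above[0] + 1  # integer-grid estimate
        assert measured_fwhm == pytest.approx(4.0, abs=1.0)

    def test_smooth_preserves_total_intensity(self, rng):
        vol = rng.standard_normal((12, 12, 6, 3))
        out = smooth(vol, fwhm_vox=3.0)
        assert out.sum() == pytest.approx(vol.sum(), abs=1e-6)


class TestClusterCorrect:
    def test_planted_cluster_survives(self, short_schedule):
        coords = np.array(
            [[i, j, k] for i in range(4, 7) for j in range(4, 7) for k in range(2, 5)]
        )
        hits = 0
        for seed in range(10):
            vol = simulate_voxel_bold(
                (16, 16, 8), [(coords, 2.0)], short_schedule, noise_sd=1.0, seed=seed
            )
            design = build_design(short_schedule)
            clusters, _ = cluster_correct(
                vol, design, {"Upregulation": 1.0, "Rest": -1.0},
                n_perm=150, seed=seed + 100,
            )
            hits += any(c.size >= 20 for c in clusters)
        assert hits >= 9

    def test_null_volume_usually_empty(self, short_schedule):
        empty = 0
        design = build_design(short_schedule)
        for seed in range(20):
            vol = simulate_voxel_bold((16, 16, 8), [], short_schedule, 1.0, seed=seed)
            clusters, _ = cluster_correct(
                vol, design, {"Upregulation": 1.0, "Rest": -1.0},
                n_perm=150, seed=seed,
            )
            empty += not clusters
        assert empty >= 19  # cluster_p = 0.01 -> ~0.2 expected failures in 20

    def test_min_permutations_enforced(self, short_schedule):
        vol = simulate_voxel_bold((8, 8, 4), [], short_schedule, 1.0, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            cluster_correct(
                vol, build_design(short_schedule),
                {"Upregulation": 1.0, "Rest": -1.0}, n_perm=50,
            )


class TestPSC:
    def test_simple_arithmetic(self, one_run_schedule):
        y = np.ones(one_run_schedule.n_volumes)
        for _, _, sl in one_run_schedule.volume_slices(label=UPREGULATION):
            y[sl] = 1.01
        psc_uv, psc_ur = psc_from_series(y, one_run_schedule)
        assert psc_uv == pytest.approx(1.0, abs=1e-9)
        assert psc_ur == pytest.approx(1.0, abs=1e-9)

    def test_trim_rule_ignores_first_two_up_volumes(self, one_run_schedule):
        y = np.ones(one_run_schedule.n_volumes)
        for _, _, sl in one_run_schedule.volume_slices(label=UPREGULATION):
            y[sl] = 1.01
            y[sl.start : sl.start + 2] = 1e3  # corrupt the trimmed volumes
        psc_uv, _ = psc_from_series(y, one_run_schedule)
        assert psc_uv == pytest.approx(1.0, abs=1e-9)

    def test_zero_view_mean_flagged(self, one_run_schedule):
        y = np.zeros(one_run_schedule.n_volumes)
        with pytest.raises(ZeroDivisionError):
            psc_from_series(y, one_run_schedule)

    def test_roi_mask_empty_intersection_returns_none(self, short_schedule):
        vol = simulate_voxel_bold((8, 8, 4), [], short_schedule, 0.0, seed=0)
        roi = np.zeros((8, 8, 4), bool)
        roi[0, 0, 0] = True
        activated = np.zeros((8, 8, 4), bool)
        assert roi_percent_signal_change(vol, short_schedule, roi, activated) is None

    def test_roi_psc_recovery(self, short_schedule):
        coords = np.array([[2, 2, 2], [2, 3, 2], [3, 2, 2]])
        vol = simulate_voxel_bold((8, 8, 4), [(coords, 1.5)], short_schedule, 0.0)
        roi = np.zeros((8, 8, 4), bool)
        roi[tuple(coords.T)] = True
        psc_uv, psc_ur = roi_percent_signal_change(vol, short_schedule, roi)
        # planted PSC is defined against Rest; Up-vs-Rest should recover it
        assert psc_ur == pytest.approx(1.5, abs=0.15)


class TestRoiEffectSizes:
    @staticmethod
    def _table(rng, n_roi=6, n_exp=10, n_ctl=8, effect_rois=()):
        rows = []
        for r in range(n_roi):
            name = f"roi{r}"
            mean = 0.8 if name in effect_rois else 0.0
            for group, n in (("experimental", n_exp), ("control", n_ctl)):
                loc = mean if group == "experimental" else 0.0
                for s in range(n):
                    rows.append(
                        {"roi": name, "subject": f"{group}{s}", "group": group,
                         "psc": rng.normal(loc, 0.5)}
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_d(self, rng):
        table = self._table(rng)
        table["psc"] = np.tile(
            table[table["group"] == "experimental"]["psc"].iloc[:1].to_numpy(), len(table)
        )
        # degenerate (constant) columns are skipped entirely
        out = roi_effect_sizes(table)
        assert out.empty

    def test_planted_effect_detected(self, rng):
        table = self._table(rng, effect_rois=("roi0", "roi1"))
        out = roi_effect_sizes(table).set_index("roi")
        assert bool(out.loc["roi0", "sig_within"])
        assert bool(out.loc["roi1", "sig_between"])

    def test_null_calibration(self, rng):
        reps, false_rois, total = 60, 0, 0
        for _ in range(reps):
            out = roi_effect_sizes(self._table(rng))
            false_rois += int(out["sig_between"].sum())
            total += len(out)
        assert false_rois / total <= 0.06

    def test_family_size_padding_reduces_rejections(self, rng):
        table = self._table(rng, effect_rois=("roi0",))
        small = roi_effect_sizes(table, family_size=6)
        large = roi_effect_sizes(table, family_size=118)
        assert large["sig_within"].sum() <= small["sig_within"].sum()
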
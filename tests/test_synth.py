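import json

import numpy as np
import pandas as pd
import pytest

from nfasym.feedback import asymmetry_series
from nfasym.glm import build_design, contrast_t, fit_glm, psc_from_series
from nfasym.paradigm import UPREGULATION, VIEW, build_schedule
from nfasym.stats import cohens_d_samples
from nfasym.synth import (
    DEFAULT_ROI_EFFECTS,
    CohortSpec,
    ConnectivitySpec,
    EEGSimParams,
    ROIEffectTable,
    ROITimeSeriesSet,
    SimulationError,
    add_gradient_artifact,
    generate_cohort,
    simulate_cohort,
    simulate_eeg,
    simulate_psychometrics,
    simulate_roi_bold,
    simulate_voxel_bold,
)


class TestSimulateEEG:
    def test_determinism(self, one_run_schedule):
        r1 = simulate_eeg(one_run_schedule, EEGSimParams(seed=11))
        r2 = simulate_eeg(one_run_schedule, EEGSimParams(seed=11))
        assert np.array_equal(r1.data, r2.data)

    def test_null_effect_has_zero_mean_asymmetry(self, one_run_schedule):
        diffs = []
        for seed in range(60):
            rec = simulate_eeg(one_run_schedule, EEGSimParams(seed=seed, asym_effect=0.0))
            ws = asymmetry_series(rec, one_run_schedule)
            diffs.append(np.mean([w.asym for w in ws]))
        d = np.asarray(diffs)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) < 3 * se + 0.01

    def test_planted_effect_recovered(self, one_run_schedule):
        diffs = []
        for seed in range(60):
            rec = simulate_eeg(one_run_schedule, EEGSimParams(seed=seed, asym_effect=0.3))
            ws = asymmetry_series(rec, one_run_schedule)
            up = np.mean([w.asym for w in ws if w.block == UPREGULATION])
            vw = np.mean([w.asym for w in ws if w.block == VIEW])
            diffs.append(up - vw)
        assert np.mean(diffs) == pytest.approx(0.3, abs=0.05)

    def test_control_profile_is_null(self, one_run_schedule):
        diffs = []
        for seed in range(40):
            rec = simulate_eeg(
                one_run_schedule, EEGSimParams(seed=seed, asym_effect=0.3), "control"
            )
            ws = asymmetry_series(rec, one_run_schedule)
            up = np.mean([w.asym for w in ws if w.block == UPREGULATION])
            vw = np.mean([w.asym for w in ws if w.block == VIEW])
            diffs.append(up - vw)
        assert abs(np.mean(diffs)) < 0.05

    def test_band_beyond_nyquist_rejected(self, one_run_schedule):
        with pytest.raises(SimulationError):
            simulate_eeg(one_run_schedule, EEGSimParams(alpha_band=(8.0, 200.0)))

    def test_ecg_has_planted_peaks(self, one_run_schedule):
        rec = simulate_eeg(one_run_schedule, EEGSimParams(seed=2))
        peaks = rec.meta["r_peaks"]
        assert len(peaks) > 100  # ~60 bpm over 130 s
        ecg = rec.channel("ECG")
        idx = (peaks * rec.rate).astype(int)
        assert np.all(ecg[idx] > 0.5)


class TestGradientArtifact:
    def test_zero_amplitude_unchanged(self, exp_recording):
        out = add_gradient_artifact(exp_recording, 2.0, 0.0)
        assert np.array_equal(out.data, exp_recording.data)

    def test_large_artifact_dominates_spectrum(self, exp_recording):
        out = add_gradient_artifact(exp_recording, 2.0, 100.0)
        assert out.channel("F3").std() > 10 * exp_recording.channel("F3").std()

    def test_ecg_channel_untouched(self, exp_recording):
        out = add_gradient_artifact(exp_recording, 2.0, 100.0)
        assert np.array_equal(out.channel("ECG"), exp_recording.channel("ECG"))

    def test_template_stored_and_subtractable(self, exp_recording):
        out = add_gradient_artifact(exp_recording, 2.0, 50.0, seed=3)
        template = out.meta["gradient_template"]
        n = out.n_samples
        tiled = np.tile(template, n // template.size + 1)[:n]
        assert np.allclose(out.channel("F3") - tiled, exp_recording.channel("F3"))


class TestSimulateRoiBold:
    def test_default_cohort_length(self, default_schedule):
        ts = simulate_roi_bold(
            default_schedule, ROIEffectTable(), ConnectivitySpec(), seed=0
        )
        assert len(ts.frame) == 650
        assert len(ts.roi_names) == 38

    def test_noiseless_psc_recovery(self, default_schedule):
        roi = ROIEffectTable(effects={"A": (1.0, 0.8), "B": (0.25, 0.5)})
        ts = simulate_roi_bold(default_schedule, roi, ConnectivitySpec(), noise_sd=0.0)
        for name, (uv, ur) in roi.effects.items():
            got_uv, got_ur = psc_from_series(ts.frame[name].to_numpy(), default_schedule)
            assert got_uv == pytest.approx(uv, abs=1e-9)
            assert got_ur == pytest.approx(ur, abs=1e-9)

    def test_delta_edge_raises_up_correlation(self, default_schedule):
        """Up-block r exceeds View-block r in >= 95% of seeds."""
        roi = ROIEffectTable(effects={"A": (0.0, 0.0), "B": (0.0, 0.0)})
        conn = ConnectivitySpec(base_corr=0.1, delta_edges=(("A", "B", 0.3),))
        from nfasym.connectivity import blockwise_correlations

        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            ts = simulate_roi_bold(default_schedule, roi, conn, noise_sd=0.5, seed=seed)
            bc = blockwise_correlations(ts, default_schedule)
            r_up = bc.loc[bc["block"] == UPREGULATION, "r"].mean()
            r_view = bc.loc[bc["block"] == VIEW, "r"].mean()
            wins += r_up > r_view
        assert wins >= int(0.95 * n_seeds)

    def test_determinism(self, short_schedule):
        roi = ROIEffectTable(effects={"A": (0.5, 0.5), "B": (0.0, 0.0)})
        t1 = simulate_roi_bold(short_schedule, roi, ConnectivitySpec(), seed=9)
        t2 = simulate_roi_bold(short_schedule, roi, ConnectivitySpec(), seed=9)
        assert t1.frame.equals(t2.frame)

    def test_impossible_delta_edge_rejected(self, short_schedule):
        roi = ROIEffectTable(effects={"A": (0.0, 0.0), "B": (0.0, 0.0)})
        conn = ConnectivitySpec(base_corr=0.8, delta_edges=(("A", "B", 0.5),))
        with pytest.raises(SimulationError, match="A"):
            simulate_roi_bold(short_schedule, roi, conn)

    def test_tsv_round_trip(self, short_schedule, tmp_path):
        roi = ROIEffectTable(effects={"A": (0.5, 0.5), "B": (0.0, 0.0)})
        ts = simulate_roi_bold(short_schedule, roi, ConnectivitySpec(), seed=1)
        path = tmp_path / "roi.tsv"
        ts.to_tsv(path)
        back = ROITimeSeriesSet.from_tsv(path)
        assert back.tr == ts.tr
        assert np.allclose(back.frame.to_numpy(), ts.frame.to_numpy(), atol=1e-5)


class TestSimulateVoxelBold:
    @staticmethod
    def _cluster():
        return np.array(
            [[i, j, k] for i in range(4, 7) for j in range(4, 7) for k in range(2, 5)]
        )

    def test_noiseless_cluster_exactly_active(self, short_schedule):
        coords = self._cluster()
        vol = simulate_voxel_bold((16, 16, 8), [(coords, 2.0)], short_schedule, 0.0)
        fit = fit_glm(vol.reshape(-1, short_schedule.n_volumes).T, build_design(short_schedule))
        t, _ = contrast_t(fit, {"Upregulation": 1.0, "Rest": -1.0})
        t3 = t.reshape(16, 16, 8)
        mask = np.zeros((16, 16, 8), bool)
        mask[tuple(coords.T)] = True
        assert np.all(np.isposinf(t3[mask]))
        assert np.all(t3[~mask] == 0.0)

    def test_cluster_outside_grid_rejected(self, short_schedule):
        with pytest.raises(SimulationError, match="outside"):
            simulate_voxel_bold((8, 8, 4), [(np.array([[9, 0, 0]]), 1.0)], short_schedule)

    def test_determinism(self, short_schedule):
        v1 = simulate_voxel_bold((8, 8, 4), [], short_schedule, 1.0, seed=4)
        v2 = simulate_voxel_bold((8, 8, 4), [], short_schedule, 1.0, seed=4)
        assert np.array_equal(v1, v2)


class TestSimulatePsychometrics:
    def test_null_effect(self):
        ds = []
        for seed in range(100):
            t = simulate_psychometrics(30, 30.0, 6.0, 0.0, seed=seed)
            ds.append(cohens_d_samples(t["before"], t["after"]).d)
        d = np.asarray(ds)
        assert abs(d.mean()) < 3 * d.std(ddof=1) / np.sqrt(d.size)

    def test_planted_d_recovered_at_large_n(self):
        t = simulate_psychometrics(1000, 31.4, 6.1, 0.97, seed=0)
        d = cohens_d_samples(t["before"], t["after"]).d
        assert d == pytest.approx(0.97, abs=0.1)

    def test_determinism(self):
        t1 = simulate_psychometrics(20, 30, 5, 0.5, seed=7)
        t2 = simulate_psychometrics(20, 30, 5, 0.5, seed=7)
        assert t1.equals(t2)

    def test_invalid_inputs(self):
        with pytest.raises(SimulationError):
            simulate_psychometrics(1, 30, 5, 0.5)
        with pytest.raises(SimulationError):
            simulate_psychometrics(10, 30, 5, 0.5, rho_pair=1.0)


class TestCohort:
    def test_default_group_sizes(self):
        spec = CohortSpec(schedule=build_schedule(n_runs=1), master_seed=0)
        cohort = generate_cohort(spec, with_eeg=False)
        groups = [s["group"] for s in cohort["subjects"]]
        assert groups.count("experimental") == 18
        assert groups.count("control") == 14

    def test_smoke_dataset_small_and_fast(self, tmp_path):
        import time

        spec = CohortSpec(
            n_experimental=1, n_control=1,
            schedule=build_schedule(n_runs=1),
            roi=ROIEffectTable(effects={"A": (0.5, 0.5), "B": (0.0, 0.0)}),
            conn=ConnectivitySpec(),
            master_seed=1,
        )
        t0 = time.time()
        manifest = simulate_cohort(spec, tmp_path / "cohort")
        assert time.time() - t0 < 5.0
        assert (tmp_path / "cohort" / "events.tsv").exists()
        assert (tmp_path / "cohort" / "manifest.json").exists()
        assert len(manifest["subject_seeds"]) == 2

    def test_manifest_seeds_reproduce_dataset(self, tmp_path):
        spec = CohortSpec(
            n_experimental=2, n_control=1,
            schedule=build_schedule(n_runs=1),
            roi=ROIEffectTable(effects={"A": (0.5, 0.5), "B": (0.0, 0.0)}),
            conn=ConnectivitySpec(),
            master_seed=5,
        )
        simulate_cohort(spec, tmp_path / "c1", with_eeg=False)
        simulate_cohort(spec, tmp_path / "c2", with_eeg=False)
        for name in ("manifest.json", "scores.tsv", "sub-01_roi_bold.tsv"):
            assert (tmp_path / "c1" / name).read_text() == (
                tmp_path / "c2" / name
            ).read_text()

    def test_default_roi_table_matches_connectivity_node_count(self):
        assert len(DEFAULT_ROI_EFFECTS) == 38

    def test_scores_table_shape(self):
        spec = CohortSpec(schedule=build_schedule(n_runs=1), master_seed=0)
        cohort = generate_cohort(spec, with_eeg=False)
        scores = cohort["scores"]
        assert set(scores.columns) == {"subject", "group", "scale", "before", "after"}
        assert scores["scale"].nunique() == 5
        per_scale = scores.groupby(["scale", "group"]).size()
        assert (per_scale.xs("experimental", level="group") == 18).all()
        assert (per_scale.xs("control", level="group") == 14).all()

    def test_invalid_cohort_sizes(self):
        with pytest.raises(SimulationError):
            CohortSpec(n_experimental=0)
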
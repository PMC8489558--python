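"""Generator: closed-form correlation oracle, rate conservation, determinism,
stimulus-train arithmetic and modulation effects."""

import numpy as np
import pytest

import synconn as sc
from synconn.synthetic import UndefinedCorrelationError, build_events, generate_feature_clusters
from synconn.types import ValidationError


def _binned_r(trains, a, b, bin_s=0.02):
    counts = sc.bin_counts(
        trains, np.array([[0.0, trains.session_duration]]), bin_s=bin_s, unit_ids=[a, b]
    )
    return float(np.corrcoef(counts.counts.astype(float))[0, 1])


class TestExpectedPairCorrelation:
    def test_perfect_common_source(self):
        assert sc.expected_pair_correlation(1.0, 1.0, 10.0, 0.0, 0.0) == 1.0

    def test_independence_when_one_unit_never_copies(self):
        assert sc.expected_pair_correlation(0.0, 0.5, 10.0, 5.0, 5.0) == 0.0

    def test_symmetric_half_copy_value(self):
        assert sc.expected_pair_correlation(0.5, 0.5, 10.0, 5.0, 5.0) == pytest.approx(0.25)

    def test_undefined_when_both_rates_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            sc.expected_pair_correlation(0.0, 0.0, 10.0, 0.0, 0.0)


class TestGenerateCorrelatedTrains:
    def _config(self, p, b, n=4, jitter=0.0, lam=10.0):
        return sc.AssemblyConfig(
            membership={f"u{i}": 0 for i in range(n)},
            copy_prob={f"u{i}": p for i in range(n)},
            mother_rate_hz=lam,
            background_rate_hz=b,
            jitter_sd_ms=jitter,
            refractory_ms=0.0,
        )

    def test_all_background_pairs_uncorrelated(self):
        cfg = self._config(p=0.0, b=8.0)
        trains, _ = sc.generate_correlated_trains(cfg, 300.0, seed=1)
        se = 1.0 / np.sqrt(300.0 / 0.02)
        for a, b in [("u0", "u1"), ("u1", "u2"), ("u2", "u3")]:
            assert abs(_binned_r(trains, a, b)) < 3 * se

    def test_full_copies_are_identical_trains(self):
        cfg = self._config(p=1.0, b=0.0)
        trains, _ = sc.generate_correlated_trains(cfg, 60.0, seed=2)
        np.testing.assert_array_equal(trains.spike_times["u0"], trains.spike_times["u1"])
        assert _binned_r(trains, "u0", "u1", bin_s=0.005) == pytest.approx(1.0)

    def test_rate_conservation_within_3_se(self):
        cfg = self._config(p=0.5, b=5.0)
        duration = 600.0
        trains, _ = sc.generate_correlated_trains(cfg, duration, seed=3)
        expected = 0.5 * 10.0 + 5.0
        se = np.sqrt(expected / duration)
        for u in trains.unit_ids:
            assert abs(trains.rate_hz(u) - expected) < 3 * se

    def test_seed_determinism_is_exact(self):
        cfg = self._config(p=0.5, b=5.0)
        t1, _ = sc.generate_correlated_trains(cfg, 120.0, seed=9)
        t2, _ = sc.generate_correlated_trains(cfg, 120.0, seed=9)
        for u in t1.unit_ids:
            np.testing.assert_array_equal(t1.spike_times[u], t2.spike_times[u])

    def test_jitter_monotonically_degrades_fine_timescale_correlation(self):
        means = []
        for jitter in (0.0, 5.0, 20.0):
            rs = []
            for seed in range(10):
                cfg = self._config(p=0.6, b=2.0, n=2, jitter=jitter)
                trains, _ = sc.generate_correlated_trains(cfg, 200.0, seed=seed)
                rs.append(_binned_r(trains, "u0", "u1", bin_s=0.002))
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]

    def test_ground_truth_closed_form_matches_empirical(self):
        cfg = self._config(p=0.5, b=5.0)
        trains, gt = sc.generate_correlated_trains(cfg, 600.0, seed=4)
        rho = gt.expected_spont_corr[("u0", "u1")]
        assert rho == pytest.approx(0.25)
        assert abs(_binned_r(trains, "u0", "u1") - rho) < 0.03


class TestBuildEvents:
    def test_ramp_hold_timing_half_hz(self):
        ev = build_events("ramp_hold", n_trials=3, start_s=5.0)
        np.testing.assert_allclose(ev.onsets, [5.0, 7.0, 9.0])
        np.testing.assert_allclose(ev.offsets, [5.2, 7.2, 9.2])

    def test_whisking_duration_ten_cycles(self):
        ev = build_events("artificial_whisking", n_trials=2)
        np.testing.assert_allclose(ev.offsets - ev.onsets, 10 / 5.5)

    def test_angle_blocks_cover_all_directions(self):
        _, _, tuning = sc.default_configs(seed=0)
        ev = build_events("ramp_hold", n_trials=480, tuning=tuning, seed=1)
        values, counts = np.unique(ev.angle_deg, return_counts=True)
        assert set(values) == {0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0}
        assert set(counts) == {60}

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValidationError):
            build_events("optogenetic", n_trials=3)


class TestGenerateSession:
    def test_null_modulation_leaves_states_indistinguishable(self):
        """With gamma = 1 and no tuned gain the evoked state is statistically
        identical to the spontaneous one.  Pairs within a session share the
        mother-process realization, so the correct unit of replication is
        the session: the per-session mean r difference must center on 0."""
        from scipy.stats import ttest_1samp

        diffs = []
        for seed in range(10):
            assembly, _, tuning = sc.default_configs(seed=seed)
            modulation = sc.StateModulation(evoked_copy_factor=1.0)
            tuning.evoked_gain_hz = 0.0
            trains, events, meta, _ = sc.generate_session(
                assembly, modulation, tuning, n_trials=100, seed=seed
            )
            windows = sc.make_state_windows(events)
            metrics = sc.pair_metrics(trains, windows, skip_ccg_below_r=None)
            spont = metrics[metrics.state == "spontaneous"].pearson_r.to_numpy()
            evoked = metrics[metrics.state == "evoked"].pearson_r.to_numpy()
            diffs.append(np.mean(spont - evoked))
        assert ttest_1samp(diffs, 0.0).pvalue > 0.05

    def test_strong_desynchronization_lowers_evoked_correlation(self):
        assembly, _, tuning = sc.default_configs(seed=6)
        modulation = sc.StateModulation(evoked_copy_factor=0.3)
        trains, events, meta, gt = sc.generate_session(
            assembly, modulation, tuning, n_trials=120, seed=6
        )
        windows = sc.make_state_windows(events)
        metrics = sc.pair_metrics(trains, windows, skip_ccg_below_r=None)
        same = set(gt.same_assembly_pairs)
        sub = metrics[[(a, b) in same for a, b in zip(metrics.unit_id_a, metrics.unit_id_b)]]
        spont = sub[sub.state == "spontaneous"].pearson_r.mean()
        evoked = sub[sub.state == "evoked"].pearson_r.mean()
        assert evoked < spont

    def test_probe_geometry_and_determinism(self):
        assembly, modulation, tuning = sc.default_configs(seed=7)
        t1, ev1, meta, _ = sc.generate_session(assembly, modulation, tuning, n_trials=5, seed=7)
        t2, _, _, _ = sc.generate_session(assembly, modulation, tuning, n_trials=5, seed=7)
        for m in meta:
            assert m.depth_um == 200.0 + 50.0 * m.contact_index
        for u in t1.unit_ids:
            np.testing.assert_array_equal(t1.spike_times[u], t2.spike_times[u])

    def test_refractory_period_enforced(self, default_session):
        trains, _, _, _ = default_session
        for u in trains.unit_ids:
            isis = np.diff(trains.spike_times[u])
            assert isis.min() >= 0.002


class TestGenerateFeatureClusters:
    def test_degenerate_zero_covariance_exact_points(self):
        df = generate_feature_clusters(
            2, 2, centers=[[0.0, 0.0], [5.0, 5.0]], covariances=np.zeros((2, 2)), seed=0
        )
        np.testing.assert_array_equal(
            df[df.unit_id == "u00"][["f1", "f2"]].to_numpy(), [[0.0, 0.0], [0.0, 0.0]]
        )

    def test_dunn_separates_distinct_from_duplicated_clouds(self):
        """Gaussian clusters 10 SD apart score far above a twice-labelled
        single cloud.  (Point-to-point Dunn of this geometry concentrates
        near 0.8 — bounded above by inter-point gap over diameter — while
        the duplicated cloud scores near 0.)"""
        for seed in range(30):
            df = generate_feature_clusters(
                2, 100, centers=[[0.0, 0.0], [10.0, 0.0]], covariances=np.eye(2), seed=seed
            )
            X = df[["f1", "f2"]].to_numpy()
            assert sc.dunn_index(X, df.unit_id.to_numpy()) > 0.5
            df = generate_feature_clusters(
                2, 100, centers=[[0.0, 0.0], [0.0, 0.0]], covariances=np.eye(2), seed=seed
            )
            X = df[["f1", "f2"]].to_numpy()
            assert sc.dunn_index(X, df.unit_id.to_numpy()) < 0.1

    def test_singular_covariance_rejected(self):
        bad = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        with pytest.raises(ValidationError):
            generate_feature_clusters(2, 10, [[0, 0], [5, 5]], bad, seed=0)
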
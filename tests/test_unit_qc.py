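"""Unit-acceptance battery: ISI statistics, waveform stability, MANOVA
separation, cluster-validity indices (with hand-computed and sklearn
cross-checks), duplicate exclusion and the combined gate."""

import numpy as np
import pandas as pd
import pytest

import synconn as sc
from synconn.unit_qc import (
    DegenerateGeometryError,
    InsufficientDataError,
    QCConfig,
    _scatter_sums,
)
from synconn.types import ValidationError
from conftest import poisson_train


class TestIsiStatistics:
    def test_hand_counted_minimum_and_violations(self):
        min_isi, viol, _ = sc.isi_statistics(np.array([0.0, 0.001, 0.05]))
        assert min_isi == pytest.approx(1.0)
        assert viol == pytest.approx(0.5)

    def test_poisson_isi_distribution_is_exponential(self):
        for seed in range(10):
            t = poisson_train(5.0, 600.0, seed)
            _, _, r2 = sc.isi_statistics(t)
            assert r2 > 0.9

    def test_periodic_train_is_not_exponential(self):
        t = np.arange(0, 60, 0.1)  # perfectly periodic 10 Hz
        _, _, r2 = sc.isi_statistics(t)
        assert r2 < 0.5

    def test_single_spike_insufficient(self):
        with pytest.raises(InsufficientDataError):
            sc.isi_statistics(np.array([1.0]))


class TestWaveformStability:
    def test_identical_segments_trivially_stable(self):
        series = np.concatenate([np.full(200, 80.0), np.random.default_rng(0).normal(80, 5, 600), np.full(200, 80.0)])
        p_amp, p_hw, stable = sc.waveform_stability(series, series)
        assert p_amp == 1.0 and p_hw == 1.0 and stable

    def test_stationary_series_usually_stable(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(100, 10, 1000)
            h = rng.normal(0.3, 0.03, 1000)
            _, _, stable = sc.waveform_stability(a, h)
            hits += stable
        # two independent tests at alpha=0.05 -> stable with prob ~ 0.95^2
        assert hits / n_rep == pytest.approx(0.95**2, abs=0.05)

    def test_linear_drift_detected(self):
        rng = np.random.default_rng(7)
        detections = 0
        for _ in range(50):
            base = 100.0
            a = base * (1 + 0.3 * np.linspace(0, 1, 1000)) + rng.normal(0, 10, 1000)
            h = rng.normal(0.3, 0.03, 1000)
            _, _, stable = sc.waveform_stability(a, h)
            detections += not stable
        assert detections >= 48  # > 95% power at 30% drift, sigma = 10% of mean

    def test_missing_series_not_evaluable(self):
        assert sc.waveform_stability(None, np.ones(100)) == (None, None, None)
        assert sc.waveform_stability(np.ones(40), np.ones(40))[2] is None


class TestClusterSeparation:
    def test_distant_clusters_highly_significant(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        labels = np.repeat(["a", "b"], 100)
        assert sc.cluster_separation_p(X, labels) < 1e-6

    def test_null_p_values_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            X = rng.normal(0, 1, (120, 2))
            labels = np.repeat(["a", "b"], 60)
            ps.append(sc.cluster_separation_p(X, labels))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            sc.cluster_separation_p(np.random.default_rng(0).normal(size=(30, 2)), np.repeat("a", 30))


class TestValidityIndices:
    def test_hand_computed_two_cluster_values(self, two_cluster_features):
        X, labels = two_cluster_features
        j1, j2, _, _ = _scatter_sums(X, labels)
        assert j1 == pytest.approx(1.0)
        assert j2 == pytest.approx(100.0)
        assert sc.j3(X, labels) == pytest.approx(100.0)
        assert sc.pseudo_f(X, labels) == pytest.approx(200.0)
        assert sc.dunn_index(X, labels) == pytest.approx(10.0)

    def test_davies_bouldin_against_sklearn(self, two_cluster_features):
        sklearn = pytest.importorskip("sklearn.metrics")
        X, labels = two_cluster_features
        assert sc.davies_bouldin(X, labels) == pytest.approx(
            sklearn.davies_bouldin_score(X, labels)
        )
        rng = np.random.default_rng(3)
        X2 = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(4, 1, (50, 3))])
        labels2 = np.repeat(["a", "b"], 50)
        assert sc.davies_bouldin(X2, labels2) == pytest.approx(
            sklearn.davies_bouldin_score(X2, labels2)
        )

    def test_pseudo_f_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(3, 1, (40, 2)), rng.normal(6, 1, (40, 2))])
        labels = np.repeat(["a", "b", "c"], 40)
        assert sc.pseudo_f(X, labels) == pytest.approx(
            sklearn.calinski_harabasz_score(X, labels)
        )

    @pytest.mark.parametrize("shift,scale", [(np.array([7.0, -3.0]), 1.0), (0.0, 2.5), (5.0, 0.3)])
    def test_rigid_translation_and_scaling_invariance(self, two_cluster_features, shift, scale):
        X, labels = two_cluster_features
        X2 = X * scale + shift
        assert sc.dunn_index(X2, labels) == pytest.approx(sc.dunn_index(X, labels))
        assert sc.davies_bouldin(X2, labels) == pytest.approx(sc.davies_bouldin(X, labels))
        assert sc.j3(X2, labels) == pytest.approx(sc.j3(X, labels))
        assert sc.pseudo_f(X2, labels) == pytest.approx(sc.pseudo_f(X, labels))

    def test_degenerate_geometries_raise(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(DegenerateGeometryError):
            sc.dunn_index(X, np.array(["a", "b"]))  # all diameters zero
        with pytest.raises(DegenerateGeometryError):
            sc.pseudo_f(X, np.array(["a", "b"]))  # n == k


class TestDuplicatePairs:
    def test_exact_copy_flagged(self):
        t = poisson_train(8.0, 120.0, 0)
        trains = sc.SpikeTrainSet({"u1": t, "u2": t.copy()}, 120.0)
        dup = sc.duplicate_pairs(trains)
        assert list(dup.excluded_unit) == ["u1"]  # equal counts -> first unit
        assert dup.r.iloc[0] == pytest.approx(1.0)

    def test_independent_trains_not_flagged(self):
        trains = sc.SpikeTrainSet(
            {"u1": poisson_train(8.0, 120.0, 1), "u2": poisson_train(8.0, 120.0, 2)}, 120.0
        )
        assert sc.duplicate_pairs(trains).empty

    def test_half_deleted_copy_below_threshold(self):
        # thinning with p=0.5 gives zero-lag r ~ sqrt(0.5) ~ 0.71 < 0.9
        rng = np.random.default_rng(3)
        t = poisson_train(10.0, 300.0, 3)
        half = t[rng.random(t.size) < 0.5]
        trains = sc.SpikeTrainSet({"u1": t, "u2": half}, 300.0)
        assert sc.duplicate_pairs(trains).empty


class TestApplyQC:
    def _session(self, seed=21, n_trials=200):
        assembly, modulation, tuning = sc.default_configs(seed=seed)
        return sc.generate_session(assembly, modulation, tuning, n_trials=n_trials, seed=seed)

    def test_low_rate_unit_rejected_with_rate_flag(self):
        trains, events, _, _ = self._session()
        slow = poisson_train(0.4, trains.session_duration, 5)
        spikes = dict(trains.spike_times)
        spikes["slow"] = slow
        trains2 = sc.SpikeTrainSet(spikes, trains.session_duration)
        _, report = sc.apply_qc(trains2, sc.make_state_windows(events))
        row = report.per_unit.set_index("unit_id").loc["slow"]
        assert not row.rate_ok and not row.accept

    def test_count_floor_rejects_sparse_unit(self):
        trains, events, _, _ = self._session()
        sparse = poisson_train(2900 / trains.session_duration, trains.session_duration, 6)
        assert sparse.size < 3000
        spikes = dict(trains.spike_times)
        spikes["sparse"] = sparse
        _, report = sc.apply_qc(
            sc.SpikeTrainSet(spikes, trains.session_duration), sc.make_state_windows(events)
        )
        row = report.per_unit.set_index("unit_id").loc["sparse"]
        assert not row.total_count_ok and not row.accept

    def test_synthetic_session_units_accepted(self):
        trains, events, _, _ = self._session(seed=22, n_trials=480)
        features = sc.generate_session_features(trains, seed=22)
        accepted, report = sc.apply_qc(trains, sc.make_state_windows(events), features=features)
        assert accepted.n_units >= trains.n_units - 2  # stability tests reject ~alpha
        assert report.per_unit.validity_ok.all()
        assert (report.per_unit.manova_p < 0.05).all()

    def test_acceptance_monotone_in_spike_count(self):
        """Adding supra-refractory spikes to a passing unit never flips the
        rate or count criteria back to failing."""
        trains, events, _, _ = self._session()
        windows = sc.make_state_windows(events)
        _, before = sc.apply_qc(trains, windows)
        u = before.per_unit.unit_id.iloc[0]
        t = trains.spike_times[u]
        extra = (t[:-1] + t[1:]) / 2.0  # midpoints keep ordering, add mass
        spikes = dict(trains.spike_times)
        spikes[u] = np.unique(np.concatenate([t, extra]))
        _, after = sc.apply_qc(sc.SpikeTrainSet(spikes, trains.session_duration), windows)
        b = before.per_unit.set_index("unit_id").loc[u]
        a = after.per_unit.set_index("unit_id").loc[u]
        for flag in ("rate_ok", "total_count_ok", "state_count_ok"):
            assert not (b[flag] and not a[flag])

    def test_duplicate_removed_from_accepted_set(self):
        trains, events, _, _ = self._session()
        spikes = dict(trains.spike_times)
        first = trains.unit_ids[0]
        spikes["zz_copy"] = spikes[first].copy()
        accepted, report = sc.apply_qc(
            sc.SpikeTrainSet(spikes, trains.session_duration), sc.make_state_windows(events)
        )
        assert "zz_copy" not in accepted.unit_ids or first not in accepted.unit_ids
        assert len(report.duplicates) == 1
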
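"""Threshold-crossing detection and the evaluation suite."""

from __future__ import annotations

import numpy as np
import pytest

import preshock as ps
from preshock.detection import RiskTrajectory


def traj(z, times=None, t_o=None, pid="p"):
    z = np.asarray(z, dtype=float)
    times = np.arange(len(z), dtype=float) if times is None else np.asarray(times, float)
    return RiskTrajectory(patient_id=pid, times=times, z=z, t_o=t_o)


class TestDetectCrossing:
    def test_first_crossing_time_and_value(self):
        r = ps.detect_crossing(traj([0.1, 0.4, 0.7], times=[0, 2, 4]), 0.5)
        assert (r.detected, r.t_d, r.z_theta) == (True, 4.0, 0.7)

    def test_never_crossing_shock_patient_is_false_negative(self):
        r = ps.detect_crossing(traj([0.1, 0.2], t_o=5.0), 0.9)
        assert (r.detected, r.outcome, r.ewt) == (False, "FN", None)

    def test_multiple_crossings_keep_the_first(self):
        r = ps.detect_crossing(traj([0.9, 0.1, 0.95]), 0.5)
        assert r.t_d == 0.0 and r.z_theta == 0.9

    def test_inclusive_comparison_at_threshold(self):
        r = ps.detect_crossing(traj([0.5]), 0.5)
        assert r.detected

    def test_ewt_is_onset_minus_detection(self):
        r = ps.detect_crossing(traj([0.1, 0.8], times=[0, 3], t_o=10.0), 0.5)
        assert r.outcome == "TP" and r.ewt == 7.0

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            ps.detect_crossing(traj([]), 0.5)

    def test_matches_brute_force_first_index_scan(self):
        rng = np.random.default_rng(3)
        for i in range(300):
            z = rng.random(rng.integers(1, 12))
            theta = float(rng.random())
            t = traj(z, t_o=20.0 if rng.random() < 0.5 else None, pid=f"p{i}")
            r = ps.detect_crossing(t, theta)
            idx = [j for j, v in enumerate(z) if v >= theta]
            assert r.detected == bool(idx)
            if idx:
                assert r.t_d == t.times[idx[0]] and r.z_theta == z[idx[0]]


class TestRoc:
    def _four_patients(self):
        return [
            traj([0.9], t_o=5.0, pid="s_hi"),
            traj([0.1], t_o=5.0, pid="s_lo"),
            traj([0.9], pid="n_hi"),
            traj([0.1], pid="n_lo"),
        ]

    def test_hand_counted_midpoint_operating_point(self):
        ev = ps.evaluate_threshold(self._four_patients(), 0.5)
        assert ev["sensitivity"] == 0.5 and ev["specificity"] == 0.5

    def test_perfect_separation_gives_auc_one(self):
        ts = [traj([0.8, 0.9], t_o=5.0), traj([0.7], t_o=5.0, pid="s2"),
              traj([0.3], pid="n1"), traj([0.1, 0.2], pid="n2")]
        assert ps.patient_level_roc(ts).attrs["auc"] == 1.0

    def test_identical_scores_give_auc_half(self):
        ts = [traj([0.5], t_o=5.0), traj([0.5], pid="n")]
        assert ps.patient_level_roc(ts).attrs["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ps.patient_level_roc([traj([0.5], t_o=5.0)])

    def test_auc_equals_mann_whitney_on_max_scores(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        for i in range(50):
            ts = []
            n_s, n_n = rng.integers(2, 10, size=2)
            for j in range(n_s):
                ts.append(traj(rng.normal(0.5, 1, rng.integers(1, 8)), t_o=30.0, pid=f"s{j}"))
            for j in range(n_n):
                ts.append(traj(rng.normal(0, 1, rng.integers(1, 8)), pid=f"n{j}"))
            auc = ps.patient_level_roc(ts).attrs["auc"]
            u = mannwhitneyu(
                [t.max_z for t in ts if t.is_shock],
                [t.max_z for t in ts if not t.is_shock],
                alternative="two-sided",
            ).statistic
            assert auc == pytest.approx(u / (n_s * n_n)), i


class TestOptimalThreshold:
    def _roc(self, points):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": np.arange(len(points), 0, -1, dtype=float),
             "fpr": [p[0] for p in points], "tpr": [p[1] for p in points]}
        )

    def test_worked_example(self):
        roc = self._roc([(0.0, 0.0), (0.2, 0.9), (0.5, 0.95), (1.0, 1.0)])
        assert ps.optimal_threshold(roc) == 3.0  # the (0.2, 0.9) point

    def test_perfect_point_wins(self):
        roc = self._roc([(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)])
        assert ps.optimal_threshold(roc) == 2.0

    def test_tie_breaks_toward_lower_fpr(self):
        roc = self._roc([(0.0, 0.7), (0.3, 1.0)])  # equidistant: 0.3 each
        assert ps.optimal_threshold(roc) == 2.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(2, 20)
            roc = self._roc(list(zip(np.sort(rng.random(n)), np.sort(rng.random(n)))))
            d2 = roc["fpr"] ** 2 + (1 - roc["tpr"]) ** 2
            best = d2[d2 == d2.min()].index
            pick = roc.loc[best, "fpr"].idxmin()
            assert ps.optimal_threshold(roc) == roc.loc[pick, "threshold"]


class TestEvaluateThreshold:
    def test_all_detected_median_ewt(self):
        ts = [traj([1.0], times=[10 - e], t_o=10.0, pid=f"s{e}") for e in range(1, 11)]
        ts.append(traj([0.0], pid="n"))
        ev = ps.evaluate_threshold(ts, 0.5)
        assert ev["sensitivity"] == 1.0
        assert ev["median_ewt"] == 5.5

    def test_infinite_threshold_no_detections(self):
        ts = [traj([0.9], t_o=5.0), traj([0.9], pid="n")]
        ev = ps.evaluate_threshold(ts, np.inf)
        assert ev["sensitivity"] == 0.0 and ev["specificity"] == 1.0
        assert not ev["ppv_defined"] and np.isnan(ev["ppv"])

    def test_ppv_from_counts(self):
        ts = [traj([0.9], t_o=5.0, pid=f"s{i}") for i in range(3)]
        ts += [traj([0.9], pid=f"n{i}") for i in range(3)]
        assert ps.evaluate_threshold(ts, 0.5)["ppv"] == 0.5


class TestPpvByDecile:
    def _results(self, z_tp, z_fp):
        out = []
        for i, z in enumerate(z_tp):
            out.append(ps.DetectionResult(f"s{i}", True, 1.0, z, 2.0, "TP"))
        for i, z in enumerate(z_fp):
            out.append(ps.DetectionResult(f"n{i}", True, 1.0, z, None, "FP"))
        return out

    def test_constructed_separation(self):
        res = self._results(z_tp=np.linspace(0.6, 0.9, 10), z_fp=np.linspace(0.1, 0.4, 10))
        table = ps.ppv_by_decile(res)
        assert list(table["ppv"]) == [0.0] * 5 + [1.0] * 5

    def test_all_true_positives(self):
        table = ps.ppv_by_decile(self._results(np.linspace(0.1, 1, 12), []))
        assert (table["ppv"] == 1.0).all()

    def test_too_few_detections_suggests_fewer_bins(self):
        with pytest.raises(ValueError, match="fewer bins"):
            ps.ppv_by_decile(self._results([0.5] * 4, []))

    def test_bin_sizes_differ_by_at_most_one(self):
        table = ps.ppv_by_decile(self._results(np.linspace(0, 1, 17), np.linspace(0, 1, 6)))
        assert table["n"].max() - table["n"].min() <= 1
        assert table["n"].sum() == 23


class TestBootstrapCompare:
    def _cohort(self, rng, informative):
        ts = []
        for j in range(12):
            mu = 1.5 if informative else 0.0
            ts.append(traj(rng.normal(mu, 1, 5), t_o=30.0, pid=f"s{j}"))
        for j in range(12):
            ts.append(traj(rng.normal(0, 1, 5), pid=f"n{j}"))
        return ts

    def test_identical_sets_are_indistinguishable(self):
        rng = np.random.default_rng(0)
        a = self._cohort(rng, True)
        out = ps.bootstrap_compare(a, a, n_boot=100, seed=1)
        assert out["p_value"] == pytest.approx(1.0)
        np.testing.assert_array_equal(out["samples_a"], out["samples_b"])

    def test_informative_beats_random_scores(self):
        rng = np.random.default_rng(4)
        a = self._cohort(rng, True)
        b = [traj(rng.normal(0, 1, 5), t_o=t.t_o, pid=t.patient_id) for t in a]
        out = ps.bootstrap_compare(a, b, n_boot=300, seed=2)
        assert out["p_value"] < 0.01
        assert out["samples_a"].mean() > out["samples_b"].mean()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        a = self._cohort(rng, True)
        b = self._cohort(rng, False)
        p1 = ps.bootstrap_compare(a, b, n_boot=120, seed=7)["p_value"]
        p2 = ps.bootstrap_compare(a, b, n_boot=120, seed=7)["p_value"]
        assert p1 == p2

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            ps.bootstrap_compare([], [], n_boot=10)


class TestEwtByRecordLength:
    def test_pairs_and_positive_trend_when_constructed(self):
        results, ts = [], []
        for i, L in enumerate(range(2, 12)):
            t = traj([0.9], times=[float(L)], t_o=float(2 * L), pid=f"s{i}")
            ts.append(t)
            results.append(ps.detect_crossing(t, 0.5))
        out = ps.ewt_by_record_length(results, ts)
        assert out["spearman_rho"] > 0

    def test_constant_ewt_gives_zero_correlation(self):
        results, ts = [], []
        for i in range(4):
            t = traj([0.9], times=[1.0 + i], t_o=6.0 + i, pid=f"s{i}")
            ts.append(t)
            results.append(ps.detect_crossing(t, 0.5))
        assert ps.ewt_by_record_length(results, ts)["spearman_rho"] == 0.0

    def test_two_patients_flagged_low_n(self):
        results, ts = [], []
        for i in range(2):
            t = traj([0.9], times=[1.0], t_o=5.0 + i, pid=f"s{i}")
            ts.append(t)
            results.append(ps.detect_crossing(t, 0.5))
        out = ps.ewt_by_record_length(results, ts)
        assert out["low_n"] and len(out["pairs"]) == 2

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            ps.ewt_by_record_length([], [])


def test_trajectory_invariants():
    with pytest.raises(ValueError):
        traj([0.1, np.nan])
    with pytest.raises(ValueError):
        RiskTrajectory("p", np.array([2.0, 1.0]), np.array([0.1, 0.2]))
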
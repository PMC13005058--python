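"""Synthetic cohort generator: determinism, structure, and effect recovery."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d
from scipy.stats import ks_2samp

from turnsignal import (
    CohortConfig, MalfunctionRates, export_csv, generate_cohort,
    inject_malfunctions, read_csv_tree, static_features,
)
from turnsignal.preprocess import clean_cohort
from turnsignal.validation import brute_force_corners


def _trees_equal(a: Path, b: Path) -> bool:
    fa = sorted(p.relative_to(a) for p in a.rglob("*.csv"))
    fb = sorted(p.relative_to(b) for p in b.rglob("*.csv"))
    if fa != fb:
        return False
    return all(filecmp.cmp(a / p, b / p, shallow=False) for p in fa)


class TestGenerate:
    def test_empty_cohort(self):
        c = generate_cohort(CohortConfig(n_healthy=0, n_mci=0))
        assert len(c.participants) == 0
        assert c.n_trips == 0

    def test_determinism_byte_identical_exports(self, small_config, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        export_csv(generate_cohort(small_config), a)
        export_csv(generate_cohort(small_config), b)
        assert _trees_equal(a, b)

    def test_gps_timestamps_strictly_increasing_and_gapped(self, small_cohort):
        for pid, trips in small_cohort.streams.items():
            prev_end = None
            for trip in trips:
                t = trip["gps"].timestamps
                assert np.all(np.diff(t) > 0)
                if prev_end is not None:
                    assert t[0] - prev_end > 60
                prev_end = t[-1]

    def test_imu_gps_length_ratio(self, small_cohort):
        for trips in small_cohort.streams.values():
            for trip in trips:
                n_gps = len(trip["gps"].timestamps)
                for sensor in ("accel", "gyro"):
                    assert abs(len(trip[sensor].timestamps) - 24 * n_gps) <= 1

    def test_speed_in_m_per_s_range(self, small_cohort):
        for trips in small_cohort.streams.values():
            for trip in trips:
                speed = trip["gps"].values[:, 2]
                assert speed.min() >= 0
                assert speed.max() < 60  # naturalistic urban driving, not a jet

    def test_planted_corners_found_by_heading_oracle(self):
        """Every trip's planted corners appear as heading-change peaks."""
        cfg = CohortConfig(n_healthy=2, n_mci=1, trips_per_participant=(2, 2),
                           trip_duration_s=(120, 150), turn_count_per_trip=(3, 3),
                           effect_size=1.0, seed=5)
        cohort = generate_cohort(cfg)
        total_corners = total_matched = 0
        for pid, trips in cohort.streams.items():
            for k, trip in enumerate(trips):
                lat = np.radians(trip["gps"].values[:, 0])
                lon = np.radians(trip["gps"].values[:, 1])
                x = lon * np.cos(lat.mean())
                y = lat
                found = brute_force_corners(x, y, 0.174533)
                planted = cohort.ground_truth[pid][k]["corners"]
                assert len(planted) == 3
                total_corners += len(planted)
                for c in planted:
                    if found and min(abs(f - c) for f in found) <= 3:
                        total_matched += 1
        assert total_matched / total_corners >= 0.9


class TestMalfunctions:
    def test_zero_rates_identity(self, small_cohort):
        out = inject_malfunctions(small_cohort, MalfunctionRates(), seed=1)
        for pid in small_cohort.streams:
            for t0, t1 in zip(small_cohort.streams[pid], out.streams[pid]):
                assert set(t0) == set(t1)
                for s in t0:
                    np.testing.assert_array_equal(t0[s].values, t1[s].values)

    def test_full_gyro_drop_causes_mismatch_everywhere(self, small_cohort):
        out = inject_malfunctions(small_cohort, MalfunctionRates(missing_trip=1.0), seed=1)
        for trips in out.streams.values():
            for trip in trips:
                assert trip == {}  # every sensor dropped at rate 1

    def test_seeded_rates_reproducible(self, small_cohort):
        rates = MalfunctionRates(missing_trip=0.2, cutoff=0.2, missing_values=0.2)
        a = inject_malfunctions(small_cohort, rates, seed=9)
        b = inject_malfunctions(small_cohort, rates, seed=9)
        for pid in a.streams:
            for ta, tb in zip(a.streams[pid], b.streams[pid]):
                assert set(ta) == set(tb)
                for s in ta:
                    np.testing.assert_array_equal(ta[s].values, tb[s].values)

    def test_ground_truth_untouched(self, small_cohort):
        out = inject_malfunctions(small_cohort, MalfunctionRates(cutoff=0.5), seed=3)
        assert out.ground_truth is small_cohort.ground_truth


class TestExport:
    def test_empty_cohort_empty_tree(self, tmp_path):
        root = export_csv(generate_cohort(CohortConfig(n_healthy=0, n_mci=0)), tmp_path / "r")
        assert list(root.glob("participant_*")) == []

    def test_file_count(self, tmp_path):
        cfg = CohortConfig(n_healthy=1, n_mci=0, trips_per_participant=(2, 2),
                           trip_duration_s=(60, 80), turn_count_per_trip=(1, 1), seed=1)
        root = export_csv(generate_cohort(cfg), tmp_path / "r")
        assert len(list(root.rglob("trip_*.csv"))) == 2 * 3  # 2 trips x 3 sensors

    def test_export_ingest_roundtrip(self, small_cohort, tmp_path):
        a = export_csv(small_cohort, tmp_path / "a")
        b = export_csv(read_csv_tree(a), tmp_path / "b")
        assert _trees_equal(a, b)


class TestClassStructure:
    def test_null_exchangeability(self):
        """With effect 1 and no impairment the class feature distributions match."""
        n_seeds, n_channels = 8, 14
        rejections = 0
        for s in range(n_seeds):
            cfg = CohortConfig(n_healthy=8, n_mci=8, trips_per_participant=(6, 6),
                               trip_duration_s=(60, 100), turn_count_per_trip=(2, 3),
                               effect_size=1.0, impaired_trip_fraction=0.0, seed=100 + s)
            trips, _, _ = clean_cohort(generate_cohort(cfg))
            lab = {p.participant_id: p.label
                   for p in generate_cohort(cfg).participants}
            feats = np.array([static_features(t) for t in trips])
            y = np.array([lab[t.participant_id] == "mci" for t in trips])
            for ch in range(n_channels):
                if ks_2samp(feats[y, ch], feats[~y, ch]).pvalue < 0.01:
                    rejections += 1
        assert rejections / (n_seeds * n_channels) <= 0.05

    def test_effect_orders_within_turn_yaw_sd(self):
        """At effect >= 2 the within-turn yaw fluctuation separates the classes."""
        cfg = CohortConfig(n_healthy=5, n_mci=5, trips_per_participant=(5, 5),
                           trip_duration_s=(90, 120), turn_count_per_trip=(3, 3),
                           effect_size=2.0, impaired_trip_fraction=1.0, seed=77)
        cohort = generate_cohort(cfg)
        sds = {"healthy": [], "mci": []}
        for p in cohort.participants:
            for k, trip in enumerate(cohort.streams[p.participant_id]):
                gz = trip["gyro"].values[:, 2]
                t = trip["gyro"].timestamps - trip["gyro"].timestamps[0]
                mask = np.zeros(len(t), bool)
                for c in cohort.ground_truth[p.participant_id][k]["corners"]:
                    mask |= (t >= c - 5) & (t <= c + 5)
                hf = gz - uniform_filter1d(gz, 49)
                sds[p.label].append(hf[mask].std())
        pairs = [(h, m) for h in sds["healthy"] for m in sds["mci"]]
        frac = np.mean([m > h for h, m in pairs])
        assert frac > 0.9


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(effect_size=0.5)
    with pytest.raises(ValueError):
        CohortConfig(impaired_trip_fraction=1.5)
    with pytest.raises(ValueError):
        CohortConfig(n_healthy=-1)
    with pytest.raises(ValueError):
        MalfunctionRates(cutoff=2.0)
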
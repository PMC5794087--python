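"""Detection-history construction, survey filtering, event independence and
naive summaries."""

import numpy as np
import pandas as pd
import pytest

from mvbocc.detections import (
    DetectionHistory,
    build_histories,
    filter_min_surveys,
    independent_events,
    naive_summary,
)


def make_history(y, occasion_days=4):
    y = np.asarray(y, dtype=float)
    n_sites, n_species, n_occ = y.shape
    starts = pd.date_range("2014-06-15", periods=n_occ, freq=f"{occasion_days}D")
    return DetectionHistory(
        y,
        tuple(f"s{i}" for i in range(n_sites)),
        tuple(["grizzly", "black", "motorised", "non-motorised"][:n_species]),
        occasion_days,
        starts,
    )


class TestBuildHistories:
    def test_no_events_active_twenty_days_gives_five_zero_occasions(self):
        dep = pd.DataFrame(
            {"site_id": ["s1"], "start": ["2014-06-15"], "end": ["2014-07-04"]}
        )
        ev = pd.DataFrame(columns=["site_id", "category", "timestamp"])
        h = build_histories(ev, dep, occasion_days=4)
        assert h.n_occasions == 5
        assert (h.y == 0).all()

    def test_single_event_on_day_five_lands_in_second_window(self):
        dep = pd.DataFrame(
            {"site_id": ["s1"], "start": ["2014-06-15"], "end": ["2014-07-04"]}
        )
        ev = pd.DataFrame(
            [("s1", "grizzly", "2014-06-19 10:00")],
            columns=["site_id", "category", "timestamp"],
        )
        h = build_histories(ev, dep, occasion_days=4)
        g = h.species.index("grizzly")
        assert h.y[0, g, 1] == 1
        assert h.y[0, g, [0, 2, 3, 4]].sum() == 0

    def test_random_events_match_brute_force_binning_oracle(self, rng):
        sites = ["s1", "s2", "s3"]
        start = pd.Timestamp("2014-06-15")
        dep = pd.DataFrame(
            {
                "site_id": sites,
                "start": [start, start + pd.Timedelta(days=3), start],
                "end": [start + pd.Timedelta(days=39)] * 3,
            }
        )
        cats = ["grizzly", "black", "motorised", "non-motorised"]
        rows = []
        for _ in range(50):
            site = sites[rng.integers(3)]
            row = dep[dep.site_id == site].iloc[0]
            span = (row.end - row.start).days + 1
            ts = row.start + pd.Timedelta(minutes=int(rng.integers(span * 24 * 60)))
            rows.append((site, cats[rng.integers(4)], ts))
        ev = pd.DataFrame(rows, columns=["site_id", "category", "timestamp"])
        h = build_histories(ev, dep, occasion_days=4)

        # oracle: loop events x windows, then overlay missingness
        expected = np.full_like(h.y, np.nan)
        width = pd.Timedelta(days=4)
        for si, site in enumerate(sites):
            row = dep[dep.site_id == site].iloc[0]
            for t in range(h.n_occasions):
                lo = start + t * width
                hi = lo + width
                if lo <= row.end + pd.Timedelta(days=1) - pd.Timedelta(seconds=1) and hi > row.start:
                    expected[si, :, t] = 0.0
            for _, e in ev[ev.site_id == site].iterrows():
                for t in range(h.n_occasions):
                    lo = start + t * width
                    if lo <= e.timestamp < lo + width:
                        expected[si, cats.index(e.category), t] = 1.0
        np.testing.assert_array_equal(h.y, expected)

    def test_event_outside_deployment_dropped_with_warning(self):
        dep = pd.DataFrame(
            {"site_id": ["s1"], "start": ["2014-06-15"], "end": ["2014-06-30"]}
        )
        ev = pd.DataFrame(
            [("s1", "grizzly", "2014-07-20 10:00")],
            columns=["site_id", "category", "timestamp"],
        )
        with pytest.warns(UserWarning, match="outside"):
            h = build_histories(ev, dep, occasion_days=4, study_end="2014-07-31")
        assert np.nansum(h.y) == 0

    def test_unknown_site_raises(self):
        dep = pd.DataFrame(
            {"site_id": ["s1"], "start": ["2014-06-15"], "end": ["2014-06-30"]}
        )
        ev = pd.DataFrame(
            [("sX", "grizzly", "2014-06-20 10:00")],
            columns=["site_id", "category", "timestamp"],
        )
        with pytest.raises(ValueError, match="undeployed"):
            build_histories(ev, dep)

    def test_unknown_category_excluded(self, small_deployments):
        ev = pd.DataFrame(
            [("s1", "unknown", "2014-06-20 10:00")],
            columns=["site_id", "category", "timestamp"],
        )
        h = build_histories(ev, small_deployments)
        assert np.nansum(h.y) == 0

    def test_detections_never_exceed_event_count(self, small_events, small_deployments):
        h = build_histories(small_events, small_deployments)
        for si, site in enumerate(h.sites):
            for pi, sp in enumerate(h.species):
                n_ev = ((small_events.site_id == site) & (small_events.category == sp)).sum()
                assert np.nansum(h.y[si, pi]) <= n_ev

    def test_partially_active_window_counts_as_surveyed(self):
        # deployment covers only the first day of the second window
        dep = pd.DataFrame(
            {"site_id": ["s1"], "start": ["2014-06-15"], "end": ["2014-06-19"]}
        )
        ev = pd.DataFrame(columns=["site_id", "category", "timestamp"])
        h = build_histories(ev, dep, occasion_days=4, study_end="2014-06-26")
        assert h.y[0, 0, 0] == 0 and h.y[0, 0, 1] == 0
        assert np.isnan(h.y[0, 0, 2])


class TestFilterMinSurveys:
    def test_site_below_threshold_removed_and_boundary_kept(self):
        y = np.zeros((2, 1, 6))
        y[0, 0, 3:] = np.nan  # 3 surveyed occasions
        y[1, 0, 4:] = np.nan  # exactly 4
        h = make_history(y)
        out = filter_min_surveys(h, 4)
        assert out.sites == ("s1",)

    def test_retained_count_matches_oracle(self, rng):
        spans = rng.integers(0, 9, size=10)
        y = np.zeros((10, 2, 8))
        for i, s in enumerate(spans):
            y[i, :, s:] = np.nan
        h = make_history(y)
        out = filter_min_surveys(h, 4)
        assert out.n_sites == int((spans >= 4).sum())

    def test_idempotent(self, rng):
        y = np.zeros((5, 1, 8))
        for i in range(5):
            y[i, :, rng.integers(3, 9) :] = np.nan
        h = filter_min_surveys(make_history(y), 4)
        again = filter_min_surveys(h, 4)
        np.testing.assert_array_equal(h.y, again.y)
        assert h.sites == again.sites

    def test_all_removed_raises_naming_threshold(self):
        y = np.full((2, 1, 6), np.nan)
        y[:, :, 0] = 0
        with pytest.raises(ValueError, match="4"):
            filter_min_surveys(make_history(y), 4)


class TestIndependentEvents:
    def test_burst_collapses_to_first_frame(self):
        ev = pd.DataFrame(
            [("s1", "grizzly", "2014-06-16 08:00"), ("s1", "grizzly", "2014-06-16 08:01")],
            columns=["site_id", "category", "timestamp"],
        )
        out = independent_events(ev, gap_minutes=30)
        assert len(out) == 1
        assert out.timestamp.iloc[0] == pd.Timestamp("2014-06-16 08:00")

    def test_events_past_gap_kept(self):
        ev = pd.DataFrame(
            [("s1", "grizzly", "2014-06-16 08:00"), ("s1", "grizzly", "2014-06-16 08:31")],
            columns=["site_id", "category", "timestamp"],
        )
        assert len(independent_events(ev, gap_minutes=30)) == 2

    def test_random_stream_matches_linear_scan_oracle(self, rng):
        times = pd.Timestamp("2014-06-15") + pd.to_timedelta(
            np.sort(rng.integers(0, 48 * 60, size=200)), unit="m"
        )
        ev = pd.DataFrame(
            {"site_id": "s1", "category": "black", "timestamp": times}
        )
        out = independent_events(ev, gap_minutes=30)
        kept = []
        last = None
        for ts in sorted(times):
            if last is None or (ts - last) >= pd.Timedelta(minutes=30):
                kept.append(ts)
                last = ts
        assert list(out.timestamp) == kept

    def test_invariant_to_burst_multiplicity(self, rng):
        base = pd.Timestamp("2014-06-15") + pd.to_timedelta(
            np.cumsum(rng.integers(40, 200, size=20)), unit="m"
        )
        single = pd.DataFrame({"site_id": "s1", "category": "grizzly", "timestamp": base})
        burst_rows = []
        for ts in base:
            for j in range(int(rng.integers(3, 6))):  # 3-5 rapid frames
                burst_rows.append(ts + pd.Timedelta(seconds=2 * j))
        burst = pd.DataFrame(
            {"site_id": "s1", "category": "grizzly", "timestamp": burst_rows}
        )
        a = independent_events(single, 30)
        b = independent_events(burst, 30)
        assert list(a.timestamp) == list(b.timestamp)


class TestNaiveSummary:
    def test_all_sites_detect_gives_one(self):
        y = np.ones((4, 1, 3))
        ns = naive_summary(make_history(y))
        assert ns.occurrence.iloc[0] == 1.0

    def test_random_history_matches_counting_oracle(self, rng):
        y = (rng.random((20, 3, 6)) < 0.2).astype(float)
        h = make_history(y)
        ns = naive_summary(h)
        det = y.sum(axis=2) > 0
        for pi, sp in enumerate(h.species):
            assert ns.occurrence[sp] == det[:, pi].mean()
        for pi in range(3):
            for pj in range(3):
                assert (
                    ns.pairwise.iloc[pi, pj] == (det[:, pi] & det[:, pj]).sum()
                )


def test_history_csv_round_trip(tmp_path, small_events, small_deployments):
    h = build_histories(small_events, small_deployments)
    frame = h.to_frame()
    path = tmp_path / "history.csv"
    frame.to_csv(path, index=False, na_rep="NA")
    back = DetectionHistory.from_frame(
        pd.read_csv(path, na_values="NA"), h.occasion_days, h.occasion_starts
    )
    np.testing.assert_array_equal(h.y, back.y)
    assert back.sites == h.sites and back.species == h.species
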
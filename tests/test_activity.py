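"""Circular kernel densities, the coefficient of overlapping and its
bootstrap interval."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import vonmises

from mvbocc.activity import (
    bootstrap_ci,
    conditional_overlap,
    fit_circular_kde,
    hours_to_radians,
    overlap_delta1,
    times_to_radians,
    vonmises_kappa_mle,
)

TWO_PI = 2 * np.pi


def true_vm_overlap(mu1, kappa1, mu2, kappa2, grid_n=8192):
    """Quadrature oracle on the true densities."""
    grid = np.linspace(0, TWO_PI, grid_n, endpoint=False)
    f = vonmises.pdf(grid, kappa=kappa1, loc=mu1)
    g = vonmises.pdf(grid, kappa=kappa2, loc=mu2)
    x = np.append(grid, TWO_PI)
    y = np.minimum(f, g)
    return np.trapezoid(np.append(y, y[0]), x)


class TestTimeMapping:
    def test_clock_times_map_linearly_to_circle(self):
        np.testing.assert_allclose(
            hours_to_radians([0, 6, 12, 18]), [0, np.pi / 2, np.pi, 3 * np.pi / 2]
        )

    def test_timestamps_use_time_of_day_only(self):
        ts = pd.to_datetime(["2014-06-15 06:00", "2014-08-01 06:00"])
        a = times_to_radians(ts)
        assert a[0] == pytest.approx(a[1])
        assert a[0] == pytest.approx(np.pi / 2)


class TestCircularKDE:
    def test_density_integrates_to_one(self, rng):
        for n in (5, 60, 400):
            kde = fit_circular_kde(rng.vonmises(1.0, 2.0, n) % TWO_PI)
            assert kde.integral() == pytest.approx(1.0, abs=1e-6)

    def test_sample_symmetric_about_pi_gives_symmetric_density(self, rng):
        half = rng.vonmises(0, 3.0, 300) % TWO_PI
        sample = np.concatenate([np.pi + half, np.pi - half]) % TWO_PI
        kde = fit_circular_kde(sample, grid_n=512)
        # symmetry about pi means f(theta) == f(2 pi - theta) on the grid
        mirrored = np.roll(kde.values[::-1], 1)
        np.testing.assert_allclose(kde.values, mirrored, atol=1e-8)

    def test_consistency_against_true_von_mises(self, rng):
        x = rng.vonmises(np.pi, 2.0, 10_000) % TWO_PI
        kde = fit_circular_kde(x)
        true = vonmises.pdf(kde.grid, kappa=2.0, loc=np.pi)
        assert np.abs(kde.values - true).max() < 0.02

    def test_fewer_than_two_events_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_circular_kde([1.0])

    def test_kappa_mle_recovers_concentration(self, rng):
        x = rng.vonmises(0.5, 3.0, 50_000) % TWO_PI
        assert vonmises_kappa_mle(x) == pytest.approx(3.0, rel=0.05)


class TestOverlapDelta1:
    def test_identical_samples_overlap_one(self, rng):
        x = rng.vonmises(2.0, 1.5, 200) % TWO_PI
        assert overlap_delta1(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_tight_separated_clusters_near_zero(self, rng):
        a = rng.vonmises(0.0, 200.0, 200) % TWO_PI
        b = rng.vonmises(np.pi, 200.0, 200) % TWO_PI
        assert overlap_delta1(a, b) < 0.05

    def test_tracks_quadrature_oracle_at_large_n(self, rng):
        a = rng.vonmises(0.0, 4.0, 5000) % TWO_PI
        b = rng.vonmises(np.pi / 2, 4.0, 5000) % TWO_PI
        assert overlap_delta1(a, b) == pytest.approx(
            true_vm_overlap(0.0, 4.0, np.pi / 2, 4.0), abs=0.03
        )

    def test_symmetric_in_arguments(self, rng):
        a = rng.vonmises(0.3, 2.0, 80) % TWO_PI
        b = rng.vonmises(2.1, 1.0, 50) % TWO_PI
        assert overlap_delta1(a, b) == pytest.approx(overlap_delta1(b, a), abs=1e-12)

    def test_invariant_to_joint_rotation(self, rng):
        a = rng.vonmises(0.3, 2.0, 100) % TWO_PI
        b = rng.vonmises(2.1, 1.5, 100) % TWO_PI
        base = overlap_delta1(a, b, grid_n=2048)
        rot = overlap_delta1((a + 1.234) % TWO_PI, (b + 1.234) % TWO_PI, grid_n=2048)
        assert rot == pytest.approx(base, abs=2e-3)

    def test_increasing_separation_decreases_true_overlap_and_estimate_tracks(self, rng):
        seps = [0.5, 1.5, 2.5]
        truths = [true_vm_overlap(0, 4, s, 4) for s in seps]
        assert truths == sorted(truths, reverse=True)
        ests = []
        for s in seps:
            a = rng.vonmises(0.0, 4.0, 3000) % TWO_PI
            b = rng.vonmises(s, 4.0, 3000) % TWO_PI
            ests.append(overlap_delta1(a, b))
        assert ests == sorted(ests, reverse=True)


class TestBootstrapCI:
    def test_interval_contains_point_estimate(self, rng):
        a = rng.vonmises(0.0, 2.0, 60) % TWO_PI
        b = rng.vonmises(1.0, 2.0, 60) % TWO_PI
        est = bootstrap_ci(a, b, n_boot=200, seed=1)
        assert est.ci_low <= est.delta <= est.ci_high
        assert 0 <= est.ci_low <= est.ci_high <= 1

    def test_same_seed_same_interval(self, rng):
        a = rng.vonmises(0.0, 2.0, 40) % TWO_PI
        b = rng.vonmises(1.0, 2.0, 40) % TWO_PI
        e1 = bootstrap_ci(a, b, n_boot=150, seed=7)
        e2 = bootstrap_ci(a, b, n_boot=150, seed=7)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_too_few_bootstrap_replicates_rejected(self, rng):
        a = rng.vonmises(0.0, 2.0, 40) % TWO_PI
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(a, a, n_boot=50, seed=1)


class TestConditionalOverlap:
    def make_history(self, detected_sites, all_sites):
        from mvbocc.detections import DetectionHistory

        y = np.zeros((len(all_sites), 4, 5))
        for s in detected_sites:
            y[all_sites.index(s), 1, 0] = 1  # conditioning = black (index 1)
        return DetectionHistory(
            y,
            tuple(all_sites),
            ("grizzly", "black", "motorised", "non-motorised"),
            4,
            pd.date_range("2014-06-15", periods=5, freq="4D"),
        )

    def _events(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "category", "timestamp"])

    def test_identical_event_times_in_both_subsets_give_equal_delta(self, rng):
        sites = ["s0", "s1"]
        hours = rng.uniform(0, 24, 40)
        rows = []
        for s in sites:
            for h in hours:
                rows.append((s, "grizzly", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        for h in rng.uniform(0, 24, 30):
            rows.append(("s0", "black", pd.Timestamp("2014-06-16") + pd.Timedelta(hours=h)))
        ev = self._events(rows)
        hist = self.make_history(["s0"], sites)  # black present only at s0
        out = conditional_overlap(ev, hist, "grizzly", "black", n_boot=100, seed=3)
        d = out.set_index("subset")["delta"]
        assert d["present"] == pytest.approx(d["absent"], abs=1e-12)

    def test_planted_activity_shift_reduces_overlap_at_present_sites(self, rng):
        sites = ["p", "q"]
        rows = []
        # focal grizzly: nocturnal at the black-present site, diurnal elsewhere
        for h in (rng.vonmises(0, 4, 80) % TWO_PI) / TWO_PI * 24:
            rows.append(("p", "grizzly", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        for h in (rng.vonmises(np.pi, 4, 80) % TWO_PI) / TWO_PI * 24:
            rows.append(("q", "grizzly", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        # reference black bears are diurnal
        for h in (rng.vonmises(np.pi, 4, 80) % TWO_PI) / TWO_PI * 24:
            rows.append(("p", "black", pd.Timestamp("2014-06-16") + pd.Timedelta(hours=h)))
        ev = self._events(rows)
        hist = self.make_history(["p"], sites)
        out = conditional_overlap(ev, hist, "grizzly", "black", n_boot=100, seed=5)
        d = out.set_index("subset")["delta"]
        assert d["present"] < d["absent"]

    def test_output_mirrors_present_absent_table_layout(self, rng):
        sites = ["p", "q"]
        rows = []
        for s in sites:
            for h in rng.uniform(0, 24, 20):
                rows.append((s, "grizzly", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        for h in rng.uniform(0, 24, 20):
            rows.append(("p", "black", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        out = conditional_overlap(
            self._events(rows), self.make_history(["p"], sites), "grizzly", "black",
            n_boot=100, seed=2,
        )
        assert list(out["subset"]) == ["present", "absent"]
        assert {"delta", "ci_low", "ci_high", "n"} <= set(out.columns)

    def test_small_subset_reported_missing_with_n(self, rng):
        sites = ["p", "q"]
        rows = [("p", "grizzly", "2014-06-15 03:00")]  # 1 event at present site
        for h in rng.uniform(0, 24, 20):
            rows.append(("q", "grizzly", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        for h in rng.uniform(0, 24, 20):
            rows.append(("p", "black", pd.Timestamp("2014-06-15") + pd.Timedelta(hours=h)))
        with pytest.warns(UserWarning, match="too few"):
            out = conditional_overlap(
                self._events(rows), self.make_history(["p"], sites), "grizzly", "black",
                n_boot=100, seed=2,
            )
        present = out[out.subset == "present"].iloc[0]
        assert np.isnan(present.delta) and present.n == 1
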
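import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacemap import (
    build_cluster_summary,
    classify_dominance,
    fit_cluster_normals,
    fit_logistic,
    kmeans_1d,
    percent_change,
    summarize_experiment,
)
from pacemap.cluster_stats import membership_curve


def wcss(values, assignments):
    values = np.asarray(values, dtype=float)
    total = 0.0
    for label in np.unique(assignments):
        v = values[assignments == label]
        total += ((v - v.mean()) ** 2).sum()
    return total


def exhaustive_best_two_partition(values):
    """Minimum WCSS over every assignment of points to 2 nonempty clusters."""
    n = len(values)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        a = np.asarray(bits)
        if a.min() == a.max():
            continue
        best = min(best, wcss(values, a))
    return best


class TestKmeans1d:
    def test_two_well_separated_triples(self):
        y = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        assignments, centers = kmeans_1d(y, k=2)
        np.testing.assert_allclose(centers, [0.2, 0.8])
        np.testing.assert_array_equal(assignments, [0, 0, 0, 1, 1, 1])

    def test_symmetric_binary(self):
        _, centers = kmeans_1d([0.0, 0.0, 1.0, 1.0], k=2)
        np.testing.assert_allclose(centers, [0.0, 1.0])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=3,
            max_size=12,
        )
    )
    def test_dp_attains_exhaustive_optimum(self, values):
        if len(set(values)) < 2:
            return
        assignments, _ = kmeans_1d(values, k=2)
        assert wcss(values, assignments) == pytest.approx(
            exhaustive_best_two_partition(values), abs=1e-9
        )

    def test_identical_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_1d([0.5] * 6, k=2)

    def test_three_clusters_exact(self):
        y = [0.0, 0.01, 0.5, 0.51, 1.0, 1.01]
        assignments, centers = kmeans_1d(y, k=3)
        np.testing.assert_allclose(centers, [0.005, 0.505, 1.005])
        np.testing.assert_array_equal(assignments, [0, 0, 1, 1, 2, 2])


class TestClusterNormals:
    def test_hand_arithmetic(self):
        out = fit_cluster_normals([0.7, 0.8, 0.9], [0, 0, 0])
        mu, sigma = out[0]
        assert mu == pytest.approx(0.8)
        assert sigma == pytest.approx(0.1)

    def test_singleton_sigma_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single member"):
            out = fit_cluster_normals([0.5, 0.1, 0.2], [1, 0, 0])
        assert out[1] == (0.5, 0.0)

    def test_monte_carlo_recovery(self, rng):
        draws = rng.normal(0.80, 0.09, size=1000)
        out = fit_cluster_normals(draws, np.zeros(1000, dtype=int))
        mu, sigma = out[0]
        assert mu == pytest.approx(0.80, abs=0.01)
        assert sigma == pytest.approx(0.09, abs=0.01)


def grid_search_loglik(hr, labels, b0s, b1s):
    hr = np.asarray(hr, dtype=float)
    y = np.asarray(labels, dtype=float)
    best = (-np.inf, None)
    for b0 in b0s:
        for b1 in b1s:
            eta = b0 + b1 * hr
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            if ll > best[0]:
                best = (ll, (b0, b1))
    return best


class TestFitLogistic:
    def test_separated_data_flagged_and_crossing_in_gap(self):
        hr = [100.0, 110.0, 120.0, 400.0, 410.0, 420.0]
        labels = [0, 0, 0, 1, 1, 1]
        b0, b1, sep = fit_logistic(hr, labels)
        assert sep
        assert b1 > 0
        crossing = -b0 / b1  # P(superior) = 0.5
        assert 120.0 < crossing < 400.0
        p = membership_curve(b0, b1, np.array(hr))
        assert (np.diff(p) >= 0).all()

    def test_symmetric_overlapping_data_cross_at_center(self):
        deltas = np.array([10.0, 30.0, 50.0, 80.0, 120.0])
        hr = np.concatenate([300 - deltas, 300 + deltas, [260.0, 340.0]])
        labels = np.concatenate([np.zeros(5), np.ones(5), [1.0, 0.0]]).astype(int)
        b0, b1, sep = fit_logistic(hr, labels)
        assert not sep
        assert -b0 / b1 == pytest.approx(300.0, abs=1.0)
        # at least as good as a dense grid search around the optimum
        ll_grid, _ = grid_search_loglik(
            hr, labels, np.linspace(-20, 20, 81), np.linspace(-0.1, 0.1, 81)
        )
        eta = b0 + b1 * hr
        ll_fit = np.sum(labels * eta - np.logaddexp(0.0, eta))
        assert ll_fit >= ll_grid - 1e-6

    def test_penalized_fit_beats_hand_chosen_parameters(self):
        hr = np.array([100.0, 120.0, 140.0, 360.0, 380.0, 400.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        lam = 1e-3
        b0, b1, sep = fit_logistic(hr, labels, ridge_lambda=lam)
        assert sep
        m, s = hr.mean(), hr.std()

        def pnll(beta0, beta1):
            eta = beta0 + beta1 * hr
            nll = np.sum(np.logaddexp(0.0, eta) - labels * eta)
            return nll + 0.5 * lam * (beta1 * s) ** 2

        best = pnll(b0, b1)
        for cand0 in (-5.0, 0.0, 5.0):
            for cand1 in (0.001, 0.01, 0.1):
                assert best <= pnll(cand0, cand1) + 1e-6

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="both"):
            fit_logistic([100.0, 200.0], [1, 1])


class TestDominance:
    def frame(self, clusters, hearts=None):
        n = len(clusters)
        return pd.DataFrame(
            {
                "heart_id": hearts or ["H1"] * n,
                "cluster": clusters,
            }
        )

    def test_all_superior_is_ssan_only(self):
        [call] = classify_dominance(self.frame(["superior"] * 10))
        assert call.call == "sSAN_only" and call.fraction_superior == 1.0

    def test_even_split_is_dual(self):
        [call] = classify_dominance(self.frame(["superior"] * 5 + ["inferior"] * 5))
        assert call.call == "dual" and call.fraction_superior == 0.5

    def test_threshold_boundaries(self):
        clusters = ["superior"] * 19 + ["inferior"]
        [call] = classify_dominance(self.frame(clusters), threshold=0.95)
        assert call.call == "sSAN_only"
        [call] = classify_dominance(self.frame(clusters), threshold=0.96)
        assert call.call == "dual"

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            classify_dominance(pd.DataFrame(columns=["heart_id", "cluster"]))


class TestPercentChange:
    def test_published_rat_ach_drop(self):
        assert percent_change(280.90, 192.30) == -31.5

    def test_no_change_and_increase(self):
        assert percent_change(123.4, 123.4) == 0.0
        assert percent_change(100.0, 150.0) == 50.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            percent_change(0.0, 100.0)


class TestSummaries:
    def records(self, rng):
        y = np.concatenate([rng.normal(0.8, 0.05, 30), rng.normal(0.25, 0.05, 30)])
        hr = np.concatenate([rng.normal(420, 20, 30), rng.normal(190, 20, 30)])
        cond = ["ISO"] * 30 + ["ACh"] * 30
        return pd.DataFrame({"y_au": y, "hr_bpm": hr, "condition": cond})

    def test_summary_means_match_hand_computation(self, rng):
        df = self.records(rng)
        summary = build_cluster_summary(df["y_au"].to_numpy(), df["hr_bpm"].to_numpy())
        tables = summarize_experiment(df, summary)
        per_cond = tables["per_condition"].set_index("condition")
        for cond in ("ACh", "ISO"):
            sub = df[df["condition"] == cond]["hr_bpm"]
            assert per_cond.loc[cond, "hr_mean"] == pytest.approx(sub.mean())
            assert per_cond.loc[cond, "hr_sd"] == pytest.approx(sub.std(ddof=1))
        assert summary.mu_sup > summary.mu_inf

    def test_cluster_summary_json_round_trip(self, rng):
        df = self.records(rng)
        summary = build_cluster_summary(df["y_au"].to_numpy(), df["hr_bpm"].to_numpy())
        d = summary.to_dict()
        assert json.loads(json.dumps(d)) == d
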
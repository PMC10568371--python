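import numpy as np
import pytest

from spastocsy import (SpectrumSet, correlation_landscape, extract_clusters,
                       prediction_strength, select_threshold,
                       select_window_size, smooth_landscape)
from spastocsy.spa import (KERNELS, ClusterSet, CorrelationLandscape,
                           NoStableClusteringError, SpatialCluster,
                           co_membership_strength, _pd_for_pair)

# ---------------------------------------------------------------------------
# independent oracles


def landscape_oracle(X, k):
    """Direct enumeration of all pairwise Pearson correlations per window."""
    n, p = X.shape
    out = np.full(p, np.nan)
    for j in range(p - k + 1):
        vals = []
        for a in range(j, j + k):
            for b in range(a + 1, j + k):
                if X[:, a].std() == 0 or X[:, b].std() == 0:
                    vals.append(0.0)
                else:
                    vals.append(np.corrcoef(X[:, a], X[:, b])[0, 1])
        out[j] = np.mean(vals)
    return out


def pacf_oracle(x, nlags):
    """Durbin-Levinson recursion on biased sample autocovariances."""
    x = np.asarray(x, float) - np.mean(x)
    n = x.size
    r = np.array([(x[: n - j] * x[j:]).sum() / n for j in range(nlags + 1)])
    phi = np.zeros((nlags + 1, nlags + 1))
    out = np.zeros(nlags + 1)
    out[0] = 1.0
    phi[1, 1] = r[1] / r[0]
    out[1] = phi[1, 1]
    for k in range(2, nlags + 1):
        num = r[k] - sum(phi[k - 1, j] * r[k - j] for j in range(1, k))
        den = r[0] - sum(phi[k - 1, j] * r[j] for j in range(1, k))
        phi[k, k] = num / den
        for j in range(1, k):
            phi[k, j] = phi[k - 1, j] - phi[k, k] * phi[k - 1, k - j]
        out[k] = phi[k, k]
    return out


def pd_oracle(scored, other, p):
    """Exhaustive pair enumeration of the co-membership fraction median."""
    lab = np.full(p, -1)
    for g, c in enumerate(other):
        lab[c.start_index:c.end_index + 1] = g
    fracs = []
    for c in scored:
        idx = list(range(c.start_index, c.end_index + 1))
        if len(idx) < 2:
            continue
        hits = sum(1 for i in idx for j in idx
                   if i != j and lab[i] >= 0 and lab[i] == lab[j])
        fracs.append(hits / (len(idx) * (len(idx) - 1)))
    return float(np.median(fracs)) if fracs else 0.0


def _clusters(runs, p=None):
    ppm = np.arange(p if p is not None else (max(e for _, e in runs) + 1),
                    dtype=float)
    return ClusterSet([SpatialCluster(s, e, float(s), float(e))
                       for s, e in runs], ppm)


# ---------------------------------------------------------------------------
# correlation landscape


class TestLandscape:
    def test_identical_nonconstant_columns_give_one(self):
        col = np.array([1.0, 2.0, 4.0, 3.0])
        X = np.tile(col[:, None], (1, 6))
        s = SpectrumSet(np.arange(6.0), X)
        land = correlation_landscape(s, k=3)
        np.testing.assert_allclose(land.values[:4], 1.0, atol=1e-12)

    def test_independent_noise_columns_near_zero(self, rng):
        X = rng.normal(size=(500, 20))
        s = SpectrumSet(np.arange(20.0), X)
        land = correlation_landscape(s, k=5)
        assert np.nanmax(np.abs(land.values)) < 0.2

    def test_toy_matrix_matches_pairwise_oracle(self):
        X = np.array([[1.0, 2.0, 0.5, 4.0, 1.0, 0.0],
                      [2.0, 1.0, 1.5, 2.0, 0.0, 1.0],
                      [0.0, 3.0, 2.5, 1.0, 2.0, 2.0]])
        s = SpectrumSet(np.arange(6.0), X)
        land = correlation_landscape(s, k=3)
        np.testing.assert_allclose(land.values[:4], landscape_oracle(X, 3)[:4],
                                   atol=1e-10)

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_matches_oracle_on_random_small_instances(self, k, rng):
        X = rng.normal(size=(8, 40))
        X[:, 10] = 3.0  # a zero-variance column inside some windows
        s = SpectrumSet(np.arange(40.0), X)
        land = correlation_landscape(s, k)
        oracle = landscape_oracle(X, k)
        np.testing.assert_allclose(land.values[:40 - k + 1],
                                   oracle[:40 - k + 1], atol=1e-10)
        assert np.all(np.isnan(land.values[40 - k + 1:]))

    def test_values_within_unit_interval(self, small_simulation):
        _, _, observed, _, _ = small_simulation
        land = correlation_landscape(observed, k=5)
        v = land.values[land.defined]
        assert v.min() >= -1.0 - 1e-12 and v.max() <= 1.0 + 1e-12


class TestSmoothing:
    def test_kernel_weights_at_reference_points(self):
        assert KERNELS["epanechnikov"](np.array([0.0]))[0] == pytest.approx(0.75)
        assert KERNELS["epanechnikov"](np.array([1.0]))[0] == 0.0
        assert KERNELS["tricube"](np.array([0.0]))[0] == pytest.approx(1.0)
        assert KERNELS["tricube"](np.array([-1.0]))[0] == 0.0
        assert KERNELS["tricube"](np.array([1.5]))[0] == 0.0

    @pytest.mark.parametrize("kernel", ["epanechnikov", "tricube"])
    def test_constant_landscape_unchanged(self, kernel):
        land = CorrelationLandscape(np.full(30, 0.42), 4, np.arange(30.0))
        out = smooth_landscape(land, kernel)
        np.testing.assert_allclose(out.values, 0.42, atol=1e-12)

    def test_smoothing_stays_within_local_range(self, rng):
        vals = rng.uniform(-1, 1, size=60)
        land = CorrelationLandscape(vals, 5, np.arange(60.0))
        out = smooth_landscape(land, "tricube", bandwidth=3)
        for i in range(60):
            lo, hi = max(0, i - 3), min(60, i + 4)
            assert vals[lo:hi].min() - 1e-12 <= out.values[i] <= vals[lo:hi].max() + 1e-12

    def test_unknown_kernel_rejected(self):
        land = CorrelationLandscape(np.zeros(10), 3, np.arange(10.0))
        with pytest.raises(ValueError, match="unknown kernel"):
            smooth_landscape(land, "gauss")


class TestWindowSelection:
    def test_white_noise_gives_floor_of_two(self, rng):
        X = rng.normal(size=(5, 600))
        s = SpectrumSet(np.arange(600.0), X)
        assert select_window_size(s) == 2

    def test_ar1_series_cuts_off_after_lag_one(self, rng):
        from spastocsy import ar1_noise
        X = ar1_noise(2000, 0.9, 1.0, rng, n=4)
        s = SpectrumSet(np.arange(2000.0), X)
        k = select_window_size(s)
        # oracle: Durbin-Levinson PACF of the mean spectrum
        vals = pacf_oracle(X.mean(axis=0), 10)
        band = 1.959963984540054 / np.sqrt(2000)
        expected = next(lag for lag in range(1, 11) if abs(vals[lag]) < band)
        assert k == max(2, expected)

    def test_pacf_matches_durbin_levinson_oracle(self, rng):
        from statsmodels.tsa.stattools import pacf
        x = rng.normal(size=400).cumsum()  # strongly autocorrelated series
        np.testing.assert_allclose(pacf(x, nlags=8, method="ywm"),
                                   pacf_oracle(x, 8), atol=1e-8)

    def test_warns_and_returns_max_lag_when_never_inside_band(self, rng):
        x = np.sin(np.arange(400) / 3.0)  # strong periodic dependence
        s = SpectrumSet(np.arange(400.0), np.tile(x, (2, 1)))
        with pytest.warns(RuntimeWarning):
            k = select_window_size(s, max_lag=5)
        assert k == 5


class TestExtractClusters:
    def test_run_length_toy_example(self):
        vals = np.array([0.9, 0.9, 0.1, 0.9, 0.9])
        land = CorrelationLandscape(vals, 2, np.arange(5.0), smoothed=True)
        cs = extract_clusters(land, 0.5, min_size=2)
        assert [(c.start_index, c.end_index) for c in cs] == [(0, 1), (3, 4)]

    def test_everything_below_threshold_gives_empty_set(self):
        land = CorrelationLandscape(np.full(20, 0.1), 3, np.arange(20.0),
                                    smoothed=True)
        assert len(extract_clusters(land, 0.5, min_size=1)) == 0

    def test_short_runs_discarded(self):
        vals = np.array([0.9, 0.0, 0.9, 0.9, 0.9, 0.0])
        land = CorrelationLandscape(vals, 2, np.arange(6.0), smoothed=True)
        cs = extract_clusters(land, 0.5, min_size=3)
        assert [(c.start_index, c.end_index) for c in cs] == [(2, 4)]

    def test_clusters_agree_with_direct_scan(self, small_simulation):
        _, _, observed, _, _ = small_simulation
        land = smooth_landscape(correlation_landscape(observed, 5))
        cs = extract_clusters(land, 0.6, min_size=2)
        above = np.nan_to_num(land.values, nan=-np.inf) >= 0.6
        covered = np.zeros(observed.n_points, bool)
        for c in cs:
            assert above[c.start_index:c.end_index + 1].all()
            covered[c.start_index:c.end_index + 1] = True
        # every uncovered run above threshold must be shorter than min_size
        i = 0
        while i < observed.n_points:
            if above[i] and not covered[i]:
                j = i
                while j < observed.n_points and above[j] and not covered[j]:
                    j += 1
                assert j - i < 2
                i = j
            else:
                i += 1

    def test_raising_lambda_shrinks_never_merges(self, rng):
        for _ in range(100):
            vals = rng.uniform(0, 1, size=rng.integers(20, 60))
            land = CorrelationLandscape(vals, 2, np.arange(float(vals.size)),
                                        smoothed=True)
            l1, l2 = sorted(rng.uniform(0.05, 0.95, size=2))
            lo = extract_clusters(land, l1, min_size=1)
            hi = extract_clusters(land, l2, min_size=1)
            for c in hi:
                # each high-threshold cluster sits inside one low-threshold one
                assert any(o.start_index <= c.start_index
                           and c.end_index <= o.end_index for o in lo)


class TestPredictionStrength:
    def test_identical_clusterings_give_one(self):
        cs = _clusters([(0, 4), (8, 12)], p=20)
        assert co_membership_strength(cs, cs, 20) == 1.0

    def test_all_singleton_opposing_clustering_gives_zero(self):
        scored = _clusters([(0, 4), (8, 12)], p=20)
        singles = _clusters([(i, i) for i in range(20)], p=20)
        assert co_membership_strength(scored, singles, 20) == 0.0

    def test_boundary_disagreement_matches_hand_enumeration(self):
        scored = _clusters([(0, 3), (6, 9)], p=12)
        other = _clusters([(0, 2), (3, 4), (6, 9)], p=12)
        # cluster 1: vars 0-3; 0,1,2 co-membered (6 ordered pairs of 12) -> 0.5
        # cluster 2: all four vars co-membered -> 1.0; median = 0.75
        assert co_membership_strength(scored, other, 12) == pytest.approx(0.75)
        assert co_membership_strength(scored, other, 12) == pytest.approx(
            pd_oracle(scored, other, 12))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle_on_random_clusterings(self, trial):
        rng = np.random.default_rng(trial)
        p = 30

        def random_runs():
            runs, pos = [], 0
            while pos < p - 2:
                s = pos + int(rng.integers(0, 3))
                e = min(p - 1, s + int(rng.integers(0, 5)))
                if s <= e:
                    runs.append((s, e))
                pos = e + 2
            return _clusters(runs, p)

        a, b = random_runs(), random_runs()
        assert co_membership_strength(a, b, p) == pytest.approx(
            pd_oracle(a, b, p), abs=1e-10)

    def test_stable_block_structure_scores_one(self, rng):
        # two perfectly correlated blocks separated by a flat gap: every
        # half reproduces the same clusters, so Pd = 1 at any threshold
        n, p = 12, 40
        drive = rng.normal(size=n)
        X = np.zeros((n, p))
        X[:, 5:15] = np.outer(drive, np.ones(10))
        X[:, 25:35] = np.outer(drive, np.ones(10)) * 2.0
        X[:, 5:15] += rng.normal(0, 1e-6, size=(n, 10))
        X[:, 25:35] += rng.normal(0, 1e-6, size=(n, 10))
        s = SpectrumSet(np.arange(float(p)), X)
        mean, se = prediction_strength(s, lam=0.5, k=3, n_folds=4, seed=0,
                                       min_size=2)
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)


class TestSelectThreshold:
    def _block_spectra(self, rng, n=12, p=40):
        drive = rng.normal(size=n)
        X = np.zeros((n, p))
        X[:, 5:15] = np.outer(drive, np.ones(10))
        X[:, 25:35] = np.outer(drive * 0.5, np.ones(10))
        X[:, 5:15] += rng.normal(0, 1e-6, size=(n, 10))
        X[:, 25:35] += rng.normal(0, 1e-6, size=(n, 10))
        return SpectrumSet(np.arange(float(p)), X)

    def test_flat_strength_chooses_smallest_lambda(self, rng):
        s = self._block_spectra(rng)
        res = select_threshold(s, k=3, n_folds=4, seed=0, min_size=2)
        assert res.chosen_lambda == res.lambda_grid[0]
        assert np.all(res.mean_strength >= 0) and np.all(res.mean_strength <= 1)

    def test_one_se_rule_allows_smaller_lambda_within_band(self, rng):
        s = self._block_spectra(rng)
        res = select_threshold(s, k=3, n_folds=4, seed=0, min_size=2)
        best = res.mean_strength.max()
        chosen_idx = np.where(res.lambda_grid == res.chosen_lambda)[0][0]
        cutoff = best - res.se_strength[np.argmax(res.mean_strength)]
        assert res.mean_strength[chosen_idx] >= cutoff
        assert not np.any(res.mean_strength[:chosen_idx] >= cutoff)

    def test_no_clusters_anywhere_raises(self):
        X = np.ones((8, 40))  # all columns zero-variance -> empty clusterings
        s = SpectrumSet(np.arange(40.0), X)
        with pytest.raises(NoStableClusteringError):
            select_threshold(s, k=3, n_folds=3, seed=0)


def test_pd_for_pair_symmetrizes_directions():
    vals1 = np.array([0.9] * 6 + [0.1] * 4 + [0.9] * 6)
    vals2 = np.array([0.9] * 4 + [0.1] * 6 + [0.9] * 6)
    land1 = CorrelationLandscape(vals1, 2, np.arange(16.0), smoothed=True)
    land2 = CorrelationLandscape(vals2, 2, np.arange(16.0), smoothed=True)
    got = _pd_for_pair((land1, land2), 0.5, 1)
    cs1 = extract_clusters(land1, 0.5, 1)
    cs2 = extract_clusters(land2, 0.5, 1)
    expected = 0.5 * (pd_oracle(cs1, cs2, 16) + pd_oracle(cs2, cs1, 16))
    assert got == pytest.approx(expected, abs=1e-10)
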
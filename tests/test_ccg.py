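import numpy as np
import pandas as pd
import pytest

from colspike.ccg import (
    CCGParams,
    CCGResult,
    bin_trials,
    ccg_from_spikes,
    classify_pair,
    cluster_pair_graph,
    compute_ccg,
    lead_lag_index,
)
from colspike.ccg import _trialwise_correlate

PARAMS = CCGParams()


def brute_force_ccg(x_j, x_k, n_lags):
    """Oracle: double loop over spike pairs, bin for bin."""
    out = np.zeros(2 * n_lags + 1)
    for i in range(x_j.shape[0]):
        tj = np.flatnonzero(x_j[i])
        tk = np.flatnonzero(x_k[i])
        for a in tj:
            for b in tk:
                d = b - a
                if -n_lags <= d <= n_lags:
                    out[d + n_lags] += 1
    return out


class TestComputeCCG:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x_j = (rng.random((5, PARAMS.n_bins)) < 0.03).astype(float)
        x_k = (rng.random((5, PARAMS.n_bins)) < 0.03).astype(float)
        res = compute_ccg(x_j, x_k, PARAMS, jitter_correct_flag=False)
        m, n = x_j.shape
        theta = n - np.abs(np.arange(-PARAMS.n_lags, PARAMS.n_lags + 1))
        expected = brute_force_ccg(x_j, x_k, PARAMS.n_lags) / (
            m * theta * x_j.mean() * x_k.mean()
        )
        np.testing.assert_allclose(res.raw, expected, rtol=1e-9, atol=1e-9)

    def test_independent_poisson_baseline(self):
        rng = np.random.default_rng(1)
        x_j = (rng.random((200, PARAMS.n_bins)) < 0.02).astype(float)
        x_k = (rng.random((200, PARAMS.n_bins)) < 0.02).astype(float)
        res = compute_ccg(x_j, x_k, PARAMS)
        assert res.raw.mean() == pytest.approx(1.0, abs=0.05)
        se = res.corrected.std() / np.sqrt(res.corrected.size)
        assert abs(res.corrected.mean()) < 3 * se + 1e-3

    def test_shifted_copy_peak(self):
        rng = np.random.default_rng(2)
        spikes = [np.sort(rng.uniform(0.4, 0.995, 20)) for _ in range(30)]
        onsets = np.arange(30) * 2.0
        sp_j = np.sort(np.concatenate([s + o for s, o in zip(spikes, onsets)]))
        sp_k = np.sort(sp_j + 0.005)  # target fires 5 ms after reference
        res = ccg_from_spikes(sp_j, sp_k, onsets, PARAMS, jitter_correct_flag=False)
        assert res.lags_ms[int(np.argmax(res.raw))] == 5.0

    def test_mirror_identity_exact(self):
        rng = np.random.default_rng(3)
        x_j = (rng.random((20, PARAMS.n_bins)) < 0.05).astype(float)
        x_k = (rng.random((20, PARAMS.n_bins)) < 0.05).astype(float)
        a = compute_ccg(x_j, x_k, PARAMS)
        b = compute_ccg(x_k, x_j, PARAMS)
        np.testing.assert_allclose(b.raw, a.raw[::-1], rtol=1e-9)
        np.testing.assert_allclose(b.corrected, a.corrected[::-1], rtol=1e-8, atol=1e-12)

    def test_zero_spike_unit_error(self):
        x = np.zeros((5, PARAMS.n_bins))
        y = np.ones((5, PARAMS.n_bins))
        with pytest.raises(ValueError, match="zero spikes"):
            compute_ccg(x, y, PARAMS)

    def test_jitter_window_smaller_than_bin_error(self):
        p = CCGParams(jitter_ms=0.5)
        x = np.ones((5, p.n_bins))
        with pytest.raises(ValueError, match="jitter"):
            compute_ccg(x, x, p)

    def test_theta_at_zero_lag(self):
        res = CCGResult(
            (0, 1), PARAMS.lags_ms, np.ones(201), None, 2, 0.1, 0.1, PARAMS
        )
        assert res.theta[100] == PARAMS.n_bins


class TestJitterCorrection:
    def test_comodulation_suppressed(self):
        rng = np.random.default_rng(4)
        n = PARAMS.n_bins
        t = np.arange(n) / 1e3
        rate = 0.08 * (1.0 + 0.9 * np.sin(2 * np.pi * 5.0 * t))  # 200 ms period
        x_j = (rng.random((5000, n)) < rate).astype(float)
        x_k = (rng.random((5000, n)) < rate).astype(float)
        res = compute_ccg(x_j, x_k, PARAMS)
        ratio = np.abs(res.corrected).max() / np.abs(res.raw - 1.0).max()
        assert ratio < 0.1  # >= 90% suppression

    def test_synaptic_peak_retained(self):
        rng = np.random.default_rng(5)
        n = PARAMS.n_bins
        x_j = (rng.random((400, n)) < 0.02).astype(float)
        x_k = (rng.random((400, n)) < 0.02).astype(float)
        transmitted = ((rng.random((400, n)) < 0.3) & (x_j == 1)).astype(float)
        x_k = np.clip(x_k + np.roll(transmitted, 2, axis=1), 0, 1)
        res = compute_ccg(x_j, x_k, PARAMS)
        i0 = PARAMS.n_lags + 2
        peak_raw = res.raw[i0] - np.median(res.raw)
        peak_corr = res.corrected[i0] - np.median(res.corrected)
        assert peak_corr >= 0.8 * peak_raw


def _fake_ccg(corrected, params=PARAMS):
    return CCGResult(
        pair=(0, 1),
        lags_ms=params.lags_ms,
        raw=corrected + 1.0,
        corrected=corrected,
        M=100,
        lambda_j=0.02,
        lambda_k=0.02,
        params=params,
    )


class TestClassifyPair:
    def _noise(self, seed, sd=0.05):
        return np.random.default_rng(seed).normal(0.0, sd, 201)

    def test_flat_is_ns(self):
        cls = classify_pair(_fake_ccg(self._noise(0)))
        assert cls.kind == "ns"

    def test_injected_peak_excitatory(self):
        y = self._noise(1)
        band = (np.abs(PARAMS.lags_ms) >= 50) & (np.abs(PARAMS.lags_ms) <= 100)
        sd = y[band].std(ddof=1)
        y[PARAMS.n_lags + 3] += 10.0 * sd
        cls = classify_pair(_fake_ccg(y))
        assert cls.kind == "excitatory"
        assert cls.extremum_lag_ms == 3.0
        assert cls.extremum_z > 7.0

    def test_injected_trough_inhibitory(self):
        y = self._noise(2)
        band = (np.abs(PARAMS.lags_ms) >= 50) & (np.abs(PARAMS.lags_ms) <= 100)
        sd = y[band].std(ddof=1)
        y[PARAMS.n_lags - 4] -= 6.0 * sd
        cls = classify_pair(_fake_ccg(y))
        assert cls.kind == "inhibitory"
        assert cls.extremum_lag_ms == -4.0

    def test_peak_outside_window_is_ns(self):
        y = self._noise(3)
        band = (np.abs(PARAMS.lags_ms) >= 50) & (np.abs(PARAMS.lags_ms) <= 100)
        y[PARAMS.n_lags + 30] += 20.0 * y[band].std(ddof=1)
        assert classify_pair(_fake_ccg(y)).kind == "ns"

    def test_degenerate_zero_sd(self):
        cls = classify_pair(_fake_ccg(np.zeros(201)))
        assert cls.kind == "ns"
        assert cls.degenerate

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(6)
        fp = 0
        n_pairs = 300
        for _ in range(n_pairs):
            y = rng.normal(0.0, 0.05, 201)
            if classify_pair(_fake_ccg(y)).kind == "excitatory":
                fp += 1
        assert fp / n_pairs < 0.01


class TestLeadLagIndex:
    def test_all_mass_right(self):
        y = np.zeros(201)
        y[PARAMS.n_lags + 2] = 0.5
        y[PARAMS.n_lags + 7] = 0.2
        assert lead_lag_index(_fake_ccg(y)) == 1.0

    def test_all_mass_left(self):
        y = np.zeros(201)
        y[PARAMS.n_lags - 3] = 0.4
        assert lead_lag_index(_fake_ccg(y)) == -1.0

    def test_symmetric_zero(self):
        y = np.zeros(201)
        y[PARAMS.n_lags - 5] = y[PARAMS.n_lags + 5] = 0.3
        assert lead_lag_index(_fake_ccg(y)) == 0.0

    def test_negative_mass_rectified(self):
        y = np.zeros(201)
        y[PARAMS.n_lags + 2] = 0.5
        y[PARAMS.n_lags - 2] = -0.9  # negative values do not count as mass
        assert lead_lag_index(_fake_ccg(y)) == 1.0

    def test_undefined_error(self):
        with pytest.raises(ValueError, match="undefined"):
            lead_lag_index(_fake_ccg(np.zeros(201)))


class TestClusterPairGraph:
    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(7)
        rows = []
        for _ in range(60):
            a, b = rng.choice(["NS", "BS", "TP"], 2, replace=False)
            rows.append(
                dict(ref_cluster=a, target_cluster=b, kind="excitatory",
                     CA=float(rng.uniform(-1, 1)))
            )
        summary = cluster_pair_graph(pd.DataFrame(rows))
        m = summary.median_CA
        for a in summary.clusters:
            for b in summary.clusters:
                if a != b and not np.isnan(m.loc[a, b]):
                    assert m.loc[a, b] == -m.loc[b, a]

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(8)
        rows = [
            dict(ref_cluster="NS", target_cluster="BS", kind="excitatory",
                 CA=float(rng.uniform(0.5, 0.9)))
            for _ in range(30)
        ]
        summary = cluster_pair_graph(pd.DataFrame(rows))
        edges = summary.directed_edges
        assert len(edges) == 1
        assert edges[0]["source"] == "NS" and edges[0]["target"] == "BS"
        assert edges[0]["p"] < 0.01

    def test_no_coupling_no_edges(self):
        rows = [
            dict(ref_cluster="NS", target_cluster="BS", kind="ns", CA=np.nan)
            for _ in range(10)
        ]
        summary = cluster_pair_graph(pd.DataFrame(rows))
        assert summary.directed_edges == []
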
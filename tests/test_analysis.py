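"""Tests for the rate, correlogram and information measures.

The single-cell information implementation is checked against an
independent brute-force oracle that builds the P(r|s) and P(r) tables by
explicit enumeration; the Bayesian decoder is checked against a direct
per-trial Gaussian-likelihood computation with scipy.
"""

import numpy as np
import pytest
from scipy import stats

import spikeseg as ss
from spikeseg.analysis import (
    ConfusionMatrix,
    RateTable,
    _circular_corr,
)
from spikeseg.protocol import Interval, SpikeRecord


def make_record(events, intervals):
    """events: list of (neuron_id, time_ms)."""
    if events:
        ids, times = map(np.array, zip(*sorted(events, key=lambda e: e[1])))
    else:
        ids, times = np.zeros(0, dtype=int), np.zeros(0)
    return SpikeRecord(ids, times.astype(float), intervals, "test")


def rate_table(rates):
    rates = np.asarray(rates, dtype=float)
    return RateTable(rates=rates, cell_ids=np.arange(rates.shape[0]))


# ---------------------------------------------------------------------------
# compute_rates


class TestComputeRates:
    def test_rate_arithmetic_and_conservation(self):
        """25 spikes in a 500 ms window is 50 spikes/s; summed rate x
        window time recovers the total event count per cell."""
        intervals = [
            Interval(0.0, 500.0, "test", 0, 0),
            Interval(500.0, 1000.0, "test", 1, 0),
        ]
        events = [(0, 10.0 + 19.0 * k) for k in range(25)]  # cell 0, stim 0
        events += [(1, 505.0 + 9.0 * k) for k in range(50)]  # cell 1, stim 1
        rec = make_record(events, intervals)
        table = ss.compute_rates(rec, slice(0, 3))
        assert table.rates[0, 0, 0] == pytest.approx(50.0)
        assert table.rates[1, 1, 0] == pytest.approx(100.0)
        assert np.all(table.rates[2] == 0.0)  # silent cell
        total = (table.rates * 0.5).sum()
        assert total == pytest.approx(len(events))

    def test_unannotated_record_rejected(self):
        rec = make_record([], [Interval(0.0, 10.0, "train", -1, 0)])
        with pytest.raises(ValueError):
            ss.compute_rates(rec, slice(0, 1))


# ---------------------------------------------------------------------------
# correlograms


class TestPopulationCorrelogram:
    def _square_wave_record(self, period=50.0, offset=25.0, n_cycles=40):
        """Two pools firing periodic volleys, the second offset in time."""
        events = []
        for c in range(n_cycles):
            for n in range(8):
                events.append((n, c * period + 1.0))
                events.append((8 + n, c * period + 1.0 + offset))
        intervals = [Interval(0.0, n_cycles * period, "test", 0, 0)]
        return make_record(events, intervals)

    def test_autocorrelation_is_one_at_zero_lag(self):
        rec = self._square_wave_record()
        corr = ss.population_correlogram(
            rec, {0: np.arange(8), 1: np.arange(8, 16)}, n_surrogates=0)
        for ac in corr.auto.values():
            assert ac[corr.lags == 0][0] == pytest.approx(1.0)

    def test_antiphase_square_waves(self):
        """Exactly anti-phase trains: cross-correlation minimal at zero lag
        and maximal at half the period."""
        rec = self._square_wave_record(period=50.0, offset=25.0)
        corr = ss.population_correlogram(
            rec, {0: np.arange(8), 1: np.arange(8, 16)}, max_lag_ms=60.0,
            n_surrogates=0)
        cc = corr.cross[(0, 1)]
        lags = corr.lags
        assert cc[lags == 0][0] <= cc.min() + 1e-12
        peak_lags = np.abs(lags[cc == cc.max()])
        assert np.all(peak_lags == 25.0)
        m = ss.antiphase_metrics(corr)
        assert m["zero_lag_cross"] < 0
        assert abs(m["peak_lag"]) == pytest.approx(25.0)
        assert m["auto_period"] == pytest.approx(50.0)
        assert not m["synchronized"]

    def test_identical_series_peak_at_zero(self):
        rec = self._square_wave_record(offset=0.0)
        corr = ss.population_correlogram(
            rec, {0: np.arange(8), 1: np.arange(8, 16)}, n_surrogates=50,
            rng=np.random.default_rng(0))
        cc = corr.cross[(0, 1)]
        assert cc[corr.lags == 0][0] == pytest.approx(1.0)
        m = ss.antiphase_metrics(corr)
        assert m["synchronized"] and m["zero_lag_is_max"]

    def test_constant_series_flagged(self):
        rec = make_record([(0, 5.0)], [Interval(0.0, 100.0, "test", 0, 0)])
        with pytest.raises(ValueError):
            _circular_corr(np.zeros(10), np.ones(10), np.arange(-2, 3))
        with pytest.raises(ValueError):
            ss.population_correlogram(rec, {0: np.array([0]),
                                            1: np.array([1])},
                                      n_surrogates=0)


# ---------------------------------------------------------------------------
# single-cell information


def brute_force_single_cell_info(rates, n_bins=10):
    """Independent enumeration oracle for the stimulus-specific
    information: builds the discrete P(r|s), P(r) tables with explicit
    loops and dictionaries."""
    rates = np.asarray(rates, dtype=float)
    n_cells, n_s, n_t = rates.shape
    out = np.zeros((n_cells, n_s))
    for c in range(n_cells):
        lo = rates[c].min()
        hi = rates[c].max()
        if hi <= lo:
            continue
        width = (hi - lo) / n_bins

        def bin_of(x):
            b = int((x - lo) / width)
            return min(b, n_bins - 1)

        cond = [dict() for _ in range(n_s)]
        marg = dict()
        for s in range(n_s):
            for t in range(n_t):
                b = bin_of(rates[c, s, t])
                cond[s][b] = cond[s].get(b, 0.0) + 1.0 / n_t
                marg[b] = marg.get(b, 0.0) + 1.0 / (n_t * n_s)
        for s in range(n_s):
            acc = 0.0
            for b, p in cond[s].items():
                acc += p * np.log2(p / marg[b])
            out[c, s] = acc
    return out


class TestSingleCellInformation:
    def test_selective_invariant_cell_reaches_one_bit(self):
        """50 spikes/s to every transform of one stimulus and silence to
        the other: the theoretical maximum of log2(2) = 1 bit."""
        rates = np.zeros((1, 2, 13))
        rates[0, 0, :] = 50.0
        info = ss.single_cell_information(rate_table(rates))
        assert info[0, 0] == pytest.approx(1.0)
        assert info[0, 1] == pytest.approx(1.0)

    def test_uninformative_cell_is_zero_bits(self):
        rates = np.full((1, 2, 13), 30.0)
        info = ss.single_cell_information(rate_table(rates))
        assert np.all(info == 0.0)

    def test_half_responsive_cell_matches_enumeration_oracle(self):
        """A cell firing to exactly half the transforms of stimulus 1 and
        silent otherwise (S=2, T=12), evaluated against the brute-force
        table enumeration."""
        rates = np.zeros((1, 2, 12))
        rates[0, 0, :6] = 50.0
        info = ss.single_cell_information(rate_table(rates))
        oracle = brute_force_single_cell_info(rates)
        assert np.allclose(info, np.clip(oracle, 0, 1), atol=1e-12)
        expected_s0 = 0.5 * np.log2(0.5 / 0.25) + 0.5 * np.log2(0.5 / 0.75)
        assert info[0, 0] == pytest.approx(expected_s0, abs=1e-12)

    def test_oracle_equivalence_on_random_tables(self, rng):
        """Implementation agrees with the independent enumeration oracle to
        1e-12 on random three-cell tables."""
        for n_s in (2, 3, 4):
            rates = rng.uniform(0, 60, size=(3, n_s, 7))
            info = ss.single_cell_information(rate_table(rates))
            oracle = brute_force_single_cell_info(rates)
            assert np.allclose(info, np.clip(oracle, 0, np.log2(n_s)),
                               atol=1e-12)

    def test_information_bounded_by_log2_s(self, rng):
        rates = rng.uniform(0, 50, size=(20, 4, 9))
        info = ss.single_cell_information(rate_table(rates))
        assert np.all(info >= 0.0) and np.all(info <= 2.0)

    def test_label_shuffling_destroys_information(self, rng):
        """Data-processing sanity: permuting the (stimulus, transform)
        labels of a selective rate table drives the median single-cell
        information towards zero."""
        rates = np.zeros((30, 2, 13))
        rates[:15, 0, :] = rng.normal(50, 2, size=(15, 13))
        rates[15:, 1, :] = rng.normal(50, 2, size=(15, 13))
        info = ss.single_cell_information(rate_table(rates))
        assert np.median(info.max(axis=1)) > 0.9
        flat = rates.reshape(30, 26)
        perm = rng.permutation(26)
        shuffled = flat[:, perm].reshape(30, 2, 13)
        info_sh = ss.single_cell_information(rate_table(shuffled))
        assert np.median(info_sh.max(axis=1)) < 0.1


# ---------------------------------------------------------------------------
# decoding and mutual information


class TestBayesianDecode:
    def test_separable_ensemble_gives_diagonal_confusion(self, rng):
        rates = np.zeros((4, 2, 8))
        rates[:2, 0, :] = 40 + rng.normal(0, 0.5, size=(2, 8))
        rates[2:, 1, :] = 40 + rng.normal(0, 0.5, size=(2, 8))
        conf = ss.bayesian_decode(rate_table(rates))
        assert np.allclose(np.diag(conf.conditional()), 1.0, atol=1e-6)

    def test_uninformative_ensemble_gives_uniform_rows(self):
        """Cells responding identically to every stimulus and transform
        cannot be decoded: the conditional rows are exactly uniform."""
        rates = np.full((3, 2, 8), 15.0)
        conf = ss.bayesian_decode(rate_table(rates))
        assert np.allclose(conf.conditional(), 0.5, atol=1e-9)

    def test_matches_direct_gaussian_computation(self, rng):
        """Single cell, two overlapping response distributions: the
        confusion table equals a direct per-trial jackknifed Gaussian
        posterior computed with scipy.stats.norm."""
        rates = np.empty((1, 2, 6))
        rates[0, 0] = [10, 11, 12, 13, 14, 15]
        rates[0, 1] = [13, 14, 15, 16, 17, 18]
        conf = ss.bayesian_decode(rate_table(rates), sd_floor_frac=0.0,
                                  sd_floor_abs=1e-6)
        expected = np.zeros((2, 2))
        r = rates[0]
        for s_true in range(2):
            for t in range(6):
                x = r[s_true, t]
                logp = []
                for s in range(2):
                    resp = np.delete(r[s], t) if s == s_true else r[s]
                    logp.append(stats.norm.logpdf(x, resp.mean(), resp.std()))
                post = np.exp(logp - np.max(logp))
                expected[s_true] += post / post.sum()
        expected /= 12.0
        assert np.allclose(conf.p, expected, atol=1e-9)

    def test_zero_variance_handled_by_sd_floor(self):
        rates = np.zeros((1, 2, 5))
        rates[0, 0, :] = 30.0
        conf = ss.bayesian_decode(rate_table(rates))
        assert np.all(np.isfinite(conf.p))
        assert conf.p.sum() == pytest.approx(1.0)


class TestMutualInformation:
    def test_perfect_decoding_reaches_one_bit(self):
        conf = ConfusionMatrix(p=np.eye(2) / 2, n_trials=10 ** 9)
        assert ss.mutual_information(conf) == pytest.approx(1.0, abs=1e-6)

    def test_independent_table_gives_zero(self):
        conf = ConfusionMatrix(p=np.full((2, 2), 0.25), n_trials=26)
        assert ss.mutual_information(conf) == 0.0

    def test_bias_correction_reduces_estimate_on_independent_draws(self, rng):
        """Plug-in MI of finite tables drawn from independent (s, s') is
        biased upward; the corrected estimate is closer to the true value
        of zero in at least 95% of 200 draws."""
        wins = 0
        n = 26
        for _ in range(200):
            counts = rng.multinomial(n, np.full(4, 0.25)).reshape(2, 2)
            conf = ConfusionMatrix(p=counts / n, n_trials=n)
            raw = ss.mutual_information(conf, bias_correct=False)
            corrected = ss.mutual_information(conf, bias_correct=True)
            if corrected <= raw:
                wins += 1
        assert wins >= 190

    def test_clipped_to_theoretical_limits(self):
        conf = ConfusionMatrix(p=np.eye(4) / 4, n_trials=8)
        val = ss.mutual_information(conf)
        assert 0.0 <= val <= 2.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            ss.mutual_information(ConfusionMatrix(p=np.eye(2) / 2, n_trials=0))


class TestMultipleCellInformation:
    def _separable_table(self, n_s, per_stim=5, n_t=8, noise=0.3, rng=None):
        rng = rng or np.random.default_rng(0)
        n_cells = n_s * per_stim
        rates = rng.normal(2.0, noise, size=(n_cells, n_s, n_t))
        for s in range(n_s):
            rows = slice(s * per_stim, (s + 1) * per_stim)
            rates[rows, s, :] = rng.normal(45.0, noise, size=(per_stim, n_t))
        return np.clip(rates, 0, None)

    def test_separable_population_reaches_ceiling_quickly(self):
        """With >= 5 exclusive invariant cells per stimulus the decoded
        information reaches log2(S) at small ensemble sizes."""
        curve = ss.multiple_cell_information(rate_table(
            self._separable_table(2)), max_cells=5,
            rng=np.random.default_rng(1))
        assert curve[1] == pytest.approx(1.0, abs=0.01)
        assert curve[-1] == pytest.approx(1.0, abs=0.01)

    def test_four_stimulus_ceiling_is_two_bits(self):
        curve = ss.multiple_cell_information(rate_table(
            self._separable_table(4)), max_cells=8,
            rng=np.random.default_rng(1))
        assert curve[-1] == pytest.approx(2.0, abs=0.02)

    def test_single_stimulus_tuning_plateaus_below_ceiling(self, rng):
        """All cells tuned to the same single stimulus (S = 3): the other
        stimuli stay confused pairwise, so the curve plateaus near
        log2(3) - 2/3 bits, well below the log2(3) ceiling."""
        rates = rng.normal(2.0, 0.3, size=(10, 3, 8))
        rates[:, 0, :] = rng.normal(45.0, 0.3, size=(10, 8))
        curve = ss.multiple_cell_information(rate_table(np.clip(rates, 0, None)),
                                             max_cells=5, rng=rng)
        assert 0.5 < curve[-1] < 1.2
        assert curve[-1] < np.log2(3) - 0.3

    def test_curve_is_monotone_up_to_noise(self):
        curve = ss.multiple_cell_information(rate_table(
            self._separable_table(2, noise=3.0)), max_cells=5,
            rng=np.random.default_rng(2))
        assert np.all(np.diff(curve) >= -0.05)
        assert np.all(curve >= 0) and np.all(curve <= 1.0)


class TestInformationScore:
    def test_two_stimulus_threshold_is_95_hundredths_of_a_bit(self):
        """For S = 2 the qualifying threshold is 0.95 x log2(2) = 0.95
        bits: a cell at 0.951 bits counts, one at 0.949 does not."""
        info = np.array([[0.951, 0.0], [0.949, 0.96]])
        assert ss.information_score(info, n_output=2) == pytest.approx(0.5)
        info_none = np.array([[0.949, 0.0], [0.2, 0.949]])
        assert ss.information_score(info_none, n_output=2) == 0.0

    def test_least_represented_stimulus_sets_the_score(self, rng):
        """100 qualifying cells for one stimulus and 80 for the other in a
        256-cell output layer scores 80/256."""
        info = np.zeros((256, 2))
        info[:100, 0] = 1.0
        info[100:180, 1] = 1.0
        assert ss.information_score(info, n_output=256) == pytest.approx(80 / 256)

    def test_evaluate_information_bundle(self, rng):
        rates = rng.uniform(0, 40, size=(12, 2, 6))
        res = ss.evaluate_information(rate_table(rates), max_cells=3,
                                      rng=rng)
        assert res.single_cell.shape == (12, 2)
        assert res.single_cell_max.shape == (12,)
        assert res.multi_cell.shape == (3,)
        assert res.ceiling == pytest.approx(1.0)
        assert 0.0 <= res.info_score <= 1.0
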
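import numpy as np
import pytest

import spinefc as sfc
from spinefc.correlogram import Correlogram
from tests.conftest import make_train


def brute_force_ccg(times_a, times_b, binwidth=1.0, max_lag=50.0):
    """O(n^2) oracle: histogram every ordered spike-pair difference."""
    k_max = int(round(max_lag / binwidth))
    counts = np.zeros(2 * k_max + 1, dtype=int)
    for ta in times_a:
        for tb in times_b:
            d = tb - ta
            if -(max_lag + binwidth / 2) <= d < max_lag + binwidth / 2:
                counts[int(np.floor(d / binwidth + 0.5)) + k_max] += 1
    return counts


class TestComputeCCG:
    def test_autocorrelogram_of_three_spikes(self, geometry):
        tr = make_train(geometry, "a", 1, [10.0, 20.0, 30.0])
        ccg = sfc.compute_ccg(tr, tr)
        lags = ccg.lags()
        assert ccg.counts[lags == 0.0] == 3
        assert ccg.counts[lags == 10.0] == 2
        assert ccg.counts[lags == -10.0] == 2

    def test_single_difference_lands_in_its_bin(self, geometry):
        a = make_train(geometry, "a", 1, [10.0])
        b = make_train(geometry, "b", 9, [16.0])
        ccg = sfc.compute_ccg(a, b)
        assert ccg.counts.sum() == 1
        assert ccg.counts[ccg.lags() == 6.0] == 1

    def test_empty_train_gives_all_zero(self, geometry):
        a = make_train(geometry, "a", 1, [])
        b = make_train(geometry, "b", 9, [5.0, 10.0])
        assert not np.any(sfc.compute_ccg(a, b).counts)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, geometry, seed):
        rng = np.random.default_rng(seed)
        a = make_train(geometry, "a", 1, np.sort(rng.uniform(0, 2000, 80)))
        b = make_train(geometry, "b", 9, np.sort(rng.uniform(0, 2000, 70)))
        ccg = sfc.compute_ccg(a, b)
        assert np.array_equal(ccg.counts, brute_force_ccg(a.times, b.times))

    def test_symmetry_under_pair_reversal(self, geometry, rng):
        """counts_ab[k] == counts_ba[-k] (unordered-pair contract)."""
        a = make_train(geometry, "a", 1, np.sort(rng.uniform(0, 5000, 120)))
        b = make_train(geometry, "b", 9, np.sort(rng.uniform(0, 5000, 90)))
        ab = sfc.compute_ccg(a, b).counts
        ba = sfc.compute_ccg(b, a).counts
        assert np.array_equal(ab, ba[::-1])

    def test_max_lag_must_be_multiple_of_binwidth(self, geometry):
        a = make_train(geometry, "a", 1, [1.0])
        with pytest.raises(ValueError):
            sfc.compute_ccg(a, a, binwidth_ms=3.0, max_lag_ms=50.0)


class TestExpectedCount:
    def test_empty_train_expects_zero(self):
        assert sfc.expected_count(0, 100, 1.0, 100.0) == 0.0

    def test_closed_form(self):
        assert sfc.expected_count(100, 100, 1.0, 100.0) == pytest.approx(0.1)

    def test_monte_carlo_mean_matches_expectation(self, geometry):
        """Mean CCG bin count of independent Poisson pairs hits n_a*n_b*dt/T."""
        deviations = []
        for seed in range(150):
            a = sfc.simulate_baseline(sfc.make_unit("a", 1, geometry), 20.0, 10.0, 0.0, seed)
            b = sfc.simulate_baseline(sfc.make_unit("b", 9, geometry), 20.0, 10.0, 0.0, 1000 + seed)
            ccg = sfc.compute_ccg(a, b)
            expected = sfc.expected_count(a, b, 1.0, 10.0)
            deviations.append(ccg.counts.mean() - expected)
        se = np.std(deviations) / np.sqrt(len(deviations))
        assert abs(np.mean(deviations)) < 3 * se


class TestNormalize:
    def make_ccg(self, counts, n_a=100, n_b=100):
        counts = np.asarray(counts)
        k = (counts.size - 1) // 2
        return Correlogram("a", "b", 1.0, float(k), counts, n_a, n_b)

    def test_counts_equal_expected_gives_zero_z(self):
        # n_a*n_b*dt/T = 100*100*0.001/10 = 1.0 per bin
        ccg = self.make_ccg(np.ones(101, dtype=int))
        ccg = sfc.normalize_ccg(ccg, 10.0)
        assert np.allclose(ccg.z, 0.0)

    def test_three_sigma_excess_gives_z_three(self):
        counts = np.full(101, 4)
        counts[60] = 10  # expected 4, excess 3*sqrt(4)
        ccg = self.make_ccg(counts, n_a=200, n_b=200)  # expected = 4
        ccg = sfc.normalize_ccg(ccg, 10.0)
        assert ccg.expected == pytest.approx(4.0)
        assert ccg.z[60] == pytest.approx(3.0)

    def test_empty_train_flags_undefined_z(self, geometry):
        a = make_train(geometry, "a", 1, [])
        b = make_train(geometry, "b", 9, [5.0])
        ccg = sfc.normalize_ccg(sfc.compute_ccg(a, b), 1.0)
        assert ccg.expected == 0.0 and ccg.z is None

    def test_null_pair_z_tail_calibration(self, geometry):
        """|z| > 1.96 in ~5% of bins for independent stationary pairs."""
        zs = []
        for seed in range(60):
            a = sfc.simulate_baseline(sfc.make_unit("a", 1, geometry), 20.0, 100.0, 0.0, seed)
            b = sfc.simulate_baseline(sfc.make_unit("b", 9, geometry), 20.0, 100.0, 0.0, 777 + seed)
            ccg = sfc.normalize_ccg(sfc.compute_ccg(a, b), 100.0)
            zs.append(ccg.z)
        frac = np.mean(np.abs(np.concatenate(zs)) > 1.96)
        assert 0.03 < frac < 0.07


class TestPolarityLatency:
    def make_z(self, z):
        z = np.asarray(z, dtype=float)
        k = (z.size - 1) // 2
        ccg = Correlogram("a", "b", 1.0, float(k),
                          np.ones(z.size, dtype=int), 10, 10,
                          expected=1.0, z=z)
        return ccg

    def test_flat_correlogram_is_none(self):
        call = sfc.call_polarity_latency(self.make_z(np.zeros(101) + 0.5))
        assert call.polarity == "none"

    def test_all_zero_counts_reports_missing_latency(self, geometry):
        a = make_train(geometry, "a", 1, [1.0])
        b = make_train(geometry, "b", 9, [5000.0])
        ccg = sfc.normalize_ccg(sfc.compute_ccg(a, b), 10.0)
        call = sfc.call_polarity_latency(ccg)
        assert call.polarity == "none" and call.latency_ms is None

    def test_tie_broken_toward_smallest_then_positive_lag(self):
        z = np.zeros(11)
        z[[1, 8]] = 4.0        # lags -4 and +3 -> smaller |lag| wins
        assert sfc.call_polarity_latency(self.make_z(z)).peak_lag_ms == 3.0
        z = np.zeros(11)
        z[[2, 8]] = 4.0        # lags -3 and +3 -> positive wins
        assert sfc.call_polarity_latency(self.make_z(z)).peak_lag_ms == 3.0

    def test_embedded_excitatory_called_at_six_ms(self, geometry):
        src = sfc.simulate_baseline(sfc.make_unit("s", 1, geometry), 8.0, 120.0, 2.0, 1)
        tgt = sfc.simulate_baseline(sfc.make_unit("t", 9, geometry), 8.0, 120.0, 2.0, 2)
        out = sfc.embed_excitatory(src, tgt, 6.0, 0.5, 0.5, 3, 120.0)
        ccg = sfc.normalize_ccg(sfc.compute_ccg(src, out), 120.0)
        call = sfc.call_polarity_latency(ccg)
        assert call.polarity == "excitatory"
        assert abs(call.latency_ms - 6.0) <= 1.0

    def test_embedded_inhibitory_called_inside_window(self, geometry):
        src = sfc.simulate_baseline(sfc.make_unit("s", 1, geometry), 15.0, 300.0, 2.0, 1)
        tgt = sfc.simulate_baseline(sfc.make_unit("t", 9, geometry), 15.0, 300.0, 2.0, 2)
        out = sfc.embed_inhibitory(src, tgt, 2.0, 5.0, 1.0, 0)
        ccg = sfc.normalize_ccg(sfc.compute_ccg(src, out), 300.0)
        call = sfc.call_polarity_latency(ccg)
        assert call.polarity == "inhibitory"
        assert call.latency_ms <= 7.0

    def test_latency_recovery_across_grid(self, geometry):
        """Median |latency error| <= 1 bin over embedded latencies 1..10 ms."""
        errors = []
        for lat in range(1, 11):
            src = sfc.simulate_baseline(
                sfc.make_unit("s", 1, geometry), 8.0, 120.0, 2.0, lat)
            tgt = sfc.simulate_baseline(
                sfc.make_unit("t", 9, geometry), 8.0, 120.0, 2.0, 100 + lat)
            out = sfc.embed_excitatory(src, tgt, float(lat), 0.5, 0.5,
                                       200 + lat, 120.0)
            ccg = sfc.normalize_ccg(sfc.compute_ccg(src, out), 120.0)
            call = sfc.call_polarity_latency(ccg)
            errors.append(abs(call.latency_ms - lat))
        assert np.median(errors) <= 1.0

    def test_mean_excitatory_latency_exceeds_inhibitory(self, geometry):
        """With couplings at the observed latency means (6.4 exc / 2.7 inh),
        recovered excitatory latencies are longer on average."""
        exc, inh = [], []
        for seed in range(6):
            src = sfc.simulate_baseline(
                sfc.make_unit("s", 1, geometry), 12.0, 200.0, 2.0, seed)
            tgt = sfc.simulate_baseline(
                sfc.make_unit("t", 9, geometry), 12.0, 200.0, 2.0, 50 + seed)
            out = sfc.embed_excitatory(src, tgt, 6.4, 0.5, 0.5, seed, 200.0)
            exc.append(sfc.call_polarity_latency(
                sfc.normalize_ccg(sfc.compute_ccg(src, out), 200.0)).latency_ms)
            out = sfc.embed_inhibitory(src, tgt, 2.7, 5.0, 1.0, seed)
            inh.append(sfc.call_polarity_latency(
                sfc.normalize_ccg(sfc.compute_ccg(src, out), 200.0)).latency_ms)
        assert np.mean(exc) > np.mean(inh)
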
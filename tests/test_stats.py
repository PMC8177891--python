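import math

import numpy as np
import pytest
from scipy import stats as sps

import spinefc as sfc
from spinefc import stats as fstats
from tests.conftest import make_train


class TestBinarize:
    def test_empty_train_all_zero(self, geometry):
        occ = sfc.binarize(make_train(geometry, "u", 1, []), 1.0, 1.0)
        assert occ.shape == (1000,) and not occ.any()

    def test_two_spikes_one_bin(self, geometry):
        occ = sfc.binarize(make_train(geometry, "u", 1, [0.2, 0.7]), 1.0, 0.01)
        assert occ.sum() == 1 and occ[0]

    def test_ones_bounded_by_spike_count(self, geometry, rng):
        tr = make_train(geometry, "u", 1, np.sort(rng.uniform(0, 5000, 300)))
        occ = sfc.binarize(tr, 1.0, 5.0)
        assert occ.sum() <= tr.n_spikes


class TestPhi:
    def test_identical_trains_perfectly_correlated(self, geometry):
        tr = make_train(geometry, "u", 1, np.arange(50) * 20.0 + 3.0)
        r, _ = sfc.phi_at_lag(tr, tr, 0.0, 1.0, 1.0)
        assert r == pytest.approx(1.0)

    def test_independent_dense_sequences_near_zero(self, geometry, rng):
        a = make_train(geometry, "a", 1, np.sort(rng.uniform(0, 10000, 3000)))
        b = make_train(geometry, "b", 9, np.sort(rng.uniform(0, 10000, 3000)))
        r, _ = sfc.phi_at_lag(a, b, 0.0, 1.0, 10.0)
        assert abs(r) < 0.05

    @pytest.mark.parametrize("lag", [-7.0, 0.0, 3.0])
    def test_matches_product_moment_oracle(self, geometry, rng, lag):
        """phi equals np.corrcoef of the aligned binary vectors."""
        a = make_train(geometry, "a", 1, np.sort(rng.uniform(0, 3000, 150)))
        b = make_train(geometry, "b", 9, np.sort(rng.uniform(0, 3000, 180)))
        r, table = sfc.phi_at_lag(a, b, lag, 1.0, 3.0)
        occ_a = sfc.binarize(a, 1.0, 3.0).astype(float)
        occ_b = sfc.binarize(b, 1.0, 3.0).astype(float)
        k = int(lag)
        va = occ_a[: occ_a.size - k] if k >= 0 else occ_a[-k:]
        vb = occ_b[k:] if k >= 0 else occ_b[: occ_b.size + k]
        assert r == pytest.approx(np.corrcoef(va, vb)[0, 1])
        assert table.M == va.size

    def test_empty_margin_gives_zero(self, geometry):
        a = make_train(geometry, "a", 1, [])
        b = make_train(geometry, "b", 9, [5.0])
        r, _ = sfc.phi_at_lag(a, b, 0.0, 1.0, 1.0)
        assert r == 0.0

    def test_zero_overlap_rejected(self, geometry):
        a = make_train(geometry, "a", 1, [0.5])
        with pytest.raises(ValueError):
            sfc.phi_at_lag(a, a, 10.0, 1.0, 0.005)


class TestPValue:
    def test_zero_r_large_table_gives_one(self):
        # margins 1000/1000 over M=10000 -> expected n11=100, chisq branch
        table = sfc.ContingencyTable(100, 900, 900, 8100)
        p, used = sfc.p_value(table, 0.0)
        assert p == 1.0 and used == "chisq"

    def test_fisher_example_matches_hypergeometric_enumeration(self):
        """Table (5,0,0,5): two-sided exact p = 2/C(10,5) = 2/252."""
        table = sfc.ContingencyTable(5, 0, 0, 5)
        p, used = sfc.p_value(table, 1.0)
        assert used == "fisher"
        assert p == pytest.approx(2 / 252)
        # independent oracle: enumerate the hypergeometric support
        probs = [sps.hypergeom.pmf(k, 10, 5, 5) for k in range(6)]
        oracle = sum(q for k, q in enumerate(probs) if q <= probs[5] + 1e-12)
        assert p == pytest.approx(oracle)

    def test_degenerate_margin_gives_one(self):
        assert sfc.p_value(sfc.ContingencyTable(0, 0, 0, 100), 0.0)[0] == 1.0

    def test_branch_concordance_near_fifty_occupied_bins(self, rng):
        """Fisher and the large-N branch agree in accept/reject >= 95% of the
        time on tables straddling the N=50 branch point."""
        agree = total = 0
        rel_diffs = []
        for _ in range(200):
            M = 5000
            na, nb = rng.integers(40, 70, 2)
            a = np.zeros(M, bool)
            b = np.zeros(M, bool)
            ia = rng.choice(M, na, replace=False)
            a[ia] = True
            b[rng.choice(M, nb, replace=False)] = True
            b[rng.choice(ia, int(rng.integers(0, 6)), replace=False)] = True
            n11 = int((a & b).sum())
            n10 = int(a.sum()) - n11
            n01 = int(b.sum()) - n11
            table = sfc.ContingencyTable(n11, n10, n01, M - n11 - n10 - n01)
            r = sfc.phi_from_table(table)
            _, p_fisher = sps.fisher_exact([[n11, n10], [n01, M - n11 - n10 - n01]])
            p_large, _ = sfc.p_value(table, r, fisher_max_n=0)
            total += 1
            agree += (p_fisher <= 0.05) == (p_large <= 0.05)
            rel_diffs.append(abs(p_large - p_fisher) / p_fisher)
        assert agree / total >= 0.95
        assert np.median(rel_diffs) <= 0.25

    def test_sidak_correction_identities(self):
        assert fstats.sidak_correct(0.0, 101) == 0.0
        assert fstats.sidak_correct(1.0, 101) == 1.0
        assert fstats.sidak_correct(0.01, 3) == pytest.approx(1 - 0.99 ** 3)


class TestAllPairs:
    def test_single_unit_yields_no_pairs(self, geometry):
        trial = sfc.Trial("one", 10.0, geometry,
                          [make_train(geometry, "u", 1, [5.0])])
        with pytest.warns(UserWarning):
            assert fstats.test_all_pairs(trial) == []

    def test_five_units_yield_ten_pairs(self, small_trial):
        assert len(fstats.test_all_pairs(small_trial)) == 10

    def test_results_invariant_to_unit_listing_order(self, small_trial):
        shuffled = small_trial.with_trains(list(reversed(small_trial.trains)))
        a = fstats.results_to_frame(fstats.test_all_pairs(small_trial))
        b = fstats.results_to_frame(fstats.test_all_pairs(shuffled))
        assert a.equals(b)

    def test_power_increases_with_efficacy(self, geometry):
        """Detection of embedded couplings is monotone in efficacy."""
        detections = []
        for eff in (0.05, 0.3, 0.8):
            params = sfc.CohortParams(
                regional_unit_means={"sDH": 4, "dDH": 8, "IG": 5, "VH": 5},
                regional_unit_sd={r: 0.0 for r in sfc.REGIONS},
                duration_s=120.0,
                rate_distribution=sfc.RateDistribution(
                    "lognormal", log_mean=float(np.log(6.0)), log_sd=0.2))
            spec = sfc.ConnectionSpec(n_excitatory=8, excitatory_latency_ms=6.0,
                                      excitatory_efficacy=eff)
            trial, truth = sfc.simulate_trial(params, spec, seed=5)
            results, _ = sfc.bh_fdr(fstats.test_all_pairs(trial))
            sig = {frozenset((r.unit_a, r.unit_b)) for r in results if r.significant}
            detections.append(sum(c.pair in sig for c in truth))
        assert detections[0] <= detections[1] <= detections[2]
        assert detections[2] >= 6


class TestBH:
    @staticmethod
    def hand_step_up(pvals, q):
        """Independent oracle: literal Benjamini-Hochberg step-up."""
        m = len(pvals)
        order = np.argsort(pvals)
        k_star = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= rank * q / m:
                k_star = rank
        flags = np.zeros(m, bool)
        if k_star:
            thr = pvals[order[k_star - 1]]
            flags = np.asarray(pvals) <= thr
        return flags

    def _results(self, pvals, geometry):
        res = []
        for i, p in enumerate(pvals):
            res.append(fstats.ConnectionResult(
                unit_a=f"a{i}", unit_b=f"b{i}", electrode_a=1, electrode_b=2,
                region_a="sDH", region_b="sDH", pair_category="sDH-sDH",
                r=0.0, p=float(p), test_used="chisq", latency_ms=None,
                polarity="none", peak_z=0.0, test_lag_ms=0.0))
        return res

    def test_all_ones_nothing_significant(self, geometry):
        out, thr = sfc.bh_fdr(self._results([1.0] * 5, geometry))
        assert thr == 0.0 and not any(r.significant for r in out)

    def test_step_up_on_small_list(self, geometry):
        # 0.04 > 3*0.05/4 = 0.0375, so the procedure stops at k=2
        out, thr = sfc.bh_fdr(self._results([0.01, 0.02, 0.04, 0.8], geometry))
        assert [r.significant for r in out] == [True, True, False, False]
        assert thr == 0.02

    def test_single_zero_p(self, geometry):
        out, _ = sfc.bh_fdr(self._results([0.0, 1.0, 1.0, 1.0], geometry))
        assert sum(r.significant for r in out) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_hand_step_up_on_random_lists(self, geometry, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.beta(0.3, 3.0, size=40)
        out, _ = sfc.bh_fdr(self._results(pvals, geometry))
        assert [r.significant for r in out] == list(self.hand_step_up(pvals, 0.05))

    def test_empty_input(self, geometry):
        assert sfc.bh_fdr([]) == ([], 0.0)
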
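import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mupoolsim import (FiringSet, central_bin_prob, ci_histogram, cisi,
                       cor_matrix, cor_mu, cross_intervals, summarize_sync)
from mupoolsim.firing import SpikeTrain, binarize
from mupoolsim.fixtures import (brute_force_ci, brute_force_coincidences,
                                make_renewal_pair)


def train(times, idx=1):
    return SpikeTrain(idx, np.asarray(sorted(times), dtype=np.int64))


def fset(*trains):
    return FiringSet({t.mu_index: t for t in trains})


class TestCorMu:
    def test_identical_series_full_correlation(self, ns_firings):
        b = binarize(ns_firings[1])
        assert cor_mu(b, b) == pytest.approx(100.0)

    def test_disjoint_supports_zero(self):
        a = binarize(train(np.arange(2000, 2400, 100)))
        b = binarize(train(np.arange(2050, 2450, 100)))
        assert cor_mu(a, b) == 0.0

    def test_single_coincidence_of_four(self):
        a = binarize(train([2000, 2100, 2200, 2300]))
        b = binarize(train([2000, 2150, 2250, 2350]))
        assert cor_mu(a, b) == pytest.approx(25.0)

    def test_symmetry_and_zero_convention(self, ns_firings):
        a = binarize(ns_firings[9])
        b = binarize(ns_firings[10])
        assert cor_mu(a, b) == pytest.approx(cor_mu(b, a))
        assert cor_mu(a, np.zeros_like(a)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cor_mu(np.zeros(10), np.zeros(11))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.sets(st.integers(2000, 2200), min_size=1, max_size=25),
        b=st.sets(st.integers(2000, 2200), min_size=1, max_size=25),
    )
    def test_bounded_symmetric_for_arbitrary_trains(self, a, b):
        sa, sb = binarize(train(a, 1)), binarize(train(b, 2))
        v = cor_mu(sa, sb)
        assert 0.0 <= v <= 100.0
        assert v == pytest.approx(cor_mu(sb, sa))
        assert cor_mu(sa, sa) == pytest.approx(100.0)

    def test_coincidences_match_set_intersection(self, rng):
        for _ in range(100):
            a = train(rng.choice(np.arange(2000, 2200),
                                 size=rng.integers(1, 20), replace=False), 1)
            b = train(rng.choice(np.arange(2000, 2200),
                                 size=rng.integers(1, 20), replace=False), 2)
            sa, sb = binarize(a), binarize(b)
            expected = brute_force_coincidences(a, b)
            got = cor_mu(sa, sb) / 100 * np.sqrt(sa.sum() * sb.sum())
            assert got == pytest.approx(expected)


class TestCorMatrix:
    def test_identical_pair_matrix(self):
        t = np.arange(2000, 4000, 25)
        m = cor_matrix(fset(train(t, 1), train(t, 2)))
        assert np.allclose(m, 100.0)

    def test_symmetric_unit_diagonal(self, ns_firings):
        m = cor_matrix(ns_firings)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 100.0)

    def test_ns_pairs_weakly_correlated(self, ns_firings):
        m = cor_matrix(ns_firings)
        off = m[np.triu_indices(57, k=1)]
        assert np.quantile(off, 0.99) < 20.0


class TestCrossIntervals:
    def test_nearest_neighbour_signs(self):
        ref = train([2010, 2020, 2030], 1)
        par = train([2011, 2019, 2031], 2)
        assert list(cross_intervals(ref, par).values) == [-1, 1, -1]

    def test_identical_trains_all_zero(self):
        t = train(np.arange(2000, 4000, 40))
        assert np.all(cross_intervals(t, train(t.times, 2)).values == 0)

    def test_tie_resolves_to_earlier_partner(self):
        ref = train([2010], 1)
        par = train([2008, 2012], 2)
        assert list(cross_intervals(ref, par).values) == [2]

    def test_length_equals_reference_count(self, ns_firings):
        ci = cross_intervals(ns_firings[1], ns_firings[2])
        assert len(ci.values) == len(ns_firings[1].in_window())

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            ref = train(rng.choice(np.arange(2000, 2300),
                                   size=rng.integers(1, 25), replace=False), 1)
            par = train(rng.choice(np.arange(2000, 2300),
                                   size=rng.integers(1, 25), replace=False), 2)
            assert np.array_equal(cross_intervals(ref, par).values,
                                  brute_force_ci(ref, par).values)


class TestCiHistogram:
    def test_coincident_mass_in_central_bin(self):
        t = train(np.arange(2000, 4000, 40))
        h = ci_histogram(cross_intervals(t, train(t.times, 2)))
        assert h.loc[0] == 1.0 and h.sum() == 1.0

    def test_small_example_bins(self):
        ref = train([2010, 2020, 2030], 1)
        par = train([2011, 2019, 2031], 2)
        h = ci_histogram(cross_intervals(ref, par))
        assert h.loc[-1] == pytest.approx(2 / 3)
        assert h.loc[1] == pytest.approx(1 / 3)

    def test_normalization_within_range(self, ns_firings):
        ci = cross_intervals(ns_firings[9], ns_firings[10])
        h = ci_histogram(ci)
        if np.abs(ci.values).max() <= 15:
            assert h.sum() == pytest.approx(1.0)
        assert h.sum() <= 1.0 + 1e-12

    def test_out_of_range_excluded(self):
        ref = train([2100], 1)
        par = train([2000], 2)  # CI = +100, beyond the +/-15 ms support
        assert ci_histogram(cross_intervals(ref, par)).sum() == 0.0

    def test_ns_histogram_flat_no_central_peak(self, ns_firings):
        # averaged over partners, the central bin should not stand out
        ref = ns_firings[1]
        hs = [ci_histogram(cross_intervals(ref, ns_firings[j]))
              for j in range(2, 30)]
        h = sum(hs) / len(hs)
        inner = h.loc[-6:6]
        assert h.loc[0] < 2 * inner.mean()


class TestCentralBinAndCisi:
    def test_central_bin_examples(self):
        ref = train([2010, 2020, 2030], 1)
        assert central_bin_prob(
            cross_intervals(ref, train([2011, 2019, 2031], 2))) == 0.0
        assert central_bin_prob(
            cross_intervals(ref, train([2010, 2025, 2030], 2))) == pytest.approx(2 / 3)
        assert central_bin_prob(
            cross_intervals(ref, train(ref.times, 2))) == 1.0

    def test_identical_pair_full_index(self):
        t = np.arange(2000, 4000, 40)
        fs = fset(train(t, 1), train(t, 2))
        assert cisi(fs, 1) == pytest.approx(100.0)

    def test_three_unit_worked_example(self):
        fs = fset(train([2010, 2020, 2030], 1),
                  train([2011, 2019, 2031], 2),
                  train([2010, 2025, 2030], 3))
        assert cisi(fs, 1) == pytest.approx(100 * 0.5 * (0 + 2 / 3))

    def test_bounded(self, ns_firings):
        for i in (1, 20, 45):
            assert 0.0 <= cisi(ns_firings, i) <= 100.0

    def test_renewal_coincidence_expectation(self):
        # independent renewal partners: P(CI = 0) ~ 1 ms / partner IPI
        probs = []
        for seed in range(20):
            a, b = make_renewal_pair(50.0, 50.0, 100_000, seed)
            probs.append(central_bin_prob(cross_intervals(a, b, (0, 100_000))))
        assert np.mean(probs) == pytest.approx(0.05, rel=0.15)


class TestSummarize:
    def test_identical_pool_saturates(self, pool):
        t = np.arange(2000, 4000, 25)
        fs = FiringSet({i: train(t, i) for i in range(1, 58)})
        summary = summarize_sync(fs, pool)
        assert np.allclose(summary.aggregates["corMU_mean"], 100.0)
        assert np.allclose(summary.aggregates["CISI_mean"], 100.0)
        assert np.allclose(summary.aggregates["corMU_sd"], 0.0)

    def test_aggregate_structure(self, ns_firings, pool):
        summary = summarize_sync(ns_firings, pool)
        assert list(summary.aggregates.index) == ["S", "FR", "FF", "all"]
        # the all-MU column aggregates all unordered pairs, so it lies within
        # the span of the per-type means only for CISI (per-MU average)
        cisi_means = summary.aggregates["CISI_mean"]
        assert (cisi_means["S"] <= cisi_means["all"] <= cisi_means["FF"] or
                cisi_means["FF"] <= cisi_means["all"] <= cisi_means["S"])
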
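"""k-multiplet tallies, doublet inversion and theoretical unanimity rates."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdisrupt.fixtures import TABLE_MULTIPLETS
from msdisrupt.multiplet import (
    doublet_mismatch_rate,
    first_copy_length_counts,
    invert_doublet_mismatch,
    mismatch_rate_by_mrr,
    multiplet_analysis,
    partition_k_subsets,
    tally_multiplets,
    theoretical_unanimity_conflicts,
    theoretical_unanimity_rate,
)


class TestInversion:
    @pytest.mark.parametrize(
        "x,p",
        [
            (6.68e-4, 3.34e-4),  # disrupted mono-C doublet mismatch
            (2.52e-3, 1.26e-3),  # disrupted di-CA doublet mismatch
            (0.0, 0.0),
            (0.5, 0.5),
        ],
    )
    def test_published_estimates(self, x, p):
        assert invert_doublet_mismatch(x) == pytest.approx(p, rel=2e-3)

    @given(st.floats(0.0, 0.5))
    @settings(deadline=None)
    def test_round_trip_identity_in_x(self, p):
        """x -> p -> 2p(1-p) reproduces x to near machine precision."""
        x = 2 * p * (1 - p)
        q = invert_doublet_mismatch(min(x, 0.5))
        assert 2 * q * (1 - q) == pytest.approx(x, abs=1e-12)

    @given(st.floats(0.0, 0.499))
    @settings(deadline=None)
    def test_round_trip_identity_in_p(self, p):
        """p -> x -> p holds to 1e-12 away from the quadratic critical point
        at p = 0.5, where the map is not invertible to float precision."""
        x = 2 * p * (1 - p)
        assert invert_doublet_mismatch(x) == pytest.approx(p, abs=1e-12)

    def test_unreliable_regime_rejected(self):
        with pytest.raises(ValueError):
            invert_doublet_mismatch(0.6)


class TestTheory:
    @pytest.mark.parametrize("p,k,expected", [(0.16, 2, 0.7312), (0.16, 5, 0.4183), (0.0, 4, 1.0)])
    def test_unanimity_rate(self, p, k, expected):
        assert round(theoretical_unanimity_rate(p, k), 4) == expected

    @pytest.mark.parametrize(
        "p,k,expected", [(0.16, 2, 3.50e-2), (1.26e-3, 3, 2.01e-9), (0.0, 4, 0.0)]
    )
    def test_unanimity_conflicts(self, p, k, expected):
        assert float(f"{theoretical_unanimity_conflicts(p, k):.3g}") == expected

    def test_rates_decline_with_k(self):
        for p in (0.01, 0.16, 0.4):
            rates = [theoretical_unanimity_rate(p, k) for k in range(2, 8)]
            conf = [theoretical_unanimity_conflicts(p, k) for k in range(2, 8)]
            assert rates == sorted(rates, reverse=True)
            assert conf == sorted(conf, reverse=True)


class TestPartition:
    def test_sizes_and_leftovers(self, rng):
        subsets = partition_k_subsets(list(range(7)), 3, rng)
        assert len(subsets) == 2 and all(len(s) == 3 for s in subsets)
        used = [x for s in subsets for x in s]
        assert len(set(used)) == 6  # disjoint

    def test_too_few_items(self, rng):
        assert partition_k_subsets([1, 2], 5, rng) == []

    def test_deterministic_under_seed(self):
        a = partition_k_subsets(list(range(10)), 2, np.random.default_rng(3))
        b = partition_k_subsets(list(range(10)), 2, np.random.default_rng(3))
        assert a == b


def _brute_force(subset):
    """Explicit enumeration oracle over all multiplets of one subset."""
    reads = [list(c.elements()) for c in subset]
    total = unanimous = 0
    per_len = Counter()
    for combo in itertools.product(*reads):
        total += 1
        if len(set(combo)) == 1:
            unanimous += 1
            per_len[combo[0]] += 1
    conflict = unanimous - max(per_len.values()) if per_len else 0
    return total, unanimous, conflict


class TestTally:
    def test_all_unanimous(self):
        t = tally_multiplets([[Counter({18: 2}), Counter({18: 3})]])
        assert t.n_multiplets == 6 and t.unanimity_rate == 1.0

    def test_hand_enumeration(self):
        t = tally_multiplets([[Counter({18: 1, 17: 1}), Counter({18: 1})]])
        assert t.n_multiplets == 2 and t.n_unanimous == 1
        assert t.unanimity_rate == 0.5

    def test_empty_first_copy_skips_subset(self):
        t = tally_multiplets([[Counter(), Counter({18: 2})]])
        assert t.n_subsets == 0 and t.n_multiplets == 0

    @given(
        st.lists(
            st.lists(
                st.dictionaries(
                    st.integers(24, 27), st.integers(1, 4), min_size=1, max_size=3
                ),
                min_size=2,
                max_size=3,
            ),
            min_size=1,
            max_size=4,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_enumeration(self, instances):
        """Counter-product tallies equal explicit multiplet enumeration."""
        subsets = [[Counter(d) for d in subset] for subset in instances]
        t = tally_multiplets(subsets)
        total = unanimous = conflict = 0
        for s in subsets:
            a, b, c = _brute_force(s)
            total += a
            unanimous += b
            conflict += c
        assert (t.n_multiplets, t.n_unanimous, t.n_conflict) == (total, unanimous, conflict)


def _doublet_counts(n_templates, p, true_len, rng, reads_per_fc=1):
    counts = {}
    for t in range(n_templates):
        fcs = []
        for _ in range(2):
            c = Counter(
                true_len if rng.random() >= p else true_len - 2
                for _ in range(reads_per_fc)
            )
            fcs.append(c)
        counts[(f"T{t}", f"T{t}")] = fcs
    return counts


class TestDoubletEstimation:
    @pytest.mark.parametrize("p", [1e-2, 1e-1])
    def test_parameter_recovery(self, p):
        rng = np.random.default_rng(17)
        counts = _doublet_counts(100_000, p, 26, rng)
        est = doublet_mismatch_rate(counts)
        assert est.p == pytest.approx(p, rel=0.10)

    def test_error_free_data_estimates_zero(self):
        rng = np.random.default_rng(0)
        counts = _doublet_counts(500, 0.0, 26, rng)
        est = doublet_mismatch_rate(counts)
        assert est.x == 0.0 and est.p == 0.0

    def test_aggregate_mismatch_matches_binomial_theory(self):
        """Observed x lies within three standard errors of 2p(1-p)."""
        p, n = 3.3e-3, 200_000
        rng = np.random.default_rng(5)
        counts = _doublet_counts(n, p, 26, rng)
        est = doublet_mismatch_rate(counts)
        x_true = 2 * p * (1 - p)
        se = np.sqrt(x_true * (1 - x_true) / n)
        assert abs(est.x - x_true) < 3 * se


def test_mismatch_rate_by_mrr_monotone_when_error_grows(clean_ca_library):
    """Error-free simulated data yields a zero mismatch rate at every MRR."""
    import pandas as pd

    from msdisrupt.consensus import (
        CoverageThresholds,
        build_first_copy_table,
        build_template_table,
        well_covered_first_copies,
    )

    _, _, _, reads = clean_ca_library
    thr = CoverageThresholds(min_proper_reads=2)
    fc = build_first_copy_table(reads, thr)
    templates = build_template_table(well_covered_first_copies(fc), 26, thr)
    curve = mismatch_rate_by_mrr(reads, templates)
    assert len(curve) >= 1
    assert (curve["mismatch_rate"] == 0.0).all()


def test_multiplet_analysis_reports_requested_ks(clean_ca_library):
    _, _, _, reads = clean_ca_library
    counts = first_copy_length_counts(reads)
    table = multiplet_analysis(counts, [2, 3], np.random.default_rng(1), p_theory=0.01)
    assert list(table["k"]) == [2, 3]
    assert (table["observed_unanimity_rate"] == 1.0).all()
    assert table["theoretical_unanimity_rate"].iloc[0] == pytest.approx(
        theoretical_unanimity_rate(0.01, 2)
    )


def test_published_multiplet_theory_columns_reproduced():
    """Every published theoretical unanimity/conflict cell follows from the
    three library error rates."""
    from msdisrupt.fixtures import ERROR_RATES

    for row in TABLE_MULTIPLETS.itertuples():
        p = ERROR_RATES[row.library]
        assert round(theoretical_unanimity_rate(p, row.k), 4) == row.theoretical_unanimity_rate
        got = float(f"{theoretical_unanimity_conflicts(p, row.k):.3g}")
        assert got == pytest.approx(row.theoretical_unanimity_conflicts, rel=1e-6)
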
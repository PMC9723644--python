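"""Hierarchical consensus tables, on-target summaries and variant flagging."""

import numpy as np
import pandas as pd
import pytest

from msdisrupt.consensus import (
    CoverageThresholds,
    build_first_copy_table,
    build_template_table,
    deviation_histogram,
    error_rate_after_variant_removal,
    error_rate_from_counts,
    modal_length,
    on_target_fraction_from_counts,
    on_target_summary,
    well_covered_first_copies,
)
from msdisrupt.fixtures import TABLE_FIRST_COPIES, TABLE_READS
from msdisrupt.readproc import READ_TABLE_COLUMNS, UNQUALIFIED


@pytest.mark.parametrize(
    "lengths,expected",
    [
        ([26, 26, 24], (26, 2)),
        ([26, 24], (None, 1)),  # tie -> no modal call
        ([18, 18, 18], (18, 3)),
        ([], (None, 0)),
    ],
)
def test_modal_length(lengths, expected):
    assert modal_length(lengths) == expected


def _read_rows(vt1, vt2, vt3, lengths, n_improper=0, conv=0.5, mrr=3):
    rows = [
        {"vt1": vt1, "vt2": vt2, "vt3": vt3, "proper": True,
         "qualified_msl": l, "conversion_rate": conv if l != UNQUALIFIED else None,
         "mrr_units": mrr if l != UNQUALIFIED else None, "on_target": None}
        for l in lengths
    ]
    rows += [
        {"vt1": "", "vt2": "", "vt3": "", "proper": False,
         "qualified_msl": UNQUALIFIED, "conversion_rate": None,
         "mrr_units": None, "on_target": None}
        for _ in range(n_improper)
    ]
    return rows


def _table(rows):
    return pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)


class TestFirstCopyTable:
    thr = CoverageThresholds(min_proper_reads=10)

    def test_well_covered_with_modal_call(self):
        rows = _read_rows("T1", "T2", "F1", [18] * 5 + [UNQUALIFIED] * 7)
        fc = build_first_copy_table(_table(rows), self.thr)
        rec = fc.iloc[0]
        assert rec.n_proper == 12 and rec.n_qualified == 5
        assert rec.well_covered and rec.modal_length == 18 and rec.n_modal == 5

    def test_too_few_qualified_not_well_covered(self):
        rows = _read_rows("T1", "T2", "F1", [18] * 2 + [UNQUALIFIED] * 10)
        fc = build_first_copy_table(_table(rows), self.thr)
        rec = fc.iloc[0]
        assert rec.properly_covered and not rec.well_covered

    def test_low_coverage_tag_error_dropped(self):
        """A tag one substitution away from a real one, seen once, is removed
        from the well-covered table by the proper-read threshold."""
        rows = _read_rows("T1", "T2", "FCAAAAAAAAAAAA1", [18] * 12)
        rows += _read_rows("T1", "T2", "FCAAAAAAAAAAAA2", [18])
        fc = build_first_copy_table(_table(rows), self.thr)
        wc = well_covered_first_copies(fc)
        assert len(fc) == 2 and len(wc) == 1

    def test_disruption_label_from_median_indices(self):
        rows = _read_rows("T1", "T2", "F1", [18] * 5, conv=0.5, mrr=3)
        rows += _read_rows("T1", "T2", "F2", [18] * 5, conv=0.95, mrr=3)
        fc = build_first_copy_table(_table(rows), CoverageThresholds(min_proper_reads=3))
        assert fc.set_index("vt3").loc["F1", "disrupted"]
        assert not fc.set_index("vt3").loc["F2", "disrupted"]


class TestTemplateTable:
    thr = CoverageThresholds(min_proper_reads=3)

    def _templates(self, fc_lengths_by_template, expected=26):
        rows = []
        for t, fcs in fc_lengths_by_template.items():
            for i, lengths in enumerate(fcs):
                rows += _read_rows(t, t, f"F{i}", lengths)
        fc = build_first_copy_table(_table(rows), self.thr)
        return build_template_table(well_covered_first_copies(fc), expected, self.thr)

    def test_unanimous_off_target_is_synthetic_variant(self):
        t = self._templates({"T1": [[25] * 3] * 3})
        assert t.iloc[0].synthetic_variant and t.iloc[0].well_covered

    def test_two_first_copies_not_well_covered(self):
        t = self._templates({"T1": [[25] * 3] * 2})
        assert not t.iloc[0].well_covered and not t.iloc[0].synthetic_variant

    def test_non_unanimous_not_flagged(self):
        t = self._templates({"T1": [[26] * 3, [26] * 3, [26] * 3, [24] * 3]})
        assert not t.iloc[0].synthetic_variant

    def test_first_copy_counts_conserved(self):
        t = self._templates({"T1": [[26] * 3] * 3, "T2": [[26] * 3] * 2})
        assert int(t["n_well_covered_first_copies"].sum()) == 5


class TestSummaries:
    def test_histogram_conserves_totals(self, rng):
        values = rng.integers(18, 34, 500)
        hist = deviation_histogram(values, 26)
        assert int(hist.sum()) == 500

    def test_on_target_summary_matches_fixture_convention(self):
        hist, frac = on_target_summary([26, 26, 24, 31, 20], 26)
        assert hist["0"] == 2 and hist["-2"] == 1 and hist[">=+5"] == 1 and hist["<=-5"] == 1
        assert frac == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "table,key,expected",
        [
            (TABLE_READS, ("CA-", "all"), 0.83),
            (TABLE_READS, ("C++", "all"), 0.99),
            (TABLE_FIRST_COPIES, ("CA-", "all"), 0.96),
        ],
    )
    def test_published_on_target_fractions(self, table, key, expected):
        assert round(on_target_fraction_from_counts(table.loc[key]), 2) == expected

    def test_published_error_rates_after_variant_removal(self):
        err_c = error_rate_from_counts(TABLE_READS.loc[("C++", "wc-synth")])
        err_ca = error_rate_from_counts(TABLE_READS.loc[("CA++", "wc-synth")])
        assert err_c == pytest.approx(3.63e-4, rel=0.005)
        assert err_ca == pytest.approx(1.26e-3, rel=0.005)


def test_error_rate_after_variant_removal_excludes_variants():
    rows = []
    rows += _read_rows("GOOD", "GOOD", "F0", [26] * 4)
    rows += _read_rows("GOOD", "GOOD", "F1", [26] * 4)
    rows += _read_rows("GOOD", "GOOD", "F2", [26] * 3 + [24])
    rows += _read_rows("VAR", "VAR", "F0", [25] * 4)
    rows += _read_rows("VAR", "VAR", "F1", [25] * 4)
    rows += _read_rows("VAR", "VAR", "F2", [25] * 4)
    reads = _table(rows)
    thr = CoverageThresholds(min_proper_reads=3)
    fc = build_first_copy_table(reads, thr)
    templates = build_template_table(well_covered_first_copies(fc), 26, thr)
    assert int(templates["synthetic_variant"].sum()) == 1
    err = error_rate_after_variant_removal(reads, templates, 26)
    assert err == pytest.approx(1 / 12)


def test_all_on_target_error_rate_zero():
    rows = _read_rows("T", "T", "F0", [26] * 3) + _read_rows("T", "T", "F1", [26] * 3) \
        + _read_rows("T", "T", "F2", [26] * 3)
    reads = _table(rows)
    thr = CoverageThresholds(min_proper_reads=3)
    fc = build_first_copy_table(reads, thr)
    templates = build_template_table(well_covered_first_copies(fc), 26, thr)
    assert error_rate_after_variant_removal(reads, templates, 26) == 0.0


def test_consensus_monotonicity():
    """With per-read error below 50%, consensus tightens at each level:
    first-copy modal error <= read error, template unanimity error <=
    first-copy error."""
    rng = np.random.default_rng(42)
    p, true_len = 0.2, 26
    rows = []
    for t in range(300):
        for f in range(3):
            lengths = [true_len if rng.random() >= p else 24 for _ in range(5)]
            rows += _read_rows(f"T{t:04d}", f"T{t:04d}", f"F{f}", lengths)
    reads = _table(rows)
    thr = CoverageThresholds(min_proper_reads=3)
    fc = build_first_copy_table(reads, thr)
    wc = well_covered_first_copies(fc)
    templates = build_template_table(wc, true_len, thr)
    read_err = (reads["qualified_msl"] != true_len).mean()
    fc_err = (wc["modal_length"].dropna() != true_len).mean()
    # a template-level error is a false unanimous off-target call
    template_err = templates["synthetic_variant"].mean()
    assert template_err <= fc_err <= read_err
    assert fc_err < p
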
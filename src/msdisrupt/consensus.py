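"""Hierarchical tag consensus: reads -> first copies -> templates.

A *first copy* is a (VT1, VT2, VT3) triplet.  It is properly-covered with
enough proper reads (a library-depth-dependent threshold), and well-covered
if additionally at least three reads are qualified.  Its consensus call is
the modal length over qualified reads.  A *template* is a (VT1, VT2) pair
with at least one well-covered first copy; it is well-covered with at least
three of them, and flagged as a *synthetic variant* when three or more first
copies unanimously agree on a length different from expected — an error
introduced during oligonucleotide synthesis rather than amplification.

Thresholding on proper-read counts removes spurious tag combinations created
by single-base sequencing errors in the varietal tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import DisruptionIndices, DisruptionThresholds
from .readproc import UNQUALIFIED, is_sufficiently_disrupted

#: per-library proper-read thresholds used for the five synthetic libraries
COVERAGE_PRESETS = {
    "A-": 10,
    "C-": 10,
    "CA-": 20,
    "C+": 50,
    "CA+": 100,
}

DEVIATION_BINS = ["<=-5", "-4", "-3", "-2", "-1", "0", "+1", "+2", "+3", "+4", ">=+5"]


@dataclass(frozen=True)
class CoverageThresholds:
    min_proper_reads: int = 10
    min_qualified_reads: int = 3
    min_well_covered_first_copies: int = 3

    def __post_init__(self) -> None:
        if min(self.min_proper_reads, self.min_qualified_reads,
               self.min_well_covered_first_copies) < 1:
            raise ValueError("coverage thresholds must be >= 1")


def modal_length(lengths) -> tuple[int | None, int]:
    """Most common length and its multiplicity.

    A tie between distinct lengths yields no modal call (mode None); the
    record is kept but excluded from consensus calls.  Empty input -> (None, 0).
    """
    counts = Counter(lengths)
    if not counts:
        return None, 0
    (top, n), *rest = counts.most_common(2)
    if rest and rest[0][1] == n:
        return None, n
    return top, n


def _lower_median(values) -> float | None:
    """Median with the lower of the two middle values for even counts."""
    vals = sorted(v for v in values if v is not None and not pd.isna(v))
    if not vals:
        return None
    return vals[(len(vals) - 1) // 2]


FIRST_COPY_COLUMNS = [
    "vt1", "vt2", "vt3", "n_proper", "n_qualified", "modal_length", "n_modal",
    "median_conversion_rate", "median_mrr", "properly_covered", "well_covered",
    "disrupted",
]


def build_first_copy_table(
    read_table: pd.DataFrame,
    thr: CoverageThresholds = CoverageThresholds(),
    dis_thr: DisruptionThresholds = DisruptionThresholds(),
) -> pd.DataFrame:
    """FIRST COPY TABLE: one row per (vt1, vt2, vt3) among proper reads.

    Disruption labels come from the (lower) median disruption indices over
    qualified reads, judged by the read-level rule.
    """
    proper = read_table[read_table["proper"].astype(bool)]
    rows = []
    for (vt1, vt2, vt3), grp in proper.groupby(["vt1", "vt2", "vt3"], sort=True):
        qual = grp[grp["qualified_msl"] != UNQUALIFIED]
        mode, n_modal = modal_length(qual["qualified_msl"].tolist())
        med_conv = _lower_median(qual["conversion_rate"])
        med_mrr = _lower_median(qual["mrr_units"])
        properly = len(grp) >= thr.min_proper_reads
        well = properly and len(qual) >= thr.min_qualified_reads
        disrupted = (
            med_mrr is not None
            and is_sufficiently_disrupted(
                DisruptionIndices(med_conv, int(med_mrr)), dis_thr
            )
        )
        rows.append(
            (vt1, vt2, vt3, len(grp), len(qual), mode, n_modal,
             med_conv, med_mrr, properly, well, disrupted)
        )
    df = pd.DataFrame(rows, columns=FIRST_COPY_COLUMNS)
    if len(df):
        df["modal_length"] = df["modal_length"].astype("Int64")
    return df


def well_covered_first_copies(fc_table: pd.DataFrame) -> pd.DataFrame:
    """WELL-COVERED FIRST COPY TABLE: drops low-coverage tag combinations."""
    return fc_table[fc_table["well_covered"].astype(bool)].reset_index(drop=True)


TEMPLATE_COLUMNS = [
    "vt1", "vt2", "n_qualified_reads", "n_well_covered_first_copies",
    "first_copy_modal_lengths", "median_conversion_rate", "median_mrr",
    "well_covered", "disrupted", "synthetic_variant",
]


def build_template_table(
    wc_fc_table: pd.DataFrame,
    expected_msl: int,
    thr: CoverageThresholds = CoverageThresholds(),
    dis_thr: DisruptionThresholds = DisruptionThresholds(),
) -> pd.DataFrame:
    """TEMPLATE TABLE from the well-covered first copy table.

    A template is any (vt1, vt2) with at least one well-covered first copy.
    Well-covered templates are flagged synthetic variants when three or more
    first copies unanimously agree on a modal length different from expected;
    a first copy without a modal call (tie) blocks unanimity.
    """
    rows = []
    for (vt1, vt2), grp in wc_fc_table.groupby(["vt1", "vt2"], sort=True):
        modes = grp["modal_length"].tolist()
        defined = [int(m) for m in modes if not pd.isna(m)]
        n_fc = len(grp)
        med_conv = _lower_median(grp["median_conversion_rate"])
        med_mrr = _lower_median(grp["median_mrr"])
        well = n_fc >= thr.min_well_covered_first_copies
        disrupted = (
            med_mrr is not None
            and is_sufficiently_disrupted(
                DisruptionIndices(med_conv, int(med_mrr)), dis_thr
            )
        )
        unanimous = len(defined) == n_fc and len(set(defined)) == 1
        synthetic = well and unanimous and defined[0] != expected_msl
        rows.append(
            (vt1, vt2, int(grp["n_qualified"].sum()), n_fc,
             ",".join(str(m) for m in defined), med_conv, med_mrr,
             well, disrupted, synthetic)
        )
    return pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)


def deviation_histogram(values, expected_msl: int) -> pd.Series:
    """Counts of deviation from the expected length, binned <=-5 ... >=+5."""
    counts = dict.fromkeys(DEVIATION_BINS, 0)
    for v in values:
        d = int(v) - expected_msl
        if d <= -5:
            key = "<=-5"
        elif d >= 5:
            key = ">=+5"
        elif d == 0:
            key = "0"
        elif d > 0:
            key = f"+{d}"
        else:
            key = str(d)
        counts[key] += 1
    return pd.Series(counts, name="count")


def on_target_summary(values, expected_msl: int) -> tuple[pd.Series, float]:
    """Deviation histogram plus on-target fraction for a collection of
    qualified read MSLs or first-copy modal lengths."""
    hist = deviation_histogram(values, expected_msl)
    total = int(hist.sum())
    frac = hist["0"] / total if total else float("nan")
    return hist, frac


def on_target_fraction_from_counts(row) -> float:
    """On-target fraction from a deviation-binned count row (bin '0' is on-target)."""
    row = pd.Series(row)
    return float(row["0"] / row.sum())


def error_rate_from_counts(row) -> float:
    """Off-target fraction from a deviation-binned count row."""
    row = pd.Series(row)
    return float((row.sum() - row["0"]) / row.sum())


def error_rate_after_variant_removal(
    read_table: pd.DataFrame,
    template_table: pd.DataFrame,
    expected_msl: int,
) -> float:
    """Off-target fraction of qualified reads, restricted to non-variant
    well-covered templates."""
    keep = template_table[
        template_table["well_covered"].astype(bool)
        & ~template_table["synthetic_variant"].astype(bool)
    ][["vt1", "vt2"]]
    qual = read_table[read_table["qualified_msl"] != UNQUALIFIED]
    merged = qual.merge(keep, on=["vt1", "vt2"], how="inner")
    if not len(merged):
        return float("nan")
    return float((merged["qualified_msl"] != expected_msl).mean())


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_first_copy_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"vt1": str, "vt2": str, "vt3": str})
    df["modal_length"] = df["modal_length"].astype("Int64")
    return df


def read_template_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"vt1": str, "vt2": str, "first_copy_modal_lengths": str},
        keep_default_na=False, na_values=[""],
    )
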
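"""Published summary tables for the five synthetic-template libraries.

These count matrices and rates are the deposited reference results for the
method on synthetic templates: deviation-binned MSL counts for reads and
first copies (per library, with and without synthetic-variant removal), the
k-multiplet unanimity statistics, and the library-level error and conversion
rates.  They are frozen inputs, never regenerated.
"""

from __future__ import annotations

import pandas as pd

from .consensus import DEVIATION_BINS

#: library -> achieved bisulfite conversion rate
CONVERSION_RATES = {"C+": 0.77, "CA+": 0.66}

#: per-read MSL error rates derived from the wc-synth deviation counts
ERROR_RATES = {"CA-": 0.16, "CA++": 1.26e-3, "C++": 3.63e-4}

#: doublet mismatch rates measured over templates with MRR <= 5
DOUBLET_MISMATCH_RATES = {"C++": 6.68e-4, "CA++": 2.52e-3}

#: per-read error rates inverted from the doublet mismatch rates
DOUBLET_ERROR_ESTIMATES = {"C++": 3.34e-4, "CA++": 1.26e-3}

_READ_ROWS = {
    # (library, subset): counts for deviations <=-5, -4 ... +4, >=+5
    ("A-", "all"): [1540, 2382, 15687, 129032, 662810, 1318654, 496859, 114349, 19831, 3342, 5390],
    ("C-", "all"): [4913, 2511, 10068, 31175, 56529, 44531, 9785, 1360, 229, 51, 200],
    ("C++", "all"): [1072, 1, 5, 14, 8451, 1641719, 60, 2, 0, 0, 0],
    ("CA-", "all"): [8957, 37395, 2357, 339586, 14455, 2120035, 5291, 18719, 18, 702, 121],
    ("CA++", "all"): [8395, 206, 848, 2544, 51425, 4413601, 14353, 244, 1, 10, 3],
    ("C++", "wc-synth"): [2, 1, 5, 12, 509, 1612051, 54, 2, 0, 0, 0],
    ("CA-", "wc-synth"): [3777, 32367, 413, 303560, 1321, 1910332, 450, 16818, 0, 589, 115],
    ("CA++", "wc-synth"): [61, 196, 2, 2453, 2076, 4312537, 405, 236, 0, 10, 3],
}

_FIRST_COPY_ROWS = {
    ("A-", "all"): [96, 58, 180, 2250, 50762, 164225, 20588, 1515, 112, 13, 5],
    ("C-", "all"): [294, 81, 383, 7171, 13146, 6717, 428, 11, 0, 0, 4],
    ("C++", "all"): [7, 0, 0, 0, 58, 11644, 0, 0, 0, 0, 0],
    ("CA-", "all"): [86, 82, 23, 1211, 275, 44142, 95, 36, 0, 2, 1],
    ("CA++", "all"): [13, 0, 2, 0, 61, 5852, 18, 0, 0, 0, 0],
    ("C++", "wc-synth"): [0, 0, 0, 0, 0, 11415, 0, 0, 0, 0, 0],
    ("CA-", "wc-synth"): [6, 54, 5, 1047, 25, 39557, 8, 32, 0, 1, 1],
    ("CA++", "wc-synth"): [0, 0, 0, 0, 0, 5680, 0, 0, 0, 0, 0],
}


def _frame(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=DEVIATION_BINS)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["library", "subset"])
    return df


#: deviation-binned read counts per library
TABLE_READS = _frame(_READ_ROWS)

#: deviation-binned first-copy modal-length counts per library
TABLE_FIRST_COPIES = _frame(_FIRST_COPY_ROWS)

_MULTIPLET_ROWS = [
    # library, k, n_subsets, n_multiplets, obs unanimity, obs conflicts,
    # theor unanimity, theor conflicts
    ("CA-", 2, 21062, 6.09e7, 0.7281, 2.36e-2, 0.7312, 3.50e-2),
    ("CA-", 3, 12110, 1.89e9, 0.6024, 6.50e-3, 0.5968, 6.86e-3),
    ("CA-", 4, 7682, 6.68e10, 0.5082, 1.99e-3, 0.4985, 1.31e-3),
    ("CA-", 5, 5048, 2.40e12, 0.4271, 3.97e-4, 0.4183, 2.51e-4),
    ("CA++", 2, 2795, 1.56e9, 0.9974, 1.58e-6, 0.9975, 1.59e-6),
    ("CA++", 3, 1722, 7.36e11, 0.9961, 4.58e-9, 0.9962, 2.01e-9),
    ("CA++", 4, 1192, 3.84e14, 0.9949, 1.53e-11, 0.9950, 2.53e-12),
    ("CA++", 5, 878, 2.14e17, 0.9937, 1.04e-13, 0.9937, 3.20e-15),
    ("C++", 2, 6082, 1.05e8, 0.9993, 1.02e-7, 0.9993, 1.32e-7),
    ("C++", 3, 3815, 8.63e9, 0.9990, 0.0, 0.9989, 4.79e-11),
    ("C++", 4, 2667, 8.05e11, 0.9986, 0.0, 0.9985, 1.74e-14),
    ("C++", 5, 2016, 7.83e13, 0.9982, 0.0, 0.9982, 6.31e-18),
]

#: k-multiplet observed and predicted statistics
TABLE_MULTIPLETS = pd.DataFrame(
    _MULTIPLET_ROWS,
    columns=[
        "library", "k", "n_subsets", "n_multiplets",
        "observed_unanimity_rate", "observed_unanimity_conflicts",
        "theoretical_unanimity_rate", "theoretical_unanimity_conflicts",
    ],
)

#: expected tract length (bp) per library
EXPECTED_LENGTHS = {"A-": 17, "C-": 18, "C+": 18, "C++": 18, "CA-": 26, "CA+": 26, "CA++": 26}

#: fraction of reads sufficiently disrupted in the mutagenized libraries
DISRUPTED_READ_FRACTIONS = {"C++": 0.29, "CA++": 0.73}
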
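"""Matched-read error estimation with independent k-multiplets.

A k-multiplet draws one qualified read from each of k different first copies
of the same template.  If the per-read length error rate is p, a doublet
(k = 2) mismatches with probability x = 2p(1 - p); inverting the observed
mismatch rate gives p = (1 - sqrt(1 - 2x)) / 2.  Unanimity of a k-multiplet
occurs with probability p^k + (1 - p)^k under a constant error model, and a
unanimous multiplet conflicts with the template's majority unanimous length
with probability p^k / (p^k + (1 - p)^k).

Multiplets are never enumerated: for a k-subset of first copies with per-copy
length counts c_i(L) and totals n_i, the number of multiplets is prod(n_i)
and the number unanimous for L is prod(c_i(L)).  Counts are kept as exact
Python integers (they reach 1e17 at realistic depth).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from math import prod, sqrt

import numpy as np
import pandas as pd

from .readproc import UNQUALIFIED

#: per-read MSL error rates derived from the deviation-count tables for the
#: three libraries amenable to consensus calling
TABLE_DERIVED_ERROR_RATES = {"CA-": 0.16, "CA++": 1.26e-3, "C++": 3.63e-4}


@dataclass(frozen=True)
class ErrorEstimate:
    """Doublet mismatch rate x and the per-read error p inverted from it."""

    x: float
    p: float


@dataclass(frozen=True)
class MultipletTally:
    k: int
    n_subsets: int
    n_multiplets: int  # exact big integer
    n_unanimous: int
    n_conflict: int

    @property
    def unanimity_rate(self) -> float:
        return self.n_unanimous / self.n_multiplets if self.n_multiplets else float("nan")

    @property
    def conflict_rate(self) -> float:
        return self.n_conflict / self.n_unanimous if self.n_unanimous else float("nan")


def invert_doublet_mismatch(x: float) -> float:
    """Per-read error rate p from the doublet mismatch rate x = 2p(1 - p)."""
    if not 0.0 <= x <= 0.5:
        raise ValueError(
            "doublet mismatch rate must be in [0, 0.5]; beyond that the "
            "per-read error exceeds 50% and estimates are unreliable"
        )
    return (1.0 - sqrt(1.0 - 2.0 * x)) / 2.0


def theoretical_unanimity_rate(p: float, k: int) -> float:
    """Probability that a k-multiplet is unanimous: p**k + (1-p)**k."""
    if not 0.0 <= p <= 1.0 or k < 1:
        raise ValueError("require p in [0,1] and k >= 1")
    return p**k + (1.0 - p) ** k


def theoretical_unanimity_conflicts(p: float, k: int) -> float:
    """Proportion of unanimous k-multiplets conflicting with the majority:
    p**k / (p**k + (1-p)**k)."""
    if not 0.0 <= p < 1.0 or k < 1:
        raise ValueError("require p in [0,1) and k >= 1")
    return p**k / (p**k + (1.0 - p) ** k)


def partition_k_subsets(
    items: list, k: int, rng: np.random.Generator
) -> list[list]:
    """Uniformly random partition into floor(n/k) disjoint subsets of size k;
    leftovers are unused.  Fewer than k items -> no subsets."""
    if k < 2:
        raise ValueError("k must be >= 2")
    order = list(rng.permutation(len(items)))
    n_sub = len(items) // k
    return [[items[i] for i in order[j * k : (j + 1) * k]] for j in range(n_sub)]


def tally_multiplets(k_subsets: list[list[Counter]]) -> MultipletTally:
    """Aggregate unanimity and conflict counts over k-subsets.

    Each subset is a list of per-first-copy Counters of qualified read
    lengths.  Subsets containing an empty first copy are skipped.  Rates are
    weighted by multiplet count across subsets.
    """
    k = len(k_subsets[0]) if k_subsets else 0
    total = unanimous = conflict = 0
    n_used = 0
    for subset in k_subsets:
        counts = [Counter(c) for c in subset]
        if any(sum(c.values()) == 0 for c in counts):
            continue
        n_used += 1
        total += prod(sum(c.values()) for c in counts)
        common = set(counts[0])
        for c in counts[1:]:
            common &= set(c)
        per_len = {L: prod(c[L] for c in counts) for L in common}
        if per_len:
            subset_unanimous = sum(per_len.values())
            unanimous += subset_unanimous
            conflict += subset_unanimous - max(per_len.values())
    return MultipletTally(k, n_used, total, unanimous, conflict)


def first_copy_length_counts(
    read_table: pd.DataFrame, fc_table: pd.DataFrame | None = None
) -> dict[tuple, list[Counter]]:
    """Qualified-read length counts per first copy, grouped by template.

    When ``fc_table`` is given, only first copies listed there (e.g. the
    well-covered table) are kept.
    """
    qual = read_table[
        read_table["proper"].astype(bool)
        & (read_table["qualified_msl"] != UNQUALIFIED)
    ]
    allowed = None
    if fc_table is not None:
        allowed = set(zip(fc_table["vt1"], fc_table["vt2"], fc_table["vt3"]))
    by_template: dict[tuple, dict[str, Counter]] = defaultdict(dict)
    for (vt1, vt2, vt3), grp in qual.groupby(["vt1", "vt2", "vt3"], sort=True):
        if allowed is not None and (vt1, vt2, vt3) not in allowed:
            continue
        by_template[(vt1, vt2)][vt3] = Counter(grp["qualified_msl"].tolist())
    return {t: [fc[v] for v in sorted(fc)] for t, fc in by_template.items()}


def multiplet_analysis(
    template_counts: dict[tuple, list[Counter]],
    ks: list[int],
    rng: np.random.Generator,
    p_theory: float | None = None,
) -> pd.DataFrame:
    """Observed (and optionally theoretical) k-multiplet statistics.

    For each k, the first copies of every template are randomly partitioned
    into disjoint k-subsets and tallied without enumeration.  Returns one row
    per k with the eight summary columns of the matched-read analysis.
    """
    rows = []
    for k in ks:
        subsets: list[list[Counter]] = []
        for fcs in template_counts.values():
            subsets.extend(partition_k_subsets(fcs, k, rng))
        tally = tally_multiplets(subsets)
        row = {
            "k": k,
            "n_subsets": tally.n_subsets,
            "n_multiplets": float(tally.n_multiplets),
            "observed_unanimity_rate": tally.unanimity_rate,
            "observed_unanimity_conflicts": tally.conflict_rate,
        }
        if p_theory is not None:
            row["theoretical_unanimity_rate"] = theoretical_unanimity_rate(p_theory, k)
            row["theoretical_unanimity_conflicts"] = theoretical_unanimity_conflicts(
                p_theory, k
            )
        rows.append(row)
    return pd.DataFrame(rows)


def doublet_mismatch_rate(template_counts: dict[tuple, list[Counter]]) -> ErrorEstimate:
    """Doublet mismatch rate over all cross-first-copy pairs, and the
    per-read error inverted from it.

    Uses every unordered pair of first copies within each template (the
    exhaustive k = 2 tally), weighting by doublet count.
    """
    total = match = 0
    for fcs in template_counts.values():
        m = len(fcs)
        for i in range(m):
            n_i = sum(fcs[i].values())
            for j in range(i + 1, m):
                n_j = sum(fcs[j].values())
                total += n_i * n_j
                match += sum(fcs[i][L] * fcs[j][L] for L in fcs[i] if L in fcs[j])
    if total == 0:
        return ErrorEstimate(float("nan"), float("nan"))
    x = (total - match) / total
    return ErrorEstimate(x, invert_doublet_mismatch(min(x, 0.5)))


def mismatch_rate_by_mrr(
    read_table: pd.DataFrame, template_table: pd.DataFrame
) -> pd.DataFrame:
    """Doublet mismatch rate stratified by template median MRR.

    Groups templates by their (rounded) median MRR and computes the
    cross-first-copy doublet mismatch rate within each group; groups with no
    doublets are omitted.  Returns columns mrr, n_doublets, mismatch_rate.
    """
    counts = first_copy_length_counts(read_table)
    mrr_of = {
        (r.vt1, r.vt2): int(round(r.median_mrr))
        for r in template_table.itertuples()
        if not pd.isna(r.median_mrr)
    }
    groups: dict[int, dict[tuple, list[Counter]]] = defaultdict(dict)
    for key, fcs in counts.items():
        if key in mrr_of:
            groups[mrr_of[key]][key] = fcs
    rows = []
    for mrr in sorted(groups):
        total = match = 0
        for fcs in groups[mrr].values():
            for i in range(len(fcs)):
                n_i = sum(fcs[i].values())
                for j in range(i + 1, len(fcs)):
                    n_j = sum(fcs[j].values())
                    total += n_i * n_j
                    match += sum(
                        fcs[i][L] * fcs[j][L] for L in fcs[i] if L in fcs[j]
                    )
        if total:
            rows.append((mrr, total, (total - match) / total))
    return pd.DataFrame(rows, columns=["mrr", "n_doublets", "mismatch_rate"])
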
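"""Locus-resolved analysis for panel-enriched genomic libraries.

Reads from capture panels are localized not by genome-scale alignment but by
direct search for the 20-bp reference sequences flanking each target
microsatellite, matched *up to C-to-T conversion*: reference C positions
match C or T (and, on the opposite polarity, G matches G or A), so converted
and unconverted reads both match.  A read pair is assigned to a locus when a
single read contains both flanks of exactly one locus; the inter-flank
distance is the length call and the intervening sequence yields the
disruption indices.  Ambiguous multi-locus hits are rejected.

Per-locus quality is summarized by the spanning ratio (covering over
bracketing read pairs) and length profiles are built from unanimous
3-multiplets, one per template.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import DisruptionIndices, MicrosatelliteDef, revcomp
from .readproc import conversion_rate, max_residual_repeat


@dataclass(frozen=True)
class LocusDef:
    """A panel target: tract definition plus reference flanks and context."""

    locus_id: str
    chrom: str
    start: int  # 0-based half-open MS interval in the reference
    end: int
    strand: str
    ms: MicrosatelliteDef
    left_flank20: str
    right_flank20: str
    window: str  # reference context containing the MS interval
    window_start: int = 0  # reference coordinate of window[0]

    @property
    def reference_length(self) -> int:
        return self.end - self.start


def _longest_tandem_units(seq: str, motif_len: int) -> int:
    """Longest tandem run, in units, over all motifs of the given length."""
    best = 0
    n = len(seq)
    for i in range(n - motif_len + 1):
        u = seq[i : i + motif_len]
        if motif_len > 1 and len(set(u)) == 1:
            continue  # homopolymer motifs are handled at motif_len 1
        k = 0
        j = i
        while seq[j : j + motif_len] == u:
            k += 1
            j += motif_len
        best = max(best, k)
    return best


def flank_max_repeat_units(flank: str) -> int:
    """Largest tandem run (units) of any 1-2 bp motif within a flank."""
    return max(_longest_tandem_units(flank, 1), _longest_tandem_units(flank, 2))


def filter_loci(loci: list[LocusDef], max_flank_repeat_units: int = 5) -> list[LocusDef]:
    """Drop loci with a repeat of ``max_flank_repeat_units`` or more units of
    any 1-2 bp motif in either 20-bp flank (disruption there is unmeasured)."""
    return [
        loc
        for loc in loci
        if flank_max_repeat_units(loc.left_flank20) < max_flank_repeat_units
        and flank_max_repeat_units(loc.right_flank20) < max_flank_repeat_units
    ]


class FlankMatcher:
    """Substring matcher tolerant of bisulfite conversion.

    ``polarity="CT"`` lets reference C positions match C or T;
    ``polarity="GA"`` lets reference G positions match G or A.  Up to
    ``max_mm`` additional substitutions are allowed.
    """

    def __init__(self, reference: str, polarity: str = "CT"):
        if polarity not in ("CT", "GA"):
            raise ValueError("polarity must be 'CT' or 'GA'")
        self.reference = reference
        self.polarity = polarity
        wild = ("C", "T") if polarity == "CT" else ("G", "A")
        self.allowed = [
            frozenset(wild) if b == wild[0] else frozenset((b,)) for b in reference
        ]

    @property
    def probe(self) -> str:
        """The fully converted probe sequence."""
        src, dst = ("C", "T") if self.polarity == "CT" else ("G", "A")
        return self.reference.replace(src, dst)

    def matches_at(self, seq: str, pos: int, max_mm: int = 1) -> bool:
        if pos < 0 or pos + len(self.allowed) > len(seq):
            return False
        mm = 0
        for ok, b in zip(self.allowed, seq[pos : pos + len(self.allowed)]):
            if b not in ok:
                mm += 1
                if mm > max_mm:
                    return False
        return True

    def search(self, seq: str, max_mm: int = 1, start: int = 0) -> int | None:
        """Leftmost match position, or None."""
        for pos in range(start, len(seq) - len(self.allowed) + 1):
            if self.matches_at(seq, pos, max_mm):
                return pos
        return None


def convert_flank_patterns(locus: LocusDef) -> dict[str, tuple[FlankMatcher, FlankMatcher]]:
    """Conversion-tolerant (left, right) flank matchers for both polarities.

    The ``CT`` pair matches reads sequenced on the converted design strand;
    the ``GA`` pair matches the reverse-complement polarity, with the flank
    order swapped accordingly.
    """
    return {
        "CT": (
            FlankMatcher(locus.left_flank20, "CT"),
            FlankMatcher(locus.right_flank20, "CT"),
        ),
        "GA": (
            FlankMatcher(revcomp(locus.right_flank20), "GA"),
            FlankMatcher(revcomp(locus.left_flank20), "GA"),
        ),
    }


@dataclass
class PanelAssignment:
    locus_id: str | None
    msl: int | None
    indices: DisruptionIndices | None
    covering: bool
    bracketing_loci: frozenset  # loci bracketed (flanks seen on both sides of the pair)
    ambiguous: bool


class LocusIndex:
    """Precompiled flank matchers for a panel of loci."""

    def __init__(self, loci: list[LocusDef], max_mm: int = 1):
        self.loci = {loc.locus_id: loc for loc in loci}
        self.max_mm = max_mm
        self._matchers = {loc.locus_id: convert_flank_patterns(loc) for loc in loci}

    def _read_hits(self, read: str, locus_id: str):
        """(has_left, has_right, msl, region) for one read against one locus.

        The read is tried as-is against the CT polarity and reverse
        complemented (mapping the GA polarity back to the design strand).
        """
        left, right = self._matchers[locus_id]["CT"]
        flank_len = len(left.reference)
        for seq in (read, revcomp(read)):
            lpos = left.search(seq, self.max_mm)
            rpos_any = right.search(seq, self.max_mm)
            if lpos is not None and rpos_any is not None:
                rpos = right.search(seq, self.max_mm, start=lpos + flank_len)
                if rpos is not None:
                    ms_start = lpos + flank_len
                    return True, True, rpos - ms_start, seq[ms_start:rpos]
            if lpos is not None or rpos_any is not None:
                return lpos is not None, rpos_any is not None, None, None
        return False, False, None, None


def assign_and_measure(
    r1: str, r2: str, index: LocusIndex
) -> PanelAssignment:
    """Localize a read pair to at most one locus and measure its tract.

    A pair *covers* a locus when a single read contains both 20-bp flanks;
    it *brackets* a locus when flanks from both sides of the tract are seen
    across the pair (covering implies bracketing).  Pairs covering more than
    one locus are ambiguous and left unassigned.
    """
    covered: dict[str, tuple[int, str]] = {}
    bracketing: set[str] = set()
    for locus_id in index.loci:
        l1, r1h, msl1, reg1 = index._read_hits(r1, locus_id)
        l2, r2h, msl2, reg2 = index._read_hits(r2, locus_id)
        if msl1 is not None:
            covered[locus_id] = (msl1, reg1)
        elif msl2 is not None:
            covered[locus_id] = (msl2, reg2)
        if (l1 or l2) and (r1h or r2h):
            bracketing.add(locus_id)
    if len(covered) != 1:
        return PanelAssignment(
            None, None, None, False, frozenset(bracketing), len(covered) > 1
        )
    locus_id, (msl, region) = next(iter(covered.items()))
    ms = index.loci[locus_id].ms
    indices = DisruptionIndices(
        conversion_rate=conversion_rate(region, ms.unit),
        mrr_units=max_residual_repeat(region, ms),
    )
    return PanelAssignment(locus_id, msl, indices, True, frozenset(bracketing), False)


PANEL_READ_COLUMNS = [
    "locus_id", "vt1", "vt2", "vt3", "msl", "conversion_rate", "mrr_units",
    "covering", "bracketing",
]


def build_panel_read_table(
    records: list[dict], index: LocusIndex
) -> pd.DataFrame:
    """Panel READ TABLE from simulated records carrying tags and sequences.

    Each record holds vt1/vt2/vt3 and the raw r1/r2 sequences; assignment and
    measurement come exclusively from the flank search.  Bracketing without
    coverage is recorded against the bracketed locus when unambiguous.
    """
    rows = []
    for rec in records:
        a = assign_and_measure(rec["r1"], rec["r2"], index)
        if a.locus_id is not None:
            rows.append(
                (a.locus_id, rec["vt1"], rec["vt2"], rec["vt3"], a.msl,
                 a.indices.conversion_rate, a.indices.mrr_units, True, True)
            )
        elif len(a.bracketing_loci) == 1 and not a.ambiguous:
            (locus_id,) = a.bracketing_loci
            rows.append(
                (locus_id, rec["vt1"], rec["vt2"], rec["vt3"], None,
                 None, None, False, True)
            )
    df = pd.DataFrame(rows, columns=PANEL_READ_COLUMNS)
    if len(df):
        df["msl"] = df["msl"].astype("Int64")
    return df


def spanning_ratio(locus_reads: pd.DataFrame) -> float | None:
    """Covering over bracketing read-pair counts; None when nothing brackets."""
    n_bracket = int(locus_reads["bracketing"].sum())
    if n_bracket == 0:
        return None
    return float(locus_reads["covering"].sum() / n_bracket)


@dataclass
class LocusProfile:
    locus_id: str
    triplet_histogram: dict  # length -> count, plus the 'M' mismatch bin
    n_triplets: int
    primary_length: int | None
    genotype: tuple[int, ...]
    display_length: int | None  # the longer allele for heterozygous loci
    low_coverage: bool
    spanning: float | None = None


def locus_profile(
    locus_id: str,
    template_counts: dict[tuple, list[Counter]],
    rng: np.random.Generator,
    n_triplets: int | None = None,
    min_templates: int = 20,
    het_fraction: float = 0.25,
) -> LocusProfile:
    """Triplet length profile of one locus.

    For each template with at least three distinct first copies, a single
    3-multiplet is drawn (one read from each of three randomly selected first
    copies).  Unanimous triplets contribute to their length bin, conflicted
    ones to 'M'.  When ``n_triplets`` is given, triplets are down-sampled to
    that count for cross-library comparison.  The primary length is the most
    common unanimous length; a second allele is reported when carried by at
    least ``het_fraction`` of the unanimous triplets.
    """
    triplets = []
    for fcs in template_counts.values():
        eligible = [c for c in fcs if sum(c.values())]
        if len(eligible) < 3:
            continue
        chosen = [eligible[i] for i in rng.choice(len(eligible), 3, replace=False)]
        draws = []
        for c in chosen:
            lengths = sorted(c)
            weights = np.array([c[L] for L in lengths], float)
            draws.append(lengths[rng.choice(len(lengths), p=weights / weights.sum())])
        triplets.append(draws[0] if len(set(draws)) == 1 else "M")
    low = len(triplets) < min_templates
    if n_triplets is not None and len(triplets) > n_triplets:
        keep = rng.choice(len(triplets), n_triplets, replace=False)
        triplets = [triplets[i] for i in sorted(keep)]
    hist = Counter(triplets)
    unanimous = Counter({L: n for L, n in hist.items() if L != "M"})
    primary = None
    genotype: tuple[int, ...] = ()
    if unanimous:
        ranked = unanimous.most_common()
        primary = ranked[0][0]
        genotype = (primary,)
        if len(ranked) > 1 and ranked[1][1] >= het_fraction * sum(unanimous.values()):
            genotype = (primary, ranked[1][0])
    display = max(genotype) if genotype else None
    return LocusProfile(
        locus_id, dict(hist), len(triplets), primary, genotype, display, low
    )


def profile_panel(
    panel_reads: pd.DataFrame,
    rng: np.random.Generator,
    n_triplets: int | None = None,
    min_templates: int = 20,
) -> list[LocusProfile]:
    """Per-locus profiles (triplet histograms plus spanning ratio)."""
    profiles = []
    for locus_id, grp in panel_reads.groupby("locus_id", sort=True):
        cov = grp[grp["covering"].astype(bool) & grp["msl"].notna()]
        by_template: dict[tuple, dict[str, Counter]] = defaultdict(dict)
        for (vt1, vt2, vt3), g in cov.groupby(["vt1", "vt2", "vt3"], sort=True):
            by_template[(vt1, vt2)][vt3] = Counter(int(v) for v in g["msl"])
        counts = {t: [fc[v] for v in sorted(fc)] for t, fc in by_template.items()}
        prof = locus_profile(locus_id, counts, rng, n_triplets, min_templates)
        prof.spanning = spanning_ratio(grp)
        profiles.append(prof)
    return profiles


# ---- synthetic panel construction ----

def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_synthetic_panel(
    n_loci: int,
    unit: str,
    units_range: tuple[int, int],
    rng: np.random.Generator,
    window_len: int = 1000,
    flank_len: int = 20,
) -> list[LocusDef]:
    """Random panel loci with known tracts planted mid-window.

    Flanks are re-drawn until free of 5-unit repeats (so every locus passes
    ``filter_loci``) and are unique across loci with overwhelming probability.
    """
    loci = []
    for i in range(n_loci):
        n_units = int(rng.integers(units_range[0], units_range[1] + 1))
        ms = MicrosatelliteDef(unit, n_units)
        while True:
            lf = _random_seq(flank_len, rng)
            rf = _random_seq(flank_len, rng)
            # flanks must not extend the tract or carry their own repeats
            if flank_max_repeat_units(lf) >= 5 or flank_max_repeat_units(rf) >= 5:
                continue
            if lf.endswith(ms.unit[-1]) or rf.startswith(ms.unit[0]):
                continue
            break
        tract = ms.sequence
        pad = (window_len - len(tract) - 2 * flank_len) // 2
        window = (
            _random_seq(pad, rng) + lf + tract + rf
            + _random_seq(window_len - pad - 2 * flank_len - len(tract), rng)
        )
        start = pad + flank_len
        loci.append(
            LocusDef(
                locus_id=f"locus{i:04d}",
                chrom="chrSim",
                start=start,
                end=start + len(tract),
                strand="+",
                ms=ms,
                left_flank20=lf,
                right_flank20=rf,
                window=window,
                window_start=0,
            )
        )
    return loci


def simulate_panel_library(
    loci: list[LocusDef],
    rng: np.random.Generator,
    templates_per_locus: int = 20,
    first_copies_per_template: int = 3,
    reads_per_first_copy: int = 1,
    conversion_rate: float = 0.0,
    fragment_len: int = 300,
    read_len: int = 150,
    genotypes: dict[str, tuple[int, ...]] | None = None,
    dropout_after_run: int = 10,
    dropout_slope: float = 0.09,
    dropout_cap: float = 0.95,
) -> list[dict]:
    """Simulate tagged panel fragments and their read pairs.

    Each template draws an allele length (bp) from the locus genotype
    (reference length by default), splices a tract of that length into the
    reference window, fragments around the locus, converts once, and emits
    ``reads_per_first_copy`` read pairs per tagged first copy.  Base-quality
    dropout after long homopolymer runs is applied as in the synthetic-template
    simulator.  Records carry tags, sequences and the true locus for
    round-trip checks.
    """
    from .simulate import simulate_conversion, _tract_of_length, _longest_homopolymer, _corrupt_from

    records = []
    for loc in loci:
        alleles = (genotypes or {}).get(loc.locus_id, (loc.reference_length,))
        for t in range(templates_per_locus):
            allele = int(alleles[int(rng.integers(0, len(alleles)))])
            tract = _tract_of_length(loc.ms, allele)
            seq = loc.window[: loc.start] + tract + loc.window[loc.end :]
            ms_pos = loc.start
            lo = max(0, ms_pos + len(tract) + 20 - fragment_len)
            hi = min(ms_pos - 20, len(seq) - fragment_len)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
            frag = seq[start : start + fragment_len]
            frag = simulate_conversion(frag, conversion_rate, rng)
            vt1 = _random_seq(15, rng)
            vt2 = _random_seq(15, rng)
            # dropout keyed to the converted tract actually present in the fragment
            conv_tract = frag[ms_pos - start : ms_pos - start + len(tract)]
            run = _longest_homopolymer(conv_tract)
            p_drop = min(dropout_cap, dropout_slope * max(0, run - dropout_after_run))
            for f in range(first_copies_per_template):
                vt3 = _random_seq(15, rng)
                for _ in range(reads_per_first_copy):
                    r1 = frag[:read_len]
                    r2 = revcomp(frag)[:read_len]
                    if p_drop > 0.0 and rng.random() < p_drop:
                        r1 = _corrupt_from(r1, ms_pos - start + len(tract), rng)
                    if p_drop > 0.0 and rng.random() < p_drop:
                        r2 = _corrupt_from(
                            r2, len(frag) - (ms_pos - start), rng
                        )
                    records.append(
                        {
                            "vt1": vt1, "vt2": vt2, "vt3": vt3,
                            "r1": r1, "r2": r2,
                            "true_locus": loc.locus_id, "true_msl": allele,
                        }
                    )
    return records
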
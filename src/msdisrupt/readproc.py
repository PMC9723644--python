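"""Parse raw read pairs into tagged records and measure microsatellite lengths.

A *proper* read pair matches (allowing up to ``max_primer_mismatch``
substitutions each) UP1, UP2, UP3 and the MS-proximal flank of each read, from
which the three varietal tags are extracted at their fixed offsets.  From each
read we then search for the MS-distal flank; when found, the microsatellite
length (MSL) is the number of bases strictly between the two flank matches.
A pair is *qualified* if both reads agree on the MSL or exactly one read
reports a length; qualified pairs additionally carry two disruption indices,
the tract C-to-T conversion rate and the maximal residual repeat (MRR).

All coordinates are 0-based half-open.  Reads are handled on the design strand
as emitted by the simulator: read 2 segments are reverse complements of the
design-strand segments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .architecture import (
    DisruptionIndices,
    DisruptionThresholds,
    MicrosatelliteDef,
    ReadArchitecture,
    revcomp,
)

UNQUALIFIED = -1  # sentinel MSL for non-qualified pairs

READ_TABLE_COLUMNS = [
    "vt1", "vt2", "vt3", "proper", "qualified_msl",
    "conversion_rate", "mrr_units", "on_target",
]


def match_with_mismatch(
    haystack: str,
    pattern: str,
    max_mm: int = 0,
    start: int = 0,
    end: int | None = None,
) -> int | None:
    """Leftmost start position in ``haystack[start:end]`` where ``pattern``
    aligns with Hamming distance <= ``max_mm``; None if no such position.

    ``end`` bounds the *start* position of the match (half-open); the match
    itself may extend past ``end`` but not past the haystack.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    m = len(pattern)
    limit = len(haystack) - m
    if end is not None:
        limit = min(limit, end - 1)
    for pos in range(start, limit + 1):
        mm = 0
        for a, b in zip(pattern, haystack[pos : pos + m]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return pos
    return None


def _matches_at(haystack: str, pattern: str, pos: int, max_mm: int) -> bool:
    if pos + len(pattern) > len(haystack):
        return False
    mm = 0
    for a, b in zip(pattern, haystack[pos : pos + len(pattern)]):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def deconstruct_read_pair(
    r1: str, r2: str, arch: ReadArchitecture
) -> tuple[bool, str | None, str | None, str | None]:
    """Locate the fixed architecture segments and extract the varietal tags.

    Returns ``(proper, vt1, vt2, vt3)``; improper pairs carry no tags.  Tags
    are not validated here — tag sequencing errors are handled downstream by
    coverage filtering.
    """
    mm = arch.max_primer_mismatch
    ok = (
        _matches_at(r1, arch.up1, 0, mm)
        and _matches_at(r1, arch.left_flank, arch.r1_flank_start, mm)
        and _matches_at(r2, arch.up3, 0, mm)
        and _matches_at(r2, revcomp(arch.up2), arch.r2_up2_start, mm)
        and _matches_at(r2, revcomp(arch.right_flank), arch.r2_flank_start, mm)
        and len(r1) >= arch.r1_ms_start
        and len(r2) >= arch.r2_ms_start
    )
    if not ok:
        return False, None, None, None
    vt1 = r1[arch.r1_vt1_start : arch.r1_vt1_start + arch.vt1_len]
    vt3 = r2[arch.r2_vt3_start : arch.r2_vt3_start + arch.vt3_len]
    vt2 = revcomp(r2[arch.r2_vt2_start : arch.r2_vt2_start + arch.vt2_len])
    return True, vt1, vt2, vt3


def measure_msl(
    read: str, ms_start: int, distal_flank: str, max_mm: int = 1
) -> int | None:
    """MSL from the distance between flanks within one read.

    ``ms_start`` is the position just past the located proximal flank;
    the distal flank is searched left-to-right with up to ``max_mm``
    substitutions.  Returns the number of bases strictly between the flanks,
    or None when the distal flank is not found (the read reports no length).
    """
    pos = match_with_mismatch(read, distal_flank, max_mm, start=ms_start)
    if pos is None:
        return None
    return pos - ms_start


def classify_qualified(msl_r1: int | None, msl_r2: int | None) -> int:
    """Qualified MSL of a pair: both agree -> that value; exactly one reports
    -> that value; otherwise the sentinel -1."""
    if msl_r1 is None and msl_r2 is None:
        return UNQUALIFIED
    if msl_r1 is None:
        return msl_r2
    if msl_r2 is None:
        return msl_r1
    return msl_r1 if msl_r1 == msl_r2 else UNQUALIFIED


def conversion_rate(ms_region: str, unit: str) -> float | None:
    """Proportion of C bases converted to T within the tract.

    Counted over positions of ``ms_region`` whose base is C or T; other bases
    are uninformative for conversion and ignored.  Returns None when the unit
    carries no convertible base or no informative position is present.
    """
    if "C" not in unit:
        return None
    n_c = ms_region.count("C")
    n_t = ms_region.count("T")
    if n_c + n_t == 0:
        return None
    return n_t / (n_c + n_t)


def _longest_tandem_run(region: str, unit: str) -> int:
    """Longest run of consecutive tandem copies of ``unit`` in ``region``, in units."""
    m = len(unit)
    n = len(region)
    if m == 1:
        best = run = 0
        for b in region:
            run = run + 1 if b == unit else 0
            if run > best:
                best = run
        return best
    best = 0
    for i in range(n - m + 1):
        k = 0
        j = i
        while region[j : j + m] == unit:
            k += 1
            j += m
        if k > best:
            best = k
    return best


def max_residual_repeat(
    ms_region: str, ms: MicrosatelliteDef, mode: str = "both"
) -> int:
    """Maximal residual repeat: the largest number of tandem repeat units
    present in the (possibly disrupted) microsatellite, in units.

    With ``mode="both"`` (default) conversion-created repeats count too: for a
    mono-C tract the longest C-run *or* T-run, for a CA tract the longest
    CA-run or TA-run.  ``mode="residual_only"`` counts only the native unit.
    """
    units = {ms.unit}
    if mode == "both":
        units.add(ms.converted_unit)
    return max(_longest_tandem_run(ms_region, u) for u in units)


def is_sufficiently_disrupted(
    idx: DisruptionIndices, thr: DisruptionThresholds = DisruptionThresholds()
) -> bool:
    """True iff conversion rate is within [conv_low, conv_high] and the MRR
    does not exceed mrr_max units.  Undefined conversion rate -> False."""
    if idx.conversion_rate is None:
        return False
    return (
        thr.conv_low <= idx.conversion_rate <= thr.conv_high
        and idx.mrr_units <= thr.mrr_max
    )


@dataclass
class ReadPairRecord:
    """One parsed read pair."""

    vt1: str | None
    vt2: str | None
    vt3: str | None
    proper: bool
    msl_r1: int | None
    msl_r2: int | None
    qualified_msl: int
    indices: DisruptionIndices | None
    on_target: bool | None


def process_read_pair(r1: str, r2: str, arch: ReadArchitecture) -> ReadPairRecord:
    """Full per-pair processing: deconstruction, MSL measurement,
    qualification and disruption indices."""
    proper, vt1, vt2, vt3 = deconstruct_read_pair(r1, r2, arch)
    if not proper:
        return ReadPairRecord(None, None, None, False, None, None, UNQUALIFIED, None, None)
    mm = arch.max_primer_mismatch
    msl_r1 = measure_msl(r1, arch.r1_ms_start, arch.right_flank, mm)
    msl_r2 = measure_msl(r2, arch.r2_ms_start, revcomp(arch.left_flank), mm)
    qual = classify_qualified(msl_r1, msl_r2)
    indices = None
    on_target = None
    if qual != UNQUALIFIED:
        # take the tract from a read that reported the qualified length,
        # mapped back to the design strand
        if msl_r1 == qual:
            region = r1[arch.r1_ms_start : arch.r1_ms_start + qual]
        else:
            region = revcomp(r2[arch.r2_ms_start : arch.r2_ms_start + qual])
        indices = DisruptionIndices(
            conversion_rate=conversion_rate(region, arch.ms.unit),
            mrr_units=max_residual_repeat(region, arch.ms, arch.mrr_mode),
        )
        on_target = qual == arch.ms.expected_length_bp
    return ReadPairRecord(vt1, vt2, vt3, True, msl_r1, msl_r2, qual, indices, on_target)


def build_read_table(
    pairs: Iterable[tuple[str, str]], arch: ReadArchitecture
) -> pd.DataFrame:
    """READ TABLE from an iterable of (r1, r2) sequences.

    Columns: vt1, vt2, vt3, proper, qualified_msl (-1 sentinel),
    conversion_rate (NaN if undefined), mrr_units, on_target.
    """
    rows = []
    for r1, r2 in pairs:
        rec = process_read_pair(r1, r2, arch)
        rows.append(
            (
                rec.vt1 or "", rec.vt2 or "", rec.vt3 or "", rec.proper,
                rec.qualified_msl,
                rec.indices.conversion_rate if rec.indices else None,
                rec.indices.mrr_units if rec.indices else None,
                rec.on_target,
            )
        )
    df = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
    df["qualified_msl"] = df["qualified_msl"].astype(int)
    return df


# ---- FASTQ I/O ----

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (r1, r2) sequence pairs from two FASTQ files (gzip allowed)."""
    from Bio import SeqIO

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for rec1, rec2 in zip(
            SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq"), strict=True
        ):
            yield str(rec1.seq), str(rec2.seq)


def process_fastq(
    r1_path: str | Path, r2_path: str | Path, arch: ReadArchitecture
) -> pd.DataFrame:
    """READ TABLE from paired FASTQ files."""
    return build_read_table(iter_fastq_pairs(r1_path, r2_path), arch)


def write_read_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"vt1": str, "vt2": str, "vt3": str},
        keep_default_na=False,
        na_values=[""],
    )
    df[["vt1", "vt2", "vt3"]] = df[["vt1", "vt2", "vt3"]].fillna("")
    return df
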
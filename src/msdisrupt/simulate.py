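"""Generative model for tagged partial-mutagenesis libraries.

The simulator reproduces the bench protocol's structure: each original
template carries a random VT1/VT2 tag pair around its microsatellite tract;
the template is partially bisulfite converted once (every C independently
becomes T); several tagged first copies are then synthesized during linear
amplification, each acquiring its own VT3 and subject to polymerase slippage
(stutter); PCR and sequencing produce read pairs per first copy, with further
per-read slippage trials, uniform substitution errors, and loss of the distal
flank after long homopolymer runs (emulating base-quality decay after reading
through an undisrupted mononucleotide tract).

Slippage is modeled per replication round as a probability that depends on
the current maximal residual repeat (MRR) of the tract:

    rate(MRR) = r0 * max(0, MRR - m0) ** gamma

Each slip changes the tract by one repeat unit, deletions outnumbering
insertions (``deletion_bias``).  The defaults (r0=4.31e-7, m0=2, gamma=4.32)
put the per-round off-target rate near 5e-5 for a disrupted tract (MRR 5)
and near 1.35e-2 for an intact 13-unit CA tract (MRR 13).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import DisruptionThresholds, MicrosatelliteDef, ReadArchitecture, revcomp
from .readproc import max_residual_repeat

READ_LEN = 150
_BASES = "ACGT"


@dataclass(frozen=True)
class StutterModel:
    """MRR-dependent per-replication-round slippage model."""

    r0: float = 4.31e-7
    m0: float = 2.0
    gamma: float = 4.32
    deletion_bias: float = 0.8
    slip_units: int = 1

    def rate(self, mrr_units: int) -> float:
        """Per-round slip probability at the given maximal residual repeat."""
        return min(1.0, self.r0 * max(0.0, mrr_units - self.m0) ** self.gamma)


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    arch: ReadArchitecture
    n_templates: int = 200
    conversion_rate: float = 0.0  # 0 disables mutagenesis
    first_copies_per_template: float = 4.0  # truncated-at-1 Poisson mean
    reads_per_first_copy: float = 12.0  # truncated-at-1 Poisson mean
    linear_rounds: int = 9
    pcr_rounds: int = 18
    stutter: StutterModel = field(default_factory=StutterModel)
    seq_sub_rate: float = 0.0
    dropout_after_run: int = 10  # homopolymer run length where distal-flank loss ramps
    dropout_slope: float = 0.09
    dropout_cap: float = 0.95
    true_length_distribution: dict[int, float] | None = None  # MSL bp -> fraction
    tag_alphabet: str = "ACGT"
    seed: int = 0

    def validate(self) -> None:
        if self.n_templates <= 0:
            raise ValueError("n_templates must be positive")
        for name in ("conversion_rate", "seq_sub_rate", "dropout_slope", "dropout_cap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name != "dropout_slope":
                raise ValueError(f"{name} must be in [0, 1]")
        if self.first_copies_per_template <= 0 or self.reads_per_first_copy <= 0:
            raise ValueError("count distribution means must be positive")
        if self.true_length_distribution is not None:
            total = sum(self.true_length_distribution.values())
            if not np.isclose(total, 1.0):
                raise ValueError("true_length_distribution fractions must sum to 1")


def simulate_conversion(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Partial bisulfite conversion: each C independently becomes T with
    probability ``rate``; all other bases are unchanged."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or "C" not in seq:
        return seq
    chars = list(seq)
    for i, b in enumerate(chars):
        if b == "C" and rng.random() < rate:
            chars[i] = "T"
    return "".join(chars)


def _longest_run_location(region: str, units: tuple[str, ...]) -> tuple[int, int, str]:
    """(run length in units, start, unit) of the longest tandem run over ``units``."""
    best = (0, 0, units[0])
    for u in units:
        m = len(u)
        i = 0
        while i <= len(region) - m:
            k = 0
            j = i
            while region[j : j + m] == u:
                k += 1
                j += m
            if k > best[0]:
                best = (k, i, u)
            i = j if k else i + 1
    return best


def replicate_with_stutter(
    ms_region: str,
    ms: MicrosatelliteDef,
    model: StutterModel,
    rounds: int,
    rng: np.random.Generator,
    mrr_mode: str = "both",
) -> str:
    """Apply ``rounds`` independent slip trials to the tract sequence.

    Each trial slips with probability rate(MRR of the current region); a slip
    removes (with probability ``deletion_bias``) or duplicates one repeat unit
    within the longest residual run.  Returns the resulting tract sequence;
    a tract driven empty stays empty.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    region = ms_region
    units = (ms.unit,) if mrr_mode == "residual_only" else (ms.unit, ms.converted_unit)
    rate = None
    for _ in range(rounds):
        if rate is None:
            rate = model.rate(max_residual_repeat(region, ms, mrr_mode)) if region else 0.0
        if rate == 0.0 or rng.random() >= rate:
            continue
        run_len, start, unit = _longest_run_location(region, units)
        if run_len == 0:
            continue
        m = len(unit)
        if rng.random() < model.deletion_bias:
            region = region[:start] + region[start + m * model.slip_units :]
        else:
            region = region[:start] + unit * model.slip_units + region[start:]
        rate = None  # region changed; recompute on next trial
    return region


def _trunc_poisson(mean: float, rng: np.random.Generator) -> int:
    """Poisson draw conditioned on being >= 1."""
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def _random_tag(n: int, alphabet: str, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _tract_of_length(ms: MicrosatelliteDef, length_bp: int) -> str:
    """A tract of the unit motif truncated/extended to an exact bp length."""
    m = len(ms.unit)
    return (ms.unit * (length_bp // m + 1))[:length_bp]


def _longest_homopolymer(region: str) -> int:
    best = run = 0
    prev = ""
    for b in region:
        run = run + 1 if b == prev else 1
        prev = b
        if run > best:
            best = run
    return best


def _add_substitutions(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return read
    chars = list(read)
    n_err = rng.binomial(len(chars), rate)
    if n_err == 0:
        return read
    for i in rng.choice(len(chars), size=n_err, replace=False):
        alts = [b for b in _BASES if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _corrupt_from(read: str, pos: int, rng: np.random.Generator) -> str:
    """Replace the read tail from ``pos`` with random bases (quality collapse)."""
    if pos >= len(read):
        return read
    junk = "".join(_BASES[i] for i in rng.integers(0, 4, len(read) - pos))
    return read[:pos] + junk


TRUTH_COLUMNS = [
    "vt1", "vt2", "vt3", "template_true_msl", "template_conversion_fraction",
    "fc_true_msl", "n_reads",
]


def generate_library(cfg: SimConfig) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a full library: returns (read pairs, truth table).

    The truth table has one row per first copy, carrying its template's
    pre-conversion MSL and realized conversion fraction plus the first copy's
    post-slippage tract length.  Deterministic under a fixed config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    arch = cfg.arch
    ms = arch.ms

    if cfg.true_length_distribution:
        lengths = sorted(cfg.true_length_distribution)
        probs = np.array([cfg.true_length_distribution[l] for l in lengths], float)
        probs /= probs.sum()
    else:
        lengths, probs = [ms.expected_length_bp], np.array([1.0])

    pairs: list[tuple[str, str]] = []
    truth_rows = []
    for _ in range(cfg.n_templates):
        vt1 = _random_tag(arch.vt1_len, cfg.tag_alphabet, rng)
        vt2 = _random_tag(arch.vt2_len, cfg.tag_alphabet, rng)
        true_len = int(lengths[rng.choice(len(lengths), p=probs)])
        tract = _tract_of_length(ms, true_len)
        # conversion acts once, on the original molecule: all first copies of
        # a template share the conversion pattern
        vt1_c = simulate_conversion(vt1, cfg.conversion_rate, rng)
        vt2_c = simulate_conversion(vt2, cfg.conversion_rate, rng)
        tract_c = simulate_conversion(tract, cfg.conversion_rate, rng)
        n_conv = tract.count("C")
        conv_frac = (
            (n_conv - tract_c.count("C")) / n_conv if n_conv else float("nan")
        )
        n_fc = _trunc_poisson(cfg.first_copies_per_template, rng)
        for _ in range(n_fc):
            vt3 = _random_tag(arch.vt3_len, cfg.tag_alphabet, rng)
            fc_tract = replicate_with_stutter(
                tract_c, ms, cfg.stutter, cfg.linear_rounds, rng, arch.mrr_mode
            )
            n_reads = _trunc_poisson(cfg.reads_per_first_copy, rng)
            # tags are recorded as sequenced (post-conversion): that is the
            # identity visible to the analysis
            truth_rows.append(
                (vt1_c, vt2_c, vt3, true_len, conv_frac, len(fc_tract), n_reads)
            )
            for _ in range(n_reads):
                read_tract = replicate_with_stutter(
                    fc_tract, ms, cfg.stutter, cfg.pcr_rounds, rng, arch.mrr_mode
                )
                top = (
                    arch.up1 + vt1_c + arch.left_flank + read_tract
                    + arch.right_flank + vt2_c + arch.up2
                    + revcomp(vt3) + revcomp(arch.up3)
                )
                r1 = top[:READ_LEN]
                r2 = revcomp(top)[:READ_LEN]
                # base-quality decay after a long homopolymer: the distal
                # flank becomes unreadable with a run-length-dependent chance
                run = _longest_homopolymer(read_tract)
                p_drop = min(
                    cfg.dropout_cap,
                    cfg.dropout_slope * max(0, run - cfg.dropout_after_run),
                )
                if p_drop > 0.0 and rng.random() < p_drop:
                    r1 = _corrupt_from(r1, arch.r1_ms_start + len(read_tract), rng)
                if p_drop > 0.0 and rng.random() < p_drop:
                    r2 = _corrupt_from(r2, arch.r2_ms_start + len(read_tract), rng)
                r1 = _add_substitutions(r1, cfg.seq_sub_rate, rng)
                r2 = _add_substitutions(r2, cfg.seq_sub_rate, rng)
                pairs.append((r1, r2))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return pairs, truth


def write_fastq_pairs(
    pairs: list[tuple[str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write read pairs as two plain FASTQ files with uniform qualities."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, (r1, r2) in enumerate(pairs):
            f1.write(f"@pair{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@pair{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def expected_disruption_yield(
    ms: MicrosatelliteDef,
    rate: float,
    thr: DisruptionThresholds = DisruptionThresholds(),
    n_sim: int = 10**6,
    rng: np.random.Generator | None = None,
    mrr_mode: str = "both",
) -> float:
    """Fraction of independently converted intact tracts that are classified
    sufficiently disrupted, by Monte-Carlo simulation.

    Each draw converts every C of the intact tract with probability ``rate``
    and applies the read-level disruption rule (conversion rate within bounds,
    MRR at most ``thr.mrr_max`` units).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    unit = ms.unit
    fast = mrr_mode == "both" and unit.count("C") == 1 and "T" not in unit
    if fast:
        # one convertible position per unit: the tract reduces to a per-unit
        # conversion mask; MRR is the longest run of converted or unconverted
        # units, and the conversion rate is the mask mean
        k = ms.expected_units
        mask = rng.random((n_sim, k)) < rate
        conv = mask.mean(axis=1)
        best_t = np.zeros(n_sim, dtype=np.int32)
        best_f = np.zeros(n_sim, dtype=np.int32)
        run_t = np.zeros(n_sim, dtype=np.int32)
        run_f = np.zeros(n_sim, dtype=np.int32)
        for j in range(k):
            col = mask[:, j]
            run_t = np.where(col, run_t + 1, 0)
            run_f = np.where(col, 0, run_f + 1)
            np.maximum(best_t, run_t, out=best_t)
            np.maximum(best_f, run_f, out=best_f)
        mrr = np.maximum(best_t, best_f)
        ok = (conv >= thr.conv_low) & (conv <= thr.conv_high) & (mrr <= thr.mrr_max)
        return float(ok.mean())
    # general path: explicit sequence conversion and the readproc indices
    from .readproc import conversion_rate as conv_rate_fn
    from .architecture import DisruptionIndices
    from .readproc import is_sufficiently_disrupted

    tract = ms.sequence
    n_ok = 0
    for _ in range(n_sim):
        region = simulate_conversion(tract, rate, rng)
        idx = DisruptionIndices(
            conversion_rate=conv_rate_fn(region, unit),
            mrr_units=max_residual_repeat(region, ms, mrr_mode),
        )
        n_ok += is_sufficiently_disrupted(idx, thr)
    return n_ok / n_sim
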
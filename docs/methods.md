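# Methods

## Model overview

The package models and analyzes a partial-mutagenesis protocol for
microsatellite length (MSL) measurement. A template molecule carries a
tract of a short repeat unit (mono-C, mono-A or di-CA here) between fixed
flanking sequences, bracketed by varietal tags (VT1, VT2; 15 random bases
each) and cytosine-free universal primers (UP1, UP2). Partial bisulfite
treatment converts each C independently to T with a set probability.
Tagged linear amplification then produces *first copies*, each acquiring a
VT3 tag behind a third C-free primer (UP3), followed by PCR and 2×150 bp
paired-end sequencing. Read 1 sequences the design strand from the UP1 end
and read 2 the complement from the UP3 end, so both reads traverse the tract.

The analysis rests on two per-read *disruption indices* measured on the
inter-flank sequence:

- **conversion rate** — n_T / (n_C + n_T) over positions whose base is C or
  T (positions uninformative for conversion, e.g. the A of a CA unit, are
  ignored; a unit without C leaves the index undefined);
- **maximal residual repeat (MRR)** — the longest run of tandem repeat
  units, in units, counting both the native unit and its fully converted
  form (C-runs *and* T-runs for mono-C; CA *and* TA runs for di-CA).

A read is *sufficiently disrupted* when the conversion rate lies in
[0.15, 0.85] and the MRR does not exceed 5 units. Counting
conversion-created runs in the MRR is deliberate: complete conversion of a
C tract creates a T homopolymer that slips just as readily, and only this
convention reproduces the observed disrupted-read proportions (about 29%
for C₁₈ at 77% conversion, 73% for (CA)₁₃ at 66%) in the Monte-Carlo yield
calculation. A `residual_only` mode is available for comparison.

## Read processing

A pair is *proper* when UP1, UP2, UP3 and the MS-proximal flank of each
read match at their fixed offsets with at most one substitution each
(`max_primer_mismatch`, default 1). Tags are then taken at fixed offsets
and are not validated — tag sequencing errors produce spurious low-coverage
tag combinations that the coverage thresholds remove. The distal flank is
searched left-to-right beyond the proximal flank, again allowing one
substitution, taking the leftmost acceptable position (a 1-mismatch hit
closer to the tract wins over a more distal exact hit; the convention is
fixed, cheap, and indistinguishable on clean data). The MSL is the number
of bases strictly between the flank matches. A pair is *qualified* when
both reads agree on the MSL or exactly one reports a length; the sentinel
−1 marks unqualified pairs in the read table. Indices are computed from a
read that reported the qualified length, mapped to the design strand.
Coordinates are 0-based half-open throughout.

The conversion rate is computed from observed C/T composition rather than
against the expected unit phase, so off-target lengths still receive
indices; for clean conversion products the two definitions coincide.

## Consensus hierarchy

First copies (VT1, VT2, VT3) are *properly-covered* with at least
`min_proper_reads` proper reads (a library-depth-dependent threshold; the
five synthetic-library presets are 10, 10, 20, 50, 100) and *well-covered*
with additionally ≥3 qualified reads. The consensus call is the modal
length over qualified reads; a tie yields no modal call — the record is
kept but cannot support (or be) a consensus. Templates (VT1, VT2) require
at least one well-covered first copy, are well-covered with ≥3, and are
flagged *synthetic variants* when all their well-covered first copies have
defined modal lengths, unanimous and different from the expected length —
length errors introduced during oligonucleotide synthesis, not
amplification. A tied first copy blocks unanimity (conservative; the
evidence is genuinely mixed). Median disruption indices use the lower
median for even counts; any consistent convention lands identically against
the 0.15/0.85/5 bounds in practice.

## Matched-read error model

For two reads drawn from different first copies of one template, a length
mismatch implies at least one is wrong; at per-read error p the mismatch
probability is x = 2p(1 − p), inverted as p = (1 − √(1 − 2x))/2. The
inversion is restricted to x ≤ 0.5 (beyond it the error exceeds 50% and
the estimate is meaningless). Note the inverse map is ill-conditioned at
p = 0.5: x = 0.5 − 2δ² is indistinguishable from 0.5 in float64 for
δ ≲ 10⁻⁸, so round-trip identity is checked in the well-conditioned
direction (x → p → x) to 10⁻¹².

k-multiplets (one read from each of k first copies) are tallied exactly
without enumeration: a k-subset with per-copy length counts cᵢ(L) and
totals nᵢ contributes ∏nᵢ multiplets, ∏cᵢ(L) unanimous for L, and its
conflicts are the unanimous multiplets off the subset's majority unanimous
length. Counts are exact Python integers (they reach ~10¹⁷ at published
depth); library-level rates weight subsets by multiplet count, matching the
single library-level rates reported alongside total multiplet counts. First
copies are partitioned into disjoint k-subsets uniformly at random
(leftovers unused), deterministic under a fixed seed. Under a constant
error model the unanimity rate is pᵏ + (1 − p)ᵏ and the conflict fraction
pᵏ/(pᵏ + (1 − p)ᵏ).

## Simulator

The generator's defaults encode the protocol's stated conditions:
conversion once per template (bisulfite acts on the original molecule, so
all first copies share a conversion pattern — and the sequenced tag
identity is the converted tag), 9 linear amplification rounds to first
copies, 18 PCR rounds to reads, 2×150 bp reads. First-copy and read counts
per parent are truncated-at-1 Poisson (means 4 and 12 by default; only
depth thresholds, not depth distributions, are published). Tags are uniform
over ACGT (AGT in C-free panel-adapter mode).

Stutter is a per-replication-round slip probability depending on the
current MRR: rate(MRR) = r0·max(0, MRR − m0)^γ with r0 = 4.31×10⁻⁷,
m0 = 2, γ = 4.32, chosen once so the per-round off-target rate is ≈5×10⁻⁵
at MRR 5 (disrupted) and ≈1.35×10⁻² at MRR 13 (intact (CA)₁₃) —
bracketing the published per-round anchors (2.8×10⁻⁵, 4.95×10⁻⁵,
1.35×10⁻²). A slip removes (probability 0.8) or duplicates one unit within
the longest residual run, giving the observed deletion bias.

Sequencing substitutions are uniform across positions. Base-quality decay
after long homopolymer runs is modeled only as distal-flank loss: each read
whose tract contains a homopolymer run of r bases loses its distal flank
with probability min(0.95, 0.09·(r − 10)) (ramping above 10, where
unmutagenized mono-C spanning collapses); with an intact C₁₈ run this
yields roughly half of pairs reporting no consistent length, versus >99%
for disrupted tracts. Miscalls from quality decay are not modeled — the
pipeline's observable is flank findability.

The expected disruption yield is computed by Monte Carlo: n independent
conversions of the intact tract, classified by the read-level rule. For
units with exactly one C and no T (C, CA) the computation vectorizes over
the per-unit conversion mask, where the MRR is the longest run of converted
or unconverted units; the mask path is cross-checked in tests against an
explicit sequence-level classification.

What the simulator does not emulate: PCR efficiency/branching structure,
chimeras, capture efficiency beyond per-locus counts, quality-score
physics, indels outside the tract, and methylated-CpG non-conversion.
Passing tests therefore demonstrate the pipeline's correctness under the
stated generative assumptions, not robustness to every artifact of real
libraries.

## Panel mode

Genome-scale bisulfite alignment is replaced by direct conversion-wildcard
flank matching against per-locus reference windows: reference C matches C
or T (G matches G or A on the opposite polarity, handled by reverse
complementing the read), plus one free substitution. A pair is assigned
when a single read contains both 20-bp flanks of exactly one locus;
multi-locus hits are rejected rather than scored. Loci with a tandem run of
≥5 units of any 1–2 bp motif in either 20-bp flank are excluded (disruption
is only measured within the tract, so repeat-bearing flanks are
unreliable). A pair *brackets* a locus when flanks from both sides are seen
across the pair, and *covers* it when one read spans tract plus both
flanks; the per-locus spanning ratio is covering/bracketing.

Length profiles draw one random 3-multiplet per template with ≥3 first
copies; unanimous triplets bin by length, conflicted ones as 'M'. Loci with
fewer than 20 eligible templates are flagged low-coverage, and triplets can
be down-sampled for cross-library comparison. The primary length is the
most common unanimous length; a second allele is called when it carries at
least 25% of unanimous triplets (the genotyping threshold is this package's
choice, configurable); the display length of a heterozygous locus is the
longer allele.

The panel simulator plants known tracts mid-window in random reference
sequence, fragments around the locus, converts once per template, and
reuses the homopolymer dropout model; it hands tags to the read table
directly, since adapter-tag extraction is structurally identical to the
synthetic-template path already covered in read processing.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: simulated
libraries of tens to hundreds of templates (10³–10⁴ read pairs), 50-locus
panels, 10⁵–3×10⁵ planted doublets for parameter recovery, and 10⁶ draws
for disruption yields — sizes at which every Monte-Carlo assertion has
standard error well inside its stated tolerance. Tie-breaks are
deterministic (leftmost flank match, lower median, no modal call on ties);
degenerate inputs (empty tract, empty table, zero bracketing pairs) return
defined sentinels (0, empty frame, None) rather than raising. All
randomness flows through a single numpy Generator per run, seeded from the
configuration, so identical config + seed gives byte-identical outputs.

## Known limitations

- Primer/flank matching is substitution-only; indels inside primers or
  flanks fail the match rather than shifting it.
- The error model is direction- and length-independent; the doublet
  inversion approximates total error and upper-bounds any particular error
  type.
- Tag handling is purely threshold-based; optional 1-mismatch tag
  collapsing is not implemented.
- Panel bracketing is defined from flank observations across the pair, not
  from mapped fragment endpoints.
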
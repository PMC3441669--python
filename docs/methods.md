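# Methods

This note documents the models, conventions and numerical choices behind
`srnapipe`, and what its synthetic-data tests do and do not demonstrate
about real libraries.

## Read cleaning

Raw reads pass through the elimination steps in a fixed order: (1) low
quality, (2) 5′-adapter contaminant, (3) missing 3′ adapter, (4) empty
insert, (5) poly-A insert, (6) insert shorter than 18 nt. Each read is
attributed to the *first* step it fails, which makes the accounting
identity `high_quality = Σ removals + clean_reads` exact on every run —
the property the tests assert. Reads whose trimmed insert exceeds 30 nt
are neither clean nor any named removal class; they go to their own
`longer_than_30nt` counter, included in the identity (the bundled −S
reference counters are internally inconsistent by one read as printed;
reports rebuilt from removal counters restore exact conservation).

Definitions the field leaves loose are parameterized and defaulted here:

- **High quality**: a read is low quality when more than 50% of its base
  calls are below Phred 20 (Sanger +33). Reads containing `N` also fail.
  Both the fraction and the threshold are configurable (`QualityConfig`).
- **3′-adapter detection**: exact match of the adapter's first 6 nt
  (configurable), leftmost occurrence; the insert is everything before
  it. Mismatch-tolerant matching is out of scope — exact matching keeps
  the stage deterministic.
- **5′-adapter contaminant**: the read begins with the first 6 nt of the
  5′ adapter.
- **Poly-A insert**: ≥ 80% A over the insert.

Tags are stored in the DNA alphabet internally and rendered as RNA (U) in
miRNA-facing reports.

## Exact mapping

An 18-mer hash over the plus strand of each chromosome seeds candidate
loci; candidates are verified by direct comparison, and minus-strand hits
come from looking up the reverse complement, so both strands are covered
without a second index. Zero mismatches, all hits reported; coordinates
are 1-based inclusive with `start < end` on both strands plus a strand
flag (BED export converts to 0-based half-open). A naive sliding-window
scan serves as the test oracle; the two agree exactly on hundreds of
random and planted tags.

## Annotation priority

Across all of a tag's hits the highest-priority *containing* interval
wins: housekeeping ncRNA (Genbank tier before Rfam tier) > known miRNA >
repeat > exon > intron; no containing interval means unannotated. Full
containment is the deliberate, stricter reading of interval overlap
(configurable via `require_containment=False`). Ties inside a rank are
broken deterministically (sense before antisense, then category name,
then coordinates), so shuffling hits or records never changes the
assignment. Repeat-claimed tags outrank exons/introns but are reported
under `unann` since the composition table has no repeat row. siRNA is
assigned *after* this chain: duplex members claim only tags that were
unannotated or exon/intron fragments, so database-backed ncRNA calls are
stable.

Live BLAST searches against sequence databases are emulated by the
provided interval/sequence annotation; E-value matching is not
reproduced.

## siRNA duplex geometry

For exactly genome-matched tags, "each strand 2 nt longer than the other
at its 3′ end" reduces to coordinates: a plus-strand tag at [a, b] and a
minus-strand tag at [a−2, b−2], both 22–24 nt (which the offset identity
forces to equal length). Pairs are deduplicated by locus; a tag may join
multiple pairs at repeated loci. An all-pairs check over every hit pair is
the test oracle.

## RNA folding model

The default folder maximizes total pairing energy over nested structures
by dynamic programming with per-pair energies G:C = −3.0, A:U = −2.0,
G:U = −1.0 kcal/mol and a minimum hairpin loop of 3. It is **not** a
nearest-neighbour thermodynamic model: reported energies are comparable
within this package, not with thermodynamic folders, and published MFE
values for real precursors are therefore not reproduction targets. The
engine is pluggable — any callable `seq -> (dot_bracket, mfe)` can
replace it behind the same contract.

Numerical conventions:

- energies are integer multiples of 1 kcal/mol internally, so equality
  comparisons in the traceback are exact;
- the reported MFE always equals an independent re-scoring of the
  returned structure, and is exactly 0 iff the structure has no pairs;
- tie-break: the traceback pairs the earliest unresolved 5′ position
  whenever pairing it achieves the optimum, choosing its *outermost*
  admissible partner. Among equal-energy structures this prefers one long
  stem over fragmenting into small local hairpins — the behaviour a
  hairpin-centric pipeline needs — and makes the output a pure function
  of the sequence.
- the DP is verified against exhaustive enumeration of all nested
  structures for sequences up to 20 nt.

The DP fill is JIT-compiled with numba; a pure-Python fill with identical
semantics remains as fallback.

## Hairpin miRNA prediction

For each unannotated tag with ≤ 20 genomic loci and length 18–25, every
hit spawns candidate precursor windows: the spec-level maximal windows
(tag as 5′ arm `[start−20, end+300+20]`, tag as 3′ arm mirrored — exposed
as `candidate_windows`) and, inside them, a scan over miRNA/miRNA\*
spacings of 40/80/160/300 nt in both arm roles. The scan exists because a
single global fold of a 361-nt GC-rich window is highly degenerate: the
mature can be paired with distant pseudo-targets even when a clean local
hairpin exists.

In each folded window the star arm is located from the mature's pairing
partners: the side holding the majority of partners is chosen, partner
positions separated from the bulk by more than 4 unpaired bases (e.g. a
stray pair into the hairpin loop) are discarded, and the star interval is
the remaining block extended by the canonical 2-nt 3′ overhang.

Acceptance requires all of (thresholds inclusive):

| criterion | default |
|---|---|
| precursor energy | ≤ −18 kcal/mol |
| miRNA/miRNA\* base pairs | ≥ 16 |
| largest duplex bulge | ≤ 4 |
| duplex asymmetry | ≤ 4 |
| arms on one stem-loop | required |
| miRNA–miRNA\* spacing | ≤ 300 nt |

The reported precursor is the duplex extent plus 20 nt of flank on each
side; its structure is the window structure *restricted* to that span and
its energy is the energy of exactly that structure. Every reported metric
therefore describes the reported fold, and an independent re-check of the
six predicates from the candidate record alone must pass (tested). The
restricted energy is ≥ the true optimum of the excised sequence, i.e. the
−18 bound is applied conservatively. The star-length bounds (20/23)
recorded in `MireapParams` are metadata, not an acceptance predicate.
Expression evidence for the star strand is not required. Among a tag's
accepted candidates the lowest energy wins, then the shorter precursor,
then the leftmost location.

Known miRNAs are quantified by exact identity with a mature sequence or
exact containment in a precursor; tags matching several references count
for each and are flagged multi-assigned.

## Differential expression

TPM = count / total clean reads × 10⁶ (rendered at 4 decimals; fold
changes at 8). Fold change = log2(treatment TPM / control TPM), defined
only when both counts are positive. The Audic–Claverie conditional
p(y|x) is evaluated through log-gamma; tails are summed in log space,
the upper tail with a geometric bound on the remainder (relative cutoff
1e−15), so counts up to 10⁷ against totals of 10⁸ neither overflow nor
lose the tail (they underflow gracefully toward 0, the printed convention
for vanishing p-values). The pmf is identical to a negative binomial with
size x+1 and success probability (N₂/N₁)/(1+N₂/N₁), which the tests use
as an independent oracle.

`ac_pvalue` returns the single tail in the direction of the observed
change (D for apparent up-regulation, C for down). As a significance
measure that directional tail is anti-conservative — selecting the tail
after seeing the direction roughly doubles the false-positive rate
(simulated 0.094 at the 0.05 level) — so significance calls in
`diff_table` use `ac_pvalue_two_sided` = min(1, 2·tail), which simulates
at 0.042 type-I error and ≥ 0.99 power for a true 4-fold change at
control counts ≥ 20 (totals 10⁶/10⁶). No multiple-testing correction is
applied, matching the upstream analysis convention.

Zero-count handling uses no pseudocounts: a miRNA seen in only one
library becomes a condition-specific call (plus_only / minus_only) and is
flagged significant when its count reaches a configurable floor (default
10 reads). "Significant change" means |log2 FC| ≥ 1 (linear fold 2) with
p < 0.05, or a condition-specific call above the floor.

## Synthetic data

The generator emulates the study conditions: a GC-rich toy genome
(default one 100-kb chromosome at 64% GC, the *C. reinhardtii* regime)
carrying planted features, and two libraries of fixed total read count
with condition-dependent abundances.

- **Hairpins** are constructed as mature + loop + star, the star being
  the reverse complement of the mature offset by 2, so the duplex has
  `len(mature) − 2` Watson–Crick pairs and 2-nt 3′ overhangs on both
  strands; loop and star-tail bases are chosen so they cannot pair with
  the adjacent mature bases. The demo plants 10 hairpins (4 annotated as
  known, 6 novel, two of the novel −S-specific) with fold changes
  spanning down-, un- and up-regulation.
- **siRNA loci** plant both duplex strands at the exact 2-nt offset.
- **Housekeeping ncRNAs, exons, introns, repeats** emit a central ~21-nt
  fragment each.
- **Contaminants** are generated per cleaning category at configurable
  fractions; planted tags are rejection-sampled so they always survive
  adapter trimming intact.
- **Background** degradation fragments are drawn from a bounded pool of
  genomic loci (default 300), mimicking the concentration of degradation
  at a limited set of sites and bounding the unique-tag universe.

Per-feature counts are multinomial with expectation TPM × total / 10⁶;
library totals are met exactly; everything derives from
`numpy.random.default_rng` seeded from the spec, so fixed seeds give
byte-identical files.

What passing tests show — and not: the simulation has no sequencing
errors, no quality-score realism, no instrument artifacts, and its
background is i.i.d. genome sequence rather than a transcriptome, so
planted-feature recovery here demonstrates the correctness of the
pipeline's logic, not its sensitivity on real degraded libraries.
Measured on this generator, 98/100 planted hairpins are recovered across
ten seeds (the recovery test aggregates 30 hairpins over three seeds
against the ≥ 90% bar), and planted siRNA duplexes are recovered exactly.

## Problem sizes used in the test suite

Simulated libraries in the tests run at 1,500–20,000 reads per condition
with 40–300 background loci; the bundled demonstration uses 2×50,000
reads and completes in well under a minute on one CPU, including JIT
compilation. These sizes exercise every code path while keeping the whole
suite fast; all statistical checks (type-I, power, pmf normalization) use
the replicate counts stated above.

## Known limitations

- The pair-energy folding model overestimates the stability of GC-rich
  sequence relative to thermodynamic folders, so background windows in a
  64% GC genome frequently satisfy the −18 kcal/mol bound; candidate
  lists on synthetic data are correspondingly permissive. Plugging in a
  thermodynamic engine tightens this without code changes.
- With a pluggable external engine, the excised precursor's reported
  energy still comes from the internal pair model (the restriction step
  re-scores retained pairs); engine-reported energies apply to whole
  windows only.
- Repeat annotation depends entirely on the provided GFF; no repeat
  discovery is attempted.
- The Audic–Claverie test models sampling noise only; biological
  replicate dispersion is out of scope.
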
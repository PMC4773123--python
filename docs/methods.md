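# Methods

## Scope and model of the problem

The package implements a genome-independent route to a plant miRNA
catalogue. The central modelling assumption, inherited from the
genome-free identification strategy it follows, is that conserved mature
miRNAs are identical across plant species at the sequence level, so a
sequenced small-RNA tag can be *annotated* — not merely aligned — by exact
full-length identity to a mature miRNA of another species. All matching in
the annotation path is therefore exact: the original study ran BLASTn at
`-perc_identity 100`, and at 100% identity over the full tag the BLAST
predicate degenerates to exact substring containment (ncRNA subtraction)
or exact equality (miRNA identification). Implementing the predicate
directly removes E-value, word-size and dialect dependence and makes every
stage reproducible bit for bit.

Consequences worth keeping in mind: a single sequencing error or a true
species-specific variant fails annotation (it lands in the novel-candidate
or low-abundance bin), and matching is strand-as-given — small-RNA
libraries are sense-stranded, so reverse-complement matching is off (a
configurable flag was considered and rejected as a default because it
doubles the false-match surface without a biological rationale here).

## Preprocessing

Stages run in a fixed order: adapter clip → terminal quality trim →
artifact removal → length filter → collapse. Parameters, with defaults:

| parameter | default | rationale |
|---|---|---|
| adapter | TruSeq small-RNA 3' adapter | standard chemistry for 1x50 small-RNA runs |
| min. adapter anchor | 5 nt | shortest prefix accepted as read-through evidence |
| quality threshold | Phred 20 | conventional terminal-trim cutoff; the source protocol names none |
| min. insert length | 15 nt | stated cutoff, boundary inclusive |
| keep unclipped reads | yes | dropping them is not stated anywhere; configurable |

Adapter matching is exact (no mismatches): the leftmost position where a
prefix of the adapter — at least the anchor long, and extending either
through the whole adapter or to the end of the read — occurs. Exactness
keeps the cascade idempotent and the synthetic recovery contract exact;
real adapters with sequencing errors would need a mismatch-tolerant
clipper, which is deliberately out of scope.

Artifacts are defined as reads containing N, homopolymers, or strict
dinucleotide repeats spanning the whole insert. This is a fixed, testable
definition of an otherwise vague notion ("sequencing artifacts").

Collapsing returns unique tags ordered by descending count then sequence,
so all downstream outputs are deterministic without sorting caveats.

## Classification and binning

Every unique tag ends in exactly one of six bins, and stage counts
conserve the input at every step (a tested invariant):

short (< 15 nt) → removed at the ncRNA stage entry;
ncRNA → exact substring of a reference ncRNA;
below-abundance (< 10 copies) → removed at the identification stage entry;
conserved → exact match to a mature miRNA reference;
candidate → unmatched, ≥ 18 nt (emitted as FASTA for external novel-miRNA
prediction); other-unmatched → the remainder.

The abundance filter precedes matching because the source describes
discarding low-copy reads "in the alignment process"; one consequence is
that novel candidates are also abundance-filtered, which matches the small
candidate set reported there. When several reference species carry the
identical mature sequence, the call is named after the lexicographically
smallest (species, member) pair and all sources are recorded — the
original library preparation ("low-redundancy") is not specified, so the
tie-break is explicit and stable rather than implicit in file order.

Family derivation strips the arm suffix (`-5p`/`-3p`), a trailing `*`,
`.N` variant suffixes and trailing lowercase letters from the member name
(`miR159b.1 → miR159`). Applied to the packaged catalogue transcription
this reproduces its printed 40-family grouping with maximum family size 8.
Duplicate member labels with different mature sequences count as distinct
members, matching the printed family sizes.

## Conservation rate

The score counts mature reference *entries* from other species matching
the query, default mode exact equality. The unit (entries vs distinct
species) and the mode (exact vs containment in either direction) are both
configurable and logged, because the original definition is not
recoverable: rates of order 150 for canonical sequences are consistent
with entry counts over a redundant multi-species reference, but nothing
printed pins this down. The correlation with abundance uses Pearson r on
(rate, log10 count); the log base only rescales and leaves r unchanged.

## Cross-kingdom comparison

Plant and animal miRNA are overlaid ungapped at every offset with at least
10 overlapping bases; the best offset maximizes matching positions (ties:
smaller |offset|, then smaller offset). The alignment frame is the animal
miRNA: the pattern string has one character per animal position and
`r = matches / len(animal)`. This reconstruction is inferred, not stated —
but it reproduces all nine printed r-values exactly after half-up rounding
to two decimals, and the printed pattern lengths track the animal sequence
(a 21-nt plant miRNA appears with a 17-character pattern against a 17-nt
human miRNA). Alternative denominators (overlap length, longer sequence)
are provided for sensitivity checks.

The seed region defaults to animal positions 2–8 (1-based) with a minimum
of 5 matches. One printed pair yields only 4 matches under this
convention yet was published as passing; since the original coordinate
convention is unstated, the window and threshold are parameters and no
test asserts printed seed counts. Rounding for reporting is half-up on the
exact rational matches/length (decimal arithmetic, no float artifacts);
comparisons against thresholds use full precision.

## qPCR quantification

Standard 2^−ΔΔCt: replicate Ct values are aggregated by arithmetic mean
(the aggregation is unstated in the source; the mean is the conventional
choice), ΔCt is taken against an endogenous control assay within each
sample, ΔΔCt against a calibrator sample, fold = 2^−ΔΔCt. Replicate SD is
carried through for reporting only; no efficiency correction and no error
propagation into fold confidence intervals. Because the calibrator used
for each published figure is not stated, the calibrator is a required
explicit input rather than a default. `normalize_to_assay` covers the
variant where expression is reported relative to one miRNA set to 1
within each sample.

## Synthetic libraries

The generator defines the study conditions for all tests. Defaults:
50,000 reads (desk-scale stand-in for a ~31M-read run), 20 families with
1–8 members, mature lengths 18–24 nt with weights peaked at 21 and 24 nt
(the two observed modal lengths), log-normal abundance weights with
σ = 1.8 — chosen so that planted counts span roughly four orders of
magnitude, matching the 12–65,243 spread of the published catalogue — 30%
of members with a miR* arm at 2–20% of the duplex abundance, 30% of mature
sequences copied under 1–4 additional species codes, two planted novel
(reference-absent) miRNAs, 15% ncRNA-fragment and 10% degradation-fragment
contamination (uniform 15–35-nt windows of reference ncRNAs and of decoy
transcripts respectively), full 3' adapter read-through on 1x50 reads, and
substitution error rate 0.

Construction guarantees that make exact recovery well defined: focal
mature sequences are mutually distinct, never contain the adapter, and
never occur inside ncRNA references or decoy transcripts; planted counts
are produced by largest-remainder apportionment, so they sum exactly to
(1 − contamination fractions) × total reads and the manifest is exact, not
expected. The seed fully determines references, reads and manifest
(byte-identical FASTQ across runs).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing errors beyond independent
substitutions (no indels, no quality decay along the read, no ligation
bias), 5' adapter contamination, genuine family-internal sequence
similarity (members are independent random sequences), chimeric reads,
and real ncRNA sequence composition. The recovery results are contracts
about the pipeline's logic, not about wet-lab error modes.

## Numerical and degenerate-input choices

Counts and rates are integers end to end; the only floating-point
quantities are proportions, Pearson r and qPCR folds. Fixture count cells
accept both "," and "." as 3-digit group separators (the printed tables
use both), and NA/blank cells parse to an absent-value marker that
contributes nothing to family totals — never zero. Empty FASTQ input is
an empty stream; an empty ncRNA reference is a configuration error
(silent pass-through would look like successful subtraction); an empty
reference in conservation scoring returns 0 with a logged warning;
correlations need ≥ 3 points with positive counts and non-zero variance.
Tags containing N survive normalization but are removed as artifacts.

## Problem sizes

Tests run simulations of 500–12,000 reads and brute-force oracles on
instances of ≤ 200 tags against ≤ 100 reference entries, where all-pairs
scans are exact and fast; the full suite completes in a few seconds. The
acceptance script operates on the packaged fixture tables only and runs
in under a second.

## Known limitations

Exact matching cannot annotate variants one substitution away from a
reference (they become candidates); the conservation-rate unit is a
modelling choice, not a recovered fact; the cross-kingdom r-value
reconstruction fits all printed rows but remains an inference; and the
novel-miRNA step ends at candidate extraction — duplex/hairpin prediction
belongs to external tools.
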
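# Methods

## The analysis model

The pipeline assumes small RNAs were cloned by 5′P/3′OH-specific linker
ligation, so every 454-style read is exactly
`5′-linker + insert + 3′-linker` and every SOLiD read starts at the
insert's 5′ base and runs a fixed 35 colors into the 3′ adapter. Two
consequences drive the preprocessing design:

- **Linker damage is terminal.** Adapters are ligated, so a partial
  adapter can only be missing bases at its outer end. The 454 trimmer
  accepts a linker lacking up to 3 terminal nucleotides (`max_missing`
  = 4, i.e. "fewer than 4 missing") and tolerates no internal
  mismatches.
- **SOLiD reads must be trimmed by alignment.** Colorspace decoding is
  a per-position bijection (color = XOR of the 2-bit base codes), but
  the true insert length is unknown and a single color error corrupts
  every downstream base. The rescue rule keeps a read if its longest
  genome match anchored at position 0 is perfect and ≥ `min_insert`
  (16 nt), trimming to that length, or if the full 35 nt match with
  exactly one mismatch. Base-space alignment is used (color-aware
  alignment is out of scope); the anchored-seed search uses two 8-mer
  seeds so a single mismatch anywhere cannot hide a hit.

Unique tags are built by greedy longest-first clustering: a sequence
joins a representative iff it is an exact substring covering ≥ 0.8 of
the representative's length (100% identity, 0.8 length-similarity).
Ties between equal-length candidates are broken lexicographically for
determinism. Clustering is done once across all libraries — per-library
counts are carried on each tag, so per-library tables downstream are
identical to clustering per platform and pooling afterwards.

Degradation filtering removes tags whose best local alignment to an
rRNA/tRNA/ribosomal reference covers ≥ 70% of the tag at ≥ 90%
identity. Identity is computed over the full alignment length
*including gap columns*; computing it over matched columns only lets
gappy chance alignments of random 21-mers against a few hundred
nucleotides of reference reach 90%+ and purge genuine tags. Tags whose
best-scoring reference hit is annotated miRNA are always kept. The 70%
coverage value is the method's standard operating point; the 90% identity is
this package's default (the source protocol left it unstated) and both
are configurable.

## Hairpin model and filters

Folding defaults to a deliberately transparent additive engine: each
pair contributes G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol; each
hairpin-loop closure costs +4.0; loops span ≥ 3 nt; interior loops,
bulges and multiloops are free. The engine is a Nussinov-style dynamic
program over three tables (any structure / at-least-one-pair / paired
ends) so the +4 closure term is exact, and the test suite proves its
minima equal exhaustive enumeration over all pseudoknot-free
structures for sequences ≤ 24 nt. It is **not** a nearest-neighbour
thermodynamic model: its −20 kcal/mol threshold is calibrated to the
same operating point but absolute energies differ from Turner-rule
folders. The engine is pluggable (`fold_engine: rnafold` shells out to
ViennaRNA when installed) and every threshold is a parameter.

Candidate evaluation excises two precursors per alignment — mature arm
near the 5′ end (star expected downstream) and near the 3′ end — of at
most `tag + flank + 20` nt with `flank` = 100, and applies:

- `MFE < −20 kcal/mol` (strict, per the operating point),
- terminal loop ≥ 10 nt, measured by walking the mature arm's stem
  inward to its innermost pair; a branched (multiloop) stem fails,
- maximum unpaired run ≤ 3 nt over the **entire mature arm** — the
  constraint is on the mature sequence itself, which also makes the
  filter selective under the permissive energy model,
- all mature pairing partners on one side (the arm may not span the
  loop).

The predicted miRNA\* interval is the mature arm's partner span
extended 2 nt at its 3′ end (canonical Dicer 2-nt overhang); star
evidence tolerates ±3 nt at both ends. Expression evidence follows the
2-of-3-libraries-or-star rule. Tags overlapping any annotated repeat
are excluded before folding, as are tags flagged as degradation. When
two passing calls lie on each other's predicted star arms they are two
arms of one duplex and are collapsed, keeping the more abundant tag as
the mature call.

## siRNA classification and cross-matching

Repeat precedence follows the removal order of the source analysis:
miRNA first, then any tag with ≥ 1 nt repeat overlap becomes rasiRNA
(minimum overlap configurable), the remainder is oriented against
*full gene spans* — antisense pairing acts on the pre-mRNA, so introns
count. Multi-mapped tags get per-alignment sub-labels and a tag-level
class of `mixed` when sub-labels disagree; distribution tables are
emitted under both unique-tag and read-count weighting since the
choice is not dictated by the method.

Cross-platform rasiRNA agreement uses ungapped local alignment
(match +1, mismatch −3) scored per diagonal, with
`E = K·m·n·e^(−λS)` (λ = 1.33, K = 0.621 — standard ungapped
nucleotide constants), keeping matches at `E ≤ 1e−5`; `m` is the query
length and `n` the total length of the compared set, so the measure is
deliberately asymmetric in (A, B).

## Coverage

Each alignment occurrence increments the bin of its start coordinate
(`floor(start / 10000)`) on its strand, weighted by the tag's library
read count; multi-mapped occurrences each count. No length-proportional
splitting is done — a 20–35-nt tag essentially never straddles a 10-kb
bin boundary in a way that matters. Normalization divides by the
library's total read count after preprocessing (configurable to a
unique-tag denominator).

## Target prediction

Animal mode: exact reverse-complement of miRNA nt 2–7. Plant mode: the
full miRNA placed ungapped against the transcript; defects
(non-Watson-Crick positions, wobbles included) budgeted ≤ 1 in miRNA
positions 1–8 and ≤ 3 elsewhere — independent budgets — and duplex
energy ≤ −20 kcal/mol under the additive pair model (G:U scores −1 but
counts as a defect). Modelling the duplex without bulges keeps the
scanner exactly checkable position by position; the cost is that sites
rescued only by a compensating bulge are missed, which is conservative.
Overlapping plant sites are resolved to the lowest-energy one (one
duplex per footprint). Regions are assigned by site midpoint relative
to the CDS on transcripts that carry start/stop (UTR) annotation;
others report `unknown`. GO bias is the ratio of term representation
among target genes to the genome-wide representation, ranked
descending.

## Synthetic data: what it emulates, and what it does not

`simulate.SimConfig` defaults define the study design used everywhere:
two 100-kb chromosomes; 40 genes (half with introns of 60–140 nt, 60%
with annotated UTRs); four transposon families (Copia, Gypsy,
Harbinger, MuDR) at 8 copies each with 2% copy divergence; rRNA/tRNA
loci that also serve as the degradation-background source (10% of
reads); 20 planted miRNA hairpins; 30 repeat-derived tags; 20
antisense tags; three libraries "L454", "EF", "EC" with mean per-locus
depth 5; zero color error unless configured. All randomness derives
from one seed; identical (config, seed) yields byte-identical files.

Planted hairpins are designed for *provable* filter compliance under
the additive energy model: mature arms use only A/T, the star arm is
the reverse complement with two interior substitutions to C, and the
loop and ±130-nt flanking pads are C-only. Since C pairs only G and
the locus region contains no G, nothing outside the designed duplex
can pair, making the designed stem the unique maximum-weight
non-crossing matching — the precursor's MFE structure — at every seed.
A GC-rich stem dropped into random flanks, by contrast, is frequently
*not* the minimum under this model because free interior loops let
flank sequence out-pair it. The price is unrealistic base composition
around miRNA loci; consequently the suite demonstrates correctness of
the decision logic, not folding performance on natural sequence.
Fifteen loci are expressed in both SOLiD libraries (2-of-3 evidence,
half also emitting star reads) and five in one library with mandatory
star reads (star-evidence path); star depth is clamped below mature
depth, as in real hairpin expression.

Guard bases: alignment-trimming extends a SOLiD insert for as long as
the genome happens to continue with the adapter sequence, so the
generator sets the base 3′ of **every** ≤ 1-mismatch genomic
occurrence of each planted insert (sibling repeat copies included) to
differ from the adapter's first base. Without this, a few tags per
run acquire +3-nt extensions and fall below the 90% reciprocal-overlap
bar of the recovery scorer.

Not emulated: quality values, PCR duplicates, realistic base
composition, the 18/35-nt SOLiD length-bias artifact (an optional
`truncation_bias` knob truncates reads to 18 nt but makes no mechanistic
claim), and sequencing depths beyond a few hundred reads per library —
the design is a scaled-down experiment chosen so the full suite runs in
well under a minute per pipeline pass.

## Numerical and procedural choices

- Coordinates are 0-based half-open everywhere internally; GFF3 and
  RepeatMasker convert at the I/O boundary and round-trip exactly.
- Energy ties in the fold DP are broken deterministically (pairing
  preferred, smallest split point), so witness structures are stable.
- Recovery scoring matches calls to planted loci at ≥ 90% reciprocal
  interval overlap on the same strand; precision is reported as NA for
  empty call sets.
- The analysis itself draws no random numbers; only simulation
  consumes the seed. Reruns of the same config are byte-identical.
- At a 2% per-color error rate the pinned default design yields miRNA
  recall 0.95; across other seeds this fluctuates around 0.85–1.0
  because the five star-evidence loci depend on one or two star reads
  surviving uncorrupted. This is a property of the design's depth, not
  of the caller.

## Known limitations

- The additive energy model has no stacking, interior-loop or
  multiloop terms; absolute MFEs are not comparable to thermodynamic
  folders, only the filter logic is.
- Plant-mode target sites are bulge-free (see above).
- SOLiD rescue anchors at read position 0 and cannot recover reads
  whose very first bases are corrupted, mirroring the ligation-site
  assumption of the protocol.
- Reads mapping within ~35 nt of a chromosome edge on the minus strand
  can be missed by the anchored-seed search; planted loci keep a
  300-nt margin.
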
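# Methods

## Problem and model

Unstranded RNA-seq libraries lose the information of which genomic strand a
read's RNA was transcribed from. For most genes this is harmless, but when
the opposite strand of a locus is transcribed — an antisense gene with
exonic overlap, or nascent RNA "carrying over" past the 3' end of a highly
expressed neighbor — strand-blind counting attributes those reads to the
wrong gene. The package quantifies this failure mode and predicts it from
alignments alone.

### Count types

All counting is union-mode against exon-union gene models: a read is a
candidate for every gene whose exon union any aligned block touches with at
least one base. Six tallies are kept per gene:

- `n_ust`: every candidate gene is incremented (multi-assignment is
  intentional: `n_ust` is a within-gene expression proxy, never summed
  across genes).
- `n_ustno`: incremented only when the read touches exactly one gene's
  exons — the unstranded count over the gene's *unique* region.
- `n_st`: like `n_ust`, restricted to genes whose strand matches the
  read's inferred transcriptional strand (dUTP "R" convention by default:
  first-mate alignment strand is opposite the transcript).
- `n_stno`: reads counted in `n_ustno` whose inferred strand matches the
  gene. Candidate resolution is strand-blind for both `*no` types, so
  `n_stno ≤ n_ustno` holds identically and the two tally reads over the
  *same* genomic region. This is what makes log₂(N_ustno/N_stno) a clean
  per-gene overestimation factor; resolving stranded candidates
  strand-aware instead would count overlap-region reads in `n_stno` only
  and could push the ratio below 1.
- `n_jctn`: the read has a CIGAR-N gap exactly equal to an annotated
  junction of the gene (no tolerance; novel junctions are ignored) and the
  read counts toward that gene's `n_ust`.
- `n_intr`: the read overlaps the gene's introns and no gene's exons
  anywhere — intron density is meant to measure pre-mRNA/antisense signal,
  not mis-annotated exons.

Filters: primary alignments only, MAPQ ≥ 10 by default (configurable),
duplicates skipped unless requested. Paired-end data can be counted per
read or per fragment (mates pooled, fragment counted once; mates on
different chromosomes are skipped with a diagnostic).

### Gene models

GTF input (1-based inclusive) is converted to 0-based half-open intervals
on read. Per gene: the exon union over all transcripts; the unique
(non-overlapping) region = exon union minus every other gene's exon union
on either strand; introns = span minus exon union; junctions = consecutive
exon pairs of each transcript (overlapping or touching exons within a
transcript are merged with a warning, so a junction always has donor <
acceptor); neighbors = genes whose spans lie within 2,000 bp (inclusive;
span-to-span distance, 0 for overlap). Genes with exons on multiple
chromosomes or mixed strands are rejected. All transcripts are used by
default; `--transcript-tag basic` restricts to a tagged subset, which is
advisable for annotations carrying very rare isoform models (rare
retained-intron transcripts bias the junction expectation downward).

The database serializes to canonical JSON (sorted keys), so rebuilding from
the same GTF is byte-identical.

### Junction-read expectation

For each isoform of length L, every read placement is enumerated: single-end
starts 0…L−ℓ for read length ℓ (a molecule shorter than the read contributes
one whole-molecule placement); paired-end fragment placements per fragment
length, optionally weighted over an empirical fragment-length distribution.
A placement spans a junction if some internal exon boundary has at least
`min_overhang` aligned bases on both sides within a mate (a junction inside
the mate overlap counts once). Placements are pooled over isoforms:
p_expected = junction placements / all placements. Pooling encodes equal
molar isoform abundance under uniform fragmentation — each molecule yields
reads in proportion to its placement count. The alternative (equal *read*
share per isoform, i.e. averaging per-isoform probabilities) would weight
short isoforms up; we use molar pooling and note the choice here.

Enumeration is exact and closed-form for single-end reads (interval-union
arithmetic over start positions), and an explicit loop for paired-end. The
default `min_overhang` is 8, mirroring the junction-overhang minimum of
spliced aligners (a read an aligner would not split should not count as
detectable); synthetic-fixture analyses use overhang 1 because the
generator splices every boundary-crossing placement (see below).

### Features, labels, classifier

From an unstranded pass (pseudocount ε = 1 read throughout; the observed
junction-fraction distribution has mass at zero, so unsmoothed ratios would
be degenerate):

- junction_log_ratio = log₂((n_jctn + ε) / (p_expected·n_ust + ε))
- exon_intron_log_ratio = log₂(((n_ustno + ε)/unique_len) /
  ((n_intr + ε)/intron_len)); lengths are clamped to ≥ 1 bp because
  multi-isoform unions can tile the span leaving no intronic bases
- neighbor_expression = max over neighbors of n_ust/exonic_len (reads per
  kb; exonic length, not span length — the choice is documented here, the
  span alternative differs only by a per-gene constant)
- overlap_fraction = 1 − unique_len/exonic_len

Labels from a stranded pass: affected ⇔ log₂((n_ustno+ε)/(n_stno+ε)) > 1
and TPM(n_ustno) > 1. TPM uses unique-region length for `*no` counts and
full exonic length otherwise; genes with zero usable length get TPM 0 and
are excluded from the denominator.

Training pools (gene × sample) instances across stranded samples; only
detectable genes enter. Two `DecisionTreeClassifier`s (scikit-learn),
max_depth 5 (multiexonic, 4 features) and 3 (monoexonic, 2 features), fixed
`random_state`, class-weight balanced (affected genes are a ~10% minority;
balancing stabilizes the leaf probabilities used as scores). The fitted
trees are exported to JSON arrays (children/feature/threshold/leaf class
weights) and prediction on a saved model walks those arrays (left branch on
feature ≤ threshold, as in scikit-learn), so models are text, versioned and
bit-reproducible. p_affected is the leaf's class-weight fraction;
confidence = 1 − p_affected. Genes with n_ust = 0 are not scored (NA).

## Synthetic data generator

The generator is the package's test bed and defines what the tests prove.
One synthetic chromosome carries (defaults): ~30 genes, ~35% monoexonic,
2–7 exons of 80–400 bp with 200–1500 bp introns, up to one
alternative exon-skipping isoform per gene; a forced antisense
exon-overlapping pair, a forced sub-2 kb pair, a forced super-2 kb pair;
log-normal expression (σ = 1.2). Reads are 50 bp single-end under the dUTP
reverse protocol — the configuration of the blood-cell compendium this
method was developed against — drawn uniformly over pooled placements
(exactly the junction model's two assumptions) with spliced CIGARs at every
boundary crossing. The unstranded library is the same read set with strand
flags randomized.

Carry-over is planted as *unspliced* reads on the source's strand scattered
uniformly over an opposite-strand target's span, at a configured fraction
(0.1–0.4) of the boosted source's read count; carry pairs are the forced
antisense and close pairs plus a subset of additionally generated close
pairs. Every read is traceable (source gene, transcript, true strand, carry
flag encoded in its name), and per-gene ground truth — including the
realized unstranded/stranded ratio over the unique region, computed by an
internal per-base replay — is exact.

Pseudo-cell-type series: 15 types share one annotation; each type
resamples expression (×lognormal(0, 0.5)) and carry intensities
(×lognormal(0, 0.3)); carry pairs with multiexonic targets are active in
every type, monoexonic-target pairs toggle per type (p = 0.7), so affected
sets overlap without coinciding. Training uses 14 types, evaluation the
held-out 15th.

What the generator does **not** emulate: sequencing errors and indels
(counting is CIGAR-driven, so they are irrelevant to the tested surface),
coverage bias along transcripts, GC effects, unequal isoform abundance,
multimapping, and aligner overhang-dependent clipping of near-boundary
reads. Passing tests therefore demonstrate correctness of the counting,
enumeration, labeling and learning machinery under the model's stated
assumptions — not robustness to real-data violations of those assumptions
(on real data, observed junction frequencies correlate with, but scatter
around, the expectation).

## Problem sizes and numerical choices

Test and validation runs use, as the package's own design: five 22-gene /
~10⁴-read fixtures for counter-vs-oracle equivalence; a 10-gene /
~1.1×10⁵-read equal-depth run (≥10⁴ reads per gene) for generator/model
concordance (per-gene agreement within 3 binomial SEs, Pearson r across
genes); 15 pseudo-cell types of 48 genes / 4×10⁴ reads for the hold-out
classifier experiment. The full suite runs in ~30 s on one CPU.

Degenerate inputs: empty BAM yields all-zero counts; all-zero counts yield
all-zero TPM; monoexonic genes have p_expected = 0 and undefined
junction/intron features by construction; reads on chromosomes absent from
the database are skipped and tallied in a diagnostic counter.

## Known limitations

- Junction matching is exact-coordinate; novel junctions contribute
  nothing (by design — the expectation is over *annotated* junctions).
- No multimapper handling beyond the MAPQ filter; no fractional
  assignment.
- The fixtures-trained model ships as a recipe, not a file; decision
  thresholds learned from synthetic data transfer to real data only as a
  sanity screen — train on stranded data from a comparable protocol for
  production use.
- Carry-over in the generator is uniform over the target span; real
  nascent-RNA coverage decays with distance from the source.
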
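# Methods

This note documents the models and procedures behind each pipeline stage,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Evidence layer

**Motif scanner.** The five NBS motifs are modelled as degenerate patterns
over per-position residue sets (`x` = any, `h` = hydrophobic L/I/V/M/F,
`[...]` = explicit set). The shipped defaults are

| motif | pattern |
|---|---|
| P-loop | `[GA]xxxxGK[ST]` |
| Kinase2 | `hhhhLDD` |
| Kinase3a | `GSR[IL][IL][LIV]TTR` |
| GLPL | `GLPL[AT]` |
| MHDL | `[MI]HD[LV]` |

A window's score is the fraction of constrained positions matching;
`min_score` defaults to 1.0 (exact match of every constrained position).
Users can substitute their own patterns, e.g. built from a reference
alignment. Per motif only the best-scoring (ties: left-most) hit is kept;
cross-motif overlaps are resolved by score, then canonical motif order.
These choices make the scanner a deterministic function of the sequence, so
it can be validated against an exhaustive per-offset oracle, which the test
suite does on dozens of random and cassette-planted proteins.

**Coiled-coil scorer.** Real pipelines use an HMM (MARCOIL-class) that
emits per-residue probabilities which are then thresholded at 0.02, 0.10,
0.50 and 0.90. We reproduce that graded behaviour with a windowed
heptad-register score: for every window of 28 residues (four heptads;
minimum 14) and every register, the raw score is the mean of the
hydrophobic fraction at core a/d positions and the charged (D/E/K/R)
fraction at flank e/g positions. The best raw score covering a residue is
mapped through a logistic `p = 1/(1+exp(-20.3 (s - 0.7418)))`, calibrated
so an ideal `LEALEKK` repeat scores ≈ 0.995 (detected at 0.90) and a
proline homopolymer scores ≈ 3e-7 (rejected even at 0.02). Because every
threshold cuts the same per-residue profile, segment nesting across
thresholds — the graded structure real predictors show — holds by
construction. The scorer is a self-contained propensity model, not an HMM:
absolute probabilities are not comparable to MARCOIL's, only the graded
threshold behaviour is.

**Qualification.** A gene qualifies as NBS-encoding when it carries NBS
domain evidence (PF00931 or equivalent). When a BLAST table against a
reference R-protein set is supplied, the gene must additionally hit at
least one reference at e ≤ 1e-15. Without such a table (synthetic runs)
NBS evidence alone qualifies. A built-in homology mode scores local
BLOSUM62 alignments and thresholds on raw score instead of e-value, since
no database size exists at desk scale. Unknown accessions ingest as
`OTHER(name)` and never block classification.

## Classification

Regularity demands all five motifs in canonical order *and* a complete ORF
(initial Met, no internal stop; when nucleotide gene models are available
their start/stop annotations may substitute). Non-regular genes keep their
ordered subset plus a contiguity flag — truncation from either end of the
cassette yields a contiguous rank range, which is how degraded family
members usually present.

The N-terminus is the region strictly before the NBS span (ingested NBS
evidence if present, else the motif-hit span). TIR evidence wins over
coiled-coil when both occur (`tir_priority`, configurable); `C` requires
probability ≥ 0.90 somewhere in the flank, `c` any of the lower thresholds,
`X` a flank strictly longer than 100 residues. `OTHER` domain evidence does
not suppress `X`: long N-termini carrying novel domains still belong to the
"other kind of N-terminal" group. The same >100-residue rule applies to the
post-NBS tail for the `X` C-terminal code; LRR evidence yields `L`.
Percentages in summaries are rounded half-up to two decimals (one decimal
where the field's tables print one), via exact decimal arithmetic.

## Genome architecture

**Clusters.** The 200-kb rule is applied to adjacent-gene gaps
(edge-to-edge, `max(0, next.start − prev.end)`; overlap counts as 0) with
transitive chaining, so a long tandem array is one cluster even when its
ends are megabases apart — this matches the observation of very large
clusters in real genomes. Chains of ≥ 2 genes are clusters.

**Duplications.** Protein sequences are aligned globally (match +1,
mismatch −1, linear gap −2 — a deliberately simple scoring that an
independent DP oracle reimplements in the tests). Coverage = alignable
columns / longer-gene length; identity = identical / alignable columns;
both thresholds are strict (> 0.70). Protein rather than nucleotide
identity is used; at the identity levels the rule targets the two are
close, and proteins are the input the rest of the pipeline already
requires. Events between genomically adjacent members of one cluster are
flagged *linked*; an optional collapsed view keeps only adjacent-pair
events inside a cluster so a tandem array is not over-counted, while the
raw pair list remains available. Events spanning different sequences are
flagged chromosome-level; no synteny inference is attempted.

**Summary conventions.** The clustered share divides by
(total − sole-location genes); the duplicated-in-cluster share divides by
duplicated genes and is printed to one decimal, mirroring how such tables
are conventionally formatted.

## Phylogenetics

Distances use pairwise deletion (columns gapped in either row of a pair are
skipped). The protein default is the Poisson correction −ln(1−p); the
Kimura 2-parameter model is provided for nucleotide alignments only, since
it is defined on transitions/transversions. (Workflows that report "K2P on
amino acids" are, in MEGA terms, a mislabelled protein-distance run; we do
not reproduce that combination.) Saturated distances (p ≥ 1, or a
non-positive K2P log argument) raise an error naming the pair.

Neighbor joining follows the standard Q-criterion with the usual
branch-length formulas; ties in the Q minimum go to the lowest-index pair,
making runs reproducible under any input order. Negative branch lengths
are kept by default (an option clamps at zero) so that additive matrices
are reproduced exactly — the test suite verifies path-length equality on
hundreds of random additive matrices built by independent edge
subdivision. Bootstrap resamples columns with replacement under a seeded
generator; support is the percentage of replicates containing each
internal bipartition, and runs are bit-reproducible given the seed.
Monophyly of a tip set on the unrooted tree is the existence of an edge
inducing exactly that bipartition.

## QTL co-localization

Electronic PCR reports every convergent site pair — forward primer on one
strand, reverse on the other, 3' ends facing — whose amplicon lies in
[80, 700] bp. The size window is the only constraint real workflows state;
the mismatch model (≤ 2 per primer, no indels, exact 3-base 3' anchor)
follows common e-PCR practice and is configurable. Multi-hit markers are
represented by the placement nearest to any NBS gene — the reading most
favorable to co-localization — while all placements stay reported.
Distance is product midpoint to nearest gene-interval edge, and the 3-Mb
flank is symmetric. Markers on scaffolds are split out: a scaffold with
NBS genes is its own category, a gene-free scaffold ≤ 2 Mb might still land
within a flank once anchored to a chromosome and is counted separately.
The headline co-localized share counts chromosome within-flank markers
plus NBS-scaffold markers over all placed markers; the chromosome-only
decomposition is also reported, since both conventions appear in practice.

## Synthetic data

The generator emulates the statistical structure the pipeline detects:
letter-code classes of both regularities (defaults: 60 genes, about half
non-regular, spanning CN/CNL/CNX/cN(±L,X)/TN(±L,X)/XN(±L,X)/N/NL/NX),
five clusters (sizes 12/9/7/6/5, intra-cluster gaps 60 kb, inter-cluster
gaps 400 kb), four duplicate families (sizes 3/3/2/2 at identities
0.90/0.85/0.90/0.80, realized by chain-mutating a parent outside planted
feature blocks), eight sole-gene scaffolds, and 30 markers across the five
placement categories with products of 120–600 bp. Flanks and linkers are
uniform over the 20 residues; genomes are uniform over ACGT.

Consistency between emitted data and truth is enforced by construction:
every gene is resampled until the pipeline's own scanners and classifier
reproduce its planted class; the full all-vs-all duplication graph is
checked so that exactly the planted families (and nothing else) satisfy
the 70/70 rule — necessary because independently generated genes of one
class share cassette blocks and can drift over the line; every marker is
re-verified by e-PCR on the assembled genome and its primers resampled on
any spurious or missing product. TIR and LRR cassettes are fixed synthetic
marker sequences tied to accession rows, not biological consensi; their
alphabets avoid the motif patterns and the coiled-coil scoring classes.
Noise knobs degrade motif and coiled-coil blocks by point substitution
only, keeping truth alignment trivial.

Passing the zero-noise recovery tests therefore shows the pipeline is
internally consistent and exact on clean, planted signal. It does **not**
show robustness to the ways real data differ: genuine motif degeneracy
beyond the shipped patterns, indels, biased residue composition,
HMM-calibrated coiled-coil probabilities, fragmented assemblies, or
annotation error. The oracle-equivalence tests carry the correctness
burden for the scanning algorithms themselves, independent of the
generator.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use: one 60-gene synthetic
genome (~24 Mb over 18 sequences), ≥ 50 random instances per scanner-oracle
comparison (proteins ≤ 500 aa, sequences ≤ 2.5 kb), 200 random proteins for
threshold nesting, 100 random additive matrices (n ≤ 12) for NJ, and
bootstrap runs of 40–200 replicates — sizes chosen so the whole suite
exercises every code path in a few minutes on one core while keeping every
check exact rather than statistical. Percentages use half-up decimal
rounding; all residue and base-pair intervals are 1-based inclusive
in memory and in GFF3, 0-based half-open in BED output; random draws all
flow from a single `numpy` generator per run, so equal seeds give
byte-identical artifacts.

## Known limitations

* The motif patterns are canonical consensi, not fitted PWMs; real
  divergent family members will be missed unless users supply their own
  models (`MotifModel` accepts any degenerate pattern and threshold).
* The coiled-coil scorer's absolute probabilities are a calibration
  convention; only the threshold grading is meaningful.
* Multiple sequence alignment is out of scope: phylogenetic inputs are
  pre-aligned FASTA.
* e-PCR has no thermodynamic model; primer binding is string matching.
* Subgenome-origin reasoning for polyploid-derived markers is reduced to
  the `unplaced` reporting category; it needs a polyploid assembly.
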
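# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Coordinates and topology

All public coordinates are 1-based inclusive (GenBank convention). A
feature spanning the circular junction keeps `start <= end` by letting
`end` exceed the sequence length and carries a `wraps` flag;
`segments()` splits it into junction-free intervals for all interval
arithmetic (coverage, scanning, grouping). The `end < start`
representation is never used. bedGraph export converts to 0-based
half-open intervals at write time.

Ambiguity codes other than N are accepted verbatim but every composition
statistic (GC%, skew, p-distance) treats anything outside A/C/G/T as
unknown: excluded from denominators, contributing zero skew, discarded
pairwise in alignments.

## GC skew and origin/terminus prediction

The windowed profile computes GC% = (G+C)/(A+C+G+T) and skew =
(G−C)/(G+C) per window (10,000 nt windows in 200 nt steps by default).
Two sign conventions exist in the literature — (G−C)/(G+C) and its
negation — so the convention is an explicit parameter, defaults to
`G_minus_C`, and is recorded in every result. Windows are anchored at
1, 1+step, … and wrap on circular sequences, giving ceil(L/step) windows;
the reported center is `start + floor(window/2)`. Windows without G or C
get skew 0 by convention.

The cumulative skew is the running sum of per-base contributions (+1 for
G, −1 for C). On a chromosome with two replichores whose leading strands
are G-rich, this walk drifts up along one arm and down the other, so its
global minimum marks oriC and its global maximum the terminus (roles swap
under `C_minus_G`). The predictor reports the position immediately after
the first extremal step; ties go to the smallest genome position. No
smoothing is applied: the noise in the cumulative walk is a random walk
itself, so local averaging does not improve extremum localization — the
localization error is governed by the ratio of the per-base variance
(≈ the GC fraction) to the squared per-base drift, giving an error scale
of `gc / (2·delta)^2` bases for a leading-strand G−C frequency difference
of `2·delta`. At the generator's default (gc 0.35, delta 0.05) this is
roughly 35 bp, comfortably inside one 200 nt window step; weak skews
(effective drift below ~0.03/base) blur the extremum over many hundreds
of bases, which is a property of the data, not the estimator.

A prediction is flagged "dnaA-supported" when an annotated dnaA gene
(gene name `dnaA`, or a product containing "chromosomal replication
initiat") lies within 20 kb (configurable) of the predicted origin.
Replichore 1 is the ori→ter arm in increasing coordinates; its leading
strand is '+', the other arm's is '−'. A CDS belongs to the replichore
containing its start; the pooled leading-strand count is tested against
0.5 with a two-sided exact binomial test.

## DnaA-box scanning

IUPAC consensus matching is exact (regular-expression alphabet classes),
reports overlapping matches individually, scans both strands by default
(minus-strand sites are matches of the reverse-complemented consensus on
the forward sequence, reported at their forward start coordinate), and
honors circular wrap. The DnaA-box report counts hits in (a) the
intergenic region upstream of dnaA — from the end of the circularly
preceding annotated feature to the base before dnaA's 5' end, capped at
1000 bases (configurable; published counts do not state the window, so
the cap is exposed) — and (b) the region strictly between dnaA and dnaN.
Whether published box counts include minus-strand matches is generally
unstated; both strands are counted here because DnaA binds double-stranded
boxes in either orientation.

## rRNA operons and the density survey

Operon calling is single-linkage chaining of rRNA features along the
circle: consecutive rRNA genes at most `max_gap` apart (default 3000 nt)
join one operon; intervening tRNAs do not break a chain because only
rRNA-to-rRNA gaps are examined; chains meeting across the junction merge.
The 3 kb default accommodates the tRNAs commonly encoded in 16S–23S
spacers; published operon counts rarely state their grouping rule, so the
threshold is a parameter. Density is operons per Mbp at full precision,
rounded to two decimals only in reports (7 operons on 1,298,316 bp print
as 5.39/Mbp).

The survey applies, in order: (1) drop genomes flagged Candidatus or not
free-living — lifestyle is metadata, not computable from sequence, so it
comes from the input table; (2) keep one genome per species, the
highest-density representative; (3) keep densities strictly above the
threshold (default 2.9/Mbp); (4) rank by density, ties broken by genome
id. The packaged `data/rrn_survey_example.tsv` carries 12 genomes with
sizes and stable-RNA counts following public annotations of the listed
accessions, including duplicate-species and Candidatus rows so every rule
is exercised.

## Codon usage bias

The metric is the classical reference-set adaptation index. Pooled codon
counts over the reference genes give the relative adaptiveness
w(codon) = count / max(count over synonymous codons); codons absent from
the reference receive a floor of 0.01 to keep geometric means finite. A
gene's score is exp(mean(log w)) over its codons, excluding stop codons
and the single-codon amino acids Met (ATG) and Trp (TGG), which carry no
synonymous choice; a score of 1 means every countable codon is a major
codon. Genes are validated against the bacterial genetic code (table 11):
length divisible by 3, no ambiguous codons, no internal stop; invalid
genes are flagged and excluded from ranking rather than raising. The
default reference set is genes whose product matches "ribosomal protein",
the canonical highly-expressed proxy; an explicit id list can override it.
RSCU vectors (observed / expected-under-uniform-synonymous-usage) are
available for inspection. Published top-N lists produced with unstated
metrics and reference sets cannot be reproduced membership-for-membership;
the ranking here is validated against planted synthetic truth instead.

## Genome statistics

GC% is computed over unambiguous bases. Coding density is reported in two
labeled variants, because published tables use either without saying so:
the union variant (percent of bases covered by at least one CDS or
pseudogene body, circular-aware) and the summed variant (sum of CDS
lengths / size, which can exceed the union when genes overlap).
Pseudogenes are excluded from the ORF count and mean ORF length by
default (they are always counted separately); a switch includes them,
since published ORF totals may or may not.

## Phylogeny

Distances are uncorrected p-distances with pairwise deletion: for each
pair, sites where either row has a gap, N or another ambiguity are
discarded and the distance is mismatches / retained sites. A pair with
zero retained sites is an error naming the pair. A Jukes–Cantor
correction (−3/4 ln(1 − 4p/3)) is available but off by default; published
similarity matrices rarely state a correction model, and assuming one
silently would misrepresent them.

Neighbor-joining is the classical agglomerative algorithm: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j, with the standard
branch-length and distance-update formulas. Determinism: Q ties are
broken by the lexicographically smallest sorted pair of cluster labels,
where a cluster's label is the smallest leaf name beneath it, and
children are ordered by that label in the output. Negative branch
lengths are clamped to zero with the deficit moved to the sister edge
(standard practice; noted in that the sum of the pair's edges is
preserved). On additive matrices the algorithm reproduces the generating
topology and branch lengths exactly (verified to 1e−9), which is the
consistency guarantee of NJ.

Bootstrap: columns are resampled with replacement, the tree rebuilt per
replicate, and the support of each internal bipartition of the full-data
tree is the percentage of completed replicates containing it. A replicate
whose resampled columns leave some pair with no comparable sites is
skipped with a warning and excluded from the denominator. Bipartitions
are canonicalized as the leaf set not containing the alphabetically first
taxon, which makes supports invariant to input row order. Display
thresholds (e.g. "show supports over 50%") are applied only at
serialization time. Newick output quotes names containing spaces or
Newick metacharacters; re-parsing (via dendropy) reproduces topology,
lengths and supports.

Multiple sequence alignment construction is out of scope: the module
consumes pre-aligned FASTA.

## Synthetic-data generator

The genome generator emulates the statistical structure the analyses
assume, with every planted quantity recorded in a truth object:

- **Replichores.** Background bases are i.i.d. with P(G) = gc/2 + δ,
  P(C) = gc/2 − δ on the leading strand (δ = `skew_delta`, default 0.05;
  gc default 0.35), switching sign at ter = ori + L/2. The leading-strand
  G−C frequency difference is therefore 2δ. δ is defined as the
  probability excess added to G (and removed from C): this keeps GC fixed
  and makes the origin-recovery guarantee quoted above hold at the
  default settings.
- **Coding sequences** are placed non-overlapping with the coding strand
  equal to the leading strand with probability `strand_bias` (default
  0.8). Codons come from a mixture: with probability m_g the amino
  acid's major codon (the A/T-ending synonym, the pattern of low-GC
  firmicutes), otherwise a uniform synonymous codon. The mixing weight is
  a saturating function of expression, m_g = `codon_bias_strength` ·
  e_g/(e_g + median(e)), so bias grows smoothly with expression and the
  top of the distribution is clearly separated; default expression levels
  are lognormal(0, 1). Wherever the third codon base has both G- and
  C-ending synonyms, the G variant is chosen with probability 0.5 ± δ
  (sign by whether the coding strand is leading), mirroring real genomes,
  where skew persists at neutral wobble sites inside genes.
- **Origin module.** dnaA and dnaN are planted at the origin with
  consensus DnaA boxes (random N instantiation, random strand) at random
  non-overlapping offsets in the upstream region and the dnaA–dnaN gap.
  Truth box counts are defined by rescanning the emitted sequence over
  the same regions the reporting rule examines, so chance background
  matches are absorbed into truth and the box tests are exact.
- **Stable RNAs.** rRNA operons are 16S–23S–5S blocks with 150 nt
  internal gaps; inter-block gaps around operons are kept above the
  operon-grouping threshold so the planted operon count is recoverable by
  construction. tRNAs are 75 nt genes on random strands.
- **Pseudogenes.** A fraction of CDSs (default 0.1) receive a single-base
  deletion mid-gene with one random base appended at the 3' end, i.e. a
  frameshift that preserves coordinates.
- The `sanfranciscensis_like` preset mirrors the headline architecture of
  a small sourdough-lactobacillus chromosome: 1,298,316 bp, GC target
  0.347, 1250 genes of mean length 835 nt, 7 operons, 61 tRNAs, 5+3 DnaA
  boxes, 10.6% pseudogenes.

What the generator does **not** emulate: rRNA/tRNA gene sequence content
(stable-RNA bodies keep background composition — grouping and counting
operate on annotations, not sequence homology); insertion elements and
repeats; indel evolution in alignments; unequal replichores; amino-acid
composition bias, so simulated coding regions have higher GC than a real
low-GC genome (the preset's overall GC comes out near 46%, not 34.7% —
background composition targets apply to intergenic sequence only).
Passing tests on synthetic data therefore validate the algorithms'
correctness against known truth, not parser robustness against the full
messiness of real annotation records.

The alignment simulator evolves i.i.d. uniform root sites down a given
tree under Jukes–Cantor (substitution probability 3/4(1 − e^(−4t/3)) per
branch of length t), no indels. All randomness in both generators flows
from a single mandatory seed; equal specs give byte-identical output.

## Problem sizes and runtime

The test suite and the acceptance script run on deliberately compact
problems chosen to make the statistical checks sharp: 100 kb genomes for
origin recovery (20 replicates), a single 1.3 Mb preset chromosome for
architecture recovery, 50 random 5–8 taxon trees for NJ exactness, one
megabase of uniform sequence for motif-rate calibration, 100-gene genomes
for the codon-usage ranking, and 100 bootstrap replicates on short
alignments. The whole suite completes in seconds.

## Known limitations

- The origin predictor reports raw cumulative-skew extrema; genomes with
  weak or multi-modal skew produce low-confidence calls that should be
  checked against the dnaA-distance flag.
- The dnaA-box "upstream" window is a convention (1 kb cap); published
  counts made with a different window will differ.
- The operon-grouping threshold trades splitting against merging; 3 kb is
  calibrated for typical 16S–23S spacers with tRNAs, not for unusual
  operon layouts.
- The survey's lifestyle flags are taken on trust from the metadata table.
- The codon-usage metric is one member of the adaptation-index family;
  rankings are comparable within a run, not across metrics.
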
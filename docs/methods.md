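# Methods

This note records the models implemented in `paleosieve`, the defaults
chosen where the design was open, and what the packaged simulations do and
do not establish about real data.

## Taxonomy and LCA

A taxonomy is a rooted tree of `(taxon_id, parent_id, rank, name)` nodes;
the root is the unique node that is its own parent (NCBI convention).
Ranks are free strings compared only by identity: the retention rule
"classified at the target's order or lower" is implemented as subtree
membership of the order node, never as rank-name ordering, because rank
names are not totally ordered across real lineages. LCA queries are
two-pointer walks on precomputed depths; `lca_of_set` is the left fold and
is order-independent because pairwise LCA is associative and commutative.

## Classifier

The database maps every canonical k-mer (lexicographic minimum of a
window and its reverse complement, alphabet A<C<G<T, windows containing
any non-ACGT base voided) to the LCA of all taxa whose genomes contain
it. Classification counts database hits over a read's windows, scores
each hit-bearing taxon by the summed hits on its root-to-taxon path, and
assigns the deepest maximal-score taxon; incomparable ties resolve to
their LCA. With a confidence threshold c > 0 the assignment walks rootward
until the fraction of k-mers hitting inside the assigned clade reaches c;
the default is 0.

This is an *exact* hash, deliberately not a minimizer-keyed probabilistic
compact hash: the compact structure trades memory for occasional false
classifications, which is an implementation artifact rather than part of
the classification model. Consequences worth keeping in mind when
extrapolating to production classifiers: here a read drawn verbatim from a
database genome can never be unclassified, and there are no
hash-collision misclassifications. The k parameter still carries the real
trade-off: k = 35 cannot classify fragments shorter than 35 bp and breaks
on fewer mismatches (specific, less sensitive); k = 29 reaches shorter
and damaged fragments at the cost of specificity. Two database
conventions mirror that trade-off: the positive-filter database (target +
close relatives, k = 29) and the negative-filter database (target + broad
contaminant panel, k = 35).

`build_alt_consensus` substitutes biallelic-SNP ALT alleles into a copy of
the reference (contigs suffixed `_alt`), skipping non-SNP/multiallelic
records and rejecting REF mismatches with counts rather than errors. The
consensus is added *under the same taxon* by default, so augmentation
widens k-mer coverage around known variation without changing the
database's taxon set — the guard against reference bias in positive
filtering. A flag-equivalent (distinct taxon id) is simply passing a
different id to `add_genome`.

## Read simulator

Fragment lengths are truncated-lognormal: ln L ~ N(ln 55, 0.35²) rounded
and truncated to [30, 150] bp. The 30 bp floor coincides with the
conventional minimum-length cut so the prep filter is actually exercised;
the median of 55 bp and the right-skewed shape are typical of degraded
aDNA libraries. A parametric family replaces any empirical fragment-size
table so that tests can check moments in closed form.

Deamination is exponential-decay terminal damage: the position-i
probability from an end is `background + p_max·exp(−λ·i)`. Single-stranded
libraries deaminate cytosines at both ends (one combined C→T draw per
position); double-stranded libraries show 5' C→T and 3' G→A. UDG
treatment scales the terminal maxima: none ×1, half ×0.5, full ×0 (the
constant background floor remains). The packaged ancient profile is a
partially UDG-treated single-stranded library: p5 = p3 = 0.3 before the
UDG-half scaling, λ = 0.5, background = 0.01. A parametric damage model —
rather than an empirical misincorporation table — is what makes the
parameter-recovery test possible: simulate at known (p_max, λ), measure
the profile, refit.

Pairs are rendered at 75 bp: R1 reads the fragment 5'→3', R2 its reverse
complement; fragments shorter than the read length run through into the
adapter (TruSeq sequences, stored in config) and then random bases.
Sequencing errors are uniform substitutions at a per-base rate (default
10⁻³); qualities are constant Phred 37, capped at 41, +33 encoded. Truth
travels in the read name (`taxid|contig|start|end|strand|serial`) and in a
mirror TSV. With a fixed seed every output, including gzip members
(mtime 0, no embedded filename), is byte-identical.

Not modelled: indels, PCR duplicates, GC bias, position-dependent quality,
modern/ancient mixtures within one taxon. Passing benchmarks here
therefore say nothing about classifier robustness to indel error or to
library-preparation artifacts.

## Read prep

Adapter trimming takes, scanning trim points left to right, the longest
suffix-prefix overlap with the adapter at ≤ 10% mismatches. Merging
aligns R1 against the reverse complement of R2 over all shifts, accepts
the longest overlap of ≥ 11 bases at ≤ 10% mismatches, takes the
higher-quality base in the overlap (quality = max of the two, capped 41),
then quality-trims ends below Q20 and discards merged reads shorter than
30 bp. Unmerged pairs are discarded (`keep_unmerged` is deliberately not
the default: downstream mapping consumes merged reads only).

Edge case, documented rather than hidden: one or two terminal bases can
chance-match the adapter prefix and be trimmed; the partner read's bases
restore them during merging, so error-free overlapping pairs still
reconstruct their fragment exactly. Only fragments within ~10 bp of twice
the read length (≥ ~136 bp at 2×75) can lose their already-minimal overlap
this way and fail to merge; such losses are charged to recall like any
other prep loss.

## Mapper

A stand-in aligner, not a bwa reimplementation — the evaluation harness
treats the mapper as pluggable and consumes any SAM. Candidate loci come
from exact seed hits (forward seed table; reverse strand found by
searching the read's reverse complement) at every query offset; extension
is ungapped, +1 match / −3 mismatch; a read maps when its best locus has
at most ceil(0.04·L) mismatches. MapQ = min(60, 4·Δscore) against the
best alternative locus, 0 on ties — the only downstream use is the
MapQ > 20 threshold, so any deterministic, monotone uniqueness score
serves. CIGAR is always full-length `M`; coordinates are 0-based
half-open internally, 1-based in SAM.

Seed length bounds sensitivity: an alignment with m mismatches on a read
of length L is guaranteed a clean seed only if `seed_len ≤ (L−m)/(m+1)`.
At the 4% mismatch ceiling, seed_len = 8 makes the mapper provably
equivalent to an exhaustive scan for L ≥ 30 (the oracle tests run this
configuration); the workflow default of 13 trades a negligible corner of
that guarantee for speed, as production seed-based mappers do.

Competitive mapping is the same machinery over a composite index whose
contigs carry genome labels; the evaluator counts a best hit on a
non-target label as not mapped to the target. Equal-score ties break
deterministically by (contig, position, strand), and label assignment is
invariant to genome order in the index.

## Benchmark harness

Each simulated read is scored against its truth: endogenous means the
truth taxon lies in the endogenous clade (one clade parameter serves any
target species); predicted-positive means retained by the filter *and*
mapped to the target with MapQ > 20. Reads discarded during prep or left
unmapped count toward FN/TN because the recall denominator is all
endogenous reads in the dataset. Undefined metrics (0/0) are explicit
`None` markers, never 0 — silent zeros could fake a pass. Length
stratification uses the merged-read length (true fragment length for
reads that never reached the SAM) over bins 30–40, 41–50, 51–60, 61+.

Misincorporation profiles measure, per distance from the read 5' end,
`#C→T / #aligned reference C` (and G→A from the 3' end; 3' C→T is also
reported for single-stranded libraries). For parameter recovery the
alignments are written at the fragments' true coordinates: an aligner in
the loop preferentially drops heavily damaged reads and would bias
terminal rates downward.

The six benchmark conditions (mapping only, competitive, and each
filtering strategy alone and combined with competitive mapping) are
evaluated from two mapping passes only, because filtering subsets reads
and never alters alignments.

## Fixture design

The toy taxonomy has a target species and sibling species in one genus
and order; a second order holding the human-analog contaminant and two
unrelated vertebrates; and a microbial domain with three species. Two
kinds of homology are planted, because they play different roles:

* the **sibling** carries an exact copy of 50% of its length from the
  target — the close-relative genomes one would put *in* the positive
  database; shared k-mers take genus-valued LCAs, which exercises
  LCA-rank classification;
* the **cross-order contaminant** carries copies of 30% of its length
  from the target, mutated at 5% per base — homologous but diverged, like
  a mammalian contaminant against a mammalian target. Its reads are the
  precision threat: some align to the target within the mismatch budget,
  while classification can still separate most of them (their exact
  k-mers are their own; only ~0.95²⁹ ≈ 2% of shared windows survive
  intact).

A within-order contaminant could never be removed by an order-level
clade filter, which is why the diverged relative sits in the other order
— the configuration in which filtering has something to prove. Scenario
configs fix the mixtures: scenario 1 (high vertebrate contamination — 5%
endogenous, 20% diverged relative, 15% other vertebrates, 60% microbial)
and scenario 2 (microbial-dominated — 20% endogenous, 5% vertebrate
total, 75% microbial). These are structural analogs of full-genome
benchmark designs, not replicas; absolute precision/recall values at toy
scale do not transfer, only the directional comparisons between methods.

## f4 reference-bias test

Pseudo-haploid calls sample one base per site (MapQ ≥ 20, baseQ ≥ 20,
base ∈ {ref, alt}), replicated three times with different draws, at sites
ascertained heterozygous in an outgroup individual. f4(Filt, Unfilt;
ref-like, outgroup) is the mean over complete sites of
(pA−pB)(pC−pD); its SE comes from a delete-one *weighted* block jackknife
(Busing-style, h_j = n/m_j) over contiguous blocks of 200 sites at
fixture scale — with equal blocks this reduces exactly to the textbook
delete-one jackknife, and for a linear statistic the jackknife point
estimate equals the full-sample mean. Blocks are site-count blocks
because toy panels have no genetic map; the size is a parameter. The
verdict is one-sided: "biased" iff Z > 3, since filtering can only push
calls *toward* the reference in this configuration; |Z| is reported
alongside.

Calibration uses synthetic pileups at 5000 het sites, mean depth ~6:
dropping alt-carrying bases at 30% (planted bias) versus dropping bases
at 30% regardless of allele (null). The null stays within |Z| < 3 and the
planted effect exceeds Z = 3 in ≥ 18/20 trials each; planted strength and
Z increase together.

## Problem sizes and numerical choices

Benchmark runs use 50 000 read pairs over ~180 kb of fixture genomes,
chosen so a complete six-condition benchmark finishes in about a minute
on one CPU while keeping binomial standard errors small enough for the
directional comparisons to be stable across seeds. Oracle-equivalence
checks run 1000 random instances each. All RNG flows through
`numpy.random.default_rng` with explicit seeds; any derived seeds stay
below 2³¹. Ties anywhere (classification, mapping, apportionment) break
deterministically, and largest-remainder apportionment makes component
read counts match their fractions exactly.

## Known limitations

* The exact-hash classifier overstates the accuracy of compact-hash
  classifiers; it cannot reproduce their false-classification modes.
* The mapper is ungapped; indel-rich regions and real aligner MapQ
  models are out of scope, and the MapQ > 20 threshold is assumed
  transferable across mappers.
* Toy genomes lack repeats, GC structure and real k-mer sharing
  gradients; directional results, not absolute metric values, are the
  supported conclusions.
* The f4 blocks are site-count-based; linkage-aware blocking on real
  genomes would give larger SEs than fixture-scale blocks suggest.
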
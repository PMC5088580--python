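# Methods

## The error model

A sequencing run is summarised by a 4×4 substitution matrix *M* with
`M[ref][read]` the probability of observing a given read base where the
reference holds a given base, plus per-aligned-position insertion and
deletion probabilities *I* and *D*.  The orientation is fixed so that the
PAR-CLIP conversion — reference T read as C — is row T, column C; this is
the single convention the whole package shares, and reverse-strand
alignments are complement-flipped before counting so that a genomic A→G
event on the minus strand is scored as a sense T→C.

Estimation counts aligned base pairs reconstructed from CIGAR + MD tags,
divides by row totals, floors every entry at 1e-4 and renormalises rows.
The floor prevents a substitution the sample happened not to show from
becoming categorically impossible in the aligner; its magnitude sits well
below typical per-base sequencing-error rates (≈ 1e-3–7e-3) so it never
dominates an observed rate.  *I* and *D* are event counts over aligned
positions, floored the same way.

Two variants of the matrix are kept deliberately distinct:

* the **aligner profile** *M* keeps the observed T→C rate, conversions
  included (in PAR-CLIP data roughly 6 %, an order of magnitude above the
  other rates) — the aligner *wants* conversions to be cheap;
* the **background profile** ε replaces the T→C entry with the mean of the
  eleven other off-diagonal rates — the simulator must not inject
  conversions through the sequencing-error channel, because conversion
  placement is governed by its own site model.

The conversion site model consists of α (mean conversion frequency of the
rank-r site across clusters, rank 1 = the major site), β (distribution of
the major site's relative position within the cluster, discretised into 20
equal-width bins — the discretisation is this package's choice), and a
per-cluster site-count distribution.  A position qualifies as a
"conversion site" when it has ≥ 5 covering reads and ≥ 5 % conversion
frequency; both cut-offs are package choices that make ranking stable on
shallow clusters.  Per-read-position indel rates μ and Phred distributions
δ complete the model.

## The simulator

The generative process mirrors a PAR-CLIP library preparation on a
transcript database:

1. transcripts are drawn uniformly (with replacement) from the database;
   transcripts shorter than the maximum read length plus a small margin
   are skipped;
2. per transcript, Uniform{1..3} clusters are placed with uniform start
   positions; the read count of a cluster is round(Normal(16, 10)),
   redrawn until ≥ 1 (i.e. a normal truncated at one read) — parameter
   recovery therefore uses a truncated-normal likelihood;
3. each cluster is a binding site with probability λ (default 0.65, the
   recommended range being 0.5–0.7); the rest model contaminating unbound
   RNA.  Because cluster size and the binding label are independent, the
   *read-level* binding fraction converges to λ as well;
4. reads start at the cluster start plus round(Normal(0, 1)), clamped to
   the transcript, with lengths Uniform{20..30} by default (published
   PAR-CLIP libraries show mean trimmed read lengths of 23–26 bases; a
   fixed-length mode exists for tests);
5. binding clusters receive conversion sites: the count from the
   site-count distribution, the major site's position from β snapped to
   the nearest reference T, minor sites uniform over the remaining Ts;
   every covering read converts site s independently with probability
   α[rank(s)].  A binding cluster whose span contains no T is re-placed up
   to 10 times and then demoted to contamination;
6. sequencing noise is applied *after* conversions, in order: substitution
   of each (possibly converted) base via its ε row, per-position
   insertions/deletions via μ, and Phred scores via δ.

All randomness flows through a single numpy PCG64 generator seeded from
the configuration, so output is byte-reproducible.  Each read's truth
(origin, strand, cluster, binding flag, conversion count) is encoded in
its name and duplicated in a TSV sidecar; the in-memory result also keeps
the full edit log, and reverting that log must reproduce the reference
substring exactly (a tested invariant).

Default study conditions where no external profile is supplied: background
substitutions at 0.001 per off-diagonal entry (≈ 0.3 errors per 100
bases), indels at 5e-4 per position split evenly between insertion and
deletion, α = (0.70, 0.40, 0.20) — a 70 % major-site conversion frequency
with decaying minor ranks — site count uniform on {1, 2, 3}, β
centre-peaked (triangular over 20 bins), and qualities drawn around Q39
early in the read decaying to ≈ Q33.  What the generator deliberately does
*not* emulate: exon–exon junctions (reads are simulated on transcript
sequences; junction handling enters only through the liftover of
transcriptome alignments), PCR duplicates, strand mixtures (all simulated
reads are transcript-sense), motif-driven base composition, and
multi-mutation hotspots.  Tests passing on this generator therefore
demonstrate correctness of the algorithms under these idealised
conditions, not performance on any particular real library.

## The aligner

The reference (both its forward sequence only; N runs split sequences into
separately indexed segments) is indexed with a suffix array built by numpy
prefix-doubling, from which the BWT, cumulative counts and a full
occurrence table derive.  Backward search extends a suffix-array interval
by one preceding reference base at a time; an interval is exactly a node
of the reference's prefix trie, so the search literally walks that trie
from the last read base to the first.

Each extension multiplies a running probability: `M[ref][read]` for a
substitution/match column, *I* for an inserted read base, *D* for a
deleted reference base (which consumes no read base).  A placement is
accepted when the completed product reaches

    T = avg(match)^(L−X) · avg(mismatch)^X,

computed in log space.  X is real-valued; `estimate_X` returns the
expected mismatch count `max(1, L·m̄)` with
`m̄ = (1/4)·Σ_{i≠j} M[i][j] + I + D` under a uniform reference-base
assumption.  The package's default for alignment runs, however, is X = 2
rather than the expectation: at PAR-CLIP conversion rates the expectation
evaluates to ≈ 0.6–1 for 25-base reads, and at X = 1 the threshold rejects
even a single rare (non-conversion) sequencing error — `avg(mismatch)`
averages the cheap conversion with the expensive rare errors, so an
X-of-1 budget is spent entirely by one rare event.  X = 2 mirrors the
two-mismatch convention of the baseline search it replaces and admits, at
the default profile, up to three conversions, one rare error, or one
conversion plus one rare error.

Search-space control:

* **dynamic pruning** — a partial path with probability q and r read bases
  left is abandoned when `q · b^r < T`, with `b = max(diag(M), 1−(I+D))`
  an upper bound on every recursion factor, so no accepted placement is
  ever missed;
* **indel gating** — indels are forbidden within the first/last two read
  bases and runs of more than two consecutive indel ops are not explored;
  both bounds exist to keep the trie search finite and are far outside the
  probability mass that survives T at realistic profiles;
* **strands** — the reverse strand is searched by aligning the
  reverse-complemented read against the forward index with the
  complement-permuted matrix, so p is always the probability of the read
  given its own template strand.  (Note p is *template-composition*
  dependent: an exact match over a T-rich template scores lower than over
  an A-rich one, because M[T][T] < M[A][A] when T→C mass is large.)
* **N bases** — a read N scores as the smallest entry of M against any
  reference base; N runs in the reference are simply not indexed.

Per placement the maximal-probability path is reported; its probability is
recomputed canonically (left-to-right over the alignment) from the edit
list, and the tested contract is that this reproduces the search's value
to 1e-12 relative and that an exhaustive window-scoring oracle agrees with
the hit set exactly and with log p to 1e-9.  Primary records are chosen by
highest p, then reference order, leftmost position, forward strand; MAPQ
is `min(60, round(−10·log10(1 − p_best/Σp)))`, a package convention.
Comparison counting, used by the six-base worked example, counts one
comparison per evaluation of a read base against an existing trie branch
(failing branches included; indel extensions and sentinel branches never
counted).

The counted-mismatch baseline (`align_baseline`) is the same backward
search with an integer mismatch budget and no indels.  It serves two
roles: the comparator in the worked example, and the pipeline's first pass
from which the error profile is estimated — keeping the pipeline free of
external aligners.  The probabilistic stage is not a strict per-read
superset of the baseline: a read with two rare errors passes a 2-mismatch
budget but falls below T at X = 2.  The tested (and observed) property is
aggregate: on PAR-CLIP-like simulations the probabilistic stage maps more
reads and attains strictly higher recall, because multi-conversion reads
outnumber two-rare-error reads by a wide margin at these rates.

Transcriptome rescue: reads unmapped on the genome but mapped to a
transcript are lifted through the transcript's exon blocks (BED12),
producing N-gapped CIGARs for junction-spanning reads; minus-strand
transcripts flip the read orientation during the lift.  MD tags are
recomputed against the genome when its sequence is supplied and dropped
otherwise (a transcript-space MD is meaningless after the lift).

## Clustering and filters

Mapped reads on the same reference and strand are linked when their
aligned spans (CIGAR reference length, 1-based inclusive) share at least
5 bases; clusters are the connected components, computed by a start-sorted
sweep that is provably equivalent to single linkage and is checked against
an O(n²) overlap-graph oracle in the tests.  Strands never link — the
conversion orientation differs.  Per sense-T position the cluster records
coverage and conversion count.

A cluster is kept as a high-confidence binding-site candidate iff it has
≥ 10 reads, ≥ 25 % conversion ("25 % T–C conversions per cluster" is read
as the fraction of member reads carrying a conversion; a position-level
mode is available via `tc_fraction_mode="positions"`), spans ≤ 75 bases,
and has at least one conversion site absent from the user-supplied SNP
BED.  A cluster with no conversion sites at all fails both the fraction
rule and the SNP rule.

## Benchmarking

A mapped read is correct when reference and strand match the truth and the
reported start is within 5 bases (configurable) of the true start — slack
for the simulated start wobble and indel-induced shifts.  Recall is
correct/simulated, precision correct/mapped, and accuracy
correct/(simulated + false placements); the accuracy denominator charges
every wrong placement on top of the full read set, which bounds accuracy
by both recall and precision.  This accuracy definition is a package
convention, stated here because composite "accuracy" numbers in the
literature are not always computed identically.

## Numerical and scale choices

All probability arithmetic is in log space; threshold comparisons carry a
1e-9 log-space slack so float rounding cannot flip an accept/prune
decision.  The acceptance checks run at sizes a laptop handles in minutes:
oracle equivalence on a ≈ 50 kb reference with 500 simulated reads,
closed-loop profile recovery on ≥ 1e5 aligned bases (4,200 reads),
parameter recovery on 10,000 cluster placements, and the recall-ordering
comparison on 3,000 reads.  The full occurrence table makes the index
memory linear in reference length with a constant of ~40 bytes/base,
adequate for transcript databases and test genomes up to a few megabases;
gapped-seed heuristics for mammalian-genome scale are explicitly out of
scope.

## Known limitations

* The suffix array is O(n log² n) and the occurrence table dense; both are
  fine at transcriptome-fixture scale and wasteful at genome scale.
* The aligner ignores base qualities (quality-aware scoring is a
  different method family).
* Paired-end reads, adapter trimming and BAM/CRAM are out of scope; SAM
  text is the only alignment container.
* α is summarised by per-rank means (the full per-rank histograms are
  retained on the model object for inspection, but the simulator draws
  conversions from the means).
* The simulator models neither junction-spanning reads nor HITS-CLIP-style
  deletion signatures.
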
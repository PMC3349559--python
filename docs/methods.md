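# Methods

## Tag model

A library is a multiset of 21-bp reads. A valid tag is the NlaIII recognition
site `CATG` followed by 17 bases (the MmeI release length). The reference tag
set of a unigene collection contains, for every sequence and both strands,
every `CATG` occurrence with at least 17 subsequent bases; tags spanning an
`N` are skipped. De novo unigenes have unknown orientation, so both strands
are indexed even though the chemistry produces tags only from the
transcript's 3'-most site; the indexer records gene, strand and site rank
(1 = closest to that strand's 3' end) for diagnostics.

## Cleaning

Raw reads are classified in a fixed order: adaptor-only or empty (exact match
to a configured adaptor string, or zero length), then N-containing, then
malformed (length ≠ 21, missing `CATG` prefix, or non-ACGT characters) —
malformed reads are booked as *low quality*, which keeps them distinct from
the *containing N* category. Surviving reads are tallied by distinct tag
sequence and, last, tags below the copy-number floor (`min_copy`, default 2)
are removed as probable sequencing errors, their reads booked as *singleton
removed*. Ordering matters: singleton removal must run after tallying so an
error tag one substitution away from an abundant tag is removed, never
merged. The ledger identity

    raw = clean + adaptor_only + containing_N + low_quality + singleton_removed

holds on every input and is asserted at construction. No quality-score
filtering exists anywhere; quality is defined by sequence content only.

`min_copy=1` disables the singleton filter. That is the correct setting for
error-free input (e.g. validating mapping fidelity on noise-free
simulations): with no sequencing errors a copy-number-1 tag is a real
observation, and removing it would make exact count recovery impossible for
genes sampled once.

## Mapping

Each distinct clean tag is assigned at the minimal Hamming distance not
exceeding `max_mismatch` (default 1; 0–2 supported). The `CATG` anchor is
enzymatically fixed, so the mismatch neighbourhood enumerates substitutions
only at the 17 variable positions (51 variants at distance 1, 1,224 at
distance 2) against a hash index — exact and fast. Tie rules:

- distance-0 hits strictly dominate distance-1 hits;
- a tag whose minimal-distance hits all lie in one gene counts once to that
  gene (*unique match*), regardless of how many sites within the gene match;
- hits in more than one gene make the tag *multi-position*: its copies count
  to no gene;
- no hit within the budget leaves the tag *unmapped*.

The mapping ledger satisfies `mapped = perfect + mismatch`,
`mapped = unique + multi_position` and `clean = mapped + unmapped`.
Coverage per gene is the fraction of bases under at least one mapped 21-bp
footprint (union of intervals, minus-strand placements converted to forward
coordinates), histogrammed by deciles.

## Normalisation and the exact test

Expression is normalised to tags per million (`count / total_clean × 10^6`);
RPKM (`count / (length/10^3) / (mapped/10^6)`) is provided for length-aware
summaries. For a gene with count `x` of `N1` total clean tags versus `y` of
`N2`, the Audic–Claverie conditional law

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) )

is the negative binomial NB(x+1, N1/(N1+N2)). The two-sided p-value is
`min(1, 2·min(lower, upper))` with `lower = Σ_{k≤y} p(k|x)` and
`upper = Σ_{k≥y} p(k|x)`.

Numerical notes:

- Both tails are computed by log-sum-exp over the log pmf
  (`gammaln`-based), never as `1 − other_tail`: the complement loses the
  small tail to cancellation exactly when it matters. The upper tail is
  truncated where terms become negligible — beyond
  `max(y, mean) + 12·sd − 50/log(q)` with `q = r/(1+r)` the asymptotic term
  ratio — which bounds the neglected mass far below double precision.
- Counts beyond ~10^6 are handled; a two-sided value that underflows double
  precision is floored at the smallest positive normal double so p stays in
  (0, 1].
- The statistic is *not* symmetric under (x,N1)↔(y,N2): the conditional law
  conditions on x+1. The asymmetry is a property of the underlying model
  (e.g. p(0,N,1,N)=1 but p(1,N,0,N)=0.5) and fades at moderate counts; the
  implementation follows the formula exactly and is verified against an
  arbitrary-precision summation oracle instead of a symmetry assumption.

Significance per comparison: Benjamini–Hochberg q < 0.001 (step-up, via the
standard multiple-testing routine) and |log2 ratio| > 1. The ratio is
case-over-control TPM with a 0.5 pseudocount added to the raw counts — a
zero count in one library otherwise produces an infinite ratio and would
dominate the extreme screen; the p-value always uses the raw counts. Genes
with zero counts in both libraries of a comparison are untestable and are
excluded from the BH family rather than diluting it.

## Screens and clustering

The staged design compares stages 2–4 of the swelling strain against two
baselines (the non-swelling mutant and stage 1), six comparisons in all. The
intersection screen keeps genes significant in every comparison (significance
required, not merely a computable ratio). The extreme screen keeps genes with
|log2 ratio| above a threshold (default 10) in *all* comparisons with a
consistent sign; mixed-sign profiles are excluded. Trend profiles (the
six-vector of log2 ratios in design order) are clustered by hierarchical
agglomeration with Euclidean distance and average linkage, cut into k groups
(default 4); rows are sorted by gene id before linkage so the partition is
independent of input order. Metric and linkage are conventional choices,
exposed as arguments.

## Enrichment

The hypergeometric upper tail `P(X ≥ m) = 1 − CDF(m−1)` is evaluated for
every term containing at least one screened gene. The background N is the
set of genes carrying at least one annotation in the supplied table — not
the whole reference — and the screened set is intersected with it first.
Bonferroni multiplies by the number of tested terms (configurable to all
terms); corrected p < 0.05 flags enrichment, the same rule for GO and KO.
No ontology-graph propagation is performed: annotations are used as given.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
exact ground truth.

- **Reference**: `n_genes` (default 1,000) uniform-random sequences of
  200–2,000 bp; 95% are tag-bearing (a `CATG` with ≥17 following bases is
  planted when absent; the remainder are scrubbed of every anchor — `CATG`
  is its own reverse complement, so scrubbing clears both strands). Half the
  unigenes are stored reverse-complemented to mimic unknown assembly
  orientation. Only the transcript's 3'-most site generates reads, matching
  the 3'-anchored chemistry, although the indexer indexes all sites.
- **Abundances**: log-normal(μ=0, σ=1.5), normalised to sum to 1 — the
  heavy-tailed profile typical of transcriptomes.
- **Trajectory**: truly changing genes (default 10%) carry fold change f
  (log-uniform in 2–16 by default) applied as the monotone ramp
  1, f^(1/3), f^(2/3), f over stages 1–4 and 1 in the mutant baseline, so
  the six comparisons differ in effect size and their intersection is
  non-trivial.
- **Direction assignment (composition balance)**: tags are sampled
  multinomially, i.e. as relative abundances, so if the changing genes add
  net tag mass every unchanged gene's relative abundance drifts and
  per-million normalisation misreads the drift as expression change.
  Per-million normalisation is only unbiased under comparable library
  composition, and the generator emulates exactly that regime: down-regulated
  genes are drawn from the well-expressed upper tier (a gene must be active
  in baseline tissue before the course can silence it), each mass-paired with
  an induced gene of roughly (1−1/f)/(f−1) times its abundance, giving a
  50/50 up/down split and near-zero net mass shift at every stage.
  Consequently the package's recovery results say nothing about robustness
  to composition shift (a regime where per-million normalisation is known to
  bias any method, this one included).
- **Noise**: per-base substitution at `error_rate` (default 0.001, iid over
  all 21 positions — errors in the anchor produce malformed reads),
  adaptor-only reads (default 0.8%) and single-N reads (default 0.01%)
  injected multinomially so the emitted read count equals the requested
  depth (default 2×10^5) exactly.
- **Not emulated**: PCR amplification bias, MmeI cut-length heterogeneity
  (20 vs 21 bp), quality scores (constant 'I'), biological replication (one
  library per stage, as in the staged design modelled), SNP-driven
  mismatches between strain and reference, and on/off switch genes extreme
  enough for the |log2| > 10 screen — that screen is exercised on
  constructed profiles. Passing tests therefore demonstrate correctness of
  the counting statistics under clean multinomial sampling, not performance
  on real libraries, where mismatch rates and unmapped fractions are far
  higher.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 1,000 genes and
2×10^5 tags per library for the statistical checks (type-I control, staged
recovery), smaller fixtures elsewhere — sizes at which multinomial sampling
noise is small relative to the tested effect sizes, chosen as the package's
standard benchmark conditions. All randomness flows from a single integer
seed (per-library generators are derived from it), making every output —
including the full pipeline report bundle — byte-identical across reruns.

## Known limitations

- The exact test assumes Poisson sampling within a library; biological
  replicate dispersion is out of scope by design (no negative-binomial
  dispersion model), matching the single-library-per-stage design.
- Multi-position tags are discarded rather than fractionally assigned, so
  expression of genes sharing tags is underestimated.
- The adaptor classifier is an exact string match; partial adaptor
  contamination inside otherwise valid reads is not modelled or removed.
- Mapping allows at most two mismatches and no indels; tags from unassembled
  transcript regions stay unmapped, as with any reference-limited method.
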
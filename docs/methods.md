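# Methods

This note documents the models and procedures implemented in `arfnet`, the
defaults chosen where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Keyword mining of annotation tables

Annotation records are (gene, term, term name, aspect, evidence, optional
GO-slim name) rows from a tab-delimited flat file; the parser is permissive
about extra columns because public slim files carry many, and the column
layout is configurable because archived releases differ. Matching is
case-insensitive substring over term name and slim name — the weakest
assumption that makes "root" recall terms like "lateral root development";
a word-boundary mode is available when substrings over-match (e.g. "root"
inside "rooting"). Evidence codes are not filtered by default, since this
stage is a recall-oriented shortlisting step; consumers can filter the
exported report. Set intersection, the final step, is exact.

## Distance trees for TF family grouping

Protein alignment is an input — the package does not align; any standard
aligner's FASTA output works. Distances are p-distances (mismatch fraction)
with pairwise deletion of gap columns; a pair with no comparable columns is
an error naming the pair rather than a silent zero. Model-based protein
distances are out of scope: family grouping only needs coarse topology.

Neighbor joining follows the Saitou–Nei Q-criterion. Two choices make it
reproducible run to run: Q-matrix ties break on the lexicographically
smallest pair of subtree labels (a subtree's label is its smallest leaf
name), and the Q-matrix is computed as (m−2)·D − (rᵢ + rⱼ) with the rank
sums added first so that it is bit-for-bit symmetric — otherwise exact tie
detection can fail on one triangle. Negative branch lengths, which arise on
non-additive inputs, are clamped to zero with the deficit moved to the
sister branch so the joined pair's distance is preserved. On additive
matrices the algorithm provably recovers the generating tree; the test
suite checks topology and path lengths to 1e−9 against randomly generated
trees and, at five taxa, against exhaustive least-squares search over all
15 topologies.

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports the percentage of replicates containing
each internal bipartition of the full-data tree. Family extraction is
anchor-based: an unlabeled leaf takes the family of the smallest clade
(side of any edge) that contains it and at least one anchor, provided all
anchors in clades of that minimal size agree; otherwise the leaf is
reported unassigned. An anchor set rather than a cut height was chosen
because family boundaries on such trees are defined by known members, not
by a universal depth.

## Putative-target inference

**Co-expression.** From an expression matrix, Pearson correlation between
the query TF and every candidate, with the two-sided p-value from
t = r·√((m−2)/(1−r²)) at m−2 degrees of freedom. Defaults r ≥ 0.7 (signed:
strong negative correlation does not qualify a target of an activator) and
p ≤ 0.05, with a per-query cap of 20 000 partners by descending r. The
module equally accepts a precomputed (query, partner, r, p) table, because
the co-expression compendia behind published analyses are usually not
recoverable; results are then taken at face value. Spearman or other
measures can be applied upstream and supplied via the table route.
Constant candidates (undefined r) are skipped with a warning; self pairs
and exact duplicate vectors are excluded.

**Motif scanning.** The AuxRE is modeled as a position-weight matrix.
Scores are log₂((p_base + ε)/q_base) summed over positions, with a
per-cell pseudocount ε = 0.01 to avoid −∞ on zero cells. The background q
is, by default, the 0-order base composition of the scanned promoter set —
the common default of FIMO-style scanners — with an explicit vector (e.g.
uniform) as an option.

The per-window p-value is P(S ≥ s) for a random word drawn i.i.d. from the
background. The score distribution is computed by dynamic programming over
positions with a *sparse* state space: partial sums are kept as exact
floats and merged when equal, and window scoring accumulates positions in
the same left-to-right order, so the DP support coincides bit-for-bit with
enumeration over all 4^w words and tail probabilities match enumeration to
~1e−13 (the residual is summation order in the tails, not discretization).
If the sparse support exceeds 200 000 states — only possible for wide,
low-information matrices — the computation falls back to a lattice of 1000
bins per position, whose error near tied scores is bounded by the
probability mass of one word. The default hit threshold is p ≤ 1e−4, the
conventional scanner default; note that a width-w consensus can only reach
p ≈ q_max_base^w, so very short motifs (w ≤ 6 under a near-uniform
background) cannot produce hits at this threshold — the bundled synthetic
AuxRE is therefore a 12-bp TGTCTC direct repeat, matching the dimeric
architecture of ARF binding sites. Both strands are scanned by default
(the strand convention of published scans is rarely stated); reverse-strand
hits are reported at the forward coordinate of their leftmost base, all
coordinates 0-based half-open.

**Intersection.** A gene passes with ≥ 1 hit (count configurable) from any
supplied PWM; per-gene provenance records the best hit (smallest p, then
largest score) and the co-expression statistics. Co-expressed genes without
a promoter sequence are dropped and counted in a logged tally rather than
treated as motif-free.

## Enrichment network maps

Annotations are propagated to all ancestors through `is_a` and `part_of`
edges (true-path rule) before testing. Every biological-process term with
at least one study and one population gene is tested with the
hypergeometric upper tail, summed in log space via log-gamma so that small
p-values are exact to machine precision. The population defaults to all
genes with ≥ 1 propagated annotation in the namespace — the standard
custom-reference choice when no background list is given — and is
configurable, since published node counts depend strongly on it.

Multiple testing defaults to Benjamini–Hochberg at q ≤ 0.05; Bonferroni
and "none" are selectable to probe sensitivity, as published analyses often
leave the correction unstated. The map contains the significant terms plus
their ancestors up to the namespace root as non-significant context nodes,
each node carrying gene count, p and q. Keyword ("root") node counting
deliberately counts significant nodes only: context ancestors are display
scaffolding, not findings. Map comparison tabulates the funnel — co-expressed
genes, motif-passing genes, significant nodes, keyword nodes — one column
per query set.

## qPCR fold changes and segregation

The comparative-Ct model assumes amplification efficiency 2. Technical
replicates are averaged first (they share the biological sample and carry
no biological information); per biological replicate ΔCt = Ct_target −
Ct_reference, ΔΔCt subtracts the calibrator line's mean ΔCt in the same
tissue, and the fold change is 2^−ΔΔCt. The reported point estimate is
2^−(mean ΔΔCt) — the geometric mean of per-replicate fold changes — which
makes the calibrator exactly 1 by construction and is the natural central
value for a log-scale quantity; the reported standard error is that of the
per-replicate fold changes, matching how such results are plotted.
Fold changes are invariant to any constant offset in Ct and halve per
extra target cycle, both covered by tests.

Mann–Whitney tests are two-sided, exact by enumeration when the pooled
sample is ≤ 12 without ties, otherwise normal approximation with midranks,
tie correction and continuity correction; an all-tied comparison returns
p = 1 rather than a degenerate statistic.

Segregation counts are tested by the uncorrected chi-square goodness of
fit to an a:b ratio at 1 degree of freedom — no Yates correction, which is
what reproduces the published statistics this package ships as an example
dataset — with the pass criterion χ² ≤ 3.84 (the upper-0.05 quantile,
computed from the chi-square inverse CDF, not hard-coded). Simulation
under a true 3:1 binomial with n = 150 seeds gives an empirical type-I
error of ~5–6%, consistent with the nominal level given the discreteness
of the counts.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (spec, seed). The master seed is split
into independent streams per generator by fixed labels, and promoter
sequences additionally per gene, so generating a subset of genes yields
the same sequences as generating all of them, and adding a generator never
perturbs another's output.

Defaults model a small but realistic study: 200 genes, a 20-gene
co-expressed block (pairwise r = 0.9 through a shared factor) containing
the query TF, 50 expression samples, 3000-bp promoters at 38% GC
(Arabidopsis-like upstream composition), one AuxRE consensus inserted per
planted promoter at a uniform offset and strand, a 60-term single-namespace
DAG in which ~10% of terms are root-named, Poisson(2)+1 annotations per
gene plus a planted root-named term annotated to block genes at 20× the 8%
background rate, qPCR designs with five biological × two technical
replicates and Ct noise of 0.1 cycles, and 150-seed segregation counts.
Every planted quantity is also written to a truth sidecar, which is the
oracle for the recovery tests.

The null counterpart of a spec removes all three plantings (block r = 0,
no motif insertions, annotation odds 1) at identical dimensions. The
end-to-end benchmark runs planted and null specs through the full funnel
and scores the fraction of replicate pairs in which the planted side
yields strictly more significant root-keyword nodes; with the defaults
this exceeds 95% over 100 pairs.

Limitations: promoters are 0-order i.i.d. sequences — no CpG structure,
repeats, or positional bias of regulatory elements; expression is Gaussian
with a single equicorrelated block — no mean-variance relation or
between-block leakage; annotations are independent across genes given the
term; and the ontology is a random DAG, not a real GO slice. Passing the
recovery benchmarks therefore demonstrates that the pipeline's inference
machinery is correct and calibrated under its own model assumptions, not
that real co-expression compendia or annotation releases would yield the
same gene lists — published funnel counts depend on archived database
versions and are reproduced here only in structure, not in number.

## Problem sizes used in validation

The shipped validation suite uses: 50 random PWMs of width 4–8 against
full 4^w enumeration; 200 random hypergeometric instances with N ≤ 25
against exact rational arithmetic; 100 random additive trees with up to 12
leaves plus 20 five-taxon instances against exhaustive topology search;
100 planted/null pipeline replicate pairs; 10 000 segregation replicates
for type-I calibration; all 70 partitions of eight values into two
four-element groups for the exact Mann–Whitney sweep; and 200 seeded qPCR
simulations for fold-change recovery. These sizes give binomial standard
errors comfortably below the margins being asserted while keeping the full
suite in the tens of seconds on a single core.
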
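# Methods

This note documents the models and procedures `sagpipe` implements, the
defaults and why they were chosen, what the synthetic generators emulate
(and do not), and the numerical conventions that make every run
reproducible.

## Conserved single-copy core and its decay curve

The marker catalog is defined combinatorially on a genome × ortholog-cluster
copy-number matrix: a cluster belongs to the single-copy core of a genome
subset S when its copy number is exactly 1 in *every* member of S.
Clusters that are multi-copy in any member are excluded for that subset —
"single-copy conserved" is a property of the subset, not of the cluster
alone. For each subset size k the distribution of core-set size over
subsets is summarized by mean, mode and population standard deviation;
the mode is computed on the integer counts with ties resolved toward the
smaller count and flagged.

Enumeration is exhaustive while C(n, k) ≤ `max_combinations` (default
10,000) and otherwise switches to uniform sampling of distinct subsets
without replacement under a fixed seed. C(25, 12) ≈ 5.2 million, so at the
default collection size the mid-range k values are sampled; the sampled
mean converges to the exhaustive mean (tested on toy matrices where both
can be computed).

The decay of mean core-set size with k is fitted with

    y(k) = c + a·k^b ,  c ≥ 0,

a power law with an additive asymptote: a pure power law cannot level off
at a nonzero core, and the biological expectation is precisely a nonzero
conserved core c. Fitting is trust-region least squares with a fixed,
documented initialization (c₀ = min y, b₀ = −1, a₀ = (y₁ − c₀)·k₁) and
tight tolerances, so the fit is deterministic. Non-convergence raises an
error carrying the best iterate. Both the fitted asymptote and the
exhaustive all-genome core are reported; they are distinct estimates of
the same biological quantity and need not coincide. In particular, on the
synthetic collection the cross-genome sharing of accessory clusters
decays geometrically (retention^k), which a power law only approximates,
so the fitted asymptote sits slightly below the designated core while the
exhaustive core equals it exactly.

## Rolling-window recovery and completeness estimation

Each reference genome is concatenated (contigs in a stated order) into a
single sequence treated as circular; windows wrap. Circularity makes all
window starts equivalent in measure and avoids truncation bias at the
sequence ends. A marker is recovered by a window only when its full span
lies inside it — partial overlap does not count. This is the conservative
choice, and the synthetic SAG generator applies the identical rule so
simulated truth and estimator speak the same language. One boundary case
is handled explicitly: a window whose length equals the genome length is
the entire circle and contains every marker, including any marker that
straddles the window's linearized boundary.

Defaults: fraction grid 0.01–1.00 in steps of 0.01, and 1,000 evenly
spaced starts per (genome, fraction). These balance the resolution of the
conditional distributions against runtime (the full default simulation is
a few seconds with the vectorized containment test) and are exposed in
the configuration. Recovery samples are pooled across all reference
genomes; a per-genome stratified summary can be produced by passing
single-layout lists.

The completeness estimate for an observed marker count k is the median
recovered fraction at k, with the first and third quartiles as spread
(box-plot convention: whiskers at the most extreme data inside
quartile ± 1.5·IQR, points beyond counted as outliers). Genome size is
assembly length / fraction — exact by construction, so size × fraction
reproduces the assembly length — and the ± is the half-width of
assembly length / f evaluated at the quartile fractions. Marker counts in
a real SAG come from a gene-vs-catalog hit table: hits above the e-value
cutoff (default 1e-10, deliberately conservative and configurable) are
dropped, each SAG gene keeps its single best cluster, and distinct
clusters are counted once.

## Paralog profiling, dereplication, majority rules

Sequence identity is global-alignment identity: identical columns /
alignment length, under match +1, mismatch −1, gap open −5, gap extend −1
(configurable). Gaps therefore dilute identity; the metric is symmetric.

The paralog profile of a proteome computes each gene's best intragenome
identity once (all-vs-all, excluding self) and reports, per threshold,
the fraction of genes at or above it — non-increasing in the threshold by
construction and asserted on every run. A single-gene proteome warns and
reports zero.

Dereplication is a greedy centroid pass in a canonical order — length
descending, then id ascending — replacing the unstated input order of the
original clustering tools with a deterministic one. Each sequence joins
the first existing centroid (in founding order) it matches at or above
the threshold, else founds a new cluster; the result is a partition.
Consensus sequences are centroid-anchored: member residues aligned to
each centroid column vote, the strict majority wins, and ties (or columns
with no votes) fall back to the centroid's residue. Insertions relative
to the centroid contribute no columns, so the consensus has the
centroid's length.

Family assignment is majority rules over member votes (each member
contributes the family of its best profile-model hit, highest bitscore
with ties to the smaller model id); the winning family is the one with
the most votes, ties resolve to the lexicographically smallest family id
and are flagged, and a lineage with no labeled member is "unassigned".
By construction the assignment partitions lineages, so the count assigned
to any family plus the count assigned elsewhere equals the lineage total.
Profile search itself is consumed as hit tables, never re-implemented.

## Reciprocal best-hit recruitment

A fragment is recruited to a focal genome only if (1) it hits the focal
scaffolds with e-value ≤ 1e-5 and alignment length ≥ 50 (conventional
fragment-recruitment candidate cutoffs; the procedure's source describes
none, and both are configurable), and (2) its single best hit against the
combined reference — highest bitscore, ties by lower e-value then subject
id, so the tie-break is total and the recruited set deterministic — lands
on a focal scaffold. Requiring the *best* stage-2 hit, rather than any
hit, is what makes the procedure reciprocal. Profiles report per-depth
relative recruitment (100 × recruited/total) and the unweighted mean
percent identity of recruited fragments (a length-weighted variant is
available). Recruitment is not corrected for genome incompleteness; an
incomplete focal assembly proportionally underestimates abundance.

For synthetic end-to-end runs the package carries a small edlib-backed
semi-global aligner that emits standard hit tables (bitscore = 2 × matched
bases; e-value a search-space-scaled score transform adequate for
best-hit ranking). It is a deterministic convenience for testing the
recruitment *rule*; real studies should feed BLAST `-outfmt 6` tables.

## Synthetic data: what it emulates, and what it does not

The pangenome generator's defaults encode the reference conditions the
estimator targets: 25 genomes of 3 Mbp sharing a designated core of 71
single-copy clusters, an accessory pool of 500 clusters retained per
genome with probability 0.3, genes of 900 bp placed without overlap and
separated by multinomial gaps. Accessory presence is drawn per cluster,
and a cluster that would by chance appear in every genome is cleared from
one, so with duplication off the designated core *is* the realized
exhaustive single-copy core — the property the tests lean on. Accessory
pool size, retention and gene length are not dictated by any reference
and were chosen once as realistic for a bacterial clade of this
diversity; duplication defaults to 0 because the reference collection is,
by definition of its core, un-duplicated in those clusters.

SAG fragmentation cuts one or several non-overlapping windows from the
circular source totalling the requested fraction (several windows crudely
mimic amplification bias; one window matches the rolling-window
calibration, and the acceptance checks use one). Paralog families descend
from independent random ancestors with per-site substitutions at
p = 1 − √t, giving expected pairwise identity (1−p)² + p²/19 ≈ t with no
indels, so identity is analytically predictable. Read sets draw uniform
positions on circular genomes, mutate at a per-depth rate, and flip
strands at random.

None of this models real MDA coverage bias, chimeras, quality scores,
indel evolution or compositional heterogeneity. Passing tests therefore
demonstrate that the *procedures* are correct and calibrated under their
own assumptions — uniform fragment sampling, substitution-only
divergence — not that the estimates are unbiased on real single-cell
data, where marker clustering and amplification bias widen the intervals.

## Numerical conventions and limitations

* Coordinates are 0-based half-open everywhere inside the package;
  1-based GFF-style conversion happens only at the I/O boundary.
* GC content excludes ambiguous bases from numerator and denominator;
  the contig-length filter keeps contigs strictly larger than the cutoff
  (default 2,000 bp).
* Every stochastic routine takes an explicit seed; pipeline runs record
  seeds, parameters and output checksums in a manifest, and identical
  configs produce byte-identical outputs.
* Acceptance-scale problem sizes — 25 genomes × 3 Mbp for the core
  analysis, one 3 Mbp layout × 100 fractions × 1,000 starts and 500 SAGs
  per true fraction for estimator calibration, ~30-sequence family sets,
  ~300-read recruitment sets — were chosen so the full suite recomputes
  everything from scratch in minutes on one CPU.
* Known limitations: the recovery distribution is only as good as the
  reference layouts (a SAG from a clade with atypical marker spacing will
  be mis-calibrated); quartile propagation understates size uncertainty
  when the conditional distribution is strongly skewed (visible at the
  extremes of the marker-count range, where outliers concentrate); and
  greedy centroid clustering is order-dependent by design — the canonical
  order makes it reproducible, not optimal.
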
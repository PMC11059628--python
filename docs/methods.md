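# Methods

This note documents the models, conventions and numerical choices behind
`epiphase`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Cytosine contexts and the captured strand

Targeted single-stranded capture sequences exactly one strand per locus (the
coding strand of each gene), so the analysis operates on a single
captured-strand sequence per target and ignores opposite-strand cytosines
entirely. A cytosine's context is a function of the two downstream bases on
that strand: CG if the +1 base is G; otherwise CHG if the +2 base is G, CHH
if it is A/C/T (H ∈ {A, C, T}).

**3′-edge rule.** CG is resolvable with one downstream base; CHG/CHH require
two. A cytosine whose context window runs off the target's 3′ end, or
contains an N, is excluded from the site list (with a logged warning). This
is a package convention for a case real pipelines rarely document; it removes
at most the last two positions of a target.

Coordinates are 0-based half-open internally (BED convention); emitted
catalogs carry 1-based positions alongside for human-readable reports.

## Read assignment, alignment and calling

Enzymatic conversion reads unmethylated C as T, so read/reference identity
must be judged in a collapsed alphabet where C ≡ T. Assignment matches each
read's first and last 30 nt against each target's collapsed terminal anchors;
a read is assignable when either anchor has ≤ 5 mismatches and goes to the
target with the fewest total anchor mismatches. The anchor length and
mismatch budget are conventions (30 nt with ≤ 5 mismatches tolerates HiFi
error and SNVs while making random matches vanishingly unlikely); they are
parameters of `assign_and_align`.

Assigned reads are globally aligned with a scoring matrix in which read T on
reference C scores as a full match, N is neutral, and gaps cost −4/−1 (end
gaps free, tolerating truncated molecules). A fast path uses the identity
alignment when the read has the target's length and ≤ 10% collapsed-alphabet
mismatches — the overwhelmingly common case for full-length amplicon reads.

Per-site calls are ternary: C → 1, T → 0, anything else (A/G/N/gap) →
missing. A read is **full-length** iff no call is missing; only full-length
reads enter per-molecule statistics. Two molecule-level filters apply:

* reads with **more than three consecutively methylated CHH sites** (a run of
  ≥ 4 over the CHH subsequence in site order) are removed — plant CHH
  methylation is sparse, and long CHH runs mark molecules that escaped
  conversion. Missing calls break runs, so no read is dropped on unobserved
  evidence. Consecutiveness is adjacency in the context subsequence, not
  genomic distance;
* reads with missing calls at > 20% of sites are discarded as low-quality
  alignments (configurable).

The **conversion rate** is #(calls = 0) / #(calls ∈ {0,1}) pooled over all
reads, replicates and all three contexts of the flagged internal-control
target (a locus with near-zero true methylation). Truly methylated control
cytosines, if any, bias the estimate down slightly; the package does not
attempt to exclude them.

## Statistics

Two layers, deliberately distinct:

* **Molecule level (mPPM/DmPPM).** mPPM is the fraction of a context's sites
  methylated in one full-length read. Between-condition comparisons pool
  molecules across the 4 biological replicates and use the Kruskal–Wallis
  rank test with tie correction (for two groups this is the rank-sum test up
  to the χ² approximation). Pairwise p-values are reported raw with an
  optional Benjamini–Hochberg column; default α = 0.05. Rationale: epiallele
  shifts move subpopulations of molecules, which distribution-level rank
  tests detect and per-site means can miss.
* **Site/region level.** Per-site mean methylation uses only non-missing
  calls at that site, pooling replicates for display profiles. For testing,
  each replicate contributes one regional mean (mean of its per-site levels
  over an optional subregion window), and condition groups of replicate means
  enter one-way ANOVA with post-hoc Tukey HSD computed from the studentized
  range (Tukey–Kramer SE for unequal group sizes). Footprint-prevalence
  comparisons across conditions use the same replicate-level ANOVA/Tukey
  layer on per-replicate fractions.

Degenerate inputs: identical pooled observations give H = 0, p = 1 (and
F = 0, p = 1) rather than NaN; groups with < 2 values yield NA with a
warning; correlations over < 3 shared sites or against a constant profile are
NA.

The GC-vs-yield QC fits `reads = a + b·ln(GC)` by least squares ("logarithmic
regression", the standard reading: predictor log-transformed) and reports R²,
the slope-test p and coefficients. Targets with non-positive GC are excluded.
Replicate and external-table concordance use Pearson correlation of paired
per-site levels with all three contexts pooled (Spearman available by flag);
the correlation method is a convention, selectable per call.

## Footprints and runs

A footprint spec is declarative: either an explicit set of context-subsequence
indices required in a given state (e.g. first two CG sites unmethylated), or
one or more index windows each required to contain a run of ≥ `min_run`
consecutive sites in the state (multiple windows are a conjunction, as in
"two or more consecutively methylated CG sites in *both* areas flanking the
element"). Footprint windows live in spec files because real cis-element
coordinates are locus-specific knowledge, not derivable from sequence alone.
Prevalence denominators are filtered full-length reads only.

## Heatmaps and clustering

Intervals between adjacent context sites are colored by the flanking call
pair (red = both methylated, black = both unmethylated, gray = transition,
blank = missing endpoint); sites are white vertical lines at true offsets;
the same molecule occupies the same row across the CG/CHG/CHH panels.

Row order comes from average-linkage agglomerative clustering of the CG call
matrix (missing imputed as 0 for the distance only) under Kendall's tau
distance 1 − τ or Euclidean distance. On binary vectors τ-b equals the phi
coefficient, so the distance matrix is computed in closed form. Constant
vectors make τ undefined; the conventions are distance 0 for two identical
constant vectors and 1 otherwise when either vector is constant. Average
linkage is the default because only the distance, not the linkage, is
standard practice in these plots; determinism is guaranteed by processing
rows in read-id order so equal-distance merges resolve identically under any
input permutation. Samples above 1,000 molecules are subsampled uniformly
with a fixed seed for display; statistics always run on the full call set.

## The synthetic generator

`scenario.simulate_scenario` emulates the statistical structure of a real
targeted experiment: ~108 targets of 509–704 nt with GC 19–52% (default demo
scenarios use fewer targets for speed and say so), one 558-nt unmethylated
internal control, four conditions × four replicates, ~90% on-target reads
(decoys are shuffled target sequences), conversion efficiency 0.995 and
methylation retention 0.995 (both comfortably above the ≥ 99% QC bar),
and Poisson per-target yields with a log-linear GC trend.

Within a condition, molecules are a two-class epiallele mixture. Each class
has per-context stationary methylation probability p and persistence ρ; site
states follow a two-state Markov chain along site order with

    P(1→1) = p_z + ρ(1 − p_z),   P(0→1) = p_z(1 − ρ),
    p_z = logistic(logit(p) + z),  z ~ Normal(0, propensity_sd) per molecule,

which keeps the stationary probability exactly p_z while ρ tunes consecutive
runs, and the shared z couples CG/CHG/CHH within a molecule. Footprint-class
molecules additionally have their first two CG sites forced unmethylated.
Background methylation defaults to CG/CHG/CHH = 0.70/0.35/0.10 with ρ = 0.3
and propensity sd = 1.0 — chosen once to give the canonical CG > CHG > CHH
ordering within molecules at realistic plant promoter levels. The four
conditions' footprint-class weights default to 8.4%, 18.0%, 39.4% and 44.0%,
the prevalence range such a footprint spans across ground/flight and
wild-type/mutant root samples.

What the generator does **not** emulate: sequencing indels or substitution
error outside cytosine sites (HiFi consensus error is negligible at this
scale), PCR duplicates, chimeric reads, per-site methylation heterogeneity
within a class beyond the latent propensity, and linkage between methylation
and sequence variants. A green test on synthetic data therefore establishes
the correctness of the computation, the calibration of the statistics and
the recoverability of mixture structure — not robustness to alignment
artifacts or real biological heterogeneity.

One property of the coupling model worth noting: conditional on z the
context mPPMs are independent, so increasing `propensity_sd` raises their
correlation across molecules but *adds* variance to mPPM differences; the
strict within-molecule ordering fractions P(mPPM_CG > mPPM_CHG) are
therefore non-increasing in the coupling strength, not increasing.

## Known limitations

* Assignment assumes reads are oriented like the captured strand (amplicon
  protocols guarantee this); reverse-complemented input reads are off-target.
* The Kruskal–Wallis χ² p-value is approximate for very small groups (n ≤ 10);
  the H statistic itself is exact.
* Tukey HSD assumes replicate-level means are approximately normal with a
  common variance — standard, but fragile with 2 replicates per condition.
* Conversion-rate estimation includes every control cytosine; residual true
  methylation in the control deflates the estimate.
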
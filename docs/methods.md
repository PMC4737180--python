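# Methods

## Data model and conventions

All genomic coordinates are 0-based, half-open (BED convention). A
methylation track is a per-chromosome array of levels in [0, 1] binned
at a fixed resolution (default 20 bp), anchored at coordinate 0; bins
without CpG coverage carry an explicit NaN sentinel — zero methylation
is a valid measurement and is never conflated with missing. bedGraph
intervals are averaged into bins weighted by their overlap, with the
denominator restricted to the covered portion of a bin; overlap weights
are expressed as fractions of a bin so that a file covering every bin
exactly once reads back bit-identically.

An AS event contributes one profile: the ±`flank_bp` (default 200 bp)
neighborhoods of its two borders, binned, concatenated I/E block first
in transcript orientation (minus-strand values reversed). Where the
expansion would cross the neighboring exon/intron border (intron side)
or the opposite body border (exon side), it stops early, flooring to
whole bins relative to the border, so block lengths vary between 2 and
`2·flank_bp/bin_size` bins per side; a side with zero bins makes the
event unusable. Missing-bin runs of at most `max_gap` (default 2) bins
are linearly interpolated from the flanking values; longer runs drop
the event with a logged reason rather than inventing shape.

Quantile normalization across samples acts on all non-missing bins
genome-wide: each sample's sorted values are replaced by the
across-sample mean quantile function (interpolated when coverage counts
differ); ties share the mean of their spanned reference values, which
preserves within-sample rank order.

## Warping distance

The similarity between two profiles S₁ = (x₀,…,x_{n−1}) and
S₂ = (y₀,…,y_{m−1}) is dynamic time warping over monotone, continuous,
bounded paths with node weights (x_i − y_j)², computed by the standard
O(nm) dynamic program. Numerical conventions:

* **Backtrace ties** are broken diagonal > vertical > horizontal,
  preferring shorter paths and making the reported path deterministic.
* **Normalization** divides the cost by the number of *nodes* of the
  backtraced optimal path; this normalized cost is the distance used
  everywhere downstream (BMU search, rankings, meta-clustering).
* **Banding**: because truncation makes profile lengths unequal, the
  corridor is slope-adjusted — |i·(m−1)/(n−1) − j| ≤ r — so the two
  endpoints always lie on the band's center line; a pure |i−j| ≤ r band
  can exclude the end point entirely. An infeasible radius raises an
  error naming the minimal feasible radius (computed from the candidate
  node-to-center distances). The default radius is 5 bins (100 bp),
  chosen as half a flank: wide enough to absorb the length variation
  truncation introduces, narrow enough to forbid degenerate alignments
  of opposite borders. Radius `None` disables banding.
* The inner DP and backtrace are numba-compiled; the first call in a
  session pays the JIT cost.

DTW with squared weights violates the triangle inequality (a test
documents a counterexample), which is why clustering is built on a SOM
rather than on centroid methods that assume a metric.

## Flexible SOM

Neurons are variable-length prototypes W with per-element accumulators
A. For each input S (visited in a seeded shuffled order per epoch) the
best matching unit is the neuron with minimal normalized DTW distance
(ties: row-major). Every neuron within grid Chebyshev distance
r ≤ ⌈σ(t)⌉ of the BMU is adjusted with force
α(t)·exp(−r²/(2σ(t)²)), where α and σ decay exponentially:
α: 0.5 → 0.01, σ: max(rows, cols)/2 → 0.5 over the training epochs
(default 30). These schedule forms are the standard SOM choices; all
are configurable. The DTW path is recomputed per adjusted neuron.

One adjustment at force α proceeds in this order:

1. compute the optimal (banded) path P between S and W;
2. per path step: *Shrinking* (i advances, j holds — W locally
   under-long) adds +α to A_j; *Expansion* (j advances, i holds — W
   locally over-long) adds −α to A_{j+1};
3. any |A_j| ≥ θ (default θ = 1) triggers a single length change at j,
   processed right-to-left: a positive trigger inserts one element
   after j valued as the mean of its new neighbors, and the surplus
   path matches of j are handed to the inserted element; a negative
   trigger merges j with its successor as their average (suppressed if
   W would drop below 2 elements). Indices above j shift by one with
   their accumulators; the triggering accumulator resets to 0;
4. each element then moves toward the mean of its matched input values,
   y′ = y + α(mean(x) − y); multiply-matched elements are averaged
   before the single update so the result is match-order independent.

Doing the length update before the value update, with match hand-off,
makes α = 1 a fixed point (the prototype becomes the input exactly when
their optimal path warrants the length change) and keeps the two
updates consistent; with θ = ∞ and inputs whose optimal paths are
diagonal the procedure reduces *exactly* to the classical SOM update
(verified bit-for-bit against an independent replica in the tests).
The accumulator sign convention pulls the prototype's local length
toward the input's; the per-step increment is the current force α,
making length changes as impact-weighted as value changes.

Grid prototypes are initialized as copies of distinct uniformly sampled
input profiles (seeded); the whole training is deterministic given
(seed, inputs, hyperparameters).

Cluster agreement is scored by normalized mutual information with the
arithmetic-mean normalization 2·I(A;B)/(H(A)+H(B)), computed via
I = H(A)+H(B)−H(A,B) so that identical labelings score exactly 1.0;
two single-cluster partitions agree perfectly and are defined as 1.0.

## Choosing the number of clusters

Full consensus clustering would re-train the FSOM for every candidate k
and every subsample. The light-weight scan instead trains one FSOM with
M prototypes (mediods; near-square grid, M defaults to 2K raised until
C(M,k) ≥ m for all scanned k), stores each item's ranking of all
mediods by normalized DTW (ties by mediod index), and for each
k ∈ [k_min, K] draws m distinct k-subsets of mediods (seeded rejection
sampling), re-assigning every item to its best-ranked mediod in the
subset — zero further DTW evaluations, which the tests assert by call
counting. Consensus entry (a,b) is the fraction of draws co-assigning
a and b; the area under the empirical CDF of the strictly-upper-triangle
entries (equivalently 1 − mean consensus) summarizes each k, and k\* is
the largest k whose relative area increase Δ(k) = (A(k)−A(k−1))/A(k−1)
reaches `delta_min` (default 0.025), the proportional-increase rule of
the consensus-clustering framework. k_min defaults to 4 (a SOM grid has
at least 4 units) and is configurable.

**Resolution limit.** This scan measures how crisp subset-reassignment
is, and two structural effects keep its area curve rising past the true
family count g when M ≫ g: a random k-subset misses an entire family
with non-trivial probability even at k = g (≈25 % per family at k = 4,
M = 12), and the M-neuron map necessarily holds several near-duplicate
prototypes per family across which items split in stable
sub-partitions. Measured on planted mixtures, within-family consensus
decays smoothly (≈0.92 → 0.68 over k = 3…8) while cross-family
consensus vanishes, so the curve plateaus near k ≈ M minus the
duplicate count rather than at g, and the Δ-threshold rule
systematically overshoots g by 2–3 (the corresponding recovery test is
expected to fail and is kept as an honest record). The scan is
therefore best read as an upper bound on the resolvable structure;
corroborate the choice with the NMI grid-stability check and the
meta-grouping. The thresholds were not adjusted to mask this behavior.

## Association statistics

Each property (Ψ, FPKM, TSS distance, and any extra numeric event
columns) is tested per cluster against the background with a two-sided
Mann–Whitney U test; the background is the *entire* event set of the
sample, cluster included, which makes the tests conservative for large
clusters (measured type-I ≈ 0.03 at a ~10 % cluster fraction; a test
asserts the one-sided bound). The exact null distribution is used when
the product of group sizes is ≤ 400 and the pooled values are tie-free,
the tie-corrected normal approximation otherwise; direction is the sign
of the median difference and is only reported for significant rows.

Border-resolved properties are tested per 20 bp bin, aligned by signed
offset from the border (not by warping — truncation makes absolute
positions incomparable); only offsets carried by ≥ `min_n` (default 5)
events per side enter, and a cluster is flagged only when strictly more
than 80 % of its tested bins are significant in the same direction
after FDR.

Motif hits are exact IUPAC-consensus matches on either strand of the
border sequence; enrichment and depletion are the upper and lower
hypergeometric tails of the cluster hit count given the background
counts. All p-value families are Benjamini–Hochberg adjusted at
FDR 0.05, with the smallest defensible family: per property across
clusters, and per motif × border side across clusters (enrichment and
depletion tails adjusted separately; the flags are mutually exclusive).

## Cross-sample meta-grouping

Per sample, every cluster with ≥ `min_members` (default 5) events
yields a median profile: the per-bin median over members on the signed
border-offset grid of the untruncated members, truncated members
contributing to the bins they possess. All samples' medians are merged
by complete-linkage hierarchical clustering under unbanded normalized
DTW (few, short sequences; a band buys nothing), and the dendrogram is
cut to exactly `n_groups` (default 4) groups, labeled I, II, … by
increasing mean methylation of their medians. Membership sharing
between (group, sample) pairs is the fraction of the two samples'
commonly covered events falling in the respective groups; edges below
5 % are omitted, and the ratio map gives each sample's group fractions
(rows sum to 1). The dendrogram exports as Newick with
`sample:row:col` leaves.

## Synthetic data

The generator exists to make every stage testable without downloads; it
is first-class, seeded, and pure in (specification, seed). A shape
family is a prototype function on [0, 1] (library: flat-low 0.2,
flat-high 0.8, step-up/step-down across the event, Gaussian dips at the
borders, a linear ramp), sampled at the profile's jittered length, plus
clipped Gaussian noise (default sd 0.1) — the untruncated grid is
sampled and intron-side bins dropped, as real truncation removes bins
rather than rescaling shape. File-backed datasets place events on a
regular stride (default: 200 events in 2 Mb) with alternating strands,
realize each profile in the written bedGraph so reading the files back
reproduces the profiles bit-exactly, couple Ψ linearly to mean border
methylation with additive noise (to give the association tests signal,
not to model biology), and plant motifs at per-family rates in random
border sequences.

What the generator does **not** emulate: CpG spacing and coverage
heterogeneity, read-level bisulfite noise, correlated neighboring
events, realistic exon/intron length distributions, or any real
Ψ–methylation mechanism. Passing the recovery tests therefore shows
that the machinery identifies well-separated shape families under
noise, jitter and truncation — not that real tissues contain such
families.

## Problem sizes and defaults

Desk-scale defaults keep every experiment on one CPU in minutes: 4
families × 50 events for typing recovery, 30 events per family for the
k-scan, 3 samples × 200 events for the meta-grouping experiment, 30
training epochs, band radius 5 bins. The full pipeline on the default
synthetic preset (200 events, 2 Mb genome) completes well under five
minutes.

## Known limitations

* The k-scan resolution limit described above.
* Banded DTW feasibility depends on both lengths; heavily truncated
  profiles against full-length prototypes may need radius ≥ the stated
  minimal feasible radius (the error names it).
* Prototype length changes are capped at one element per trigger;
  pathological inputs alternating extreme lengths adapt slowly.
* The subset background makes all cluster-vs-background tests
  conservative, increasingly so for clusters that dominate the sample.
* Motif matching is exact IUPAC consensus; no PWM scoring.
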
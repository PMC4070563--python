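# Methods

## Data model

The primary input is a ternary expression matrix: genes × conditions with
entries in {−1, 0, +1}, encoding per-condition differential-expression calls
(down / no change / up). The gene universe is the union of every gene listed
in any condition; genes absent from a condition's lists are 0 there. A gene
listed both up and down under one condition is a hard error; duplicates
within one list count once. The encoding is agnostic to what a "condition"
is (single array contrast, treatment, time point) — the granularity is
whatever the call tables provide, and it is recorded in the matrix metadata.

Promoters are modelled as 1,000-bp upstream sequences over {A,C,G,T,N},
keyed by gene ID. k-mer windows containing N are never counted.

## Linear network inference

Pearson correlation is computed over conditions for every gene pair
(population standard deviations; at least 3 conditions required). Genes with
zero variance have undefined correlation: they are marked NaN, excluded from
k-lists, and never form edges.

Two constructions are provided:

* **Fixed threshold** — edge iff r ≥ t, *signed* by default (a strongly
  anti-correlated pair is not an edge); an `absolute` option exists. All
  genes remain nodes, so the node count equals the gene universe.
* **Mutual k-nearest neighbour (mKNN)** — each gene's k-list is its k−1
  highest-correlation partners plus every gene tied (within 1e−12) at the
  k-th largest value; genes of equal correlation are equally valid
  neighbours, so ties are never broken arbitrarily. An edge requires mutual
  k-list membership. Isolated genes are dropped from the result, so mKNN
  node counts may be below the universe size. Edge counts are non-decreasing
  in k (k-lists are nested), which the tests assert on random fixtures.

## Mutual information and pruning

MI is estimated with the Kraskov k-nearest-neighbour estimator, algorithm 1
(k = 3 by default): Chebyshev distance to the k-th joint neighbour defines a
box per sample; marginal counts inside the open box enter
I = ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩. Ternary profiles are massively
tied, so i.i.d. Gaussian jitter of scale 1e−12 (configurable, seeded) is
added first. Estimates for a strongly co-expressed pair vary by well under
10 % (CV) across jitter seeds at ~270 conditions; the CV is a *relative*
measure, so it is unbounded for independent pairs whose estimates fluctuate
around zero — stability claims are therefore made for dependent pairs only.
Small negative estimates are kept raw, and the max-fraction threshold uses
the raw maximum: reproducibility over cosmetics.

Post-processing of the MI matrix:

* **ARACNE** — for every unordered triple, edge (i,j) is marked when
  MI_ij < min(MI_ik, MI_jk) − ε (additive) or < τ·min(MI_ik, MI_jk)
  (multiplicative). All decisions are computed on the input matrix and
  applied at once, so scan order is irrelevant. Defaults ε = 0, τ = 1
  (strict DPI); the two variants coincide on tie-free matrices.
* **CLR** — per-gene background (μ_i, σ_i) over the off-diagonal MI row;
  z_i(j) = max(0, (MI_ij − μ_i)/σ_i); score = sqrt(z_i(j)² + z_j(i)²).
  A zero-variance row contributes 0 (logged, not an error).
* **MRNET** — per-target forward selection with score
  s_j = MI(X_j, Y) − mean_{k∈S} MI(X_j, X_k), selecting while the best score
  is positive; a pair's weight is the larger of its two directional scores.

Networks are formed by thresholding at a fraction (0.8 or 0.9) of the
maximum off-diagonal weight of whichever matrix is being thresholded (the
post-processed scores, not the raw MI, for CLR/MRNET). Genes with no edge at
the threshold are dropped — deliberately different from the PCC-threshold
convention, matching the observation that MI-derived networks lose nodes
while threshold networks keep the full universe.

## Topology

Standard metrics are delegated to networkx (Brandes betweenness, BFS paths,
clustering); package-specific conventions:

* closeness is component-restricted: (reachable count)/(sum of distances);
* raw betweenness counts unordered pairs; normalisation divides by
  (n−1)(n−2)/2; top-n betweenness lists include every node tied at the
  cut-off value;
* the topological coefficient of n averages J(n,m)/deg(n) over partners m
  sharing at least one neighbour, with J = |shared neighbours| +1 if n,m are
  adjacent;
* density is reported in both conventions, 2E/(n(n−1)) and E/(n(n−1)):
  dense-subnetwork statistics printed by some visualisation tools treat the
  edge count as ordered pairs, and a 178-node module with a printed
  ordered-pair count of 15,720 has density 0.499 in either reading;
* power-law fits are ordinary least squares on log10(frequency) vs
  log10(degree) over non-zero frequencies (what log-scale frequency plots
  imply), not maximum-likelihood tail estimation. Integer rounding of small
  expected counts flattens the tail and biases the slope, so exponent-
  recovery tests use exact frequencies;
* hubs use an inclusive degree ≥ 50 cut-off.

Every metric is checked against from-first-principles brute force on the
complete graph atlas (all 1,253 graphs on ≤ 7 nodes) plus random 8-node
graphs. Exhaustive enumeration of all 8-node graphs (~10^10) is not
feasible; the atlas suite is the intended "all small graphs" check.

## Module detection

**Edge clustering coefficient.** ECC(u,v) = (z+1)/min(deg u −1, deg v −1)
with z the number of triangles through the edge; the +1 keeps triangle-free
regions comparable; ECC = 0 when an endpoint has degree 1.

**FAG-EC.** Singleton clusters; edges processed in non-increasing ECC order
(lexicographic tie-break on sorted endpoints, making the algorithm fully
deterministic). A cluster *locks* when its internal degree (2× within-
cluster edges, counted exactly, not merely over already-processed edges)
exceeds λ × its external degree. A merge is skipped only when *both*
endpoint clusters are locked: a locked (complete) cluster can still absorb
an unlocked straggler, which is what lets a near-complete clique pull in its
last member. λ defaults to 1.0; modules with ≥ 6 members are reported.

**MCL.** Column-stochastic transition matrix with unit self-loops;
expansion (squaring) alternates with inflation (entrywise power, default
2.0, then renormalisation) and pruning at 1e−6 until the matrix is stable.
Clusters are the connected components of the converged matrix's nonzero
structure; overlaps resolve to the larger cluster; non-convergence returns
the current partition with a warning.

Both algorithms recover planted-partition graphs (5 blocks of 20, p_in 0.8,
p_out 0.02) exactly — Rand index 1.0 across seeds.

**Module sizes.** Histogram plus a least-squares fit of
log f(s) = log c − α·log s − s/β. On *sampled* histograms the noisy
count-1 tail makes log s and s nearly collinear and the unweighted fit
overestimates α by ~0.5 at a few thousand modules; parameter recovery is
therefore validated on expected-frequency histograms, and fits on real
(sampled) size distributions should be read as descriptive, not as unbiased
parameter estimates.

## Cis-element discovery

**Aligner.** An internal seed-and-extend ungapped aligner (exact word seeds,
default word size 7; +1/−2 scoring; X-drop 10) replaces an external
alignment dependency, so the pipeline is self-contained and its statistics
testable. Overlapping hits to the same subject keep the higher score;
self-hits are excluded. E-values are Karlin–Altschul, E = K·m·n·e^(−λS)
with m × n = query length × database length, K = 0.46, and λ the positive
root of (1/4)e^λ + (3/4)e^(−2λ) = 1. That root has the closed form
λ = ln((3+√21)/2) ≈ 1.3328 (substituting u = e^λ gives u³ − 4u² + 3 = 0),
which the numeric solver reproduces to 1e−9.

**Candidates.** From every hit with identity ≥ 0.75 and E ≤ 1e−4, all
6-mers in the query-side aligned span are collected (windows containing N
skipped); 6-mers with a homopolymer run ≥ 5 are discarded (a run of exactly
4 is kept). Provenance counts supporting hits per 6-mer.

A second, alignment-free candidate mode ("direct") enumerates 6-mers present
in at least 80 % of the cluster promoters. It exists because candidate
generation via alignment requires ≥ ~13 nt of shared sequence (the E-value
cut-off at 1-kb promoter scale), which synthetic uniform-random promoter
sets — where a planted element is the *only* shared signal — never contain.
The 80 % support level is deliberately strict: scanning all 4,096 hexamers
and keeping merely "common" ones (e.g. ≥ 50 % support) selects exactly the
upward-fluctuating k-mers and inflates their fold ratios (a selection bias
that produced ~30 % spurious tier-3 calls in null calibration); requiring
near-ubiquity makes chance passage negligible (P[Bin(30, 0.21) ≥ 24] ≈
1e−15) while an element present at ≥ 1 copy per promoter passes essentially
always.

**Enrichment.** For each candidate, n_boot = 1,000 bootstrap replicates of
size m = |cluster| are drawn with replacement from the cluster and from the
background; the statistic is mean occurrences per promoter (overlapping
matches, forward strand by default; a both-strands mode adds the reverse
complement, counting palindromes once). Cluster and background means are
the replicate-distribution means; fold ratio is their quotient (flagged
undefined when the background mean is 0); the p-value is a two-sided
two-sample t-test between the replicate distributions — the bootstrap-t of
the original design, reported as such and anti-conservative, since
replicates are resamples rather than independent observations. Tier flags
(fold ≥ 2, 3, 4) are nested.

**Precision.** A found 6-mer is a true positive if it is a substring of a
known element or vice versa, on either strand (configurable to
forward-only). Precision = nTP/(nTP+nFP), undefined for an empty found set.

## Synthetic study conditions

The generators define the conditions every test runs under:

* **Expression** — modules of genes share a random non-constant ternary
  template over conditions; each cell is corrupted to a uniformly random
  *other* ternary value with probability flip_prob (must be < 0.5; defaults
  0.1). Background genes are i.i.d. with frequencies (0.1, 0.8, 0.1) for
  (−1, 0, +1) — differential calls are sparse in real tables. Benchmarks
  use 200 genes, 4 modules of 25, 100 conditions.
* **Null matrices** — per-column permutation by default (preserves each
  condition's up/down/no-change counts, the stricter null); global
  permutation and i.i.d. resampling modes are provided because the choice
  of permutation unit is a genuine modelling freedom.
* **Promoters** — i.i.d. uniform ACGT of length 1,000; every promoter gets
  Poisson(background_rate) planted motif copies, cluster promoters get an
  additional Poisson(cluster_rate), at uniform non-overlapping positions
  (recorded in metadata for evaluation). Power/null studies use 30 cluster
  and 120 background promoters, background_rate 1, cluster_rate 4 (the
  4× contrast) or 0 (null); a uniform background contributes ≈ 0.24 chance
  occurrences of any hexamer per kb on top.

What these generators deliberately do *not* emulate: probe-level microarray
noise, gene-length/GC covariates, promoter base composition and repeat
structure, and long homology blocks between promoters. Passing tests
therefore demonstrate correctness of the algorithms and calibration under
idealised conditions, not performance on real genomes — in particular the
"direct" candidate mode exists for these idealised sets, while real promoter
compendia should use the alignment mode.

## Numerical choices and degenerate inputs

* Tie equality in k-lists at 1e−12; similarity matrices validated symmetric
  to 1e−12; PCC clipped to [−1, 1] and symmetrised against BLAS round-off.
* Thresholds validated before any computation (fractions in (0,1], λ > 0,
  inflation > 1, flip_prob < 0.5).
* Degenerate cases: zero-variance genes → NaN correlation, no edges;
  all-equal MI rows → CLR zeros; all-zero similarity → thresholding is an
  error ("no edges at any threshold"); empty network → component summary is
  an error; ECC with a degree-1 endpoint → 0; fewer than 3 distinct module
  sizes → histogram without fit.
* All randomness flows through numpy Generators seeded per call; seeds are
  mandatory in library code and defaulted-and-logged in the CLI. Pipeline
  reruns with identical config and seed are byte-identical.

## Benchmark problem sizes

Test-suite and acceptance-script problem sizes (graph atlas ≤ 7 nodes,
200-gene matrices, 100-node planted partitions, 50 screening runs at
n_boot = 1,000, N = 2,000 for the Gaussian MI calibration) were chosen so
the relevant estimators are well inside their asymptotic regimes while the
whole suite completes in seconds; the statistical conclusions do not change
at larger sizes.

## Known limitations

* The Kraskov estimator on heavily tied ternary data depends on the jitter
  realisation; the seed is part of the configuration and reported.
* The bootstrap-t p-value inherits the anti-conservatism of the original
  promoter-bootstrap design; tier thresholds on the fold ratio, not the
  p-value, are the intended decision rule.
* MRNET forward selection is O(genes³) per matrix and the all-pairs Kraskov
  step is O(genes²·N log N); genome-scale matrices (~8k genes) are feasible
  but hours-scale on one CPU.
* The module-size fit is descriptive (see above). Maximum-likelihood
  power-law fitting is out of scope.
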
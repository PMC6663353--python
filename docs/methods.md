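# Methods

## The Network Dependency Index

`ndikit` analyses weighted, undirected structural connectomes: symmetric
non-negative matrices `W = {w_ij}` whose entries count (normalized)
white-matter streamlines between parcellated brain regions.  Each subject's
matrix is divided by its maximum entry, so `w_ij ∈ [0, 1]`.

The central quantity is the Network Dependency Index (NDI), a per-node
importance score derived from information loss under node removal:

1. **Topological distance.** Each edge contributes length `1/w_ij`; `D` is
   the all-pairs shortest-path matrix (Dijkstra).  Disconnected pairs are
   infinite.
2. **Information measure.** `I_ij = (1/D_ij) / I_max`, with `I_ij = 0` for
   disconnected pairs and a zero diagonal.  `I_max` is the maximum edge
   weight across the whole cohort (1 for max-normalized matrices), so the
   maximal per-pair loss is comparable across subjects.  Because shortest
   distances satisfy `D_ij ≥ 1/max(w)`, `I_ij ≤ 1` always holds; the
   implementation asserts this rather than clipping.
3. **Removal loss.** Removing node `m` leaves subnetwork `G^-m` with
   information matrix `I^-m`.  Each surviving ordered pair is charged
   `I_ij − I^-m_ij ≥ 0`; a pair newly disconnected by the removal is
   charged exactly 1 (even where that exceeds its pre-removal information —
   a deliberate cap that prices a severed connection maximally).  Pairs
   already disconnected before the removal carry no loss.
4. **Aggregation.** Each survivor `i` accumulates the *mean* loss over its
   partners, and NDI(m) is the mean of those node losses — equivalently the
   mean loss over all surviving ordered pairs.  This bounds NDI in [0, 1]:
   an isolated node scores 0, a node whose removal severs every surviving
   pair scores 1 (e.g. the hub of a star, the center of a path).  A raw-sum
   variant (`aggregate="sum"`), which grows with network size and cannot
   stay within [0, 1] for more than a few nodes, is retained for
   sensitivity analysis only.

Losses with magnitude below 1e-12 are treated as exactly zero before
aggregation, so floating-point round-off cannot produce spurious negative
losses; a negative loss beyond round-off magnitude raises, since removal
can only lengthen distances.

## Tier stratification

Across group connectomes, positive NDI spans several orders of magnitude
and its natural log is well described by a Gaussian mixture.  `tiers` fits
1-D mixtures with free component variances (10 random restarts, best
likelihood kept) to `ln(NDI > 0)` and selects the component count `g` by
BIC, reporting AIC alongside; BIC is the tiebreaker when the two disagree,
because its stronger parsimony penalty suits small 1-D samples.  Cut
points are the halfway points between consecutive sorted component means;
`g` intervals become Tiers 1..g of decreasing importance (Tier 1 above the
top cut) and nodes with NDI = 0, whose log-score is undefined, form the
dedicated Tier g+1.  A score exactly on a cut joins the higher-importance
tier — an arbitrary but fixed rule.

Subject-level labelling fits each subject's own mixture (at the
cohort-selected `g`) and uses its own boundaries; when a subject fit
degenerates (variance collapse or too few positive scores), the
cohort-level boundaries are substituted and the substitution counted and
logged.  The per-node consensus across subjects is the median tier, with
ties rounded toward the more important (lower-numbered) tier, and spread
reported as the population standard deviation of the integer labels.

## Weighted rich club

The rich-club comparison uses the Opsahl weighted coefficient: at degree
`k`, `Φ(k)` is the total weight among nodes of degree `> k` divided by the
summed weight of the equally many strongest edges anywhere in the network.
Normalization divides by the ensemble mean `Φ_rand(k)` over random
networks that preserve the degree sequence exactly (double-edge swaps,
10·|E| attempted swaps) and the edge-weight multiset exactly, while
approximately preserving node strengths: weights are reassigned to the
rewired edges in ten randomized batches, each batch rank-matching residual
strength-product order, so strength rankings survive (achieved Pearson
correlation between original and null strengths is reported; typically
> 0.98) while individual placements vary between realizations.  A
deterministic, perfectly sorted reassignment would reproduce the observed
weight concentration exactly and null out genuine rich clubs, which is why
the randomized batches matter.

Significance at each `k` is a right-sided one-sample t test of the null
sample against the observed coefficient, Bonferroni-corrected over the
number of tested degrees (the maximum degree of the connectome);
`k_max` is the largest significant degree with `Φ_norm > 1`, with no
contiguity requirement.  Rich-club members are nodes of degree ≥ `k_max`
(the coefficient itself uses the strict `> k` subclub — the off-by-one is
intentional and mirrors standard usage); remaining nodes are Feeders
(≥ 1 edge to the rich club) or Seeders (none).  The library default
ensemble size is 1000; the test suite and the acceptance script run 100
and 200 realizations respectively, sizes at which the conservation laws
are exact by construction and the t tests are already stable.

## Consensus connectomes and life-span statistics

Group/cohort connectomes keep edges present (weight > 0) in at least
`ceil(fraction·N)` subjects (default 90%) and weight them by the
arithmetic mean over *all* subjects of the group, zeros included —
"average across the group", not "average where present".  Consensus
operates on the normalized matrices, the only form carried forward.

Subnetwork topology is summarized by three whole-graph weighted measures
in the Brain Connectivity Toolbox conventions: transitivity (geometric-
mean triangle intensity over connected triples), global efficiency (mean
inverse shortest-path distance over pairs; disconnected pairs contribute
0) and assortativity (endpoint-strength correlation over edges).
Subnetwork profiles use the subgraph *induced* by the member set —
intra-subnetwork edges only — because per-subnetwork density is reported,
which presupposes an induced edge set.  Degenerate values (no triples,
zero strength variance) are missing, never silent zeros, and drop that
subject from that regression cell only, with a logged count.

Age trends are ordinary least squares `measure = m·age + b` per
(measure, subnetwork) cell on subject-level data, two-sided slope
p-values, Bonferroni-corrected over the number of planned cells (default
3 measures × the profiled subnetworks; 21 for 4 Tiers + RC/F/S).  The
significance gate defaults to corrected p < 0.001.  Cross-group NDI
consistency is the mean ± sd of pairwise Spearman rank correlations.

## The synthetic cohort generator

Real connectome cohorts cannot ship with the package, so every stage is
exercised on synthetic cohorts with a *planted* four-level core–periphery
hierarchy whose recovery is checkable:

- **Topology.** Node tiers of sizes 20/50/44/56 (170 nodes).  Blocks are
  realized near-regularly at the configured densities: within-tier blocks
  are random regular graphs; cross-tier blocks are near-biregular (every
  outer-tier node picks the same number of inner-tier partners, and
  inner-tier receive counts differ by at most one).  The default densities
  make the core complete and attachment strictly hierarchical (tier 4
  reaches the rest only through tier 3, tier 3 only through tier 2).  The
  regularity is deliberate: it gives each tier a homogeneous degree
  stratum and homogeneous upward redundancy, so the core occupies a clean
  rich-club regime and removal losses cluster by tier.
- **Weights.** Log-normal per block level (the outer of the two endpoint
  tiers), with location dropping ~1.4–1.6 natural-log units per level and
  scale 0.35.  Strong separation keeps core edges the globally strongest,
  and log-NDI separates into approximately Gaussian clusters — the
  distributional assumption the Tier model exploits.
- **Subjects.** Each subject keeps each base edge with probability 0.98,
  multiplies surviving weights by `exp(N(0, 0.1²))` noise, and is
  max-normalized.  196 subjects with ages spread uniformly over 4–85
  years (then shuffled against subject order) populate all four age
  groups.
- **Age trend.** Within-core edge weights are pulled toward the strongest
  core weight in log space by `h = slope·(age − mid-range)` (default slope
  0.008/year), i.e. `w → w^(1−h)·w_max^h`.  A purely multiplicative trend
  on core edges would be annihilated by per-subject max-normalization
  (the maximum is itself a core edge), so the planted trend compresses the
  core weight spread instead, which survives normalization as rising
  within-core efficiency.  The default slope is calibrated so the emergent
  Tier-1 efficiency slope is on the order of 1e-4 per year — the magnitude
  reported for real life-span cohorts — and is detected as positive and
  significant in essentially all replicates at ~200 subjects.

What the generator does *not* emulate: spatial embedding and distance-
dependent connection costs, hemispheric symmetry, tractography biases
(gyral bias, crossing-fiber dropouts), non-linear (U-shaped) life-span
trajectories, and heavy-tailed degree heterogeneity *within* tiers.
Passing recovery tests therefore demonstrates the pipeline's correctness
and sensitivity under the planted model, not performance guarantees on
real dMRI connectomes.

A structural finding worth knowing when reading recovery results: a few
tier-2 relay nodes legitimately outrank the weakest core members in NDI,
because a redundant core member is individually less critical than a relay
that solely serves a peripheral subtree.  Top-NDI ranks are therefore
dominated, not exhausted, by the planted core — the same phenomenon the
rich-club literature reports for high-dependency Feeder regions.

## Problem sizes and numerical choices

- NDI on a 170-node connectome is ~170 single-node removals, each an
  all-pairs Dijkstra on the survivor graph (~1.5 s per subject matrix);
  the brute-force oracle used in tests enumerates simple paths and is
  viable to order ~6.
- Symmetry tolerance on input: reject if `max|W − Wᵀ| > 1e-8·max(W)`,
  then symmetrize by averaging.  Zero weight ⇔ no edge.
- Age groups close on the upper bound (U20 ≤ 20 < U40 ≤ 40 < U60 ≤ 60);
  ages above 80 fold into O60.
- GMM fits use `reg_covar = 1e-10`; component standard deviations below
  1e-6 are treated as variance collapse and raise (or trigger the
  cohort-boundary fallback at subject level).
- All randomness flows through explicit integer seeds; ensembles derive
  per-realization seeds from a master seed, so every result is
  reproducible bit-for-bit.
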
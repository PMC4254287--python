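# Methods

## Data model

The sampling unit is the *cluster*: one independent sighting of one or
more species whose individuals were within 50 m of each other (a field
convention; the package never re-derives membership from coordinates).
Sightings are stored long-format, one row per species occurrence within a
cluster (`cluster_id, ecosystem, season, habitat, species, group_size`),
and summarized as a binary occurrence matrix whose row sums are cluster
sizes (species per cluster) and whose column sums are per-species
sighting counts. *Group size* always means conspecific individuals of one
species within one cluster; *cluster size* means the number of species.
Each cluster carries exactly one habitat label; records spanning habitat
boundaries must be resolved upstream.

The shipped catalog lists the 26 study species with feeding guild and
effective strip width (ESW, metres), the distance-sampling detectability
measure. The three sympatric jackals are pooled as one catalog entry.
The detectability filter keeps species with ESW ≥ 230 m — inclusive, so
Grant's gazelle (ESW exactly 230) is retained and the filter returns the
10 network species. The shipped survey-design table records the four
ecosystem × season strata with their cluster counts (858, 438, 2324,
1783; total 5403) and mean cluster sizes (1.223, 1.243, 1.346, 1.291).

## Randomization null and the Besag–Clifford test

"No association" is modelled as the uniform distribution over all binary
matrices with the observed row and column sums: this conditions on the
observed abundances of every species and on the number and sizes of
clusters, so raw co-occurrence counts are valid statistics even though
detectability varies by species. The sampler is the standard checkerboard
chain: propose a uniformly random (row pair, column pair); if the 2×2
submatrix is `[[1,0],[0,1]]` or `[[0,1],[1,0]]`, flip it, else stay. The
proposal kernel is symmetric, the chain is irreducible on the
fixed-margin class, and its stationary law is uniform (verified against
exhaustive enumeration by chi-square on enumerable classes).

P-values use the serial Monte-Carlo scheme of Besag and Clifford, which
does not require chain convergence: draw `U` uniform on `{0..m}`, run
`U·thin` steps from the observed matrix (by kernel symmetry a backward
run equals a forward run), then run `m·thin` steps forward from that
start state, recording the statistic every `thin` steps, and report
`p_upper = (1 + #{T_i ≥ T_obs})/(m + 1)` (mirror for the lower tail).
Ties count as exceedances in both tails and the add-one form never
returns 0, so p ∈ [1/(m+1), 1]. Defaults: `thin` = number of matrix
cells (one expected sweep between samples); `m` caller-chosen, with
p-value resolution 1/(m+1). Batch experiments in this package use
m = 199 (resolution 0.005, ample for testing at α = 0.05) and the
oracle-agreement check uses m = 10⁴; one-off analyses can afford
m = 10³–10⁴. Empirically the test is calibrated: on 200 null
communities the upper-tail rejection rate at 5% stays within binomial
noise of nominal for all three statistics.

Habitat control restricts swaps to row pairs within the same habitat
stratum, i.e. conditions the null additionally on the per-habitat cluster
composition. With a single habitat the stratified chain is identical to
the plain one.

### Statistics

* `ASSS = Σ_{i<j} w_ij²` where `w_ij` is the number of clusters holding
  both i and j; sensitive to any concentration of co-occurrence on
  specific pairs. Upper tail reported.
* Dyad: `w_ij` for one pair. Upper tail reported.
* Node strength `s_i = Σ_j w_ij`: both tails are meaningful (lower =
  avoidance of mixed groups, upper = heterospecific gregariousness), and
  both are reported; the α split between tails is the caller's choice
  (the convention used in the drivers is 0.025 per tail). No
  multiple-testing correction is applied by default because per-dyad
  p-values are reported raw; a Benjamini–Hochberg column is available as
  an option.

## Group-size permutation tests

For a species observed `k_s` times with sizes `g_1..g_ks`, the sizes are
permuted over the fixed context labels of the occurrences. Contexts are
either single- vs mixed-species clusters or partner-absent vs
partner-present. The statistic is the difference of context medians
(midpoint convention for even lengths), two-sided via its absolute value;
permuting sizes keeps the per-species size multiset (hence total
abundance) fixed. When `C(k_s, n_B) ≤ 20 000` all label assignments are
enumerated and the p-value is exact (`#{|T*| ≥ |T|}/C`); otherwise a
seeded Monte-Carlo scheme with the add-one correction is used. A context
with zero occurrences yields an explicit "untestable" result rather than
a p-value. The partner design is asymmetric: testing species A against
partner B permutes A's sizes, so (A|B) and (B|A) are different tests.

## Weighted network and betweenness

Species are nodes; every pair with `w_ij ≥ 1` gets an edge of weight
`w_ij` (a display threshold of 2 is used only for figure export, never
for analysis). Because any edge is possible in this system, the signal is
in the weights, so betweenness uses weighted shortest paths with edge
length `1/w_ij` — a strong association is a short edge; a node
intermediates a pair only when the two-hop route is shorter than the
direct edge. Scores are unnormalized, equal-length paths split counts
equally, unreachable pairs contribute nothing (networkx implementation,
checked against brute-force path enumeration on small graphs). A binary
fallback (`weighted=False`) treats all edges as unit length. Comparisons
across strata and simulations use descending average ranks of the scores
rather than raw values, since raw betweenness is scale- and
density-sensitive.

## Cluster simulator

The simulator generates cluster sets from three observable ingredients —
relative sighting frequencies, the cluster-size distribution, and
(optionally) the pairwise association strengths:

1. draw N occurrences i.i.d. from the frequency table (N = the observed
   total reproduces observed absolute frequencies on average);
2. repeatedly open a cluster with a target size drawn from the geometric
   law `P(n) = (1−p)^(n−1) p` (`p` estimated as 1/mean observed cluster
   size), truncated at the species count by resampling, and fill it by
   drawing occurrences without replacement, skipping species already in
   the cluster; stop when every occurrence is assigned;
3. (preference mode) perform k random swaps of occurrences between two
   clusters, rejecting any swap that would duplicate a species within a
   cluster or strictly increase the association-difference score (ties
   accepted). The score normalizes each co-occurrence matrix by its own
   total and sums squared differences of these relative strengths, so it
   is scale-invariant; since swaps preserve cluster sizes, the simulated
   total is constant and the score is updated incrementally. Default
   k = 10 000 (values above ~10³ give very similar results).

Near pool exhaustion a drawn size may be unfillable without duplicates;
the cluster then closes at the largest feasible size and leftover
occurrences seed new clusters. This tail policy preserves "every
occurrence assigned" with minimal size distortion; the realized size
distribution passes chi-square GOF against the truncated geometric at
N = 10⁵ under the default frequency profile. Strongly dominated profiles
(one species above ~50% of sightings) leave a detectable singleton
surplus at the very end of the pool and are not used as defaults.

Replicate analysis: each replicate generates clusters (steps 1–2, plus 3
in preference mode), builds the network, and ranks betweenness; reported
are per-species mean rank and the 5%/95% percentiles across replicates
(desk-scale default 200–1000 replicates; the drivers use 300). When the
simulation is parameterized from an observed dataset restricted to the
detectability-filtered species, frequencies are re-normalized over the
retained species and cluster sizes are counted among them.

## Synthetic ground-truth communities

The fixture generator produces communities with *known* structure for
power and calibration studies. Margins come from simulator steps 1–2;
the species-to-cluster assignment is then resampled from the
exponentially tilted family

    P(M) ∝ Π_{i<j} φ_ij^{w_ij(M)}

over the fixed-margin class, using a Metropolis version of the
checkerboard chain (acceptance `min(1, Π φ^Δw)`; 50 sweeps of
equilibration; the Metropolis sampler is verified against exact tilted
probabilities on enumerable classes). At φ = 1 this is exactly the
uniform fixed-margin distribution — the null of the randomization tests —
so planted effects nest the test null cleanly. This matters: the
sequential fill of step 2 is itself measurably non-uniform conditional on
margins (ASSS about +1 SD above the fixed-margin mean on 10-species
communities), so fill-level preference injection would contaminate
calibration studies. Planted structure: preferred dyads (φ > 1), solitary
species (all their pairwise weights divided by an avoidance strength,
default 8), partner-conditional group-size multipliers, and an i.i.d.
habitat mixture over the six habitat classes.

Default study conditions: 26 species (or 10 in reduced experiments) with
Zipf-like frequencies (`∝ 1/rank`, most common species ≈ 26–34% of
sightings, matching surveys dominated by zebra and wildebeest); mean
cluster size 1.28 (mid-range of the four strata, 1.223–1.346); group
sizes 1-shifted negative binomial with dispersion r = 1.5 and default
mean 3 (overdispersed, herd-like). What the generator does *not* emulate:
spatial structure and movement, observer error beyond the ESW filter
concept, seasonal migration dynamics, and any dependence between habitat
and species composition. Passing tests therefore demonstrate correctness
of the inference machinery under the stated generative assumptions, not
ecological validity on any particular field dataset.

## Experiment sizes and numerical choices

The validation experiments (`mixnet.experiments`, used by the test suite
and `scripts/acceptance.py`) run at desk scale, chosen as the package's
own defaults: calibration on 200 null communities of 300 clusters and 10
species at m = 199; power on 100 communities of 2000 clusters with a
planted φ = 8 dyad; oracle agreement on a 5×4 matrix (margins
(2,2,1,1,1)/(3,2,1,1), 68-matrix class) at m = 10⁴; conservation over
10⁵ chain steps and 10⁴ swaps; distribution checks at N = 10⁵
occurrences; recovery of p = 0.8 from 10⁴ clusters; hub separation over
200 replicates of a 1500-cluster community whose mid-abundance hub
(frequency 0.10) prefers all other species at φ = 20 — strong enough
that the hub's edges are at least about twice any direct edge, the
condition for reciprocal-weight betweenness to route pairs through it.

Numerical details: chain kernels are numba-compiled with proposals drawn
vectorized from a numpy Generator; all experiment randomness derives from
one seed through `SeedSequence` spawning, so identical seeds give
identical outputs. Score comparisons in the swap acceptance use a strict
tolerance of 1e-15; apparent score "increases" below 1e-12 when
recomputing from scratch are summation jitter. Degenerate inputs are
defined explicitly: an all-zero co-occurrence matrix has all-zero
relative strengths; constant statistics give p = 1; matrices smaller
than 2×2 cannot be randomized.

## Known limitations

* The Besag–Clifford scheme with thin = one sweep trades statistical
  efficiency for runtime; heavily autocorrelated statistics on very
  sparse matrices may need larger `thin` or `m`.
* Exhaustive enumeration (the oracle) is feasible only for toy margins.
* The geometric size model is assumed, not selected; no alternative count
  models are fitted.
* The group-size tests treat occurrences as exchangeable within a
  species; repeated sightings of the same herd violate this and are not
  modelled.
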
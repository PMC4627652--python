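# Methods

`fcnet` implements a graph-theoretical analysis of resting-state functional
connectomes: it turns per-subject regional BOLD time series into binary
networks across a sparsity sweep, quantifies their topology (efficiency,
modularity, nodal centrality), normalizes against degree-preserving random
networks, and tests group differences with covariate-adjusted permutation
inference. A synthetic cohort generator with known ground truth backs every
stage with testable expectations.

## Network construction

For each subject the pipeline computes the Pearson correlation r_ij between
every pair of regional time series and applies Fisher's variance-stabilizing
transform z_ij = atanh(r_ij). The z matrix is thresholded by **sparsity** S:
exactly K = round(S·N(N−1)/2) edges are kept — those with the largest |z| —
so every subject's network has identical node and edge counts and group
contrasts reflect topology, not overall connectivity strength. Because atanh
is odd and strictly increasing, ranking by |z| equals ranking by |r|; the
choice of scale is a convention. Negative correlations compete by magnitude
and lose their sign at binarization.

Rather than committing to one threshold, each matrix is binarized over the
sweep S = 0.11, 0.12, …, 0.34 (24 levels). The lower bound keeps the mean
degree 2K/N above 2·ln N (for N = 90: 9.8 > 9.0), below which thresholded
networks fragment; the upper bound keeps them in the small-world regime.
Edge selection shares one ranking across levels, so edge sets are nested and
ties at the boundary break deterministically by ascending (i, j) order —
improbable with real-valued correlations, but it guarantees bit
reproducibility.

## Topological metrics

All metrics operate on the efficiency formalism, which handles disconnected
graphs by letting unreachable pairs contribute 1/∞ = 0:

- **Global efficiency** E_glob = (1/(N(N−1))) Σ_{i≠j} 1/L_ij, with L_ij the
  BFS shortest-path length. Parallel information transfer capacity.
- **Nodal efficiency** E_i = (1/(N−1)) Σ_{j≠i} 1/L_ij. The identity
  mean(E_i) = E_glob holds exactly and is asserted in tests.
- **Local efficiency** E_loc = (1/N) Σ_i E_glob(G_i), where G_i is the
  subgraph induced on i's neighbors (i excluded; subgraphs with < 2 nodes
  score 0). Fault tolerance of local circuits.
- **Degree** K_i and **betweenness** B_i = Σ_{j<k, j≠i≠k} δ_jk(i)/δ_jk
  (fraction of j–k shortest paths through i, summed over unordered pairs;
  an ordered-pair convention would double every value uniformly and leave
  group contrasts unchanged).
- **Modularity**: Newman's leading-eigenvector spectral bisection of the
  modularity matrix B = A − kkᵀ/2E, applied recursively; a split is accepted
  only if it raises the Newman–Girvan quality
  Q = Σ_m [e_mm/(2E) − (Σ_{i∈m} K_i/2E)²]. After each bisection a
  Kernighan–Lin-style single-node sweep refines the split (on by default,
  toggleable). Determinism is pinned by fixing the eigenvector sign (first
  nonzero component positive) and breaking move ties toward the lowest node
  index. The bisection heuristic can miss optima that require >2-way splits;
  on exhaustively enumerable graphs (N ≤ 9) the tests flag and bound such
  shortfalls rather than hiding them.

Distances use an all-pairs BFS by boolean matrix powers — for dense ~90-node
graphs with small diameter this outperforms per-source traversals by a wide
margin and is verified against Floyd–Warshall and scipy implementations.
Betweenness uses Brandes' algorithm (networkx), verified against explicit
path enumeration.

## Null models and small-worldness

Each network is compared with degree-matched random graphs generated by
Markov-chain double-edge swaps: two edges (a,b), (c,d) are chosen uniformly
and rewired to (a,d), (c,b) unless a self-loop or duplicate would result.
The attempt budget is 10× the edge count (config `null.swap_factor`), the
standard mixing heuristic; connectedness is deliberately not enforced since
the efficiency formalism tolerates disconnection. The ensemble default is
100 nulls per network (config `null.n_random`); each null draws an
independent child stream from the master seed, so ensembles are bit-exactly
reproducible and order-independent. Small-worldness is summarized by the
ratios E_glob(real)/E_glob(random) ≈ 1 and E_loc(real)/E_loc(random) > 1.

## Group inference

Every metric curve Y(S_k) collapses to a threshold-free scalar by the
trapezoid rule, Y_AUC = Σ_k [Y(S_k)+Y(S_{k+1})]·ΔS/2 (width 0.23 on the
default grid). Age and sex are regressed out of the AUCs once (OLS on
[1, age, sex]), before inference. The primary test permutes group labels
(default 10 000 permutations), recomputing the difference of group means of
the residualized AUCs; the two-tailed p is (1 + #{|null| ≥ |obs|})/(n+1),
never zero. Per-level pooled-variance t-tests supply the descriptive
per-sparsity profile only. Nodal p-values are corrected per metric across
regions by Benjamini–Hochberg FDR at q = 0.05.

**Hubs**: for each group, betweenness curves are averaged over subjects; a
region "exceeds" at a level when its group-mean B is above the across-region
mean + SD at that level. Under the null hypothesis that a region is not a
hub, exceedances are coin flips, so the one-tailed sign test
p = P[Binomial(24, ½) ≥ n_exceed] applies; hubs are the regions surviving
FDR at α = 0.002. An alternative reading — summing B across thresholds per
subject before averaging — is exposed via the same machinery by passing
per-subject curves; the group-mean-curve reading is the default.

**Modules**: the group-mean z matrices are binarized at a representative
sparsity (default 0.15, config `inference.modularity_sparsity`) and
decomposed; per-subject module counts at the same level are compared by
t-test.

**Clinical association**: for metrics/regions surviving the nodal FDR gate,
Pearson's r (with its t-derived two-tailed p) is computed between patients'
nodal AUCs and their motor scores.

## Synthetic cohorts

The generator emulates the study design the pipeline targets, with every
effect known by construction:

| parameter | default | meaning |
|---|---|---|
| n_patients / n_controls | 26 / 30 | group sizes |
| n_regions / n_timepoints / TR | 90 / 230 / 2 s | cleaned BOLD dimensions |
| module sizes (control) | 5 × 18 | planted community structure |
| module sizes (patient) | 18, 18, 18, 36 | two control modules merged (one module "lost") |
| r_within / r_between | 0.40 / 0.10 | block correlation levels |
| delta_between | 0.05 | long-range deficit subtracted from patients' between-module r |
| hub_regions | 0, 18, 36, 54, 72 | rows/columns boosted by +0.1 (capped 0.95) |
| band | 0.01–0.08 Hz | spectral band-pass at 1/TR sampling |
| effect_updrs | −4.0 | planted slope of motor score on target-region connectivity |

Signals are T i.i.d. multivariate-normal rows with the block correlation
matrix (eigenvalue-clipped to the nearest positive-definite correlation
matrix when hub boosts push it indefinite), then band-passed per column.
The filter is one linear operator applied to every column, so cross-column
correlations converge to the target as T grows; at T = 230 filtering keeps
~28 % of the spectrum, inflating the sampling SD of r to ≈ 1/√(0.28·T).
Ages are N(55, 11²) truncated to [30, 80]; sexes are balanced. Patient motor
scores are clip(19 + 9·ε + effect_updrs·ẑ, ≥ 0), where ẑ is the
standardized empirical connectivity strength of the designated hub region —
so a negative slope plants a negative score-vs-centrality correlation of
population magnitude ≈ 0.4 at n = 26, in the range reported for early-stage
motor cohorts.

**What the generator does not emulate**: hemodynamics, autocorrelated BOLD
noise, head motion, physiological artifacts, spatial structure of the
parcellation, and inter-subject variability in module layout. The pipeline
consumes only correlation matrices, so passing tests demonstrate correctness
of the graph-analytic machinery and the inference calibration — not that
real acquisitions satisfy the generator's assumptions.

**A structural caveat discovered with this generator**: at fixed sparsity
the edge budget is constant, so any manipulation that removes between-module
correlation mass necessarily concentrates retained edges inside modules.
Lowering long-range connectivity therefore *raises* local efficiency while
it lowers global efficiency — the two contrasts cannot be decoupled by this
kind of planted deficit. The test suite asserts the local-efficiency
null-calibration property anyway, as the honest statement of that
expectation, and its failure documents the coupling.

## Numerical and reproducibility choices

- Edge-count rounding is half-up; rounding to 0 or to the complete graph
  warns rather than fails.
- |r| = 1 between distinct regions, zero-variance regions, and non-finite
  inputs are hard errors naming the offending region/subject.
- One master seed (config `null.master_seed`) fans out to per-subject null
  streams and per-test permutation streams via name-keyed seed sequences
  (CRC of "null:subject:level" / "perm:metric:region" spawn keys), so
  disabling one analysis never shifts another's random stream, and serial
  and parallel execution agree.
- Result tables are TSV with 6-significant-digit floats; the JSON summary
  embeds the fully resolved configuration.

## Problem sizes in the test and acceptance profiles

The default protocol (100 nulls per level, 10 000 permutations) is the
production configuration. The automated suites use reduced profiles chosen
as the package's CI settings: oracle comparisons run on ≥ 200 random graphs
with N ≤ 12; calibration runs 200 replicate default-size cohorts at 1000
permutations; effect recovery runs 20 replicate cohorts; the determinism
check runs the full 56-subject cohort twice with 3 nulls per level and 500
permutations; `scripts/acceptance.py` runs the complete default study with
20 nulls per level and 5000 permutations. Estimates are stable well below
these ensemble sizes because they enter only through means and p-value
resolution.

## Known limitations

- Weighted and directed variants of the metrics are out of scope.
- The spectral bisection can return fewer modules than a full multi-way
  optimizer on graphs whose optimum requires >2-way splits.
- The permutation test assumes exchangeability of residualized AUCs under
  the null; strong covariate-by-group interactions would violate it.
- Hub detection treats threshold levels as independent trials in the sign
  test; nested edge sets make neighboring levels positively dependent, so
  the test is anticonservative in absolute terms and is used, as is
  standard, as a reproducibility screen rather than a calibrated p-value.
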
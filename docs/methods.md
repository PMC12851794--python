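# Methods

This note documents the models and procedures implemented in
`prophagepop`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not establish about real data.

## Pairwise similarity (tANI)

Total average nucleotide identity between two phage genomes is defined as

    tANI(a, b) = 100 · 2 · matched_bases / (len_a + len_b)

where `matched_bases` counts identically aligned positions. The
definition is symmetric, bounded by 100, and penalises length differences
(a perfect match of a 20 kb genome against a 40 kb genome scores ~67, not
100), which is what makes it usable for viral species delineation.
Positions involving `N` never count as matches.

The production estimator is seed–chain–extend:

1. **Seeding**: all maximal shared k-mer runs (default k = 15) between
   `a` and each orientation of `b`. k = 15 makes random 1–3 kb pairs share
   essentially no seeds (match probability 4⁻¹⁵ per position) while pairs
   above ~85% identity still seed densely (0.85¹⁵ ≈ 0.09 per position).
2. **Chaining**: the maximum-weight strictly collinear chain of anchors,
   with overlaps trimmed so no base is counted twice (O(n²) dynamic
   programme over anchors).
3. **Gap filling**: the unanchored segments between and beyond consecutive
   anchors are aligned with a bit-vector edit-distance alignment (edlib)
   and their exactly matching bases added.

The two strand orientations are computed independently and the better one
kept — never summed — because prophages integrate on either strand.
Pairs sharing no seed in either orientation report tANI 0 without
attempting alignment; this floors the estimator at 0 for unrelated
genomes rather than spending quadratic time to discover ~0% identity.

The validation oracle is an exact global alignment (match +1, mismatch
−1, gap −2, full dynamic-programming table; Biopython's `PairwiseAligner`
with a custom ACGTN matrix in which `N` scores −1 against everything).
On simulated pairs of ≥85% identity the estimator stays within 3
percentage points of the oracle; the two routes share no code path beyond
string handling, so the agreement is informative. Absolute tANI values
from other tools will differ by estimator choice (treatment of unaligned
regions, alignment heuristics); the thresholds below are calibrated to
the definition above.

## Viral taxonomy

Species are single-linkage clusters (connected components) of the graph
whose edges are pairs with tANI ≥ 95; genera use ≥ 70. Single linkage is
the one rule under which the species partition refines the genus
partition automatically (every ≥95 edge is a ≥70 edge); the refinement is
asserted at construction. Cluster labels are deterministic — each
cluster is named by its lexicographically smallest member — so reruns
and platform changes cannot relabel clusters.

A *singleton* is a species with exactly one member; the singleton
fraction divides by the number of species, and singleton density divides
a host species' singleton count by its number of sequenced genomes
(undefined, not zero, for hosts with no genomes). The minimum cluster
sizes for the NJ tree (genus ≥ 5) and the species network (≥ 7) are
exposed as parameters.

## Trees and distances

Similarity maps linearly to distance, `d = (100 − tANI)/100 ∈ [0, 1]`.
Neighbour joining is the standard Saitou–Nei agglomeration with two
determinism guarantees: Q-matrix ties break on the lexicographically
smallest pair of clade representative labels, and negative estimated
branch lengths are clamped to zero with the deficit moved to the sibling
branch, preserving path lengths so patristic matrices stay metric. On
additive inputs NJ recovers the generating tree to 1e-9; this is the
oracle property the test suite exercises on random Yule trees (and
cross-checks against scikit-bio's independent implementation).

Patristic distances are path sums over the tree; host trees are consumed
as Newick with branch lengths and never re-inferred here.

## Cophylogeny and host jumps

Both global-fit tests start from principal coordinates of the two
patristic matrices. PCoA double-centres `−½d²` (Gower), takes the
symmetric eigendecomposition, and retains axes with eigenvalue > 1e-8.
Patristic matrices need not be Euclidean; when a meaningfully negative
eigenvalue appears the Cailliez additive correction is applied (the
smallest constant `c` such that `d + c` off-diagonal is Euclidean,
obtained from the standard 2n×2n eigenproblem) and the decomposition is
recomputed. After correction the embedding reproduces `d + c` exactly;
rank orderings of distances are unchanged.

**PACo**: each host–phage association contributes a row pairing the
host's coordinates (reference configuration X) with the phage's (Y); Y is
column-centred, rotated (SVD of the cross-product) and uniformly scaled
to minimise `Σ‖X − sYQ‖²`. The minimised value `m²` is the global
statistic; the orientation (phage onto host) encodes dependence of the
phage phylogeny on the host phylogeny and is deliberately asymmetric.
Significance comes from permuting the phage column of the association
list (the association count is preserved), re-fitting each time, with the
add-one estimator `p = (1 + #{m²_perm ≤ m²_obs})/(1 + n_perm)` — so the
smallest attainable p at 10,000 permutations is 1/10001, and a "p = 0"
is never reported.

**ParaFitGlobal**: `Σ D²` with `D = Cᵀ A B` (C phage coordinates, B host
coordinates, A the binary phage × host association matrix); the null
permutes each phage's row of A independently; p uses the same add-one
estimator with ≥ comparison.

**Host jumps**: per-association squared residuals from the observed PACo
fit are thresholded at the empirical 95th percentile, computed with
linear interpolation between order statistics (position `1 + q(n−1)`),
and *strictly* greater residuals are flagged. With n distinct residuals
this flags exactly `n − floor(1 + q(n−1))` associations — 83 of 1,650,
i.e. 5.03% — independent of the residual magnitudes; the quantile rule
is a ranking device, not an error model, and flags should be read as
candidates for host switching, not confirmed events. Flagged
associations are attributed to genera to show where switching
concentrates.

Calibration: on independent random trees with a random one-to-one
association, both tests hold their size (rejection rate at α = 0.05
within [0.02, 0.08] over 200 simulations with 99 permutations each — the
band is the ±3σ binomial envelope); on mirrored trees both reject at the
permutation floor.

## Diversity statistics

The uncertainty coefficient uses plug-in entropies in nats over the
empirical joint distribution; `U(X|Y) = MI/H(X)`, with a degenerate X
(zero entropy) defined as fully explained (U = 1). U is scale-free, so
the logarithm base is immaterial (asserted). Zero-frequency categories
contribute nothing (0·log 0 := 0). The plug-in estimator is biased
upward at small n — visible in the worked example (n = 36) — and
accurate to ±0.05 by n = 2,000, which is what the recovery test checks.

Kruskal–Wallis (mid-rank, tie-corrected, χ² with k−1 df; all-identical
data defined as H = 0, p = 1) and pairwise two-sided Mann–Whitney U
tests (exact by enumeration when n₁+n₂ ≤ 12 without ties, otherwise
normal approximation with tie and continuity corrections) with
Holm–Bonferroni step-down adjustment compare prophage burden across
groups; these are delegated to scipy/statsmodels behind the module
surface. The two-sample "Wilcoxon" comparisons of independent groups are
the rank-sum (Mann–Whitney) test.

Rarefaction uses the exact hypergeometric expectation
`E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m))`, evaluated in log-gamma space
(absolute error < 1e-9; species with `N − Nᵢ < m` contribute exactly 1).
The cross-group depth is `floor(fraction · min(retained totals))` with
fraction 0.75 and an optional minimum-total filter; floor is declared for
determinism (the depth is an integer count of sequences). The curve in
m is non-decreasing and concave, both asserted.

## Synthetic data: what it emulates and what it does not

The generator plants exactly the structure each stage is supposed to
detect, with defaults chosen to be recoverable at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_hosts` | 12 | leaves of the Yule host tree |
| `birth_rate` | 1.0 | speciation rate (Exp(k·λ) waiting times); branch lengths in expected substitutions per site |
| `prophages_per_host_mean` | 3.0 | Poisson per-host prophage count |
| `jump_probability` | 0.1 | per-association probability of a host jump |
| `within_species_identity` | 97% | planted identity inside a species (margin 2 over the 95 threshold) |
| `between_genus_identity` | 80% | planted identity across species (well below 95, above 70) |
| `metadata_association_strength` | 0.7 | mixture weight of a species' "home" category |
| `root_sequence_length` | 2000 bp | genome length (desk-scale, not a real phage genome size) |

Host trees are pure-birth; growth starts at the first split (no stem), so
a binary tree with n leaves has n−1 internal nodes and 2n−2 branches and
the expected total branch length is (n−1)/birth_rate — the analytic
moment the simulator tests check. Prophage families codiverge: the phage
tree mirrors the host tree with each host's phages attached as short tips
(0.02) under that host's position. A host jump is one Bernoulli draw per
association: the phage keeps its ancestral tree position while its
current host is reassigned uniformly among the other hosts, without
distance weighting — the simplest null consistent with host switching,
and the reason the realized jump fraction is Binomial(n, p). Jump
detection on these data therefore shows that Procrustes residuals find
*uniform random* reattachments; real switches biased toward nearby hosts
would be harder.

Sequences are substitutions-only (no indels, no recombination, no gene
content), so true pairwise identity is exact Hamming identity and species
recovery can demand ARI = 1 rather than "high". Within/between identity
targets are planted with fixed per-branch substitution counts on a
two-level family tree (root → species ancestor → member); uniform site
choice makes realized identities drift from the target only by rare site
collisions (≲0.3 points at the default length). An `insert_indels`
helper exists for exercising the tANI estimator's indel robustness but is
never used where exact truth is required. Genus truth labels are derived
by single-linkage on the exact true identities at the genus threshold, so
truth is self-consistent for any parameter choice (with the default 80%
between-species identity, all species share one genus).

Metadata categories are drawn from a mixture (home category with
probability `strength`, uniform otherwise); the generator returns the
analytic U of that mixture, in both directions, computed from the
realized species sizes. At strength 1 the category is a deterministic
function of species, so U(category|species) = 1; U(species|category)
reaches 1 only if home categories happen to be injective over species.

Everything is deterministic under a fixed seed (numpy `default_rng`
integer streams; stage seeds derived from the master seed by one integer
draw), and `build_dataset` reruns are byte-identical on disk.

What passing these tests does **not** show: performance on real prophage
catalogues with indels, mosaicism, recombination and uneven genome
lengths; robustness of tANI to the unaligned-region conventions of other
similarity tools; or cophylogenetic power against realistic,
phylogenetically biased host switching.

## Numerical and design choices

* Matrices are symmetrised on construction and symmetric to 1e-6 on
  read; eigenvalue retention threshold 1e-8; NJ recovery tolerance 1e-9.
* Permutation p-values always use the add-one estimator; permutation RNG
  seeds are recorded in results.
* The interpolated-quantile / strictly-above convention for host jumps is
  fixed (it reproduces the 83-of-1650 arithmetic exactly); the quantile
  itself is a parameter.
* "Genus with more than ≥5 members" is read as ≥ 5; the parameter is
  exposed so the stricter ≥ 6 reading is one flag away.
* Genomes with zero prophages enter burden statistics only via an
  explicit genome list, since a per-phage metadata table cannot witness
  them.
* Pipeline runs log every parameter into the report and re-verify count
  consistency (singleton totals, jump counts, partition refinement)
  before writing it.

## Problem sizes

Default test and analysis runs use 12 hosts / ~36 phages / 2 kb genomes,
200-simulation calibration batches with 99 permutations, and 10,000
permutations only where a single PACo fit is cheap. The full test suite
runs in well under a minute on one CPU; `scripts/acceptance.py` in ~10 s.
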
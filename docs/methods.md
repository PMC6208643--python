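# Methods

This note records the model, the parameter choices that matter, and the
places where the design was genuinely open.

## Phylogenies and traits

Host and microbe trees are simulated under a pure-birth (Yule) process:
exponential waiting times with unit per-lineage birth rate, the splitting
lineage chosen uniformly, the clock run one extra (unobserved) waiting time
past the last split, and every branch divided by the total elapsed time so
the tree has height exactly 1. The birth rate is irrelevant after this
rescaling, which is why it is not a parameter. Trees are rooted, binary and
ultrametric by construction; the default pools are 25 hosts and 150
microbes.

Host traits follow Brownian motion on a Pagel-δ transform of the host tree:
every node depth *d* ∈ [0, 1] is mapped to *d*^δ and branch lengths are
recomputed (tips are pinned at depth exactly 1, so the transform is closed
on unit-height trees and no post-hoc rescaling is needed). Small δ pushes
internal nodes toward the tips in depth, which concentrates shared history:
tip covariances approach 1 and trait variation becomes clade-structured
(strong phylogenetic signal). Large δ drives covariances to 0 (a near-star
tree; no signal). Brownian tip values are drawn exactly as multivariate
normal with covariance σ² C, where C(i, j) is the depth of the MRCA of tips
i and j (computed as height − d(i, j)/2); a 10⁻¹² jitter on the diagonal
keeps the Cholesky factor stable when extreme δ collapses depths. σ² = 1
and root state 0 throughout: every downstream statistic is location
invariant, and scale differences are removed when microbial preferences are
min–max mapped into the host-trait range.

Realized signal is summarized by Blomberg's K, computed by the standard GLS
ratio on the **untransformed** height-1 host tree — the tree the detection
tests use — so K describes the signal those tests can exploit. When 2 or 4
traits filter jointly, the replicate's signal is the **mean K across
traits**; nothing in the pipeline depends on a per-trait resolution of this
choice, but it is a choice.

A practical consequence of small δ worth knowing: as δ → 0 the *absolute*
spread of host traits shrinks (tips become nearly identical), so with a
fixed niche breadth the environmental filter weakens even though K is
large. Replicates with large K but a narrow trait range are therefore
genuinely harder to detect — this is a feature of the model, not an
artifact.

## Assembly

Each host's community holds exactly K = 150 individuals (carrying
capacity). Assembly starts from an empty community and, for 20 time steps,
redraws all K individuals multinomially ("full replacement"). Recruitment
probabilities mix three components, each normalized to sum 1 and weighted
by its β:

* environment: Ê ∝ Π_traits exp(−(h_t − m_t)²/(2σ²)), σ = 0.5 (trait
  units);
* abundance (reproduction): Â ∝ current abundances (uniform when the
  community is empty);
* competition: Ĉ ∝ 1 − (Σ_j a_j · overlap(i, j))/Σ_j a_j, with Gaussian
  niche overlap on the same σ.

The exact combination rule used by the original community-assembly
software this model emulates is not published in a reproducible form; the
convex additive mixture was chosen because it reproduces every scenario
limit exercised here (β.env = 1 alone ⇒ recruitment is exactly Ê, so the
whole run is distributionally one multinomial(K, Ê) draw; β.abun = 1 alone
⇒ Wright-Fisher drift from a uniform start) and makes the βs readable as
filter strengths. Power results inherit some sensitivity to this
reconstruction (see Calibration below).

Scenario presets: filtering (1, 0, 0), neutral (0, 1, 0), competition
(0.5, 0.25, 0.25) for (β.env, β.abun, β.comp). The source pool is infinite
and unbiased; there is no transmission, vertical inheritance or
codiversification — deliberately, since the point is a purely ecological
baseline.

## Beta diversity

Jaccard (presence/absence) and Bray-Curtis are standard; UniFrac variants
are delegated to scikit-bio. Weighted UniFrac uses the **normalized** form
so that all four metrics live on [0, 1] and are comparable inside UPGMA
and Mantel analyses. Unweighted UniFrac follows the classical convention:
branches absent from both communities are excluded from numerator and
denominator (disjoint presence sets are at distance exactly 1).

## Detection tests

**Mantel**: Pearson r between the strictly-lower-triangle vectors of host
cophenetic distance and community dissimilarity; the null jointly permutes
rows/columns of the community matrix; one-sided for r large. **Dendrogram**:
normalized Robinson-Foulds distance between the host tree and the UPGMA
(average-linkage, merge height = mean distance/2) dendrogram; one-sided for
nRF small. Its null either reshuffles the host tree's tip labels or draws
fresh Yule topologies on the same tips — the two agree closely in
calibration runs. **Trait Mantel**: as Mantel but with Euclidean host-trait
distances; it uses the true filter and so upper-bounds detectability.

RF uses the rooted-clade convention: the symmetric difference of
non-trivial clade sets over the maximum 2(n − 2), so 1 is attainable and 0
means identical topologies. p-values are (count + 1)/(n_perm + 1) with
n_perm = 999 by default; significance is declared at p ≤ 0.05, the exactly
calibrated rule for p-values living on the 1/(n_perm + 1) grid. With very
few labels (n ≤ 6) the Mantel null occasionally redraws the identity
permutation, so the p-value floor is only reached for moderate n — the
test suite checks small-n behaviour against exact enumeration instead.

Numerical tie-breaks: UPGMA inherits scipy's deterministic first-index
merge order; ties have measure zero for continuous dissimilarities.
Degenerate inputs (constant traits, zero-variance distance matrices, empty
communities) raise errors rather than returning arbitrary numbers.

## Experiments and binning

Replicates are pure functions of (configuration, replicate index): seed
streams are spawned per replicate from the master seed, so resuming or
extending a sweep never changes existing records. Replicates cycle through
the δ grid {0.01, 0.1, 1, 10, 1000} and are binned by realized K with
default edges (0, 0.25, 0.5, 1.5, 15) — half-open, last bin closed, larger
K flagged as overflow. The last two bins are the moderate- and
strong-signal ranges the headline results quote; bin counts are always
reported so records can be re-binned. A set fails loudly if more than 1% of
its replicates error out.

## Calibration scale and what it shows

The acceptance workload uses a 500-replicate neutral pool and a filtering
pool accumulated until the moderate and strong K bins hold ≥ 200
replicates each (roughly 900 replicates; a few minutes on one CPU). These
sizes give Monte Carlo standard errors of ~1 point on the type-I error and
~3 points on detection proportions. The neutral control calibrates both
tests near the nominal 5% level, and the filtering scenario reproduces the
qualitative structure of interest: Mantel power rising steeply with K,
dendrogram power far lower at equal K, mean Mantel r climbing from ~0.2
(moderate K) upward, mean nRF pinned near 0.9 throughout.

Two caveats. First, absolute power levels (not orderings, and not the
mean statistics) are sensitive to the reconstructed recruitment rule: the
additive rule yields clean multinomial communities, and detection
proportions track the upper end of what the same mean effect sizes can
support. Orderings between methods, metrics and nulls, the type-I
calibration, and the per-bin mean statistics are the robust outputs.
Second, the generator emulates idealized surveys: no sequencing noise, no
rarefaction, no OTU-clustering distortion, equal sampling depth per host —
passing tests say nothing about robustness to those. The simulator is a
baseline for method behaviour, not a generative model of real microbiome
data.
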
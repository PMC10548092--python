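# Methods

## Contact-matrix construction and normalization

Pair records (1-based genomic positions) are assigned to half-open, 0-based
bins of a fixed grid: position p falls in bin ⌊(p−1−start)/bin_size⌋. A
trailing partial bin is kept, so a region need not be a multiple of the bin
size; for the *Igh* model region (chr12:113,090,000–116,170,000 at 20 kb)
the arithmetic yields 154 bins. Each accepted pair increments one matrix
entry and its mirror, so the upper triangle (diagonal included) sums exactly
to the number of in-region pairs.

Low-coverage masking flags bins whose marginal falls below
`min_fraction` × median of the positive marginals (default 0.2 — explicit
and configurable, since coverage cutoffs in upstream toolchains are rarely
documented). Masked rows/columns are zeroed and stay zeroed through every
later operation.

Balancing is iterative proportional fitting with per-sweep symmetrization:
rows and columns are divided by the square root of their relative marginal
until the unmasked marginals agree to a relative tolerance (default 1e−6,
at most 200 sweeps, error on non-convergence). Total mass is rescaled to the
input mass, so balancing only redistributes counts. For symmetric input the
fixed point is the unique symmetric Sinkhorn scaling, which the test suite
cross-checks against an independent alternating row/column iteration.

Distance correction divides every entry by the mean unmasked entry at the
same |i−j|. A homogeneous-decay matrix C_ij = f(|i−j|) therefore maps to
exactly 1 everywhere; diagonals with zero expected value are left at zero
(they carry no unmasked signal and must not produce divisions by zero).

## Polymer model

The chain is a beads-on-a-string homopolymer of N beads (one per 20-kb bin)
with all lengths in units of the bond length *a* and kT = 1.

- **Bonds.** Consecutive beads are tied by stiff harmonic springs
  U = k_b (d − a)², default k_b = 100 kT/a². The bond form is a modeling
  choice: it preserves connectivity while permitting simple local moves, and
  at k_b = 100 the bond-length fluctuation (σ ≈ 0.07 a) is small against
  every radius in the model.
- **Nonbonded pairs.** Every pair interacts through a spherical well:
  +∞ below the hard core 0.6 a, depth ε_ij (≤ 0) on [0.6 a, 1.5 a), zero at
  and beyond 1.5 a (the boundary itself counts as outside the well,
  matching the strict `< 1.5 a` contact rule used in analysis). Bonded
  neighbours are excluded from the well — they sit permanently inside
  1.5 a, so their well energy is a constant offset — but the hard core
  applies to all pairs. Positive (repulsive) depths are rejected at the
  interface: repulsion is the hard core's job.
- **Sampling.** Metropolis Monte Carlo mixing two moves 1:1 — single-bead
  Gaussian displacement (step width tuned during burn-in toward ~40%
  acceptance, bounded to [0.01, 2] a) and crankshaft rotation of a random
  internal segment about the axis through its flanking beads (distances to
  the flanks are invariant, so only cross-segment nonbonded terms enter the
  energy difference). One chain per call: burn-in of 200·N sweeps, then one
  snapshot every 20·N sweeps (one sweep = N attempted moves). At these
  defaults the radius-of-gyration autocorrelation at one thinning interval
  is well under 0.2 for chains up to ~200 beads. The kernel is
  numba-compiled with its own seeded RNG, so identical inputs give
  bit-identical ensembles.
- **Validation.** The sampler is checked against an independent brute-force
  quadrature of the 3-bead chain's Boltzmann distribution (the end-to-end
  density integrated over bond lengths and bond angle): the sampled
  end-to-end distance distribution must pass a KS test against the
  quadrature CDF, and the end-to-end contact probability with an attractive
  well (ε = −2) must agree within 3 Monte-Carlo standard errors.

Contact maps count pairs strictly within 1.5 a, bonded neighbours included,
diagonal fixed at 1.

## Inverse energy fitting

Targets are balanced experimental (or synthetic) maps rescaled to contact
probabilities. The overall scale of a balanced Hi-C map is arbitrary, so one
global factor is fixed by matching the mean of unmasked separation-2 entries
to a simulated homopolymer (all ε = 0) reference at the same separation —
separation-2 contacts of a bonded chain are nearly model-independent, making
them a stable anchor. Scaled entries are clipped to ≤ 1; masked bins are
ineligible.

The fit is a damped iterative-Boltzmann scheme. Per iteration: simulate a
fresh ensemble under the current ε (sub-seed derived from the master seed
and the iteration index, so no single sample is overfitted), estimate
contact probabilities, then for every eligible pair (|i−j| ≥ 2, both bins
unmasked)

    ε_ij ← clip(ε_ij + η · log((p_sim + δ)/(p_target + δ)), [ε_min, 0])

with defaults η = 0.3 kT, δ = 1/(2 · ensemble size), ε_min = −5 kT. The
update deepens wells where the simulation under-contacts the target,
vanishes exactly when p_sim = p_target, and can never push a depth positive
or a masked row off zero. Convergence is declared at a configurable Pearson
r between simulated and target maps (computed over eligible pairs only);
a sustained material decline (five consecutive drops while > 0.05 below the
best r seen) raises an error with the trace attached, distinguishing true
divergence from Monte-Carlo jitter.

Per-iteration ensembles use a lighter schedule (burn-in 100·N, thinning
5·N sweeps) than final analysis ensembles: residual autocorrelation within
one iteration's sample only adds noise to an update that the next iteration
corrects, while final ensembles use the full schedule. On a 40-bead
synthetic target with two anchor stripes and a distal attractive block
(depths −1.5/−0.4 kT), 40 iterations of 300 structures recover a model
whose own simulated map correlates with the target at r ≥ 0.9 and whose
anchor rows are unambiguously deeper than the background distribution.

## Ensemble statistics

Bead indices are 1-based, matching locus annotation conventions. All
contact-based statistics use the strict < 1.5 a rule. Partner counts,
V_H–D_H statistics, CM/CMv distances and conditional distances are plain
averages over conformations; conditional means over an empty conditioning
subset are returned as NaN with a zero subset size, never silently 0.
V–D events are counted as bead pairs within radius per conformation,
summed, which makes the per-D and per-V tallies two marginals of one event
set (Σ per-D = Σ per-V holds exactly and is property-tested).

Conformation clustering offers two dissimilarities: (1) RMSD of the full
bead–bead distance matrices, √(mean over i<j of (d_ij(c₁) − d_ij(c₂))²) —
invariant to rigid motion by construction; (2) one minus the Jaccard overlap
of the contact sets (pairs < 1.5 a with |i−j| ≥ 2; "significant"
interactions are defined as all such contacts, since no sharper criterion is
available at single-structure level). Agglomerative clustering uses average
linkage by default with a configurable cluster count or cut height, and
emits per-cluster mean contact maps.

Spearman correlation uses average ranks for ties, drops missing values
pairwise, and flags constant input as undefined rather than returning an
arbitrary coefficient.

The packaged *Igh* bead annotation (`ighloci.synthetic.igh_bead_annotation`)
is a synthetic stand-in following the published bead indexing (3′ CBE
superanchor at bead 6, constant/Eμ block at 9–16, IGCR1 at 19, V_H genes at
24–146). The D_H bead set is not printed anywhere; beads 18–21 are used,
with bead 19 classed as IGCR1 (it carries D genes *in addition*), so V–D
analyses accept explicit bead-set overrides. CTCF levels and recombination
scores in the fixture are schematic placeholders, not measurements.

## Trans-interaction calling

Virtual-4C counting keeps pairs with exactly one end in the (merged)
viewpoint intervals and the other end on a chromosome carrying no viewpoint
interval; the other end is assigned to a fixed-grid 500-kb bin. Bins
overlapping — by even 1 bp — the first 3 Mb of any chromosome, a blacklist
interval, or a custom exclusion zone are ineligible, as is the entire
viewpoint chromosome. Raw counts (not normalized) feed the score.

The modified Z-score is the Iglewicz–Hoaglin statistic
z = 0.6745 (x − median)/MAD computed over the pooled eligible trans bins
genome-wide per replicate. When the MAD is zero the denominator falls back
to 1.253314 × mean absolute deviation; if that is also zero every score is
0. The statistic is invariant under positive affine rescaling of counts. A
bin is significant when z > 3.5 (strict) in every replicate; hits carry the
across-replicate average z and the log2(avg z + 1) profile value. Profile
clustering is Euclidean/complete-linkage hierarchical clustering over the
union of bins with missing bins imputed as 0.

Null calibration is non-trivial by design: the synthetic background is
negative-binomial (default mean 100, size 10, variance ≈ 11 × mean), so the
right tail is heavy and the single-replicate false-call rate is a real
quantity (a few per mille to a few percent depending on dispersion). Under
replicate independence the two-replicate rate is approximately the product
of single rates, which the suite verifies by pooled simulation.

## FISH statistics

Nuclei must carry exactly two spots per channel (one per allele); others
are rejected with a tally. The per-nucleus distance is the minimum over the
four cross-channel spot pairs; for three channels the "closest trio" is the
cross-channel triple minimizing the sum of its three pairwise distances,
kept iff at least two of those distances are < 1 μm (the two-of-three
rule). Distance brackets are half-open on the left join: [0, 0.5),
[0.5, 0.8), [0.8, 1.0), [1.0, ∞) μm.

The analytic random-association model is p = (4/3)πr³/V — the chance that a
partner locus placed uniformly in a spherical nucleus of volume V lies
within r of a focal locus. For V = 60 μm³: p ≈ 6.98% at r = 1 μm, 0.87% at
0.5 μm, 0.19% at 0.3 μm; the three-locus coincidence is p². The model
deliberately ignores nuclear-boundary truncation and the diploid
minimum-of-four selection; the synthetic generator therefore places the
focal locus at the nucleus centre (where the r-ball is fully interior), so
the analytic value is exact for the generated null and the Monte-Carlo
validator converges to it within binomial error. Between cell types of
different nuclear volume, distances measured in the smaller nuclei are
multiplied by a volume-adjustment factor > 1 before comparison.

Association frequencies between groups are compared with two-sided Fisher
exact tests, Bonferroni-corrected (p × m capped at 1); an observed
frequency against the analytic p uses an exact binomial test. Full distance
distributions are compared with Kruskal–Wallis (tie-corrected) plus Dunn's
rank-based pairwise z-tests with Bonferroni correction; Dunn's test is
implemented in-package (standard large-sample formula with tie correction)
as no installed statistics library provides it.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* each stage consumes:
anchor-stripe/block energy architectures, contact maps simulated from known
truths, overdispersed trans backgrounds with multiplicative spikes
reproduced across replicates, and centred-focal FISH nuclei. They do not
emulate restriction-fragment geometry, capture-efficiency bias, mappability
structure, correlated replicate noise, imaging localization error, or
nuclear-boundary effects. Green tests therefore demonstrate algorithmic
correctness under the stated models, not robustness to every artefact of
real libraries; the real-data figures of the source study (full-locus
partner-count profiles, genome-wide hit lists) require the deposited
sequencing data and full-size fits and are replaced here by directional and
conservation properties at reduced problem sizes (40-bead fits, 3,000–5,000
synthetic trans bins, 10⁵ nuclei), chosen as the package's own test-scale
defaults.

## Numerical conventions

- Positions in pair records are 1-based; bins and BED intervals 0-based
  half-open; bead indices 1-based.
- Contact boundary d = 1.5 a and Z threshold 3.5 are strict inequalities;
  bracket joins are half-open on the left.
- All stochastic components take explicit integer seeds; sub-seeds are
  derived with `numpy.random.SeedSequence` so parallel stages never share
  streams. Ensembles record seed and schedule in their provenance.
- Matrix balancing tolerance 1e−6 (relative marginal spread), max 200
  sweeps; fit defaults η = 0.3, δ = 1/(2·ensemble), ε_min = −5 kT,
  convergence r = 0.98.
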
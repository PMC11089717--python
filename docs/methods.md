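# Methods

This note documents the models implemented in `dip3d`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate about real data.

## The measurement being modeled

Diploid single-cell chromatin conformation capture produces, per cell, a
list of proximity-ligation contacts.  Each contact has two legs
(chromosome, bp coordinate); a leg carries a parental haplotype only when
its read overlapped a phased heterozygous SNP, so most legs are unphased.
Downstream structure analysis needs haplotype-resolved contacts — a
contact between `chr1` and `chr2` must be attributed to one of the four
homolog combinations before it can restrain a diploid model.

## 2D haplotype imputation

**Neighborhood metric.** Two contacts on the same chromosome pair, with leg
displacements (Δx, Δy), are compared by the order-0.5 Minkowski
dissimilarity

    d(Δx, Δy) = (√|Δx| + √|Δy|)².

This is not a norm (no triangle inequality) and is used deliberately: the
empirical conditional density of a second contact near a first one follows
p(Δx, Δy) ∝ d⁻¹ = (√Δx + √Δy)⁻², rather than the (Δx + Δy)⁻¹ expected if
the two chromosomes mixed like a single concatenated chain.  Simultaneously
large Δx *and* Δy are disfavored — chromosomes touch by protrusion.
`conditional_density`/`fit_conditional_density` estimate the density on
log-spaced 2D bins and compare the two candidate laws by least squares in
log-log space; the tests verify that samples synthesized from either law
are assigned to the correct model and that the fractional law's exponent is
recovered at −2.

**Voting.** For each target contact with ≥ 1 unknown leg, the compatible
(maternal/paternal) haplotype tuples are enumerated (2 or 4).  Every fully
phased contact on the same chromosome pair within **10 Mb** (in d) and
compatible with exactly one tuple casts one vote; the winning tuple is
imputed iff it has **≥ 3 votes** and **≥ 90% of votes** (both inclusive;
ties win nothing).  For intrachromosomal contacts the leg pairing that
minimizes d is used (an exactly tied pairing with conflicting orientations
abstains), and three special rules apply: targets with legs ≤ **10 Mb**
apart are assumed intrahomologous without voting; a winning
*inter*homologous tuple is accepted only at ≥ **100 Mb** separation; and
targets with both legs unknown are never imputed in 2D.  Rounds are
synchronous (votes counted against the frozen round-start evidence, so the
result is iteration-order independent), run **3** times with each round's
output as the next round's evidence, followed by isolation cleaning
(contacts with < **2** same-haplotype neighbors within **10 Mb** dropped;
evaluated simultaneously, so the filter is permutation-invariant) and one
final round that targets interchromosomal both-unknown contacts against the
cleaned evidence.

Unresolved contacts are not discarded silently: `ImputationResult` carries
the final assignment for every input contact in input order, so recovery
can be scored against a simulation truth, while `ImputationResult.contacts`
holds the cleaned, fully resolved set used for reconstruction.

The vectorized implementation is checked contact-by-contact against an
independent naive O(n²) reference on random sets.

## 3D reconstruction

Haplotype-resolved contacts are binned to (chromosome, haplotype, bin)
particles and turned into restraints:

* backbone: harmonic, k (d − b)² with b = 1 model unit between consecutive
  bins of a chromosome copy — harmonic at *all* extensions so a mis-imputed
  contact cannot tear the chain;
* contact: half-harmonic upper bound w·k·max(0, d − d_c)², d_c = 2 units,
  weight w = contact multiplicity;
* confinement: half-harmonic spherical wall at a radius set by a nominal
  packing fraction (0.15) of the particle volume;
* soft-core excluded volume between any two particles closer than one
  particle diameter.  Without it the energy has a degenerate global
  minimum — collapsing the whole nucleus to a point satisfies every
  upper-bound restraint — so repulsion is what gives the model an interior.

Annealing is Langevin-style stochastic descent: 20 geometric temperature
steps per stage, per-particle displacement capped at 0.2 units per
iteration (stiff, heavily weighted coarse restraints otherwise destabilize
the descent), through a coarse-to-fine bin-size ladder (default multipliers
8, 4, 2, 1 of the target resolution) with each stage seeded from the
previous stage's solution via backbone interpolation.  Reconstruction
rounds alternate with **3D imputation**: an unknown leg whose partner leg
is phased is assigned to whichever parental copy of its bin lies closer to
the partner's particle, iff near/far ≤ ρ = 0.5; both-unknown contacts are
skipped.  The default plan is 3 coarse rounds (5× the base resolution)
then 2 fine rounds, each followed by 3D imputation.

A contact map cannot identify chirality, and annealing solutions are
defined up to rigid motion and reflection; every downstream metric is
therefore rigid-motion- and reflection-invariant (asserted in tests to
1e-9).  Fidelity is measured as the Spearman correlation between the
reconstructed and true all-pairs distance matrices (chirality-free),
≥ 0.7 required and ≈ 0.9 typical on the default toy cell.

## Architecture metrics

* **Intermingling index** — per particle, the fraction of neighbors within
  3 particle radii (default; the radius is a free choice, exposed as
  `NeighborContext`) belonging to a different chromosome.  Maternal and
  paternal copies of the same chromosome count as the *same* chromosome by
  default (territory mixing is between chromosomes); a flag flips this.
* **Compartmentalization score** — Spearman correlation between each
  particle's CpG frequency and the mean CpG of its neighbors; constant
  input returns 0 with a degeneracy flag.
* **Radial positions** — distances to the cell's center of mass normalized
  by their mean (mean exactly 1); shell profiles average CpG in concentric
  shells of normalized radius (20 shells default, particles as the
  averaging unit), cohort curves are unweighted means over cells.
* **Radial-CpG correlation** — per genomic bin (haplotypes pooled), mean
  normalized radius vs bin CpG, Spearman by default.  Positive =
  "inside-out" (CpG-rich chromatin peripheral, primed-like), negative =
  "out-inside" (naive-like).  On the 6-Mb toy genome the default 1-Mb
  analysis bins give only 6 points; tests that need a stable null use
  100–200-kb analysis bins instead.
* **Contacting CpG** — single-cell compartment proxy: per bin, the
  contact-count-weighted mean CpG of partner bins, excluding partners in
  the bin itself.  Diploid mode uses phased legs with alleles as separate
  loci; cell-type mode uses all contacts with alleles pooled.  Cell-type
  clustering (PCA of the per-cell vectors + seeded 2-means) uses cell-type
  mode: cell-state discrimination is a cell-type feature and should not
  discard the ~91% of contacts with an unphased leg.
* **A/B compartments** — per chromosome on pooled contacts:
  observed/expected by diagonal means, Pearson correlation matrix, leading
  eigenvector, sign oriented so positive correlates with CpG (A = open).
  The eigenvalue share of the correlation-matrix trace is reported and
  flagged below 0.20 as weak signal.
* **Cohort comparison** — Wilcoxon rank-sum (exact p at small n; rank-based
  rather than a t test because cohort sizes of ~5 cells make normality
  unverifiable).

## The synthetic diploid-nucleus generator

The generator is the package's test bed: it produces a truth structure and
contacts with *plantable* architecture, not a mechanistic polymer model.

One particle per (chromosome, haplotype, 20-kb bin); default toy genome
3 chromosomes × 2 Mb (600 diploid particles).  The CpG track is a smoothed
lognormal field (domain length ~10 bins) so CpG-rich/poor domains are
contiguous.  Chains are initialized as confined random walks started from
well-separated directions (a randomly rotated Fibonacci sphere) —
emulating territory inheritance at mitotic exit, and necessary because the
centroid-attraction energy below cannot demix chains that start mixed —
then relaxed by ~700 sweeps of checkerboard parallel Metropolis (even/odd
beads alternate, valid because bonds couple only adjacent beads) under:
harmonic bonds, a soft spherical wall, a radial CpG bias
−sign·s·ĉ·(r/R) (sign −1 pulls CpG-rich bins inward: naive-like;
+1 pushes them outward: primed-like; s = 3 by default), and a territory
attraction t·|x − centroid|²/R² toward the chain's own centroid (t = 3
naive-like, 0 primed-like).  The paper-scale effect sizes are unknown
(figure-only), so archetype strengths are chosen for detectability of the
planted contrast at this scale, as the generator's stated purpose.

Contacts are drawn uniformly (with replacement) from particle pairs within
a capture radius of 1.8 bond lengths, excluding immediate backbone
neighbors (adjacent-bin ligations carry no 3D information); leg coordinate
= bin start + uniform offset; each leg's haplotype is revealed
independently with probability 0.3 (sparse-SNP phasing proxy).  Defaults:
20,000 contacts/cell.  A separate checkerboard generator plants alternating
A/B blocks with boosted within-set contact rates for compartment-recovery
tests.

**What passing tests show, and what they do not.** The synthetic nuclei
have no TADs, loops, polymer entanglement, replication state, or
chromosome-length heterogeneity; phasing is i.i.d. per leg rather than
SNP-clustered; contact noise (spurious ligations, duplicates) is absent.
Tests against this generator demonstrate algorithmic correctness and
end-to-end recoverability of planted architecture at desk scale — not
biological fidelity on real Dip-C libraries.

## Known limitations

* **2D imputation coverage at toy scale.** The voting rules categorically
  skip intrachromosomal both-unknown contacts, which caps the fraction of
  initially unknown legs resolvable in 2D at 1 − 0.7·f_intra for phase
  rate 0.3 (f_intra = intrachromosomal contact fraction).  Moreover, on
  2-Mb toy chromosomes the 10-Mb voting window spans the entire chromosome
  pair, so votes pool over all four homolog combinations and
  interchromosomal both-unknown targets rarely reach the 90% threshold.
  The measured 2D resolution on a default toy cell is ~0.21 of unknown
  legs at ~0.91 accuracy; on real genomes the window is local and the
  3D-imputation rounds recover much of the remainder.  The acceptance
  script reports the honestly measured fractions.
* **3D imputation** follows the nearest-homolog rule with a ratio gate and
  skips both-unknown contacts; consequently intrachromosomal both-unknown
  contacts are never resolved anywhere in this pipeline.
* The annealer is a minimal Langevin scheme, not a molecular-dynamics
  engine; energies are in arbitrary units and only relative decreases are
  meaningful.
* Model lengths are in bond units; no nm calibration is attempted.

## Problem sizes

Defaults throughout are desk scale, chosen so the full test suite and the
reproduction script each run in minutes on one CPU: 600-particle cells,
20,000 contacts, cohorts of 5–10 cells per state, reconstruction at 100-kb
coarse/20-kb fine resolution.  All sizes are parameters and scale up
unchanged.
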
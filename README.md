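# dip3d

Single-cell **diploid 3D genome analysis**: haplotype imputation of
single-cell chromatin contacts, restraint-based 3D reconstruction, and the
nuclear-architecture statistics used to distinguish cell states such as
naive vs primed human embryonic stem cells.

Single-cell chromatin conformation capture on a diploid genome yields, per
cell, a list of contacts whose two *legs* (chromosome, bp coordinate) mostly
lack a parental haplotype — only legs covering a heterozygous SNP are
phased.  This package implements the full downstream analysis:

1. **2D haplotype imputation** by neighborhood voting.  Contacts on the same
   chromosome pair are neighbors under the L^0.5 dissimilarity
   `d = (√|Δx| + √|Δy|)²` (order-0.5 Minkowski; not a norm), which matches
   the empirical conditional contact density `p(Δx, Δy) ∝ (√Δx + √Δy)⁻²` —
   contacting chromosomes protrude into each other rather than intermingle
   (the fully-mixed alternative would give `p ∝ (Δx + Δy)⁻¹`).  An unknown
   leg is imputed when one haplotype tuple wins ≥ 3 votes and ≥ 90% of votes
   from phased contacts within 10 Mb; intrachromosomal contacts ≤ 10 Mb
   apart are assumed intrahomologous, interhomologous assignments need
   ≥ 100 Mb separation, and isolated contacts (< 2 same-haplotype neighbors
   within 10 Mb) are removed.
2. **3D reconstruction** by simulated annealing: haplotype-resolved contacts
   become distance restraints between (chromosome, haplotype, 20-kb bin)
   particles, solved coarse-to-fine through a bin-size ladder, alternating
   with geometric ("3D") haplotype imputation from the reconstructed
   structure.
3. **Architecture metrics**: chromosome intermingling index,
   compartmentalization score, radial CpG profiles and the radial-position ×
   CpG correlation whose sign separates "inside-out" (euchromatin
   peripheral) from "out-inside" (euchromatin central) nuclei, single-cell
   "contacting CpG" compartments with PCA cell clustering, interchromosomal
   contact statistics, contact heatmaps, and eigenvector A/B compartments.
4. **A synthetic diploid-nucleus generator** that plants these architectures
   (radial CpG bias sign/strength, chromosome-territory strength, partial
   phasing) in a known truth structure, so every stage is testable
   end-to-end with no sequencing data.

## Worked example

```python
from dip3d import (make_toy_genome, simulate_structure, sample_contacts,
                   impute_pipeline, reconstruct_pipeline,
                   radial_cpg_correlation, intermingling_index)
from dip3d.simulate import NAIVE_LIKE

genome, cpg = make_toy_genome(seed=7)          # 3 chromosomes x 2 Mb, 20-kb bins
truth = simulate_structure(genome, cpg, NAIVE_LIKE)
contacts, _ = sample_contacts(truth, NAIVE_LIKE)   # 20,000 contacts, 30% phased

result = impute_pipeline(contacts)             # 2D voting + cleaning
print(len(result.contacts), "haplotype-resolved contacts")

structure = reconstruct_pipeline(result.contacts, genome, 20_000)
rho, _ = radial_cpg_correlation(structure, cpg)
_, mixing = intermingling_index(structure)
print(f"radial-CpG correlation {rho:.2f}, intermingling {mixing:.2f}")
```

prints, for this seed:

```
8910 haplotype-resolved contacts
radial-CpG correlation -0.26, intermingling 0.08
```

The negative radial-CpG correlation recovers the planted naive-like
"out-inside" architecture (CpG-rich euchromatin at the nuclear center), and
the low intermingling index reflects its strong chromosome territories.

The same pipeline is scriptable from the shell:

```bash
dip3d run --outdir run1 --seed 1 --n-cells 5       # simulate+impute+metrics
dip3d impute run1/naive_like_0/contacts_raw.txt --out imputed.txt
dip3d metrics structure run1/naive_like_0/structure_truth.3dg run1/cpg.bedgraph --out m.tsv
dip3d compare run1/cell_metrics.tsv --out comparison.tsv
```

## File formats

* contacts: whitespace-delimited `chrA posA hapA chrB posB hapB`
  (`mat`/`pat`/`.`)
* structures: 3DG — tab-delimited `chrom(mat|pat)  bp  x  y  z`
* CpG track: bedGraph; loci: BED4.  Coordinates 0-based, bins half-open.

See `docs/methods.md` for the models, parameter choices, and limitations.
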
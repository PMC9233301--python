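# hapshare

Haplotype-sharing analysis of fine-scale population structure and recent
demographic history from phased SNP genotypes.

Allele-frequency methods (PCA, FST) see structure accumulated over thousands
of generations; haplotype sharing sees the last tens.  `hapshare` implements
the sharing toolkit end to end:

- **Chunk painting**: every haplotype is tiled into chunks attributed to the
  other individual carrying the longest identical interval at each site
  (PBWT-style matching), yielding N×N *chunkcounts* and *chunklengths*
  coancestry matrices, plus PCA of the coancestry matrix.
- **Coancestry network clustering**: individuals are nodes, symmetrised
  chunkcounts are edges band-filtered to `2 < w < 25` (dropping both deep
  and close-relative relationships), partitioned by recursive Leiden
  community detection (depth ≤ 4, minimum community size, and a
  rewired-null modularity test so homogeneous groups are not shredded).
- **Cluster profiles**: copying vectors, non-negative least-squares sharing
  profiles β (a target cluster's mean copying expressed as a mixture of the
  other clusters), total variation distance, and Hudson's FST
  (ratio-of-averages).
- **IBD segments**: exact PBWT long-match detection (≥ 1 cM), the
  refinedIBD-style gap-merge rule (gap < 0.6 cM with at most one discordant
  site), and within-cluster sharing summaries.
- **Recent effective population size**: the within-cluster IBD length
  spectrum (> 4 cM) is matched to the coalescent-Haldane expectation
  E[#seg ≥ u] = Σ_g P(g)·2gL·e^(−2gu) over a piecewise-constant Ne(g)
  trajectory, with overdispersion-corrected bootstrap bands.
- **Inbreeding**: PLINK-style windowed ROH detection,
  F_ROH (genome fraction in ROH > 1.5 Mb) and
  F_SNP = (O(HOM) − E(HOM))/(N − E(HOM)) — separating homozygosity from
  historically small populations (high F_ROH, F_SNP ≈ 0) from ongoing
  consanguinity (both elevated).
- **A forward pedigree simulator** (`hapshare.simdata`) with migration,
  admixture, cousin marriage, genotype/phase error and *exact* ground-truth
  IBD, so every stage above is validated against truth.

`docs/methods.md` gives the full model descriptions, parameter defaults and
numerical conventions.

## Worked example

```python
import numpy as np
import pandas as pd
from hapshare import community, demography, ibd, paint, simdata

# three populations of 100 diploids drifting apart for 20 generations,
# exchanging 0.1% of matings per generation; 2 chromosomes of 100 cM
mig = np.full((3, 3), 0.0005)
np.fill_diagonal(mig, 0.999)
cfg = simdata.SimConfig(
    n_subpops=3, size_per_generation=100, migration=mig, n_generations=20,
    chromosomes=((100.0, 2000, 100_000_000),) * 2, seed=42,
)
sim = simdata.simulate(cfg)

# chunk painting -> coancestry network -> recursive Leiden
coan = paint.paint_panel(sim.panel, paint.PaintConfig(seed=42))
tree = community.leiden_recursive(community.build_graph(coan), min_size=20, seed=42)
assign = tree.assignment().reindex(sim.panel.individuals)
print(pd.crosstab(sim.labels, assign))

# IBD segments and the recent effective size of one cluster
seg = ibd.merge_ibd(ibd.detect_ibd(sim.panel, min_cM=1.0), sim.panel)
members = list(assign.index[assign == assign.iloc[0]])
within = seg[seg.id_a.isin(members) & seg.id_b.isin(members)]
spec = demography.SegmentSpectrum.from_segments(within, members, [100.0, 100.0])
traj = demography.fit_ne(spec, G=20, n_bootstrap=25, seed=42)
print(traj.at((5, 15)).round(0))
```

prints

```
cluster    0    1   2
subpop
pop0     100    0   0
pop1       0  100   0
pop2       1    0  99
   generation    ne  lo95   hi95
0           5  83.0  18.0  385.0
1          15  97.0  57.0  166.0
```

The Leiden leaves recover the three simulated populations (one migrant
individual lands in a neighbouring cluster), and the IBD length spectrum of
cluster 0 recovers the simulated diploid size of 100 (point estimates 83 and
97 at 5 and 15 generations ago, truth inside the 95% bands).

## Command line

```bash
hapshare simulate --subpops 3 --size 60 --generations 20 --outdir data/
hapshare all --config run.yaml --seed 1 --outdir run/      # full pipeline
hapshare paint --vcf data/panel.vcf --map data/sites.map --outdir paint/
hapshare cluster --chunkcounts paint/chunkcounts.tsv --outdir clust/ \
    --edge-low 2 --edge-high 25 --min-community 100
hapshare ibd --vcf data/panel.vcf --map data/sites.map --out segments.tsv
hapshare ne --segments segments.tsv --clusters clust/clusters.tsv \
    --map data/sites.map --outdir ne/
hapshare roh --vcf data/panel.vcf --outdir roh/
```

Real-data inputs are a phased VCF (GT with `|`), a PLINK `.map` genetic map
and an optional sample-label TSV.  All stage seeds derive from the single
`--seed`, so reruns are bit-identical.

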
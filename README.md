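# tmtnet

Deep isobaric-tag (TMT) proteomic network analysis of brain tissue, with a
proteogenomic pipeline for detecting alternative splicing at the protein
level.

## The scientific problem

Bulk proteomics of post-mortem brain in Alzheimer's disease (AD) compares
three case groups — cognitively normal controls, asymptomatic AD (AsymAD:
plaque and tangle pathology without dementia), and symptomatic AD — across
pooled multiplexed TMT batches. Turning reporter-ion intensities into
biology requires a chain of statistical machinery that this package
implements as a tested, reusable library:

1. **Proteogenomic junction databases** (`tmtnet.junctions`). Exon–exon
   junctions supported by ≥ 2 gapped RNA-seq reads with ≥ 4 nt exonic
   overlap on each side are summarized, and junctions that share a donor
   (5′) or acceptor (3′) end with another junction — evidence of an
   alternative splicing decision — are translated and digested in silico
   with LysC \[K|P\] (cleavage C-terminal to lysine, including Lys-Pro
   bonds, with and without miscleavage at proline). Peptides that span the
   junction with at least one residue fully encoded on each side, and that
   are not 100% homologous to another genomic locus or to a canonical
   digestion product, are appended to the protein search database as
   alternative exon–exon junction (alt-EEjxn) peptide entries.
2. **TMT normalization** (`tmtnet.normalize`). Each batch carries a pooled
   global internal standard (GIS) in one reporter channel; abundances are
   log₂(sample/GIS) ratios. Ratios at or beyond 100-fold
   (|log₂ ratio| ≥ log₂ 100 ≈ 6.64) are excluded as extreme outliers;
   features unquantifiable (GIS = 0/NA) in more than 4 of 8 batches, or
   missing in more than 23 of 47 samples (< 50%), are dropped. The peptide
   path additionally sums PTM-modified forms of a base peptide on linear
   scale and rescales batches to a common GIS mean. Missing values are
   never imputed.
3. **Cell-type deconvolution and covariate regression** (`tmtnet.deconv`).
   Per-sample weights for microglia, astrocytes, neurons and
   oligodendroglia are estimated digital-sorting style: complete-case
   marker proteins are fit against a pure-cell-type reference profile by
   non-negative least squares and row-normalized. Age, sex, post-mortem
   interval (and optionally the cell-type weights, in a two-pass scheme)
   are removed per feature by 1000-iteration nonparametric bootstrap
   regression of `value ~ covariates + group`; only the covariate
   components, evaluated at centered covariates, are subtracted — the
   disease-group term is modeled but never removed.
4. **Weighted protein correlation network analysis** (`tmtnet.network`).
   A signed network with biweight midcorrelation (bicor), adjacency
   a<sub>ij</sub> = ((1 + r<sub>ij</sub>)/2)<sup>β</sup> with β chosen as
   the lowest power reaching scale-free fit R² ≈ 0.80 (the study value is
   β = 8.0), topological overlap with the mean-connectivity denominator,
   module detection (minModuleSize 17, mergeCutHeight 0.07, deepSplit 2,
   PAM-style kME reassignment), first-PC eigenproteins, kME, and
   module–trait correlations (bicor; Spearman for MMSE).
5. **Differential abundance and enrichment** (`tmtnet.stats`). One-way
   ANOVA with Tukey(-Kramer) post hoc across the three groups,
   hypergeometric/Fisher set enrichment with Benjamini–Hochberg FDR,
   the alt-EEjxn quantifiability rule (≥ 2 measurements in ≥ 2 case
   groups), kME assignment of junction peptides to network modules
   (≤ 25 of 47 missing values allowed), and cross-network module overlap.
6. **Synthetic cohorts** (`tmtnet.synthetic`). A first-class generator
   emulating the study design — 47 samples (13 control / 14 AsymAD /
   20 AD) in 8 TMT 10-plex batches with a GIS channel — with planted group
   effects, covariate slopes, cell-type mixing, module structure, batch
   effects, missing values and PTM-split rows, all with ground truth, so
   every stage is testable without external data.

## Worked example

```python
from tmtnet import gen_tmt_cohort, normalize_protein_batches, build_network
from tmtnet.config import CohortDesign, NetworkParams

design = CohortDesign(n_features=300, ptm_split_fraction=0.0)
cohort = gen_tmt_cohort(design, seed=1)
matrix, excluded = normalize_protein_batches(cohort.batches, groups=cohort.groups)
print(f"abundance matrix: {matrix.values.shape[0]} features x {matrix.values.shape[1]} samples")

net = build_network(matrix.values, NetworkParams(), traits=cohort.traits)
print("module sizes:", net.module_sizes().to_dict())
mt = net.module_trait.set_index(["module", "trait"])
for trait in ("CERAD", "Braak", "MMSE"):
    row = mt.loc[("M1", trait)]
    print(f"M1 vs {trait}: rho={row['rho']:+.2f}  p={row['p']:.1e}  ({row['method']})")
```

prints

```
abundance matrix: 300 features x 47 samples
module sizes: {'M1': 103, 'grey': 61, 'M2': 49, 'M3': 45, 'M4': 42}
M1 vs CERAD: rho=+0.79  p=2.8e-11  (bicor)
M1 vs Braak: rho=+0.82  p=2.7e-12  (bicor)
M1 vs MMSE: rho=-0.76  p=4.2e-10  (spearman)
```

The generator plants one pathology-tracking module; the network recovers
it as M1, whose eigenprotein correlates positively with neuritic plaque
burden (CERAD) and tangle spread (Braak) and negatively with cognition
(MMSE, 0–30) — the signature expected of a disease-associated module.

The same pipeline is available from the shell:

```sh
tmtnet simulate --seed 1 --out run/
tmtnet build-db --genome-fasta run/genome.fasta --gff3 run/genes.gff3 \
    --evidence run/junction_evidence.tsv --out run/searchdb.fasta
tmtnet normalize --in run/ --out run/abundance.tsv
tmtnet deconvolve --abundance run/abundance.tsv --covariates run/covariates.tsv \
    --reference run/cell_reference.tsv --out run/deconv/
tmtnet network --abundance run/deconv/regressed.tsv --traits run/traits.tsv --out run/net/
tmtnet diffexp --abundance run/deconv/regressed.tsv --covariates run/covariates.tsv \
    --out run/diffexp.tsv
tmtnet report --network-dir run/net --diffexp run/diffexp.tsv
```

Every subcommand writes a JSON manifest recording parameters, seed,
versions and the counts at each filter step.

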
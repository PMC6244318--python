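# rfinet

Integrative miRNA–mRNA co-expression network analysis for residual feed
intake (RFI) in livestock transcriptomics.

Residual feed intake — the difference between an animal's observed and
expected feed intake — is an economically central feed-efficiency trait in
beef cattle. One proposed regulatory layer behind its variation is
post-transcriptional control by microRNAs, which repress target mRNAs by
pairing their seed region (positions 2–8) to sites in the 3′UTR. `rfinet`
implements, as a tested reusable library, the analysis workflow used to
interrogate that layer in bulk skeletal-muscle and liver expression data
from animals genetically divergent for RFI:

1. **Phenotypes** — rank animals by BLUP of genetic merit for RFI, select
   divergent tails (feed-efficient = low RFI, feed-inefficient = high RFI),
   and compare group phenotypes by Student's t-test.
2. **Differential miRNA expression** — negative-binomial counts with
   Var = μ + αμ², median-of-ratios size factors, moderated method-of-moments
   dispersions, and a Wald test of log₂(μ_eff/μ_ineff) with
   Benjamini–Hochberg FDR (threshold 0.10), run on the extreme 4-vs-4
   subset.
3. **Target prediction** — canonical seed sites (8mer, 7mer-m8, 7mer-A1,
   6mer) scanned on 3′UTRs, plus a Smith–Waterman-style local
   complementarity alignment with G:U wobbles and a double-weighted seed
   region; by default a target needs both kinds of evidence and must be
   expressed.
4. **Co-expression networks** (per RFI group, per data type) — the WGCNA
   recipe: Pearson correlation, soft-threshold adjacency `a = |r|^β` with
   β = 6, topological overlap (TOM), average-linkage clustering of 1−TOM,
   module detection with minimum sizes 5 (miRNA) / 30 (mRNA), eigengene
   merge height 0.25, module eigengenes (first PC of the standardized
   member expression) and module membership kME.
5. **Integration** — module eigengene vs RFI correlation (selected at
   p < 0.10), the full bipartite miRNA-ME × mRNA-ME correlation with
   negative pairs selected at p < 0.10, top-5 hub miRNAs per module by kME,
   and the overlap of hub-miRNA targets with the correlated mRNA module's
   genes.
6. **Enrichment** — hypergeometric over-representation analysis of gene
   lists against GMT gene sets with BH-FDR.

Because the original animal data cannot be bundled, the package ships a
**synthetic-data generator** (`rfinet.simulate`) that reproduces the
statistical shape of the study — NB counts, latent-signal co-expression
modules, hub miRNAs anti-correlated with target mRNA modules, a module-driven
RFI trait, planted DE miRNAs and planted 3′UTR target sites — together with
a ground-truth manifest, so the entire pipeline is testable end to end by
planted-structure recovery.

## Worked example

```python
from rfinet.simulate import SimulationConfig, simulate_dataset
from rfinet.preprocess import (filter_counts, size_factors,
                               normalize_counts, log_transform_for_network)
from rfinet.coexpression import CoexpressionNetwork, NetworkParams
from rfinet.integration import module_trait_correlation, cross_me_correlation
from rfinet.phenotypes import FEED_EFFICIENT

cfg = SimulationConfig(rng_seed=42)
counts_mir, counts_mrna, phen, utrs, mirna_seqs, gene_sets, truth = simulate_dataset(cfg)
eff = list(phen.loc[phen.group == FEED_EFFICIENT, "animal_id"])

nets = {}
for dt, counts, min_size in (("mirna", counts_mir, 5), ("mrna", counts_mrna, 30)):
    sub = filter_counts(counts[eff])
    norm = normalize_counts(sub, size_factors(sub))
    logx, kept = log_transform_for_network(norm)
    nets[dt] = CoexpressionNetwork(logx[kept],
                                   NetworkParams(min_module_size=min_size)).fit()
print(nets["mirna"].summary())
```

```
Weighted co-expression network
features: 150, samples: 10
soft threshold beta: 6 (unsigned)
modules: 4 (grey/unassigned: 114)
  turquoise      size    14  var explained 0.85
  blue           size     8  var explained 0.88
  brown          size     8  var explained 0.85
  yellow         size     6  var explained 0.85
```

Four miRNA modules are detected among the 150 miRNAs of the feed-efficient
group (the generator planted four); each eigengene explains ≥ 85% of its
module's standardized variance. Relating the eigengenes to RFI and to the
mRNA modules:

```python
rfi = phen.set_index("animal_id").loc[eff, "rfi"]
print(module_trait_correlation(nets["mirna"].eigengenes, rfi))
cross = cross_me_correlation(nets["mirna"].eigengenes, nets["mrna"].eigengenes)
print(cross[cross.selected])
```

```
   module         r        p  n  selected
     blue  0.797843 0.005679 10      True
    brown -0.281529 0.430689 10     False
turquoise  0.289453 0.417257 10     False
   yellow  0.461863 0.179011 10     False

mirna_module mrna_module         r        p  selected
        blue       green -0.872838 0.000978      True
       brown   turquoise -0.906982 0.000292      True
   turquoise       brown -0.829699 0.002980      True
      yellow      yellow -0.845099 0.002080      True
```

The module the generator tied to the trait ("blue", r = 0.80, p = 0.006) is
the one selected at p < 0.10, and all four planted miRNA→mRNA module
couplings (planted at −0.8) surface as selected negative pairs with r
between −0.83 and −0.91. Differential expression, target prediction, hub
selection, overlaps and ORA run the same way; `rfinet run-all --config
config.yaml` executes the whole pipeline and writes every stage's TSV plus
a run manifest and, when a truth manifest is supplied, a recovery report.

The published 20-animal Nelore phenotype table is bundled
(`rfinet.datasets.nelore_phenotypes()`): the feed-efficient and
feed-inefficient group means reproduce the published −0.6832 and
0.5296 kg/day RFI values, RFI differs between groups (Student's t,
p = 5.4e-05) while intramuscular fat does not (p = 0.53).

## Command line

```
rfinet simulate | preprocess | de | targets | network | relate | integrate | enrich | run-all
```

Every analysis threshold (β, minimum module sizes, merge height, DE FDR,
selection α, alignment scoring) is a flag or a YAML config key; defaults
follow the study design.

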
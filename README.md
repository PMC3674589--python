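# coexnet

Signed weighted gene co-expression network analysis with cross-species
module preservation, built for the kind of study design used in autoimmune
exocrinopathy research: a human cohort (healthy controls, sicca patients
with dryness symptoms, and patients with primary Sjögren's-like disease)
profiled cross-sectionally, and a spontaneous mouse disease model profiled
as a time course. The package asks two questions: *which groups of
co-expressed genes track disease in the human gland?* and *does the mouse
model reproduce the internal structure of those gene groups?*

Because real cohort data of this kind are rarely publicly deposited, the
package ships a first-class synthetic-data generator with planted ground
truth (modules, trait effects, cross-species preservation, batches,
redundant probes), so every stage of the analysis can be verified against
what was planted.

## The model and statistics

**Network.** From a genes × samples expression matrix, pairwise Pearson
correlations are soft-thresholded into a *signed* adjacency

&nbsp;&nbsp;&nbsp;&nbsp;*a<sub>ij</sub>* = ((1 + cor(*x<sub>i</sub>*, *x<sub>j</sub>*)) / 2)<sup>β</sup>,&nbsp;&nbsp;β = 12 by default,

so anti-correlated genes receive near-zero adjacency. The clustering
dissimilarity is 1 − TOM, where the topological overlap

&nbsp;&nbsp;&nbsp;&nbsp;TOM<sub>ij</sub> = (Σ<sub>u≠i,j</sub> *a<sub>iu</sub>a<sub>uj</sub>* + *a<sub>ij</sub>*) / (min(*k<sub>i</sub>*, *k<sub>j</sub>*) + 1 − *a<sub>ij</sub>*)

rewards shared network neighbours. Modules are branches of the
average-linkage tree found by a dynamic branch cut (with a hybrid stage for
borderline genes); unassigned genes are labelled `grey`, and modules get
conventional color names in decreasing size order. A blockwise mode handles
gene counts too large for one dissimilarity matrix.

**Module summaries.** Each module is summarized by its eigengene (first
principal component of the standardized module submatrix); module
membership MM(*i*) = cor(*x<sub>i</sub>*, ME) measures how central a gene
is. Modules are related to disease by cor(ME, progression) with progression
coded 0 = control, 1 = sicca, 2 = disease (standardized week for the
mouse), with Bonferroni adjustment over modules and a Kruskal–Wallis group
test reported side by side.

**Preservation.** Human-defined modules are evaluated in the mouse data
(after 1:1 ortholog mapping) by density statistics (mean within-module
correlation, adjacency, kME) and connectivity statistics (reference-vs-test
correlations of intramodular connectivity, kME, and the within-module
correlation structure). Each statistic is standardized against a
permutation null (random gene sets of the module's size), median-combined
into Z<sub>density</sub> and Z<sub>connectivity</sub>, and averaged into
**Zsummary**; Zsummary > 10 indicates strong preservation, < 2 none.
**medianRank** gives a size-insensitive rank composite (1 = most
preserved).

**Screening and enrichment.** Per-gene tables mirror standard differential
screening output (Welch *t*, *p*, BH *q*, signed fold change, AUROC, group
means/SEs, correlations with progression or time), cross-species concordant
genes are selected by requiring |cor| ≥ 0.5 with progression in *both*
species with matching sign, and module gene lists are tested for gene-set
over-representation with the hypergeometric upper-tail test against GMT
collections.

## Worked example

```python
from coexnet import (SyntheticDesign, simulate_species_pair,
                     blockwise_modules, module_preservation)
from coexnet.preprocess import map_orthologs
from coexnet.modulestats import module_eigengenes, module_trait_table
from coexnet.synthdata import human_trait_coding

design = SyntheticDesign()          # ~1,000 genes, 65 human / 25 mouse samples
human, mouse, orthologs = simulate_species_pair(design, seed=1)

modules = blockwise_modules(human["expr"], beta=12, min_module_size=30)
print(modules.value_counts().to_string())

mes, _ = module_eigengenes(human["expr"], modules)
table = module_trait_table(mes, human_trait_coding(human["meta"]),
                           groups=human["meta"]["group"])
print(table.round(4).to_string())

mouse_expr = map_orthologs(mouse["expr"], orthologs)
pres = module_preservation(human["expr"], modules, mouse_expr, n_perm=200, seed=1)
print(pres[["size", "Zdensity", "Zconnectivity", "Zsummary", "medianRank"]]
      .round(2).to_string())
```

Output:

```
module
grey         664
turquoise    104
blue          81
brown         61
yellow        50
green         40
                r       p  p_bonferroni  kruskal_H  kruskal_p
module
blue      -0.5238  0.0000           0.0    16.9612     0.0002
brown      0.1376  0.2745           1.0     6.1203     0.0469
green     -0.0276  0.8270           1.0     1.2054     0.5473
grey       0.0325  0.7970           1.0     0.5590     0.7562
turquoise  0.7122  0.0000           0.0    32.6996     0.0000
yellow    -0.0556  0.6598           1.0     3.3375     0.1885
           size  Zdensity  Zconnectivity  Zsummary  medianRank
module
blue         81     -0.64          -0.43     -0.53         4.0
brown        61     -0.30           0.51      0.10         3.0
green        40     -1.86           0.34     -0.76         5.0
turquoise   104     41.73           8.41     25.07         1.0
yellow       50     -0.31          -1.01     -0.66         3.0
```

Reading this: the generator planted six modules, two of them
disease-linked — one with a positive effect that is also preserved in the
mouse, one with a negative effect that is not. Detection recovers the five
largest (the smallest, 30 genes, fell below the branch criteria at this
seed and stayed grey). The disease-linked pair surfaces as `turquoise`
(*r* = 0.71 with progression) and `blue` (*r* = −0.52), both surviving
Bonferroni. In the mouse data only `turquoise` is preserved
(Zsummary = 25.1 > 10, medianRank 1); every scrambled module sits below the
Zsummary = 2 no-preservation line — exactly the planted structure.

The same analysis runs from the shell:

```bash
coexnet pipeline --outdir results/run --seed 0
```

which writes expression/metadata inputs, module assignments, eigengenes,
module–trait tables, preservation statistics, screening tables, the
concordant-gene table, enrichment results and a JSON run manifest; reruns
with the same seed are byte-identical.

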
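# orthovar

Gene-level decomposition of expression variation across organs and species.

When the same panel of organs is profiled by RNA-seq in several species, a
long-standing question is whether whole transcriptomes cluster by organ or
by species. `orthovar` answers this per gene rather than per transcriptome:
for every one-to-one ortholog it splits the expression variance into an
organ component, a species component, and residual noise, and it quantifies
the global clustering question with an objective network statistic instead
of visual inspection of a PCA.

The package is aimed at comparative transcriptomics: a balanced matrix of
linear-scale expression (cRPKM/RPKM) over a complete organ × species grid
(for example 6 organs × 7 vertebrates = 42 samples), analysed on
log10(x + 0.01) values.

## The model

For one gene, expression in organ *i* and species *j* is modelled
additively,

    y_ij = μ + org_i + spc_j + ε_ij ,

and on a balanced grid the total sum of squares about the grand mean splits
exactly (no fitting involved):

    SST = SSO + SSS + SSR
    SSO = n_s Σ_i (ȳ_i· − ȳ··)²      organ component
    SSS = n_o Σ_j (ȳ_·j − ȳ··)²      species component
    SSR = Σ_ij (y_ij − ȳ_i· − ȳ_·j + ȳ··)²

The proportions p_o = SSO/SST, p_s = SSS/SST, p_r = SSR/SST are the
per-gene relative contributions. Genes whose dynamic range (orders of
magnitude between max and min expression, pseudocount added) is below 2 are
*constrained*; among the rest, genes with p_o + p_s ≥ 0.75 are
tissue-variable (TVG) when p_o ≥ 2·p_s and species-variable (SVG) when
p_s ≥ 2·p_o.

Three companion analyses complete the pipeline:

* **Network modularity** — samples are nodes, edges join sample pairs whose
  Pearson correlation exceeds a threshold, and Newman's
  Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j) is compared between the
  organ labeling and the species labeling across network densities.
* **Projection score** — gene subsets nested by variance are scored by the
  gain in the fraction of variance captured by the first *d* principal
  components over within-gene permutation nulls; the best-scoring subset is
  the one driving the sample separation.
* **Simulator** — genes drawn from a TVG-like / SVG-like / balanced /
  constrained mixture, with species effects evolved as Brownian motion
  along a phylogeny, so every stage can be validated against known ground
  truth.

## Worked example

```python
from orthovar import (
    sample_gene_params, simulate_expression, log_transform,
    decompose_all, classify_genes, sample_correlations, modularity_curve,
)
from orthovar.synthetic_data import default_design, default_species_tree
from orthovar.variance_decomposition import dynamic_ranges, mean_proportions

design = default_design()                      # 6 organs x 7 species
params = sample_gene_params(2000, seed=0)      # TVG/SVG/balanced/constrained mix
matrix, truth = simulate_expression(design, params,
                                    tree=default_species_tree(), seed=1)

logmat = log_transform(matrix)                 # log10(cRPKM + 0.01)
decomp = decompose_all(logmat)
print(mean_proportions(decomp))

classes = classify_genes(decomp, dynamic_ranges(matrix.values))
print(classes["gene_class"].value_counts().to_dict())

corr = sample_correlations(logmat)
curve = modularity_curve(corr, design.organ_of(), design.species_of(),
                         edge_grid=[50, 150, 290, 500])
print(curve.round(3).to_string(index=False))
```

prints

```
{'mean_p_o': 0.5374679667157238, 'mean_p_s': 0.34498115791851364,
 'mean_p_r': 0.11755087536576243, 'n_zero_variance': 0}
{'TVG': 772, 'constrained': 628, 'SVG': 420, 'other_unconstrained': 180}
 threshold  edges  density  Q_organ  Q_species
     0.843     50    0.058    0.830     -0.206
     0.623    150    0.174    0.672     -0.004
     0.582    290    0.337    0.268      0.207
     0.455    500    0.581    0.085      0.054
```

Organ and species together explain ~88% of the mean per-gene variance, with
organ dominating (0.54 vs 0.34) — the mixture contains more organ-driven
genes — and the modularity curve agrees: at every network density the
organ grouping has higher Q than the species grouping.

The same stages are available from the shell:

```sh
orthovar simulate --n-genes 2000 --seed 0 --out sim/
orthovar full --matrix sim/matrix.tsv --samples sim/samples.tsv --out run/
```

`full` chains decompose → classify → modularity → projscore → cluster and
writes TSV/JSON artifacts plus a reproducibility manifest per stage.

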
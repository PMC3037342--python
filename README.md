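# corrbic — correlation-based Scatter Search biclustering

`corrbic` finds **biclusters** in gene expression matrices: subsets of genes
that are co-expressed over a subset of experimental conditions.  It targets
the pattern class that the classic mean-squared-residue (MSR) criterion
misses — **shifting-and-scaling patterns**, where two genes are related by

```
g_Y = α · g_X + β        (α > 0)
```

i.e. the same behaviour at different magnitudes.  Such genes are perfectly
positively linearly correlated, so the search scores a candidate bicluster
`B` with `nG` genes and `nC` conditions by its average pairwise Pearson
correlation

```
ρ(B) = ( Σ_{i<j} ρ(g_i, g_j) ) / C(nG, 2)
```

(computed over the bicluster's selected conditions) and minimises the fitness

```
f(B) = (1 − ρ(B)) + σ_ρ + M1/nG + M2/nC
```

where `σ_ρ` is the standard deviation of the pairwise coefficients (a high
mean must not hide uncorrelated members) and `M1`, `M2` are volume
penalties: raise them to obtain larger biclusters.

Optimisation uses **Scatter Search**: a population of binary-encoded
biclusters (length `N + L` bit strings: genes then conditions) is built by a
deterministic diversification rule, every candidate is repaired by an
**improvement method** that removes genes not positively correlated with
the genes already kept, and a small reference set — half best-by-fitness,
half most-scattered by Hamming distance — evolves by uniform crossover of
all member pairs until stable, then is rebuilt for diversity.  The whole
search is repeated `numBi` times and the best bicluster of each repetition
is reported, together with ρ(B), σ_ρ, MSR, gene variance and volume.

A synthetic-data module generates matrices with implanted
shifting-and-scaling biclusters and ground truth, so every stage is
testable without external data.

## Worked example

```python
import numpy as np
import corrbic as cb

# a 50x20 matrix with a hidden noiseless 8x6 shifting-and-scaling implant
matrix, truth = cb.make_matrix(50, 20, [cb.ImplantSpec(8, 6)],
                               rng=np.random.default_rng(7))

config = cb.SearchConfig(num_biclusters=5)          # numIter=20, S=10, pop=200
results = cb.run(matrix, config, np.random.default_rng(7))
for r in cb.records_from_biclusters(results, matrix, config):
    print(f"{r.bicluster_id}: {r.n_genes} genes x {r.n_conditions} conditions, "
          f"rho={r.avg_corr:.3f} sd={r.corr_sd:.3f} fitness={r.fitness:.3f}")
```

prints

```
bi1: 6 genes x 7 conditions, rho=0.905 sd=0.027 fitness=0.431
bi2: 7 genes x 6 conditions, rho=1.000 sd=0.000 fitness=0.310
bi3: 6 genes x 6 conditions, rho=1.000 sd=0.000 fitness=0.333
bi4: 5 genes x 6 conditions, rho=1.000 sd=0.000 fitness=0.367
bi5: 7 genes x 3 conditions, rho=0.978 sd=0.021 fitness=0.518
```

The best repetition (`bi2`, lowest fitness) contains 7 of the 8 implanted
genes over exactly the 6 implanted conditions — perfect correlation
(`rho=1.000`, `sd=0.000`) at a cell-level Jaccard overlap of 0.875 with the
ground truth.  `bi5` shows the typical alternative the fitness has to beat:
a small chance-correlated gene group over very few conditions.

The same workflow from the shell:

```
corrbic simulate --genes 50 --conditions 20 --seed 7 --output synthetic.tsv --truth truth.tsv
corrbic run --input synthetic.tsv --num-biclusters 5 --seed 7 --output results.tsv
```

`results.tsv` carries one row per bicluster (genes, conditions, volume,
ρ(B), σ_ρ, fitness, MSR, gene variance) and a closing row of column means.

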
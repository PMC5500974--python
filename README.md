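# epiaco

Ant-colony-optimization search for **epistatic interactions** — joint
multi-SNP effects on a binary disease phenotype that single-marker tests
miss — in case-control genotype data. The package bundles three things:

1. **The search engine**: an ant colony that proposes K-SNP combinations,
   scores them, and reinforces per-SNP pheromones, with a cross-iteration
   memory of candidate solutions.
2. **A disease-model simulator**: two-locus penetrance models (five
   benchmark models built in, custom models via YAML) and a case-control
   genotype simulator with Hardy-Weinberg background SNPs.
3. **A power-evaluation harness** that measures detection power over
   batches of simulated datasets.

## The statistic

A combination `S` of K SNPs (each with genotypes coded 0/1/2) is scored
against the phenotype `Y ∈ {0, 1}` by the **Svalue**

```
Svalue(S) = MI(S; Y) / K2log(S)
```

where `MI(S; Y) = H(S) + H(Y) − H(S, Y)` is the plug-in mutual information
(natural log) of the 3^K × 2 contingency table, and

```
K2log(S) = Σ_i [ Σ_{b=1..r_i+1} log b − Σ_j Σ_{d=1..r_ij} log d ]
```

is the logarithmic K2 Bayesian-network score of the model in which the K
SNPs are parents of the phenotype node (`r_ij` = samples with genotype
combination `i` and phenotype `j`, `r_i` = row total). MI grows and K2log
shrinks with association strength, so higher Svalue ⇔ stronger association.

Each of `m` ants builds a combination SNP-by-SNP. A fresh uniform draw `q`
is compared with `q0 = t/T` (iteration over total): `q ≤ q0` selects by
roulette wheel over `τ_i^α η_i^β` (exploitation), otherwise uniformly from
the half of the SNPs with the lowest pheromones (exploration). Pheromones
evaporate at rate `ρ` and are reinforced by the (scale-normalized) Svalue of
every combination evaluated, with an extra factor `ξ` for combinations in
the candidate memory. Per iteration, the descending Svalue curve is cut at
its second-difference inflection point and the survivors are merged into
the memory, so the best solution found is never lost.

## Worked example

```sh
# simulate one dataset: benchmark Model 1, 100 SNPs, 2000 cases/controls
epiaco simulate --model 1 --n-snps 100 --seed 42 --out-dir data/

# search it (defaults: 200 ants, 25 iterations, rho 0.2, xi 0.3)
epiaco search --input data/dataset_000.txt --seed 7 --out result.tsv
```

which prints

```
top combination: ['SNP20', 'SNP78'] svalue=4.61273e-06
```

and `data/dataset_000.txt.truth.json` confirms the embedded disease pair is
`[20, 78]`: the search recovered the planted interaction. `result.tsv` holds
the ranked candidate memory — one row per candidate with its mutual
information (`mi`), log-K2 score (`k2_log`), `svalue`, and the chi-square
statistic and p-value of its 9 × 2 genotype-by-phenotype table. The same
run from Python:

```python
from epiaco import AcoParams, get_model, run_epiaco, simulate_dataset

ds = simulate_dataset(get_model(1), n_snps=100, seed=42)
result = run_epiaco(ds, AcoParams(seed=7))
print(result.top.snps, result.top.svalue)   # (7, 26) 4.225e-06
```

Detection power (fraction of simulated datasets whose planted pair is the
top-ranked candidate) over 20 datasets:

```sh
epiaco power --model 1 --n-datasets 20 --seed 0 --out power.csv
# power: 100.00% (run dispersion 0.00%)
```

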
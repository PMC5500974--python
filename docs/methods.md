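# Methods

## Problem and model

Case-control epistasis detection: given `n` samples genotyped at `p` SNPs
(three genotype classes: homozygous common = 0, heterozygous = 1, homozygous
minor = 2) and a binary phenotype, find the K-SNP combination whose joint
genotype is most associated with disease. Exhaustive scanning is quadratic
(or worse) in `p`; the colony search trades completeness for a budget of
`m × T` evaluations guided by per-SNP pheromones.

## Disease models and simulation

An `EpistasisModel` is a vector of minor-allele frequencies (MAFs) plus a
`3^K` penetrance table `P(disease | genotype combination)`. Genotype
frequencies follow Hardy-Weinberg equilibrium (HWE): `(1−p)², 2p(1−p), p²`.
Prevalence is the HWE-weighted penetrance sum. Five benchmark two-locus
models are built in; Models 1–2 carry marginal effects (ME), Models 3–5 are
interaction-only (NME). Two of the published tables are internally
inconsistent: Model 2's penetrance rows imply prevalence ≈ 0.201 (stated:
0.050) and Model 5's imply 0.025 (stated: 0.010). The penetrance tables are
treated as authoritative; the stated prevalences of Models 1, 3 and 4 are
reproduced to three decimals and those two models are flagged in the code.

The simulator draws disease-SNP genotypes *conditionally on status* by
exact Bayes inversion: `P(g | case) ∝ P_HWE(g)·pen(g)`, and
`P(g | control) ∝ P_HWE(g)·(1−pen(g))`, sampled categorically. This is
exact and needs no rejection cap. Background SNPs get one MAF each, drawn
uniformly from [0.05, 0.5] (the benchmark convention; configurable) and HWE
genotypes independent of phenotype. Disease SNPs are placed at random
columns, recorded in a `truth` field (and a JSON sidecar on disk). Default
scale: 2000 cases, 2000 controls, 100 SNPs.

A separate forward sampler (`simulate_cohort`: genotypes first, then a
Bernoulli disease draw per penetrance cell) provides an independent oracle;
tests verify the two routes agree.

What the generator does **not** emulate: linkage disequilibrium, population
structure, genotyping error or missingness, quantitative phenotypes. Power
estimates here therefore speak to the idealized benchmark setting, not to
field data with correlated markers.

## Scores

All scores are pure functions of the `3^K × 2` contingency table (rows in
mixed-radix genotype order, last SNP fastest). Natural logarithms are used
throughout — the paper-standard "log" base cancels in rankings and natural
log matches the log-gamma numerics. Conventions: `0·log 0 = 0`; the log-K2
score is computed as `Σ gammaln(r_i+2) − Σ gammaln(r_ij+1)`, which equals
the negative log of the exact factorial product (verified against exact
rational arithmetic to < 1e−9 on 10⁴ random tables). The Svalue is
`MI / K2log` with a guard: if `K2log < 1e−12` (only near-empty tables), the
Svalue is 0 when MI = 0 and `MI / 1e−12` otherwise, preserving order
without dividing by zero. Chi-square tests for final reporting drop
zero-count genotype rows, giving df = (occupied rows − 1); degenerate
tables return p = 1.

## Colony search

Parameters (defaults follow the benchmark settings): `m = 200` ants,
`T = 25` iterations, order `K = 2`, `α = β = 1`, evaporation `ρ = 0.2`,
candidate reward `ξ = 0.3`, `τ0 = η = 1`. The iteration index is 1-based so
the exploitation threshold `q0 = t/T` reaches exactly 1 at the last
iteration. A fresh `q` is drawn per SNP choice (a one-q-per-ant switch
exists). The stochastic rule's pool is the `⌊p/2⌋` SNPs with the lowest
pheromones, ties broken by ascending index, intersected with the ant's
available set, with a uniform fallback if the intersection is empty.

**Deposit normalization.** The raw Svalue scales like
`MI / (n·H(Y|S))` ≈ 10⁻⁶ at n = 4000, while `τ0 = 1`: literal deposits are
numerically invisible against evaporation, the pheromone field stays
essentially uniform for 25 iterations, and the search degenerates to
near-random sampling (measured: Model 1 detection collapses to ~30%).
`run_epiaco` therefore divides every deposit by `m × (iteration-best
Svalue)`, which keeps the colony's total per-iteration deposit on the τ0
scale regardless of sample size and restores the intended
exploration-to-convergence behavior (Model 1 detection 100% at the default
design). The update rule itself (`update_pheromones`) implements the
literal evaporation + Svalue + ξ-reward form; normalization is a
`deposit_normalization` parameter (`"colony"` default, `"iteration_max"`,
or literal `"none"`).

**Memory.** Each iteration's unique solutions are ranked by descending
Svalue (ties by ascending index tuple) and cut at the inflection point
`f = argmax_{g≥3}` of the second difference of the score curve (smallest g
on ties; lists shorter than 3 are kept whole). Survivors are unioned with
the previous memory, re-ranked, and re-cut. The memory's best Svalue is
therefore non-decreasing; the memory update precedes the pheromone update
so the ξ-reward sees the current iteration's candidates. Duplicate
combinations among ants are deduplicated for the memory but each ant still
deposits pheromone. Scores are cached per run, so re-proposed combinations
are free.

**Detection call.** A run "perfectly identifies" the planted interaction
when the top-ranked candidate of the final memory equals the ground-truth
pair (strictest reading; a lenient "candidates" mode — truth present and
every candidate truth-overlapping — is available). Power is the percentage
of datasets detected; with multiple runs per dataset the default
aggregation is majority (mean is available).

## Reference experiment scales

The power experiments default to 20 datasets × 1 run (and 5 datasets at
the 1000-SNP design, 40 runs for the oracle-agreement check), chosen to
keep a full reproduction in the minutes range on one CPU; the full
100 × 20 design of the original study is available through the same API by
raising `n_datasets`/`runs_per_dataset`. At 20 datasets the binomial
standard error of a ~75% power estimate is ~10 percentage points.

## Known limitations

- **NME detection power.** In every simulated NME dataset examined, the
  true pair is the global Svalue argmax, so a run succeeds exactly when it
  *evaluates* the true pair. For interaction-only models no single-SNP
  signal exists, and the node-level pheromone architecture cannot steer
  toward an unseen pair: its distinct-pair coverage at the default budget
  (5000 evaluations over 4950 pairs) measures ~63%, close to uniform
  sampling with replacement. Measured NME powers (~60–70%) sit accordingly
  below the ~75–82% reported for the original implementation, whose
  internals are not public; the ME-model results (where marginal effects do
  guide pheromones) reproduce in full.
- K > 2 is supported throughout but validated only at K = 2.
- Reported chi-square p-values carry no multiple-testing correction (by
  design, matching the reference reporting).
- No support for missing genotypes — files with codes outside the dialect
  raise an error naming the line rather than imputing.
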
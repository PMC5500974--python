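"""Case-control genotype simulation under a penetrance disease model.

Disease-SNP genotypes are sampled conditional on case/control status by exact
inversion of the penetrance model (categorical sampling from
P(genotypes | status)); background SNPs are drawn independently of phenotype
under HWE with per-SNP MAFs uniform on a configurable range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    EpistasisModel,
    genotype_distribution_given_status,
    hwe_frequencies,
)

__all__ = ["GenotypeDataset", "simulate_dataset", "simulate_cohort"]


@dataclass
class GenotypeDataset:
    """Genotype matrix with binary phenotype.

    Attributes
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 matrix, values in {0, 1, 2}
        (homozygous common / heterozygous / homozygous minor).
    phenotype
        ``(n_samples,)`` int8 vector, 0 = control, 1 = case.
    snp_names
        One name per SNP column.
    truth
        Optional ground-truth disease SNP index sets (sorted tuples),
        known only for simulated data.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_names: list[str]
    truth: list[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        geno = np.asarray(self.genotypes, dtype=np.int8)
        pheno = np.asarray(self.phenotype, dtype=np.int8)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if geno.size and not np.isin(geno, (0, 1, 2)).all():
            raise ValueError("genotype values must be 0, 1 or 2")
        if pheno.ndim != 1 or pheno.shape[0] != geno.shape[0]:
            raise ValueError("phenotype length must equal the number of samples")
        if pheno.size and not np.isin(pheno, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        if len(self.snp_names) != geno.shape[1]:
            raise ValueError("snp_names length must equal the number of SNPs")
        self.genotypes = geno
        self.phenotype = pheno
        if self.truth is not None:
            self.truth = [tuple(sorted(int(i) for i in t)) for t in self.truth]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def _sample_disease_genotypes(
    model: EpistasisModel, status: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n joint genotypes (n, K) from P(genotypes | status)."""
    k = model.order
    table = genotype_distribution_given_status(model, status)
    flat = rng.choice(table.size, size=n, p=table.ravel())
    return np.stack(np.unravel_index(flat, table.shape), axis=1).astype(np.int8)


def simulate_dataset(
    model: EpistasisModel,
    n_cases: int = 2000,
    n_controls: int = 2000,
    n_snps: int = 100,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.SeedSequence = 0,
) -> GenotypeDataset:
    """Simulate a case-control dataset with one embedded interaction.

    The K disease SNPs are placed at random columns (recorded in ``truth``);
    their joint genotypes are drawn from the model's conditional distribution
    given each sample's status. Every other SNP gets an independent MAF drawn
    uniformly from ``background_maf_range`` and genotypes sampled under HWE,
    independent of phenotype. Samples are ordered cases first, then controls.

    Fully reproducible: the same ``seed`` yields a bit-identical dataset.
    """
    k = model.order
    if n_snps < k:
        raise ValueError(f"n_snps={n_snps} is smaller than the model order {k}")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    lo, hi = background_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"background MAF range must satisfy 0 < lo <= hi <= 0.5")

    rng = np.random.default_rng(seed)
    n = n_cases + n_controls

    geno = np.empty((n, n_snps), dtype=np.int8)
    # Background: one MAF per SNP, HWE genotypes independent of phenotype.
    mafs = rng.uniform(lo, hi, size=n_snps)
    cumprobs = np.cumsum(
        np.stack([hwe_frequencies(p) for p in mafs], axis=0), axis=1
    )
    u = rng.random(size=(n, n_snps))
    geno[:] = (u[:, :, None] > cumprobs[None, :, :-1]).sum(axis=2)

    disease_cols = np.sort(rng.choice(n_snps, size=k, replace=False))
    geno[:n_cases, disease_cols] = _sample_disease_genotypes(model, 1, n_cases, rng)
    geno[n_cases:, disease_cols] = _sample_disease_genotypes(
        model, 0, n_controls, rng
    )

    pheno = np.zeros(n, dtype=np.int8)
    pheno[:n_cases] = 1
    names = [f"SNP{i}" for i in range(n_snps)]
    return GenotypeDataset(
        genotypes=geno,
        phenotype=pheno,
        snp_names=names,
        truth=[tuple(int(c) for c in disease_cols)],
    )


def simulate_cohort(
    model: EpistasisModel, n: int, seed: int | np.random.SeedSequence = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate n individuals unconditionally (genotypes first, then disease).

    Joint genotypes for the model's K SNPs are drawn from their HWE
    distribution, then disease status is a Bernoulli draw with the cell's
    penetrance. Returns ``(genotypes, phenotype)`` with shapes (n, K), (n,).
    Independent of :func:`simulate_dataset`; used as a forward-sampling oracle
    for the conditional (inverted) sampler.
    """
    rng = np.random.default_rng(seed)
    geno = np.stack(
        [
            rng.choice(3, size=n, p=hwe_frequencies(p)).astype(np.int8)
            for p in model.maf
        ],
        axis=1,
    )
    pen = model.penetrance[tuple(geno[:, j] for j in range(model.order))]
    pheno = (rng.random(n) < pen).astype(np.int8)
    return geno, pheno
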
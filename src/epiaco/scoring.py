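"""Association scoring for SNP combinations against a binary phenotype.

The fitness used by the colony search is the Svalue: the mutual information
between the joint genotype of a SNP combination and the phenotype, divided by
the logarithmic K2 score of the Bayesian network in which the combination's
SNPs are the parents of the phenotype node. Mutual information grows with
association strength; the log-K2 score shrinks with it; their ratio therefore
rewards association through both numerator and denominator. Natural
logarithms are used throughout (the base cancels in rankings).

All scores are pure functions of the 3^K x 2 contingency table of genotype
combination versus phenotype, with rows indexed by the mixed-radix expansion
of the genotype codes (last SNP fastest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency

from .simulate import GenotypeDataset

__all__ = [
    "ContingencyCounts",
    "CombinationScore",
    "Chi2Result",
    "tabulate",
    "mutual_information",
    "k2_log",
    "svalue",
    "chi2_association",
    "score_combination",
]

#: Below this the log-K2 denominator is treated as degenerate (possible only
#: for near-empty tables); see :func:`svalue`.
K2_GUARD = 1e-12


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of (genotype combination, phenotype) over n samples.

    ``counts[i, j]`` is the number of samples whose K genotypes expand to row
    ``i`` in mixed radix (last SNP fastest) and whose phenotype is ``j``
    (0 = control, 1 = case). ``row_sums`` caches the per-row totals r_i.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"counts must have shape (3^K, 2), got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


class Chi2Result(NamedTuple):
    statistic: float
    pvalue: float


def _row_codes(geno: np.ndarray, snps: Sequence[int]) -> np.ndarray:
    """Mixed-radix row index of each sample's joint genotype (last SNP fastest)."""
    code = geno[:, snps[0]].astype(np.int64)
    for s in snps[1:]:
        code = code * 3 + geno[:, s]
    return code


def _counts_array(
    geno: np.ndarray, pheno: np.ndarray, snps: Sequence[int]
) -> np.ndarray:
    k = len(snps)
    cells = _row_codes(geno, snps) * 2 + pheno
    return np.bincount(cells, minlength=2 * 3**k).reshape(3**k, 2)


def tabulate(dataset: GenotypeDataset, snps: Sequence[int]) -> ContingencyCounts:
    """Exact 3^K x 2 contingency table for the given SNP indices."""
    snps = tuple(int(s) for s in snps)
    if len(set(snps)) != len(snps):
        raise ValueError(f"duplicate SNP indices in {snps}")
    if any(s < 0 or s >= dataset.n_snps for s in snps):
        raise ValueError(
            f"SNP indices {snps} out of range for {dataset.n_snps} SNPs"
        )
    return ContingencyCounts(
        _counts_array(dataset.genotypes, dataset.phenotype, snps)
    )


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 log 0 := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _mi_array(counts: np.ndarray) -> float:
    n = counts.sum()
    mi = (
        _entropy(counts.sum(axis=1) / n)
        + _entropy(counts.sum(axis=0) / n)
        - _entropy((counts / n).ravel())
    )
    # exact MI is non-negative; rounding can leave a tiny negative residue
    return max(mi, 0.0)


def mutual_information(counts: ContingencyCounts) -> float:
    """Plug-in mutual information MI(S; Y) = H(S) + H(Y) - H(S, Y), in nats."""
    if counts.n == 0:
        raise ValueError("cannot compute mutual information of an empty table")
    return _mi_array(counts.counts)


def _k2_log_array(counts: np.ndarray) -> float:
    # Eqv. to sum_i [ log((r_i+1)!) - sum_j log(r_ij!) ]; empty rows add 0.
    r = counts.sum(axis=1)
    return float(gammaln(r + 2).sum() - gammaln(counts + 1).sum())


def k2_log(counts: ContingencyCounts) -> float:
    """Logarithmic K2 score of the combination-as-parents network.

    Computed via log-gamma as
    ``sum_i [ sum_{b=1..r_i+1} log b  -  sum_j sum_{d=1..r_ij} log d ]``,
    the negative log of the exact K2 factorial product. Non-negative; lower
    means stronger association. An all-zero table scores exactly 0.
    """
    return _k2_log_array(counts.counts)


def _svalue_array(counts: np.ndarray) -> float:
    if counts.sum() == 0:
        return 0.0
    mi = _mi_array(counts)
    k2 = _k2_log_array(counts)
    if k2 < K2_GUARD:
        return 0.0 if mi == 0.0 else mi / K2_GUARD
    return mi / k2


def svalue(counts: ContingencyCounts) -> float:
    """Svalue fitness = MI / log-K2; higher means stronger association.

    A degenerate denominator below ``K2_GUARD`` (near-empty data) gives 0
    when MI is 0 and ``MI / K2_GUARD`` otherwise, preserving the ordering
    without dividing by zero.
    """
    return _svalue_array(counts.counts)


def chi2_association(counts: ContingencyCounts) -> Chi2Result:
    """Pearson chi-square of genotype combination x phenotype.

    Rows with zero total are dropped before the test, so the degrees of
    freedom are (occupied rows - 1) x 1. Degenerate tables (a single occupied
    row, or one phenotype class absent) return statistic 0 and p = 1.
    """
    if counts.n == 0:
        raise ValueError("cannot test an empty table")
    sub = counts.counts[counts.row_sums > 0]
    if sub.shape[0] < 2 or np.any(sub.sum(axis=0) == 0):
        return Chi2Result(0.0, 1.0)
    stat, p, _, _ = chi2_contingency(sub, correction=False)
    return Chi2Result(float(stat), float(p))


@dataclass(frozen=True)
class CombinationScore:
    """Scores of one SNP combination.

    ``snps`` is the sorted index tuple; ``mi`` is in nats; ``k2_log`` is the
    logarithmic K2 score; ``svalue`` their ratio; ``chi2_p`` is filled only
    for final reporting.
    """

    snps: tuple[int, ...]
    mi: float
    k2_log: float
    svalue: float
    chi2_p: float | None = None

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.snps, self.snps[1:])):
            raise ValueError(f"snps must be strictly increasing, got {self.snps}")


def score_combination(
    dataset: GenotypeDataset, snps: Sequence[int], with_chi2: bool = False
) -> CombinationScore:
    """Tabulate and score one combination; the SNP tuple is sorted first."""
    snps = tuple(sorted(int(s) for s in snps))
    counts = tabulate(dataset, snps)
    arr = counts.counts
    mi = _mi_array(arr) if counts.n else 0.0
    k2 = _k2_log_array(arr)
    if k2 < K2_GUARD:
        sv = 0.0 if mi == 0.0 else mi / K2_GUARD
    else:
        sv = mi / k2
    chi2_p = chi2_association(counts).pvalue if with_chi2 else None
    return CombinationScore(snps=snps, mi=mi, k2_log=k2, svalue=sv, chi2_p=chi2_p)
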
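"""Two-locus (and general K-locus) penetrance disease models.

A model couples minor-allele frequencies (MAFs) of the disease SNPs with a
penetrance table: the probability of disease given each joint genotype.
Genotypes are coded 0 = homozygous common, 1 = heterozygous, 2 = homozygous
minor, and genotype frequencies follow Hardy-Weinberg equilibrium (HWE),
i.e. (1-p)^2, 2p(1-p), p^2 for minor-allele frequency p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpistasisModel",
    "BUILTIN_MODELS",
    "get_model",
    "hwe_frequencies",
    "model_prevalence",
    "genotype_distribution_given_status",
]


@dataclass(frozen=True)
class EpistasisModel:
    """Disease model: MAFs plus a K-dimensional penetrance table.

    Parameters
    ----------
    maf
        Minor-allele frequency of each disease SNP, each in (0, 0.5].
    penetrance
        Array of shape ``(3,) * K`` giving P(disease | genotype combination).
        Axis order per SNP: homozygous common, heterozygous, homozygous minor.
    label
        Free-text model name.
    """

    maf: tuple[float, ...]
    penetrance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=float)
        object.__setattr__(self, "penetrance", pen)
        object.__setattr__(self, "maf", tuple(float(p) for p in self.maf))
        k = len(self.maf)
        if pen.shape != (3,) * k:
            raise ValueError(
                f"penetrance shape {pen.shape} does not match {k} SNPs "
                f"(expected {(3,) * k})"
            )
        if not all(0.0 < p <= 0.5 for p in self.maf):
            raise ValueError(f"every MAF must lie in (0, 0.5], got {self.maf}")
        if np.any((pen < 0.0) | (pen > 1.0)):
            raise ValueError("penetrance entries must lie in [0, 1]")

    @property
    def order(self) -> int:
        """Number of disease SNPs K."""
        return len(self.maf)


def hwe_frequencies(maf: float) -> np.ndarray:
    """Genotype frequencies [(1-p)^2, 2p(1-p), p^2] under HWE."""
    p = float(maf)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


def _genotype_joint(model: EpistasisModel) -> np.ndarray:
    """Unconditional joint genotype distribution: outer product of HWE margins."""
    joint = np.ones(())
    for p in model.maf:
        joint = np.multiply.outer(joint, hwe_frequencies(p))
    return joint


def model_prevalence(model: EpistasisModel) -> float:
    """Population disease probability implied by the model.

    Sums P(genotypes) * P(disease | genotypes) over all 3^K genotype
    combinations, with genotype frequencies from HWE at the model MAFs.
    """
    return float(np.sum(_genotype_joint(model) * model.penetrance))


def genotype_distribution_given_status(
    model: EpistasisModel, status: int
) -> np.ndarray:
    """P(genotype combination | case/control status), shape ``(3,) * K``.

    Bayes inversion of the penetrance table: for cases the joint HWE genotype
    distribution is reweighted by penetrance, for controls by one minus
    penetrance, then normalized.

    Parameters
    ----------
    model
        Disease model.
    status
        1 for case, 0 for control.

    Raises
    ------
    ValueError
        If the model prevalence is 0 (no cases possible) or 1 (no controls),
        making conditional sampling for the requested status unsatisfiable.
    """
    if status not in (0, 1):
        raise ValueError(f"status must be 0 (control) or 1 (case), got {status}")
    joint = _genotype_joint(model)
    weight = model.penetrance if status == 1 else 1.0 - model.penetrance
    table = joint * weight
    total = table.sum()
    if total <= 0.0:
        which = "cases" if status == 1 else "controls"
        raise ValueError(
            f"model {model.label!r} has prevalence "
            f"{model_prevalence(model):.3g}; cannot sample {which}"
        )
    return table / total


def _table(rows: list[list[float]]) -> np.ndarray:
    return np.array(rows, dtype=float)


#: Benchmark two-locus models. Rows index SNP A genotypes (AA, Aa, aa),
#: columns SNP B genotypes (BB, Bb, bb). Models 1-2 have marginal effects
#: (ME), models 3-5 have interaction effects only (NME). Model 2's published
#: table is internally inconsistent with its stated prevalence and is kept
#: only for completeness; model 5's table implies prevalence 0.025.
BUILTIN_MODELS: dict[int, EpistasisModel] = {
    1: EpistasisModel(
        maf=(0.300, 0.200),
        penetrance=_table(
            [
                [0.087, 0.087, 0.087],
                [0.087, 0.146, 0.190],
                [0.087, 0.190, 0.247],
            ]
        ),
        label="Model 1 (ME)",
    ),
    2: EpistasisModel(
        maf=(0.400, 0.400),
        penetrance=_table(
            [
                [0.042, 0.042, 0.042],
                [0.240, 0.270, 0.420],
                [0.240, 0.440, 0.090],
            ]
        ),
        label="Model 2 (ME)",
    ),
    3: EpistasisModel(
        maf=(0.500, 0.500),
        penetrance=_table(
            [
                [0.470, 0.230, 0.270],
                [0.240, 0.270, 0.420],
                [0.240, 0.440, 0.090],
            ]
        ),
        label="Model 3 (NME)",
    ),
    4: EpistasisModel(
        maf=(0.400, 0.400),
        penetrance=_table(
            [
                [0.068, 0.299, 0.017],
                [0.289, 0.044, 0.285],
                [0.048, 0.262, 0.174],
            ]
        ),
        label="Model 4 (NME)",
    ),
    5: EpistasisModel(
        maf=(0.500, 0.500),
        penetrance=_table(
            [
                [0.000, 0.000, 0.100],
                [0.000, 0.050, 0.000],
                [0.100, 0.000, 0.000],
            ]
        ),
        label="Model 5 (NME)",
    ),
}


def get_model(model_id: int) -> EpistasisModel:
    """Return a built-in benchmark model by number (1-5)."""
    try:
        return BUILTIN_MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id}; built-ins are {sorted(BUILTIN_MODELS)}"
        ) from None
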
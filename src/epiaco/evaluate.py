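"""Detection-power experiments on simulated datasets.

Power is the percentage of simulated datasets in which the embedded
interaction is perfectly identified with no false positives: by default a
dataset counts as detected when the single top-ranked combination of the
final candidate memory equals the ground-truth SNP pair. An alternative,
more lenient call ("candidates" mode) requires the truth to be present in
the candidate memory with every reported candidate overlapping the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np

from .colony import AcoParams
from .models import EpistasisModel
from .search import SearchResult, run_epiaco
from .simulate import GenotypeDataset, simulate_dataset

__all__ = [
    "PowerExperiment",
    "PowerResult",
    "detection_success",
    "detection_power",
]

DetectionMode = Literal["top1", "candidates"]


def detection_success(
    result: SearchResult,
    truth: tuple[int, ...],
    mode: DetectionMode = "top1",
) -> bool:
    """Whether a search run perfectly identified the ground-truth combination.

    ``top1`` (default): the best-ranked candidate equals the truth.
    ``candidates``: the truth is in the candidate memory and every candidate
    shares at least one SNP with the truth (no wholly false positives).
    """
    truth = tuple(sorted(int(i) for i in truth))
    if not truth:
        raise ValueError("truth must be non-empty")
    if mode == "top1":
        return result.top is not None and result.top.snps == truth
    if mode == "candidates":
        combos = result.candidates.combinations()
        if truth not in combos:
            return False
        t = set(truth)
        return all(t & set(c) for c in combos)
    raise ValueError(f"unknown detection mode {mode!r}")


@dataclass
class PowerExperiment:
    """Design of one power experiment.

    ``n_datasets`` (G) independent datasets are simulated from ``model``;
    the search runs ``runs_per_dataset`` times on each with distinct seeds.
    All per-dataset and per-run seeds are derived deterministically from
    ``seed`` via spawned seed sequences.
    """

    model: EpistasisModel
    params: AcoParams
    n_datasets: int = 20
    runs_per_dataset: int = 1
    n_cases: int = 2000
    n_controls: int = 2000
    n_snps: int = 100
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    detection_mode: DetectionMode = "top1"
    #: "majority": a dataset is detected when more than half of its runs
    #: succeed; "mean": its per-run success rate contributes fractionally
    aggregation: Literal["majority", "mean"] = "majority"

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.runs_per_dataset < 1:
            raise ValueError("need at least one dataset and one run per dataset")


@dataclass
class PowerResult:
    """Outcome of a power experiment."""

    #: 100 * R / G, the percentage of detected datasets
    power: float
    #: per-dataset detection flags (majority) or success rates (mean)
    per_dataset: list[float]
    #: standard deviation of per-run success across all runs, in percent
    run_dispersion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 100.0:
            raise ValueError("power must lie in [0, 100]")


def _search_runner(
    experiment: PowerExperiment,
) -> Callable[[GenotypeDataset, int], SearchResult]:
    def run(dataset: GenotypeDataset, seed: int) -> SearchResult:
        return run_epiaco(dataset, replace(experiment.params, seed=seed))

    return run


def _derived_seed(ss: np.random.SeedSequence) -> int:
    # keep derived integer seeds in the 31-bit range
    return int(ss.generate_state(1)[0] % (2**31))


def detection_power(
    experiment: PowerExperiment,
    runner: Callable[[GenotypeDataset, int], SearchResult] | None = None,
) -> PowerResult:
    """Run the full experiment and return Power = 100 * R / G.

    ``runner`` may substitute a different search (e.g. a random-search
    baseline) with the same (dataset, seed) -> SearchResult signature.
    """
    if runner is None:
        runner = _search_runner(experiment)
    root = np.random.SeedSequence(experiment.seed)
    dataset_seqs = root.spawn(experiment.n_datasets)

    per_dataset: list[float] = []
    all_runs: list[bool] = []
    for ds_seq in dataset_seqs:
        sim_seq, *run_seqs = ds_seq.spawn(1 + experiment.runs_per_dataset)
        dataset = simulate_dataset(
            experiment.model,
            n_cases=experiment.n_cases,
            n_controls=experiment.n_controls,
            n_snps=experiment.n_snps,
            background_maf_range=experiment.background_maf_range,
            seed=sim_seq,
        )
        truth = dataset.truth[0]
        successes = [
            detection_success(
                runner(dataset, _derived_seed(rs)),
                truth,
                mode=experiment.detection_mode,
            )
            for rs in run_seqs
        ]
        all_runs.extend(successes)
        rate = sum(successes) / len(successes)
        if experiment.aggregation == "majority":
            per_dataset.append(float(rate > 0.5))
        else:
            per_dataset.append(rate)

    power = 100.0 * sum(per_dataset) / len(per_dataset)
    dispersion = 100.0 * float(np.std(np.asarray(all_runs, dtype=float)))
    return PowerResult(
        power=power, per_dataset=per_dataset, run_dispersion=dispersion
    )
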
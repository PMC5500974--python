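"""Reading and writing case-control genotype files and search results.

Genotype files are delimited text in the dialect used by exhaustive pairwise
scanners (BOOST/BEAM style): one header row with SNP names followed by a
final ``Class`` column, then one row per sample holding genotype codes and
the 0/1 phenotype. Two genotype codings are accepted: 0/1/2 (canonical,
zero-based) and 1/2/3 (one-based); both map to homozygous common /
heterozygous / homozygous minor. Ground-truth disease SNP indices of
simulated data travel in a JSON sidecar next to the genotype file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .colony import AcoParams
from .simulate import GenotypeDataset

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "write_results",
    "truth_sidecar_path",
]

Dialect = Literal["auto", "zero", "one"]

CLASS_COLUMN = "Class"


def truth_sidecar_path(path: str | Path) -> Path:
    """Path of the metadata sidecar accompanying a genotype file."""
    path = Path(path)
    return path.with_name(path.name + ".truth.json")


def _sniff_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError("could not detect a tab or comma delimiter in the header")


def _detect_coding(values: np.ndarray) -> Dialect:
    present = set(np.unique(values).tolist())
    if not present:
        return "zero"
    if present <= {0, 1, 2}:
        if 0 in present:
            return "zero"
        # neither 0 nor 3 present: consistent with either coding
        raise ValueError(
            f"genotype coding is ambiguous (only values "
            f"{sorted(present)} present); pass dialect='zero' or "
            f"dialect='one' explicitly"
        )
    return "one"


def read_genotypes(path: str | Path, dialect: Dialect = "auto") -> GenotypeDataset:
    """Parse a delimited genotype file into the canonical 0/1/2 coding.

    The last column must be named ``Class`` and hold the 0/1 phenotype.
    Malformed rows and out-of-range codes raise errors naming the offending
    line (1-based, header = line 1). A truth sidecar written by
    :func:`write_genotypes` is picked up automatically.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    try:
        frame = pd.read_csv(path, sep=sep, header=0, dtype=np.int64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if frame.columns[-1] != CLASS_COLUMN:
        raise ValueError(
            f"{path}: last column must be named {CLASS_COLUMN!r}, "
            f"got {frame.columns[-1]!r}"
        )
    snp_names = [str(c) for c in frame.columns[:-1]]
    geno = frame.iloc[:, :-1].to_numpy(dtype=np.int64)
    pheno = frame.iloc[:, -1].to_numpy(dtype=np.int64)

    bad_pheno = np.flatnonzero(~np.isin(pheno, (0, 1)))
    if bad_pheno.size:
        raise ValueError(
            f"{path}, line {bad_pheno[0] + 2}: phenotype value "
            f"{pheno[bad_pheno[0]]} is not 0 or 1"
        )
    out_of_any = (geno < 0) | (geno > 3)
    if out_of_any.any():
        row, col = np.argwhere(out_of_any)[0]
        raise ValueError(
            f"{path}, line {row + 2}: genotype value {geno[row, col]} in "
            f"column {snp_names[col]!r} is not valid in any coding"
        )
    if dialect == "auto":
        dialect = _detect_coding(geno) if geno.size else "zero"
    offset = 1 if dialect == "one" else 0
    valid = (geno >= offset) & (geno <= offset + 2)
    if not valid.all():
        row, col = np.argwhere(~valid)[0]
        raise ValueError(
            f"{path}, line {row + 2}: genotype value {geno[row, col]} in "
            f"column {snp_names[col]!r} is invalid for the "
            f"{'1/2/3' if offset else '0/1/2'} coding"
        )
    geno = geno - offset

    truth = None
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        truth = [tuple(t) for t in meta.get("truth", [])] or None
    return GenotypeDataset(
        genotypes=geno.astype(np.int8),
        phenotype=pheno.astype(np.int8),
        snp_names=snp_names,
        truth=truth,
    )


def write_genotypes(
    dataset: GenotypeDataset,
    path: str | Path,
    dialect: Literal["zero", "one"] = "zero",
    delimiter: str = "\t",
) -> None:
    """Write a dataset in the delimited dialect; byte output is deterministic.

    Ground-truth indices, if present, go to a ``<name>.truth.json`` sidecar.
    """
    path = Path(path)
    offset = 1 if dialect == "one" else 0
    frame = pd.DataFrame(
        dataset.genotypes.astype(np.int64) + offset, columns=dataset.snp_names
    )
    frame[CLASS_COLUMN] = dataset.phenotype.astype(np.int64)
    frame.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
    if dataset.truth is not None:
        meta = {
            "truth": [list(t) for t in dataset.truth],
            "truth_names": [
                [dataset.snp_names[i] for i in t] for t in dataset.truth
            ],
        }
        truth_sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_results(
    results,  # list[CombinationScore]
    dataset: GenotypeDataset,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write a ranked result table (TSV) plus a JSON metadata sidecar.

    Columns: rank, SNP names, 0-based indices, mi, k2_log, svalue, chi2
    statistic and p-value (computed here if the scores lack them).
    """
    from .scoring import chi2_association, tabulate

    path = Path(path)
    rows = []
    for rank, score in enumerate(results, start=1):
        chi2 = chi2_association(tabulate(dataset, score.snps))
        rows.append(
            {
                "rank": rank,
                "snps": ",".join(dataset.snp_names[i] for i in score.snps),
                "indices": ",".join(str(i) for i in score.snps),
                "mi": score.mi,
                "k2_log": score.k2_log,
                "svalue": score.svalue,
                "chi2_stat": chi2.statistic,
                "chi2_p": chi2.pvalue,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
    if metadata is not None:
        meta_path = path.with_name(path.name + ".meta.json")
        meta_path.write_text(json.dumps(metadata, indent=2, default=str) + "\n")


@dataclass
class RunConfig:
    """Serializable run configuration; round-trips losslessly through YAML."""

    input: str | None = None
    output: str | None = None
    dialect: Dialect = "auto"
    detection_mode: str = "top1"
    log_level: str = "INFO"
    params: AcoParams = field(default_factory=AcoParams)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["params"] = dataclasses.asdict(self.params)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        params = AcoParams(**doc.pop("params", {}))
        return cls(params=params, **doc)
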
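"""Plain-text file formats: genotype matrices, truth manifests, model files,
results tables, run logs, metrics tables and run manifests.

All formats are tab-delimited or JSON.  The genotype matrix format is a
header row of SNP identifiers followed by a final ``Class`` column, then one
row per individual with genotypes 0/1/2 and Class 1 (case) or 2 (control).
Reader and writer are exact inverses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np

from .association import FitnessValue
from .entropy import Strategy
from .search import SearchConfig, SearchResult
from .simulator import GenotypeDataset, PenetranceModel

__all__ = [
    "DatasetParseError",
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
    "load_model",
    "load_builtin_model",
    "builtin_model_names",
    "write_model",
    "write_results",
    "read_results",
    "write_run_log",
    "write_metrics",
    "write_manifest",
]


class DatasetParseError(ValueError):
    """A genotype matrix file is malformed; the message names the line."""


# ---------------------------------------------------------------- datasets

def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write a genotype matrix as TSV with a trailing ``Class`` column."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join([*dataset.snp_ids, "Class"]) + "\n")
        for row, status in zip(dataset.genotypes, dataset.status):
            fh.write("\t".join(map(str, row.tolist())) + f"\t{int(status)}\n")


def read_dataset(path, truth: list | None = None) -> GenotypeDataset:
    """Read a genotype matrix TSV written by :func:`write_dataset`.

    Raises :class:`DatasetParseError` naming the offending line for ragged
    rows, genotypes outside {0, 1, 2} or Class codes outside {1, 2}.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise DatasetParseError(f"{path}: empty file")
        columns = header.split("\t")
        if columns[-1] != "Class":
            raise DatasetParseError(f"{path}: line 1: last header column must be 'Class'")
        snp_ids = columns[:-1]
        n_snps = len(snp_ids)
        if n_snps == 0:
            raise DatasetParseError(f"{path}: line 1: no SNP columns")
        genotypes: list[list[int]] = []
        status: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_snps + 1:
                raise DatasetParseError(
                    f"{path}: line {lineno}: expected {n_snps + 1} fields, got {len(fields)}"
                )
            try:
                values = [int(v) for v in fields]
            except ValueError as exc:
                raise DatasetParseError(f"{path}: line {lineno}: non-integer field") from exc
            geno, cls = values[:-1], values[-1]
            bad = [g for g in geno if g not in (0, 1, 2)]
            if bad:
                raise DatasetParseError(
                    f"{path}: line {lineno}: genotype {bad[0]} not in {{0, 1, 2}}"
                )
            if cls not in (1, 2):
                raise DatasetParseError(f"{path}: line {lineno}: Class {cls} not in {{1, 2}}")
            genotypes.append(geno)
            status.append(cls)
    if not genotypes:
        raise DatasetParseError(f"{path}: no individuals (header-only file)")
    return GenotypeDataset(
        genotypes=np.array(genotypes, dtype=np.int8),
        status=np.array(status, dtype=np.int8),
        snp_ids=snp_ids,
        truth=truth or [],
    )


def write_truth(truth: list, path) -> None:
    """Write ground-truth locus index sets, one tab-separated set per line."""
    with Path(path).open("w", newline="\n") as fh:
        for snp_set in truth:
            fh.write("\t".join(str(int(i)) for i in sorted(snp_set)) + "\n")


def read_truth(path) -> list[tuple[int, ...]]:
    """Read a truth manifest written by :func:`write_truth`."""
    truth = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                truth.append(tuple(int(v) for v in line.split("\t")))
    return truth


# ------------------------------------------------------------------ models

def load_model(path) -> PenetranceModel:
    """Load a penetrance model from a JSON file."""
    with Path(path).open() as fh:
        obj = json.load(fh)
    return PenetranceModel(
        name=obj["name"],
        maf_a=obj["maf_a"],
        maf_b=obj["maf_b"],
        table=np.array(obj["table"], dtype=float),
        declared_prevalence=obj.get("declared_prevalence"),
    )


def write_model(model: PenetranceModel, path) -> None:
    obj = {
        "name": model.name,
        "maf_a": model.maf_a,
        "maf_b": model.maf_b,
        "declared_prevalence": model.declared_prevalence,
        "table": model.table.tolist(),
    }
    with Path(path).open("w", newline="\n") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def builtin_model_names() -> list[str]:
    """Names of the eight packaged two-locus epistasis models."""
    root = resources.files("ieaco").joinpath("data/models")
    return sorted(p.name[: -len(".json")] for p in root.iterdir() if p.name.endswith(".json"))


def load_builtin_model(name: str) -> PenetranceModel:
    """Load one of the packaged models (``model1`` ... ``model8``)."""
    ref = resources.files("ieaco").joinpath(f"data/models/{name}.json")
    if not ref.is_file():
        raise FileNotFoundError(
            f"no builtin model {name!r}; available: {', '.join(builtin_model_names())}"
        )
    with resources.as_file(ref) as path:
        return load_model(path)


# ----------------------------------------------------------------- results

_RESULT_COLUMNS = ["snp_ids", "loci", "chi2", "dof", "p_value", "significant"]


def write_results(result: SearchResult, path, snp_ids: list[str] | None = None) -> None:
    """Write the reported interactions as a TSV table."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for snp_set, fit in result.reported:
            labels = (
                ",".join(snp_ids[i] for i in snp_set) if snp_ids else ",".join(map(str, snp_set))
            )
            loci = ",".join(map(str, snp_set))
            fh.write(
                f"{labels}\t{loci}\t{fit.chi2:.6f}\t{fit.dof}\t{fit.p_value:.6e}\t1\n"
            )


def read_results(path) -> list[tuple[tuple[int, ...], FitnessValue]]:
    """Read a results table back as (locus set, fitness) pairs, file order."""
    out = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header != _RESULT_COLUMNS:
            raise DatasetParseError(f"{path}: unexpected results header {header}")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            _, loci, chi2, dof, p_value, _ = line.split("\t")
            out.append(
                (
                    tuple(int(v) for v in loci.split(",")),
                    FitnessValue(float(chi2), int(dof), float(p_value)),
                )
            )
    return out


def write_run_log(result: SearchResult, path) -> None:
    """Per-iteration log: best set, chi2, p, entropy and active strategy."""
    hist = result.entropy_history
    with Path(path).open("w", newline="\n") as fh:
        fh.write("iteration\tbest_set\tchi2\tp_value\tentropy\tstrategy\n")
        for i, (snp_set, fit) in enumerate(result.per_iteration_best, start=1):
            # entropy at the start of iteration i = value after i-1 updates
            h = f"{hist.values[i - 1]:.6f}" if hist is not None else "NA"
            strat = result.strategies[i - 1].value
            fh.write(
                f"{i}\t{','.join(map(str, snp_set))}\t{fit.chi2:.6f}\t"
                f"{fit.p_value:.6e}\t{h}\t{strat}\n"
            )


def write_metrics(report, path, label: str = "NA", n_snps: int | str = "NA") -> None:
    """Write batch evaluation metrics as a one-row TSV."""
    power = "NA" if report.power is None else f"{report.power:.6f}"
    with Path(path).open("w", newline="\n") as fh:
        fh.write("model\tn_snps\tn_datasets\tpower\trecall\tprecision\tTP\tFP\tFN\n")
        fh.write(
            f"{label}\t{n_snps}\t{len(report.per_dataset)}\t{power}\t"
            f"{report.recall:.6f}\t{report.precision:.6f}\t"
            f"{report.tp}\t{report.fp}\t{report.fn}\n"
        )


# ---------------------------------------------------------------- manifest

def _sha256(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: SearchConfig, dataset_path, path, started=None, finished=None) -> None:
    """Record everything needed to reproduce a run bit-identically."""
    from . import __version__

    eta = config.eta
    if not np.isscalar(eta):
        eta = np.asarray(eta).tolist()
    cfg = asdict(config)
    cfg["eta"] = eta
    obj = {
        "tool": "ieaco",
        "version": __version__,
        "dataset": str(dataset_path),
        "dataset_sha256": _sha256(dataset_path),
        "seed": config.seed,
        "config": cfg,
        "started": started or datetime.now(timezone.utc).isoformat(),
        "finished": finished,
    }
    with Path(path).open("w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, default=str)
        fh.write("\n")
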
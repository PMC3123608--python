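"""Pipeline front end: control file, marker partitioning, parallel analysis.

The pipeline stages run in a fixed order — read data, build family units,
genome-wide distance matrix, Ward clustering, origin priors, then per-marker
(EM, statistic, bootstrap) analyses distributed evenly over a worker pool.
Per-marker RNG streams are derived from (seed, marker index), and rows are
written in input marker order, so the results file is byte-identical for a
fixed configuration regardless of the number of threads.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .capl_stat import (
    AnalysisContext,
    CaplResult,
    STATUS_OK,
    capl_test,
    marker_seed,
)
from .pedio import build_family_units, read_plink_binary, read_plink_text
from .popcluster import family_origin_priors, ibs_distance_matrix, ward_cluster

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ControlFileError", "parse_control_file",
           "partition_markers", "run_pipeline", "write_results"]


class ControlFileError(ValueError):
    """Malformed control file (unknown key, missing key, bad value)."""


@dataclass
class RunConfig:
    input_prefix: str
    K: int
    out_path: str
    input_format: str = "text"       # "text" | "binary"
    threads: int = 1
    B: int = 200
    seed: int = 1
    tol: float = 1e-6
    max_iter: int = 50
    epsilon: float = 0.01
    counted_allele: str = "default"  # "default" | "a1" | "lexicographic"
    dump_clusters: str | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ControlFileError("subpopulations must be >= 1")
        if self.threads < 1:
            raise ControlFileError("threads must be >= 1")
        if self.B < 2:
            raise ControlFileError("bootstraps must be >= 2")
        if self.input_format not in ("text", "binary"):
            raise ControlFileError(
                f"format must be 'text' or 'binary', got {self.input_format!r}"
            )


_REQUIRED = ("input", "subpopulations", "out")
_KNOWN = {
    "input", "format", "subpopulations", "threads", "nodes", "bootstraps",
    "seed", "out", "tol", "max_iter", "epsilon", "counted_allele",
    "dump_clusters",
}


def parse_control_file(path: str | Path) -> RunConfig:
    """Parse a ``key = value`` control file (case-insensitive keys, ``#`` comments)."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ControlFileError(f"{path}:{ln}: expected key = value")
            key, _, val = line.partition("=")
            key = key.strip().lower()
            val = val.strip()
            if key not in _KNOWN:
                raise ControlFileError(f"{path}:{ln}: unknown key {key!r}")
            if key in values:
                raise ControlFileError(f"{path}:{ln}: duplicate key {key!r}")
            values[key] = val

    missing = [k for k in _REQUIRED if k not in values]
    if missing:
        raise ControlFileError(
            f"{path}: missing required key(s): {', '.join(missing)}"
        )
    if "nodes" in values:
        logger.warning(
            "control key 'nodes' is accepted but ignored: this build runs a "
            "single-machine worker pool"
        )

    def as_int(key: str, default: int | None = None) -> int:
        if key not in values:
            return default
        try:
            return int(values[key])
        except ValueError:
            raise ControlFileError(f"{path}: key {key!r} must be an integer")

    def as_float(key: str, default: float) -> float:
        if key not in values:
            return default
        try:
            return float(values[key])
        except ValueError:
            raise ControlFileError(f"{path}: key {key!r} must be a number")

    return RunConfig(
        input_prefix=values["input"],
        K=as_int("subpopulations"),
        out_path=values["out"],
        input_format=values.get("format", "text").lower(),
        threads=as_int("threads", 1),
        B=as_int("bootstraps", 200),
        seed=as_int("seed", 1),
        tol=as_float("tol", 1e-6),
        max_iter=as_int("max_iter", 50),
        epsilon=as_float("epsilon", 0.01),
        counted_allele=values.get("counted_allele", "default").lower(),
        dump_clusters=values.get("dump_clusters"),
    )


def write_control_file(config: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig back to control-file syntax (round-trippable)."""
    with open(path, "w") as fh:
        fh.write(f"input = {config.input_prefix}\n")
        fh.write(f"format = {config.input_format}\n")
        fh.write(f"subpopulations = {config.K}\n")
        fh.write(f"threads = {config.threads}\n")
        fh.write(f"bootstraps = {config.B}\n")
        fh.write(f"seed = {config.seed}\n")
        fh.write(f"out = {config.out_path}\n")
        fh.write(f"tol = {config.tol}\n")
        fh.write(f"max_iter = {config.max_iter}\n")
        fh.write(f"epsilon = {config.epsilon}\n")
        fh.write(f"counted_allele = {config.counted_allele}\n")
        if config.dump_clusters:
            fh.write(f"dump_clusters = {config.dump_clusters}\n")


def partition_markers(n_markers: int, workers: int) -> list[range]:
    """Split 0..M-1 into ``workers`` contiguous ranges with sizes differing by <= 1."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    base, extra = divmod(n_markers, workers)
    ranges = []
    start = 0
    for w in range(workers):
        size = base + (1 if w < extra else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


def _fmt(x, digits: int = 6) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.{digits}g}"
    return str(x)


def results_to_frame(markers, results: list[CaplResult], K: int) -> pd.DataFrame:
    rows = []
    for mk, res in zip(markers, results):
        row = {
            "CHR": mk.chromosome, "SNP": mk.id, "BP": mk.position,
            "A1": mk.allele1, "A2": mk.allele2,
            "N_FAM_USED": res.n_families_used,
        }
        for k in range(K):
            row[f"P_HAT_{k + 1}"] = (
                _fmt(float(res.p_hat[k])) if res.p_hat is not None else "NA"
            )
        for j in range(3):
            row[f"Z{j}"] = (
                _fmt(float(res.z_hat[j])) if res.z_hat is not None else "NA"
            )
        row.update(
            EM_ITER=res.em_iterations,
            T=_fmt(res.T), BOOT_SD=_fmt(res.boot_sd),
            Z=_fmt(res.z_score), P=_fmt(res.p_value),
            STATUS=res.status,
        )
        rows.append(row)
    cols = (
        ["CHR", "SNP", "BP", "A1", "A2", "N_FAM_USED"]
        + [f"P_HAT_{k + 1}" for k in range(K)]
        + ["Z0", "Z1", "Z2", "EM_ITER", "T", "BOOT_SD", "Z", "P", "STATUS"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _read_input(config: RunConfig):
    prefix = config.input_prefix
    policy = config.counted_allele
    if config.input_format == "binary":
        if policy not in ("default", "a1"):
            raise ControlFileError(
                "binary input counts the .bim A1 allele; "
                f"counted_allele = {policy!r} is not available"
            )
        return read_plink_binary(prefix + ".bed", prefix + ".bim", prefix + ".fam")
    if policy not in ("default", "lexicographic"):
        raise ControlFileError(
            "text input counts the lexicographically smaller observed allele; "
            f"counted_allele = {policy!r} is not available"
        )
    return read_plink_text(prefix + ".ped", prefix + ".map")


def run_pipeline(config: RunConfig, dataset=None) -> pd.DataFrame:
    """Execute the full pipeline and write the results TSV.

    ``dataset`` may supply an in-memory ``(markers, individuals, genotypes)``
    triple (as produced by the readers or the simulator), bypassing file
    input.  Returns the results table that was written.
    """
    t0 = time.perf_counter()

    def stage(name):
        logger.info("[%.2fs] stage: %s", time.perf_counter() - t0, name)

    stage("read input")
    if dataset is None:
        markers, individuals, genotypes = _read_input(config)
    else:
        markers, individuals, genotypes = dataset

    stage("build family units")
    units, exclusions = build_family_units(individuals)
    if exclusions:
        logger.info("%d individuals excluded from units", len(exclusions))

    stage("distance matrix")
    n_markers = len(markers)
    if config.K > 1:
        if n_markers == 0:
            raise ValueError("cannot cluster with zero markers")
        distances = ibs_distance_matrix(genotypes)
        stage("ward clustering")
        assignment = ward_cluster(distances, config.K)
    else:
        distances = None
        from .popcluster import ClusterAssignment
        assignment = ClusterAssignment(
            labels=np.ones(len(individuals), dtype=np.int64), K=1
        )

    if config.dump_clusters:
        with open(config.dump_clusters, "w") as fh:
            fh.write("FID\tIID\tCLUSTER\n")
            for ind, lab in zip(individuals, assignment.labels):
                fh.write(f"{ind.family_id}\t{ind.individual_id}\t{lab}\n")

    stage("origin priors")
    ctx = AnalysisContext(
        units=units, genotypes=genotypes, distances=distances,
        assignment=assignment, K=config.K, epsilon=config.epsilon,
        tol=config.tol, max_iter=config.max_iter, individuals=individuals,
    )

    stage("per-marker analysis")

    def analyze(j: int) -> CaplResult:
        try:
            return capl_test(
                ctx, j, marker_id=markers[j].id, B=config.B,
                seed=marker_seed(config.seed, j),
            )
        except Exception:  # per-marker failures must not abort the run
            logger.exception("marker %s failed", markers[j].id)
            return CaplResult(marker_id=markers[j].id, status="untestable")

    results: list[CaplResult | None] = [None] * n_markers
    ranges = partition_markers(n_markers, config.threads)
    if config.threads == 1:
        for j in range(n_markers):
            results[j] = analyze(j)
    else:
        def work(rng_: range):
            return [(j, analyze(j)) for j in rng_]

        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            for chunk in pool.map(work, ranges):
                for j, res in chunk:
                    results[j] = res

    stage("write results")
    frame = results_to_frame(markers, results, config.K)
    write_results(frame, config.out_path)
    n_ok = sum(r.status == STATUS_OK for r in results)
    logger.info(
        "[%.2fs] done: %d markers, %d tested ok",
        time.perf_counter() - t0, n_markers, n_ok,
    )
    return frame
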
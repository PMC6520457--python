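"""End-to-end orchestration: count -> score -> classify -> call -> report.

``run_pipeline`` executes the stages in a fixed order, writes every
intermediate table as TSV under the output directory, and returns a
machine-readable :class:`RunReport` (serialized as JSON). Reruns on
identical inputs and config produce byte-identical outputs; a failure in
any stage aborts with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io_quant, scoring
from .model import PairedScreenModel

logger = logging.getLogger(__name__)

REPORT_REQUIRED_KEYS = (
    "version",
    "config",
    "stages",
    "group_sizes",
    "essential_genes",
    "ecdf_files",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


class ConfigError(ValueError):
    """The run configuration is invalid (detected before any stage runs)."""


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (mirrors the YAML keys)."""

    library: str
    outdir: str
    counts: str | None = None
    metadata: str | None = None
    fastq: dict[str, str] | None = None  # sample_id -> FASTQ path (alternative to counts)
    control_label: str = io_quant.DEFAULT_CONTROL_LABEL
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT
    center: str | None = "median"
    method: str = "t"
    alpha: float = 0.05
    day: float | None = None  # classification day; None = terminal day
    essential_threshold: float = -5.0
    restrict_to_group8: bool = True
    cell_line_a: str | None = None
    cell_line_b: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.essential_threshold >= 0:
            raise ConfigError("essential_threshold must be negative (a log2 depletion bound)")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.method not in ("t", "ks"):
            raise ConfigError(f"method must be 't' or 'ks', got {self.method!r}")
        if (self.counts is None) == (self.fastq is None):
            raise ConfigError("exactly one of 'counts' or 'fastq' must be given")
        if self.fastq is not None and self.metadata is None:
            raise ConfigError("'metadata' is required when counting from FASTQ")
        paths = [self.library]
        if self.counts is not None:
            paths.append(self.counts)
        if self.metadata is not None:
            paths.append(self.metadata)
        if self.fastq is not None:
            paths.extend(self.fastq.values())
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")

    def echo(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    version: str
    config: dict
    stages: dict[str, int]  # stage name -> rows produced
    group_sizes: dict[str, int]  # "1".."9" -> gene count
    essential_genes: list[str]
    ecdf_files: list[str]
    correlation: dict | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunReport":
        missing = [k for k in REPORT_REQUIRED_KEYS if k not in data]
        if missing:
            raise ConfigError(f"report is missing required key(s): {', '.join(missing)}")
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def write_report(report: RunReport, path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        json.dump(report.to_dict(), out, indent=2, sort_keys=True)
        out.write("\n")


def read_report(path: str | os.PathLike) -> RunReport:
    with open(path) as handle:
        return RunReport.from_dict(json.load(handle))


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapped

    return decorator


@_stage("count")
def _counts_from_fastq(config: RunConfig, library) -> io_quant.CountMatrix:
    import pandas as pd

    samples = pd.read_csv(config.metadata, sep="\t")
    samples["sample_id"] = samples["sample_id"].astype(str)
    samples = samples.set_index("sample_id")
    columns = {}
    for sample_id, fastq_path in config.fastq.items():
        sc = io_quant.count_spacers(fastq_path, library)
        columns[sample_id] = sc.counts
        samples.loc[sample_id, "unassigned"] = sc.unassigned
        samples.loc[sample_id, "ambiguous"] = sc.ambiguous
    counts = pd.DataFrame(columns)
    counts.index.name = "sgrna_id"
    samples = samples.loc[list(columns)]
    return io_quant.CountMatrix(counts=counts, samples=samples)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis and write all outputs under ``config.outdir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, int] = {}

    library = _stage("read_library")(io_quant.read_library)(
        config.library, control_label=config.control_label
    )
    stages["library"] = library.n_sgrnas

    if config.fastq is not None:
        counts = _counts_from_fastq(config, library)
        io_quant.write_counts(counts, outdir / "counts.tsv", outdir / "counts.meta.tsv")
    else:
        counts = _stage("read_counts")(io_quant.read_counts)(config.counts, config.metadata)
    stages["samples"] = len(counts.samples)

    model = PairedScreenModel(
        counts,
        library,
        cell_line_a=config.cell_line_a,
        cell_line_b=config.cell_line_b,
        pseudocount=config.pseudocount,
        test=config.method,
        center=config.center,
    )
    results = _stage("score")(model.fit)(alpha=config.alpha, day=config.day)
    stages["lfc_rows"] = len(results.lfc)
    stages["gene_scores"] = len(results.gene_scores)
    stages["classified_genes"] = len(results.classification)

    calls = results.essential_calls(
        log2_threshold=config.essential_threshold,
        restrict_to_group8=config.restrict_to_group8,
    )
    essential = calls.loc[calls["called"], "gene_id"].tolist()
    stages["essential_calls"] = len(essential)

    def _write(frame, name, index=False):
        frame.to_csv(outdir / name, sep="\t", index=index)

    _write(results.lfc, "lfc.tsv")
    _write(results.gene_scores, "gene_scores.tsv")
    _write(results.classification, "classification.tsv")
    _write(results.group_sizes.reset_index(), "group_sizes.tsv")
    _write(calls, "essential_calls.tsv")

    ecdf_files = []
    conditions = counts.samples[["cell_line", "day"]].drop_duplicates()
    for cell_line, day in conditions.itertuples(index=False):
        curve = results.ecdf(cell_line, day)
        day_label = int(day) if float(day).is_integer() else day
        name = f"ecdf_{cell_line}_d{day_label}.tsv"
        _write(curve, name)
        ecdf_files.append(name)

    try:
        corr = results.correlation
        correlation = {
            "n_shared_genes": corr.n_shared_genes,
            "pearson_r": corr.pearson_r,
            "r_squared": corr.r_squared,
        }
    except Exception:
        correlation = None

    report = RunReport(
        version=__version__,
        config=config.echo(),
        stages=stages,
        group_sizes={str(g): int(n) for g, n in results.group_sizes.items()},
        essential_genes=essential,
        ecdf_files=ecdf_files,
        correlation=correlation,
    )
    write_report(report, outdir / "report.json")
    with open(outdir / "summary.txt", "w") as out:
        out.write(results.summary() + "\n")
    return report
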
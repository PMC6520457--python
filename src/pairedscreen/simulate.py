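"""Synthetic paired pooled dropout screens with planted ground truth.

The generator emulates the structure of a genome-wide negative-selection
screen run in two matched cell contexts (a primary line A and a
transformed line B):

* a library of ``n_genes`` x ``sgrnas_per_gene`` targeting guides plus
  ``n_controls`` non-targeting controls, with unique random 20-nt spacers;
* per gene and cell line a planted fitness ``f`` in log2 units/day drawn
  from one of nine archetypes — every (sign_A, sign_B) pattern over
  {-, 0, +} — mirroring the nine differential-essentiality groups;
* per-sgRNA cutting efficiency ``e`` in [0, 1] (Beta distributed,
  mean 0.85 by default) multiplying the fitness, so partial knockouts
  deplete more slowly;
* exponential relative-abundance dynamics: the expected abundance of
  guide ``s`` in line ``c`` at day ``t`` is proportional to
  ``pi_s * 2**(e_s * f_{g(s),c} * (t - t_ref))`` with log-normal initial
  abundances ``pi_s`` mimicking cloning skew, the fitness acting from the
  reference (first) sampling day;
* sequencing as a multinomial draw of ``coverage x library size`` reads
  per sample, optionally Dirichlet-multinomial overdispersed, optionally
  preceded by a multinomial transduction bottleneck.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_quant import DEFAULT_CONTROL_LABEL, CountMatrix, LibraryTable, make_library

#: (sign in primary line A, sign in transformed line B) for each group archetype.
GROUP_SIGNS: dict[int, tuple[int, int]] = {
    1: (-1, +1),
    2: (0, +1),
    3: (+1, +1),
    4: (-1, 0),
    5: (0, 0),
    6: (+1, 0),
    7: (-1, -1),
    8: (0, -1),
    9: (+1, -1),
}

#: Benchmark mixture: a neutral majority with every archetype planted at a
#: frequency high enough that per-group precision and recall are measurable.
DEFAULT_CLASS_FRACTIONS: dict[int, float] = {
    1: 0.02,
    2: 0.05,
    3: 0.02,
    4: 0.06,
    5: 0.52,
    6: 0.05,
    7: 0.06,
    8: 0.20,
    9: 0.02,
}

#: Mixture with the proportions typical of a genome-wide dropout screen in a
#: paired primary/transformed comparison: overwhelmingly neutral, ~6% of
#: genes essential only in the transformed context, directional-conflict
#: groups vanishingly rare.
SCREEN_LIKE_CLASS_FRACTIONS: dict[int, float] = {
    1: 0.0006,
    2: 0.0343,
    3: 0.0026,
    4: 0.0202,
    5: 0.8346,
    6: 0.0278,
    7: 0.0158,
    8: 0.0634,
    9: 0.0007,
}

# Fixed vector context flanking the spacer in simulated reads: the tail of a
# U6 promoter upstream, the head of the tracrRNA scaffold downstream.
READ_5P_FLANK = "TATCTTGTGGAAAGGACGAAACACCG"
READ_3P_FLANK = "GTTTTAGAGCTAGAAATAGCAAGTT"

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated paired screen.

    Defaults reproduce the geometry and protocol of a genome-wide rat
    knockout screen: 19,840 genes x 3 guides + 10 non-targeting controls,
    sampling at days 1/4/11/21, 300x sequencing coverage, and a per-day
    log2 fitness magnitude of 0.25 so that a fully efficient essential
    guide loses 20 x 0.25 = 5 log2 units (32-fold) between day 1 and
    day 21.
    """

    n_genes: int = 19840
    sgrnas_per_gene: int = 3
    n_controls: int = 10
    spacer_length: int = 20
    days: tuple[float, ...] = (1, 4, 11, 21)
    coverage: float = 300.0
    cell_lines: tuple[str, str] = ("MM", "KMM")  # (primary A, transformed B)
    n_replicates: int = 1
    class_fractions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_size: float = 0.25  # |f| in log2 units/day for non-neutral genes
    efficiency_beta: tuple[float, float] = (8.5, 1.5)  # Beta(a, b), mean 0.85
    initial_sigma: float = 0.5  # sd of initial log2 abundance across guides
    dispersion: float = 0.0  # 0 = pure multinomial sequencing
    bottleneck: int | None = None  # optional pre-day-1 multinomial subsample size
    control_label: str = DEFAULT_CONTROL_LABEL
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise SimulationError("n_genes and sgrnas_per_gene must be >= 1")
        if self.coverage <= 0:
            raise SimulationError("coverage must be > 0")
        if self.effect_size < 0:
            raise SimulationError("effect_size must be >= 0")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if len(self.days) < 2:
            raise SimulationError("need at least a reference day and one later day")
        if len(self.cell_lines) != 2 or len(set(self.cell_lines)) != 2:
            raise SimulationError("cell_lines must be two distinct names")
        bad = [g for g in self.class_fractions if g not in GROUP_SIGNS]
        if bad:
            raise SimulationError(f"unknown group archetype(s): {bad}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise SimulationError(f"class_fractions must sum to 1, got {total}")

    @property
    def n_sgrnas(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_controls

    @property
    def reference_day(self) -> float:
        return min(self.days)

    def with_(self, **changes) -> "SimConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class FitnessTruth:
    """Planted ground truth of a simulated screen.

    fitness
        DataFrame indexed by gene_id, one column per cell line, log2
        units/day (negative = dropout).
    efficiency
        Per-sgRNA cutting efficiency in [0, 1], indexed by sgrna_id
        (controls carry a value but it is never used: their fitness is 0).
    true_group
        Per-gene archetype 1-9 implied by the fitness sign pattern.
    """

    fitness: pd.DataFrame
    efficiency: pd.Series
    true_group: pd.Series


@dataclass(frozen=True)
class SimScreen:
    library: LibraryTable
    truth: FitnessTruth
    counts: CountMatrix


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible generator per simulation stage.

    The stage name is folded in through a process-independent CRC so that
    e.g. regenerating only the counts never disturbs the library draw.
    """
    return np.random.default_rng([zlib.crc32(stream.encode()), config.seed])


def _random_spacers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random ACGT k-mers; resamples collisions."""
    max_rounds = 50
    seen: dict[str, None] = {}
    for _ in range(max_rounds):
        need = n - len(seen)
        if need == 0:
            break
        draws = _BASES[rng.integers(0, 4, size=(need, length))]
        for row in draws:
            if len(seen) < n:
                seen.setdefault("".join(row), None)
    if len(seen) < n:
        raise SimulationError(
            f"could not draw {n} distinct {length}-mers; increase spacer_length"
        )
    return list(seen)


def simulate_library(config: SimConfig) -> LibraryTable:
    """Random library with the configured geometry; deterministic given seed."""
    config.validate()
    rng = _rng(config, "library")
    width = max(5, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    sgrna_ids = [
        f"{g}_sg{j}" for g in genes for j in range(1, config.sgrnas_per_gene + 1)
    ]
    sgrna_ids += [f"nt_sg{j:02d}" for j in range(1, config.n_controls + 1)]
    gene_ids = [g for g in genes for _ in range(config.sgrnas_per_gene)]
    gene_ids += [config.control_label] * config.n_controls
    spacers = _random_spacers(rng, len(sgrna_ids), config.spacer_length)
    frame = pd.DataFrame({"sgrna_id": sgrna_ids, "gene_id": gene_ids, "spacer": spacers})
    return make_library(frame, control_label=config.control_label)


def assign_fitness(library: LibraryTable, config: SimConfig) -> FitnessTruth:
    """Draw per-gene archetypes from the class mixture and per-guide efficiencies."""
    config.validate()
    rng = _rng(config, "fitness")
    genes = library.genes
    groups = sorted(config.class_fractions)
    probs = np.array([config.class_fractions[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    true_group = pd.Series(
        rng.choice(groups, size=len(genes), p=probs), index=genes, name="true_group"
    )
    signs = np.array([GROUP_SIGNS[g] for g in true_group], dtype=float)
    line_a, line_b = config.cell_lines
    fitness = pd.DataFrame(
        {
            line_a: signs[:, 0] * config.effect_size,
            line_b: signs[:, 1] * config.effect_size,
        },
        index=genes,
    )
    a, b = config.efficiency_beta
    efficiency = pd.Series(
        rng.beta(a, b, size=library.n_sgrnas),
        index=pd.Index(library.frame["sgrna_id"], name="sgrna_id"),
        name="efficiency",
    )
    return FitnessTruth(fitness=fitness, efficiency=efficiency, true_group=true_group)


def expected_log2_change(
    library: LibraryTable, truth: FitnessTruth, config: SimConfig, cell_line: str, day: float
) -> pd.Series:
    """Noise-free per-sgRNA log2 abundance change vs the reference day.

    ``e_s * f_{g(s),c} * (t - t_ref)``; 0 for controls. This is the
    quantity the sequencing sampling fluctuates around (up to the
    renormalization shared by all guides in the sample).
    """
    frame = library.frame
    f = truth.fitness[cell_line].reindex(frame["gene_id"]).fillna(0.0).to_numpy()
    e = truth.efficiency.reindex(frame["sgrna_id"]).to_numpy()
    dt = day - config.reference_day
    return pd.Series(
        e * f * dt, index=pd.Index(frame["sgrna_id"], name="sgrna_id"), name="log2_change"
    )


def _sample_id(cell_line: str, day: float, replicate: int, n_replicates: int) -> str:
    day_label = int(day) if float(day).is_integer() else day
    base = f"{cell_line}_d{day_label}"
    return f"{base}_r{replicate}" if n_replicates > 1 else base


def simulate_counts(library: LibraryTable, truth: FitnessTruth, config: SimConfig) -> CountMatrix:
    """Sample the sgRNA x sample count matrix for the whole time course."""
    config.validate()
    rng = _rng(config, "counts")
    n = library.n_sgrnas
    log2_pi = rng.normal(0.0, config.initial_sigma, size=n)
    pi = np.exp2(log2_pi)
    if config.bottleneck is not None:
        pi = rng.multinomial(int(config.bottleneck), pi / pi.sum()).astype(float)
    total = int(round(config.coverage * n))
    growth = {
        cell_line: np.array(
            [
                expected_log2_change(library, truth, config, cell_line, day).to_numpy()
                for day in config.days
            ]
        )
        for cell_line in config.cell_lines
    }
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for cell_line in config.cell_lines:
        for di, day in enumerate(config.days):
            w = pi * np.exp2(growth[cell_line][di])
            if w.sum() == 0:
                raise SimulationError("all abundances zero (bottleneck lost the library)")
            p = w / w.sum()
            for replicate in range(1, config.n_replicates + 1):
                if config.dispersion > 0:
                    alpha = p / config.dispersion
                    pos = alpha > 0
                    q = np.zeros_like(p)
                    q[pos] = rng.dirichlet(alpha[pos])
                else:
                    q = p
                counts = rng.multinomial(total, q)
                sid = _sample_id(cell_line, day, replicate, config.n_replicates)
                columns[sid] = counts
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cell_line": cell_line,
                        "day": day,
                        "replicate": replicate,
                    }
                )
    counts = pd.DataFrame(
        columns, index=pd.Index(library.frame["sgrna_id"], name="sgrna_id"), dtype=np.int64
    )
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)


def simulate_screen(config: SimConfig) -> SimScreen:
    """Library + planted truth + sampled counts, all from one config/seed."""
    library = simulate_library(config)
    truth = assign_fitness(library, config)
    counts = simulate_counts(library, truth, config)
    return SimScreen(library=library, truth=truth, counts=counts)


def simulate_reads(screen: SimScreen, sample_id: str, path: str | os.PathLike) -> int:
    """Write a FASTQ for one sample: count-many reads per sgRNA, spacer in
    fixed vector context. Recounting with ``count_spacers`` reproduces the
    sample's counts exactly. Returns the number of reads written."""
    if sample_id not in screen.counts.counts.columns:
        raise SimulationError(f"unknown sample {sample_id!r}")
    counts = screen.counts.counts[sample_id]
    n_written = 0
    with open(path, "w") as out:
        for sid, spacer, c in zip(
            screen.library.frame["sgrna_id"], screen.library.frame["spacer"], counts
        ):
            seq = READ_5P_FLANK + spacer + READ_3P_FLANK
            qual = "I" * len(seq)
            for i in range(int(c)):
                out.write(f"@{sid}:{i}\n{seq}\n+\n{qual}\n")
                n_written += 1
    return n_written


@dataclass(frozen=True)
class RecoveryReport:
    """Agreement between called and planted groups."""

    confusion: pd.DataFrame  # index true group 1-9, columns called group 1-9
    precision: pd.Series  # per called group; NaN where nothing was called
    recall: pd.Series  # per true group; NaN where nothing was planted
    accuracy: float


def evaluate_recovery(rows: pd.DataFrame, truth: FitnessTruth) -> RecoveryReport:
    """Score a classification against the planted truth.

    ``rows`` is a classification table with ``gene_id`` and ``group``; the
    gene universes must match exactly.
    """
    called = rows.set_index("gene_id")["group"]
    if set(called.index) != set(truth.true_group.index):
        raise SimulationError("classified genes do not match the simulated gene universe")
    true = truth.true_group.reindex(called.index)
    labels = range(1, 10)
    confusion = pd.crosstab(true, called).reindex(
        index=labels, columns=labels, fill_value=0
    )
    confusion.index.name = "true_group"
    confusion.columns.name = "called_group"
    diag = np.diag(confusion.to_numpy()).astype(float)
    called_totals = confusion.sum(axis=0).to_numpy().astype(float)
    true_totals = confusion.sum(axis=1).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = pd.Series(
            np.where(called_totals > 0, diag / called_totals, np.nan),
            index=pd.Index(labels, name="group"),
            name="precision",
        )
        recall = pd.Series(
            np.where(true_totals > 0, diag / true_totals, np.nan),
            index=pd.Index(labels, name="group"),
            name="recall",
        )
    accuracy = float(diag.sum() / len(called))
    return RecoveryReport(
        confusion=confusion, precision=precision, recall=recall, accuracy=accuracy
    )
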
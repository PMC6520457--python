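"""Library validation, spacer counting and count-matrix I/O.

A pooled CRISPR screen starts from three tab-separated artifacts:

* a **library table** — one row per sgRNA with its 20-nt spacer, target
  gene, and a flag marking non-targeting controls;
* a **count matrix** — integer sgRNA x sample read counts;
* a **sample metadata table** — cell line, day post-transduction and
  replicate for every sample, plus per-sample unassigned/ambiguous read
  tallies from quantification.

Quantification itself (`count_spacers`) assigns each read to the unique
library spacer occurring as an exact forward-orientation substring; reads
hitting no spacer are *unassigned*, reads hitting spacers of two or more
distinct sgRNAs are *ambiguous* and discarded, so
``assigned + unassigned + ambiguous == total reads`` always holds.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

DEFAULT_CONTROL_LABEL = "non-targeting"

_SPACER_ALPHABET = frozenset("ACGT")

LIBRARY_COLUMNS = ("sgrna_id", "gene_id", "spacer")
METADATA_COLUMNS = ("sample_id", "cell_line", "day", "replicate")


class LibraryError(ValueError):
    """Raised when an sgRNA library fails validation."""


@dataclass(frozen=True)
class LibraryTable:
    """Validated sgRNA library.

    Attributes
    ----------
    frame
        DataFrame with columns ``sgrna_id, gene_id, spacer, is_control``,
        one row per sgRNA, in file order.
    control_label
        The reserved ``gene_id`` marking non-targeting controls.
    """

    frame: pd.DataFrame
    control_label: str = DEFAULT_CONTROL_LABEL

    @property
    def n_sgrnas(self) -> int:
        return len(self.frame)

    @property
    def n_controls(self) -> int:
        return int(self.frame["is_control"].sum())

    @property
    def genes(self) -> pd.Index:
        """Targeting gene identifiers, in order of first appearance."""
        targeting = self.frame.loc[~self.frame["is_control"], "gene_id"]
        return pd.Index(targeting.unique(), name="gene_id")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def duplicate_spacers(self) -> pd.Series:
        """Spacers shared by >1 sgRNA (flagged, not an error); counts per spacer."""
        counts = self.frame["spacer"].value_counts()
        return counts[counts > 1]

    def spacer_index(self) -> dict[str, list[str]]:
        """Map spacer sequence -> list of sgrna_ids carrying it."""
        index: dict[str, list[str]] = {}
        for sid, spacer in zip(self.frame["sgrna_id"], self.frame["spacer"]):
            index.setdefault(spacer, []).append(sid)
        return index


def make_library(frame: pd.DataFrame, control_label: str = DEFAULT_CONTROL_LABEL) -> LibraryTable:
    """Validate a raw library frame and return a :class:`LibraryTable`.

    Validation is pure: the input frame is copied, never mutated, and
    repeated calls give identical results.
    """
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise LibraryError(f"library is missing required column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(LIBRARY_COLUMNS)].copy()
    frame["sgrna_id"] = frame["sgrna_id"].astype(str)
    frame["gene_id"] = frame["gene_id"].astype(str)
    frame["spacer"] = frame["spacer"].astype(str)

    dup = frame["sgrna_id"][frame["sgrna_id"].duplicated()]
    if len(dup):
        raise LibraryError(f"duplicate sgrna_id: {dup.iloc[0]!r}")
    for line_no, (sid, spacer) in enumerate(zip(frame["sgrna_id"], frame["spacer"]), start=2):
        if not spacer or not _SPACER_ALPHABET.issuperset(spacer):
            raise LibraryError(
                f"line {line_no} (sgRNA {sid!r}): spacer {spacer!r} is not uppercase ACGT"
            )
    frame["is_control"] = frame["gene_id"] == control_label
    frame = frame.reset_index(drop=True)
    return LibraryTable(frame=frame, control_label=control_label)


def read_library(path: str | os.PathLike, control_label: str = DEFAULT_CONTROL_LABEL) -> LibraryTable:
    """Read a tab-separated sgRNA library (columns sgrna_id, gene_id, spacer)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return make_library(frame, control_label=control_label)


def write_library(library: LibraryTable, path: str | os.PathLike) -> None:
    library.frame.loc[:, list(LIBRARY_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spacer counting
# ---------------------------------------------------------------------------


@dataclass
class SpacerCounts:
    """Per-sgRNA read counts for one sample, with read accounting."""

    counts: pd.Series  # index sgrna_id, int
    unassigned: int
    ambiguous: int

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())

    @property
    def total_reads(self) -> int:
        return self.assigned + self.unassigned + self.ambiguous


def _iter_read_sequences(reads) -> Iterator[str]:
    """Yield upper-case read sequences from a FASTQ path/handle or an iterable of strings."""
    if isinstance(reads, (str, os.PathLike)):
        with open(reads) as handle:
            for record in SeqIO.parse(handle, "fastq"):
                yield str(record.seq).upper()
        return
    if isinstance(reads, io.IOBase) or hasattr(reads, "readline"):
        for record in SeqIO.parse(reads, "fastq"):
            yield str(record.seq).upper()
        return
    for seq in reads:
        yield str(seq).upper()


def count_spacers(reads, library: LibraryTable) -> SpacerCounts:
    """Quantify library spacers in a stream of reads for one sample.

    Each read is assigned to the sgRNA whose spacer occurs as an exact
    substring (forward orientation only). Reads matching spacers of two or
    more distinct sgRNAs — including a spacer duplicated in the library —
    are counted as ambiguous and discarded.

    Parameters
    ----------
    reads
        FASTQ path, open FASTQ handle, or iterable of sequence strings.
    library
        Validated library; must be non-empty.
    """
    if library.n_sgrnas == 0:
        raise LibraryError("cannot count against an empty library")
    spacer_index = library.spacer_index()
    lengths = sorted({len(s) for s in spacer_index})
    counts: dict[str, int] = dict.fromkeys(library.frame["sgrna_id"], 0)
    unassigned = 0
    ambiguous = 0
    for seq in _iter_read_sequences(reads):
        hits: set[str] = set()
        for k in lengths:
            for start in range(0, len(seq) - k + 1):
                ids = spacer_index.get(seq[start : start + k])
                if ids is not None:
                    hits.update(ids)
                    if len(hits) > 1:
                        break
            if len(hits) > 1:
                break
        if not hits:
            unassigned += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            counts[hits.pop()] += 1
    series = pd.Series(counts, name="count", dtype=np.int64)
    series.index.name = "sgrna_id"
    return SpacerCounts(counts=series, unassigned=unassigned, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# count matrix + sample metadata
# ---------------------------------------------------------------------------


class CountMatrixError(ValueError):
    """Raised when counts/metadata fail validation."""


@dataclass
class CountMatrix:
    """sgRNA x sample integer counts plus sample metadata.

    ``counts`` is indexed by sgrna_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns
    ``cell_line, day, replicate, is_reference, unassigned, ambiguous``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.name != "sgrna_id":
            counts.index.name = "sgrna_id"
        if samples.index.name != "sample_id":
            samples.index.name = "sample_id"
        missing_meta = [s for s in counts.columns if s not in samples.index]
        if missing_meta:
            raise CountMatrixError(
                f"sample(s) in counts absent from metadata: {', '.join(map(str, missing_meta))}"
            )
        extra_meta = [s for s in samples.index if s not in counts.columns]
        if extra_meta:
            raise CountMatrixError(
                f"sample(s) in metadata absent from counts: {', '.join(map(str, extra_meta))}"
            )
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise CountMatrixError("counts must be integers")
            self.counts = counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise CountMatrixError("counts must be non-negative")
        for col, default in (("is_reference", False), ("unassigned", 0), ("ambiguous", 0)):
            if col not in samples.columns:
                samples[col] = default
        samples["is_reference"] = samples["is_reference"].astype(bool)
        if (samples["day"] < 0).any():
            raise CountMatrixError("day must be non-negative")
        if (samples["replicate"] < 1).any():
            raise CountMatrixError("replicate must be a positive integer")
        key = samples[["cell_line", "day", "replicate"]]
        if key.duplicated().any():
            bad = key[key.duplicated()].iloc[0]
            raise CountMatrixError(
                f"duplicate (cell_line, day, replicate): ({bad.cell_line}, {bad.day}, {bad.replicate})"
            )
        for cell_line, grp in samples.groupby("cell_line", sort=False):
            refs = grp.loc[grp["is_reference"]]
            if refs["day"].nunique() > 1:
                raise CountMatrixError(
                    f"cell line {cell_line!r} has reference samples at multiple days: "
                    f"{sorted(refs['day'].unique())}"
                )

    @property
    def cell_lines(self) -> list[str]:
        """Cell lines in order of first appearance in the metadata."""
        return list(self.samples["cell_line"].unique())

    def reference_day(self, cell_line: str) -> float:
        """Reference day for a cell line: the flagged day, else the smallest day."""
        grp = self.samples[self.samples["cell_line"] == cell_line]
        if grp.empty:
            raise CountMatrixError(f"unknown cell line {cell_line!r}")
        refs = grp.loc[grp["is_reference"], "day"]
        if len(refs):
            return refs.iloc[0]
        return grp["day"].min()


def metadata_path_for(counts_path: str | os.PathLike) -> str:
    """Conventional companion metadata path: counts.tsv -> counts.meta.tsv."""
    base, ext = os.path.splitext(os.fspath(counts_path))
    return f"{base}.meta{ext or '.tsv'}"


def read_counts(counts_path: str | os.PathLike, metadata_path: str | os.PathLike | None = None) -> CountMatrix:
    """Read a count matrix TSV and its companion sample-metadata TSV."""
    if metadata_path is None:
        metadata_path = metadata_path_for(counts_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col="sgrna_id")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise CountMatrixError(f"non-integer count in {counts_path}")
    counts = counts.astype(np.int64)
    samples = pd.read_csv(metadata_path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise CountMatrixError(f"metadata is missing column(s): {', '.join(missing)}")
    samples["sample_id"] = samples["sample_id"].astype(str)
    samples = samples.set_index("sample_id")
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts=counts, samples=samples)


def write_counts(matrix: CountMatrix, counts_path: str | os.PathLike, metadata_path: str | os.PathLike | None = None) -> None:
    """Write counts + metadata TSVs; ``read_counts`` round-trips them exactly."""
    if metadata_path is None:
        metadata_path = metadata_path_for(counts_path)
    matrix.counts.to_csv(counts_path, sep="\t")
    cols = ["cell_line", "day", "replicate", "is_reference", "unassigned", "ambiguous"]
    matrix.samples.loc[:, cols].to_csv(metadata_path, sep="\t")
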
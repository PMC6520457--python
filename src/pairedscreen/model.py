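"""Model/Results interface over a paired dropout screen.

``PairedScreenModel`` holds the data (count matrix + library + the roles of
the two cell lines); ``fit`` runs normalization, per-sgRNA log2 fold
changes, gene-level CRISPR scores with significance tests, and the
nine-group classification at the terminal day, returning a
``PairedScreenResults`` with the estimates, diagnostics and a ``summary()``
table.

Example
-------
>>> from pairedscreen import SimConfig, simulate_screen, PairedScreenModel
>>> screen = simulate_screen(SimConfig(n_genes=500, seed=7))
>>> res = PairedScreenModel(screen.counts, screen.library).fit(alpha=0.05)
>>> res.group_sizes.sum() == 500
True
"""

from __future__ import annotations

from functools import cached_property

import pandas as pd

from . import classify as _classify
from . import scoring as _scoring
from .io_quant import CountMatrix, LibraryTable, read_counts, read_library


class PairedScreenModel:
    """A paired pooled CRISPR dropout screen ready to be scored.

    Parameters
    ----------
    counts
        sgRNA x sample count matrix with metadata.
    library
        Validated sgRNA library.
    cell_line_a, cell_line_b
        Roles of the two contexts: A is the matched primary (reference
        biology), B the transformed line whose specific vulnerabilities
        are sought. Default: first and second cell line by order of
        appearance in the metadata.
    pseudocount
        Added inside the log ratio (default 0.5).
    test
        "t" (one-sample t across a gene's sgRNAs) or "ks" (vs the
        non-targeting controls).
    center
        Composition-bias correction of the per-sgRNA lfc;
        "median" (default) subtracts each (cell line, day)'s median lfc
        so the neutral majority sits at 0, None keeps raw ratios.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: LibraryTable,
        cell_line_a: str | None = None,
        cell_line_b: str | None = None,
        pseudocount: float = _scoring.DEFAULT_PSEUDOCOUNT,
        test: str = "t",
        center: str | None = "median",
    ) -> None:
        self.counts = counts
        self.library = library
        lines = counts.cell_lines
        if cell_line_a is None or cell_line_b is None:
            if len(lines) != 2:
                raise ValueError(
                    f"screen has {len(lines)} cell lines {lines}; pass cell_line_a/cell_line_b"
                )
            cell_line_a, cell_line_b = lines
        for line in (cell_line_a, cell_line_b):
            if line not in lines:
                raise ValueError(f"cell line {line!r} not present in the metadata")
        self.cell_line_a = cell_line_a
        self.cell_line_b = cell_line_b
        self.pseudocount = pseudocount
        self.test = test
        self.center = center

    @classmethod
    def from_files(
        cls,
        counts_path,
        library_path,
        metadata_path=None,
        control_label=None,
        **kwargs,
    ) -> "PairedScreenModel":
        """Build the model straight from counts/metadata/library TSVs."""
        lib_kw = {} if control_label is None else {"control_label": control_label}
        library = read_library(library_path, **lib_kw)
        counts = read_counts(counts_path, metadata_path)
        return cls(counts, library, **kwargs)

    def fit(self, alpha: float = 0.05, day: float | None = None) -> "PairedScreenResults":
        """Score and classify the screen.

        Parameters
        ----------
        alpha
            Significance level for the per-cell-line states (strict
            p < alpha).
        day
            Day of the classification; default the terminal (largest) day.
        """
        lfc = _scoring.lfc_from_counts(
            self.counts, pseudocount=self.pseudocount, center=self.center
        )
        scores = _scoring.gene_test(lfc, self.library, method=self.test)
        if day is None:
            day = lfc["day"].max()
        scores_a = scores[scores["cell_line"] == self.cell_line_a]
        scores_b = scores[scores["cell_line"] == self.cell_line_b]
        classification = _classify.classify_screen(scores_b, scores_a, day=day, alpha=alpha)
        return PairedScreenResults(
            model=self, lfc=lfc, gene_scores=scores, classification=classification,
            alpha=alpha, day=day,
        )


class PairedScreenResults:
    """Fitted quantities of a paired screen.

    Attributes
    ----------
    lfc
        Tidy per-sgRNA log2 fold changes (sgrna_id, cell_line, day, lfc).
    gene_scores
        Per-gene CRISPR scores and p-values for every (cell_line, day).
    classification
        One row per gene: cs/p in both lines at the terminal day and the
        group 1-9.
    alpha, day
        Significance level and classification day used by the fit.
    """

    def __init__(self, model, lfc, gene_scores, classification, alpha, day):
        self.model = model
        self.lfc = lfc
        self.gene_scores = gene_scores
        self.classification = classification
        self.alpha = alpha
        self.day = day

    @cached_property
    def group_sizes(self) -> pd.Series:
        """Gene count per group 1-9; sums to the shared gene universe."""
        return _classify.group_sizes(self.classification)

    @cached_property
    def correlation(self) -> _classify.ScreenCorrelation:
        """Pearson r / r^2 of the two lines' CRISPR scores at the fit day."""
        scores_a = self.gene_scores[self.gene_scores["cell_line"] == self.model.cell_line_a]
        scores_b = self.gene_scores[self.gene_scores["cell_line"] == self.model.cell_line_b]
        return _classify.correlate_screens(scores_a, scores_b, day=self.day)

    def essential_calls(
        self,
        log2_threshold: float = _classify.DEFAULT_ESSENTIAL_LOG2_THRESHOLD,
        restrict_to_group8: bool = True,
    ) -> pd.DataFrame:
        """Strict essential calls (terminal cs_b <= threshold, group 8 by default)."""
        return _classify.call_strict_essential(
            self.classification, log2_threshold=log2_threshold,
            restrict_to_group8=restrict_to_group8,
        )

    def essential_genes(self, **kwargs) -> list[str]:
        calls = self.essential_calls(**kwargs)
        return calls.loc[calls["called"], "gene_id"].tolist()

    def ecdf(self, cell_line: str, day: float) -> pd.DataFrame:
        """Empirical CDF of sgRNA lfc for one sample condition."""
        return _scoring.ecdf(self.lfc, cell_line, day)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lib = m.library
        lines = [
            "Paired CRISPR Screen Results".center(64),
            "=" * 64,
            f"Primary line (A):     {m.cell_line_a:<12} Genes scored: {len(self.classification):>8,}",
            f"Transformed line (B): {m.cell_line_b:<12} sgRNAs:       {lib.n_sgrnas:>8,}",
            f"Test: {('one-sample t' if m.test == 't' else 'KS vs controls'):<15} "
            f"alpha: {self.alpha:<8} day: {self.day}",
            "-" * 64,
            f"{'Group':<7}{'Description':<30}{'Genes':>10}",
        ]
        for g, n in self.group_sizes.items():
            lines.append(f"{g:<7}{_classify.GROUP_DESCRIPTIONS[g]:<30}{n:>10,}")
        lines.append("-" * 64)
        essential = self.essential_genes()
        lines.append(
            f"Strict essential in B (group 8, log2 <= -5): {len(essential):,} gene(s)"
        )
        try:
            corr = self.correlation
            lines.append(
                f"A-B score correlation: r = {corr.pearson_r:+.3f}, "
                f"R^2 = {corr.r_squared:.3f} (n = {corr.n_shared_genes:,})"
            )
        except _classify.ClassifyError:
            pass
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return (
            f"<PairedScreenResults: {len(self.classification)} genes, "
            f"day {self.day}, alpha {self.alpha}>"
        )
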
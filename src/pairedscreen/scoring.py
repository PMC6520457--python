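"""Counts -> CRISPR scores.

The dropout signal of a pooled screen is read off as the change in relative
sgRNA abundance between a later sampling day and the day-1 baseline:

* counts are scaled to reads-per-million (CPM) within each sample;
* replicate samples of the same (cell line, day) are averaged on the CPM
  scale;
* per sgRNA, ``lfc = log2((cpm_t + c) / (cpm_ref + c))`` with a small
  pseudocount ``c`` (default 0.5) keeping ratios finite at zero counts;
* the per-gene **CRISPR score** is the arithmetic mean of the gene's sgRNA
  log2 fold changes — negative for depleted (essential) genes, positive
  for enriched (growth-suppressive) ones;
* a two-sided p-value per gene comes from either a one-sample t test of
  the gene's sgRNA lfc values against 0 (default), or a two-sample
  Kolmogorov-Smirnov test against the non-targeting-control lfc
  distribution.

Degenerate t cases are resolved deterministically and monotonically with
the evidence: zero variance with non-zero mean -> p = 0; zero variance with
zero mean -> p = 1; a single sgRNA -> p = 1 with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_quant import CountMatrix, LibraryTable

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5

LFC_COLUMNS = ("sgrna_id", "cell_line", "day", "lfc")
SCORE_COLUMNS = ("gene_id", "cell_line", "day", "cs", "n_sgrna")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedMatrix:
    """Reads-per-million matrix; the pseudocount is stored for downstream ratios."""

    cpm: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT


def normalize_cpm(counts: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> NormalizedMatrix:
    """Scale each sample to reads per million. Totals must be positive."""
    if pseudocount <= 0:
        raise ScoringError("pseudocount must be positive")
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ScoringError(f"sample(s) with zero total count: {', '.join(map(str, zero))}")
    cpm = counts.counts / totals * 1e6
    return NormalizedMatrix(cpm=cpm, pseudocount=pseudocount)


def sgrna_lfc(
    norm: NormalizedMatrix,
    samples: pd.DataFrame,
    reference_day: float | None = None,
    center: str | None = None,
) -> pd.DataFrame:
    """Per-sgRNA log2 fold change vs each cell line's reference day.

    Parameters
    ----------
    norm
        CPM matrix from :func:`normalize_cpm`.
    samples
        Sample metadata indexed by sample_id (``cell_line, day, replicate``,
        optional ``is_reference``).
    reference_day
        Force a common reference day. Default: per cell line, the flagged
        reference day if any, else the smallest day.
    center
        ``"median"`` subtracts the per-(cell line, day) median lfc.
        Sequencing measures *relative* abundance, so strong enrichment or
        depletion of a minority of guides shifts every other guide's raw
        ratio (composition bias); median-centering restores a zero
        baseline for the neutral majority. ``None`` (default) leaves the
        raw ratios. The reference day's lfc is identically 0 either way.

    Returns
    -------
    DataFrame
        Tidy table ``sgrna_id, cell_line, day, lfc``. Replicates are
        averaged on the CPM scale before the ratio.
    """
    if center not in (None, "median"):
        raise ScoringError(f"unknown centering {center!r} (expected None or 'median')")
    pc = norm.pseudocount
    frames: list[pd.DataFrame] = []
    for cell_line in samples["cell_line"].unique():
        grp = samples[samples["cell_line"] == cell_line]
        # replicate average per day, on the cpm scale
        by_day = {
            day: norm.cpm[list(sub.index)].mean(axis=1)
            for day, sub in grp.groupby("day", sort=True)
        }
        if reference_day is not None:
            ref = reference_day
        elif "is_reference" in grp.columns and grp["is_reference"].any():
            ref = grp.loc[grp["is_reference"], "day"].iloc[0]
        else:
            ref = grp["day"].min()
        if ref not in by_day:
            raise ScoringError(f"cell line {cell_line!r} has no sample at reference day {ref}")
        ref_cpm = by_day[ref]
        for day, cpm_t in by_day.items():
            lfc = np.log2((cpm_t + pc) / (ref_cpm + pc))
            if center == "median":
                lfc = lfc - np.median(lfc)
            frames.append(
                pd.DataFrame(
                    {
                        "sgrna_id": lfc.index,
                        "cell_line": cell_line,
                        "day": day,
                        "lfc": lfc.to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def lfc_from_counts(
    counts: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    reference_day: float | None = None,
    center: str | None = None,
) -> pd.DataFrame:
    """Convenience: CPM-normalize and compute the tidy lfc table in one step."""
    norm = normalize_cpm(counts, pseudocount=pseudocount)
    return sgrna_lfc(norm, counts.samples, reference_day=reference_day, center=center)


def _targeting_lfc(lfcs: pd.DataFrame, library: LibraryTable) -> pd.DataFrame:
    merged = lfcs.merge(
        library.frame[["sgrna_id", "gene_id", "is_control"]], on="sgrna_id", how="inner"
    )
    return merged


def gene_score(lfcs: pd.DataFrame, library: LibraryTable) -> pd.DataFrame:
    """Per-gene CRISPR score: mean sgRNA lfc per (gene, cell line, day).

    Control sgRNAs are excluded. Genes present in the library but with no
    lfc rows (all sgRNAs filtered out upstream) are dropped with a warning.
    """
    merged = _targeting_lfc(lfcs, library)
    targeting = merged[~merged["is_control"]]
    out = (
        targeting.groupby(["gene_id", "cell_line", "day"], sort=True, observed=True)["lfc"]
        .agg(cs="mean", n_sgrna="size")
        .reset_index()
    )
    scored = set(out["gene_id"].unique())
    dropped = [g for g in library.genes if g not in scored]
    if dropped:
        logger.warning(
            "%d gene(s) had no sgRNA lfc values and were dropped (first: %s)",
            len(dropped),
            dropped[0],
        )
    return out


def _t_pvalues(mean: np.ndarray, sd: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided one-sample t p-values against 0, with deterministic degenerate rules."""
    p = np.ones_like(mean, dtype=float)
    single = n < 2
    zero_var = (~single) & (sd == 0)
    regular = (~single) & (sd > 0)
    p[zero_var & (mean != 0)] = 0.0
    p[zero_var & (mean == 0)] = 1.0
    if regular.any():
        t = mean[regular] / (sd[regular] / np.sqrt(n[regular]))
        p[regular] = 2.0 * stats.t.sf(np.abs(t), df=n[regular] - 1)
    return p


def gene_test(
    lfcs: pd.DataFrame,
    library: LibraryTable,
    method: str = "t",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Gene scores with two-sided p-values per (gene, cell line, day).

    method="t"
        One-sample t test of the gene's sgRNA lfc values against 0
        (df = n_sgrna - 1). Genes with a single sgRNA get p = 1 with a
        warning; zero-variance cases follow the degenerate rules above.
    method="ks"
        Two-sample Kolmogorov-Smirnov test of the gene's sgRNA lfc values
        against the pooled non-targeting-control lfc distribution of the
        same (cell line, day); requires >= 1 control sgRNA.
    adjust="bh"
        Optionally Benjamini-Hochberg-adjust p-values within each
        (cell line, day) stratum into a ``qvalue`` column. No correction
        is applied by default.
    """
    if method not in ("t", "ks"):
        raise ScoringError(f"unknown test method {method!r} (expected 't' or 'ks')")
    merged = _targeting_lfc(lfcs, library)
    targeting = merged[~merged["is_control"]]
    grouped = (
        targeting.groupby(["gene_id", "cell_line", "day"], sort=True, observed=True)["lfc"]
        .agg(cs="mean", sd="std", n_sgrna="size")  # std is ddof=1
        .reset_index()
    )
    if method == "t":
        n = grouped["n_sgrna"].to_numpy()
        if (n < 2).any():
            warnings.warn(
                "gene(s) with a single sgRNA: t test undefined, p set to 1", stacklevel=2
            )
        grouped["pvalue"] = _t_pvalues(
            grouped["cs"].to_numpy(), grouped["sd"].fillna(0.0).to_numpy(), n
        )
    else:
        controls = merged[merged["is_control"]]
        if controls.empty:
            raise ScoringError("KS test requires at least one non-targeting control sgRNA")
        null_by_stratum = {
            key: sub["lfc"].to_numpy() for key, sub in controls.groupby(["cell_line", "day"])
        }
        pvals = np.empty(len(grouped))
        gene_values = {
            key: sub["lfc"].to_numpy()
            for key, sub in targeting.groupby(["gene_id", "cell_line", "day"], observed=True)
        }
        for i, row in enumerate(grouped.itertuples(index=False)):
            null = null_by_stratum[(row.cell_line, row.day)]
            vals = gene_values[(row.gene_id, row.cell_line, row.day)]
            pvals[i] = stats.ks_2samp(vals, null, alternative="two-sided").pvalue
        grouped["pvalue"] = pvals
    out = grouped.drop(columns="sd")
    if adjust is not None:
        if adjust != "bh":
            raise ScoringError(f"unknown adjustment {adjust!r} (expected 'bh')")
        out["qvalue"] = out.groupby(["cell_line", "day"], observed=True)["pvalue"].transform(
            lambda p: stats.false_discovery_control(p, method="bh")
        )
    return out


def score_screen(
    counts: CountMatrix,
    library: LibraryTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "t",
    adjust: str | None = None,
    center: str | None = "median",
) -> pd.DataFrame:
    """Counts -> gene score table (cs, pvalue, n_sgrna) in one call.

    Median-centers the lfc by default (see :func:`sgrna_lfc`).
    """
    lfcs = lfc_from_counts(counts, pseudocount=pseudocount, center=center)
    return gene_test(lfcs, library, method=method, adjust=adjust)


def ecdf(lfcs: pd.DataFrame, cell_line: str, day: float) -> pd.DataFrame:
    """Empirical CDF of sgRNA lfc values for one (cell line, day).

    Returns a DataFrame ``value, fraction`` with values ascending and
    fractions stepping from 1/n to 1. A leftward shift of later days
    relative to day 1 signals global guide depletion.
    """
    sel = lfcs[(lfcs["cell_line"] == cell_line) & (lfcs["day"] == day)]["lfc"]
    if sel.empty:
        raise ScoringError(f"no sgRNA lfc values for cell line {cell_line!r} at day {day}")
    values = np.sort(sel.to_numpy())
    n = len(values)
    fractions = np.arange(1, n + 1) / n
    return pd.DataFrame({"value": values, "fraction": fractions})
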
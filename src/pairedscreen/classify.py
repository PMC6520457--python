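"""Nine-group differential-essentiality classification of a paired screen.

Each gene is reduced, per cell line, to one of three states from its
terminal-day CRISPR score and p-value at level ``alpha`` (default 0.05,
strict inequality):

* **sig-up**   — p < alpha and cs > 0 (enriched / growth-suppressive)
* **sig-down** — p < alpha and cs < 0 (depleted / essential)
* **ns**       — p >= alpha, or cs exactly 0 (no direction to call)

Crossing the state of the transformed line (B) against the matched
primary line (A) gives the 3 x 3 = 9 groups:

====================  ===========  =======  ===========
B state \\ A state     sig-down     ns       sig-up
====================  ===========  =======  ===========
sig-up                group 1      group 2  group 3
ns                    group 4      group 5  group 6
sig-down              group 7      group 8  group 9
====================  ===========  =======  ===========

Group 8 — depleted only in the transformed line — holds the candidate
context-specific vulnerabilities; the *strict essential* call further
requires a terminal log2 CRISPR score <= -5, i.e. >= 32-fold depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_ESSENTIAL_LOG2_THRESHOLD = -5.0

GROUP_DESCRIPTIONS = {
    1: "B enriched, A depleted",
    2: "B enriched, A unchanged",
    3: "enriched in both",
    4: "B unchanged, A depleted",
    5: "unchanged in both",
    6: "B unchanged, A enriched",
    7: "depleted in both",
    8: "B depleted, A unchanged",
    9: "B depleted, A enriched",
}


class ClassifyError(ValueError):
    pass


def _state(cs, pvalue, alpha: float):
    """Reduce (cs, p) to a direction state: +1 sig-up, -1 sig-down, 0 ns.

    cs exactly 0 carries no direction and is forced to ns regardless of p.
    """
    cs = np.asarray(cs, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    if np.isnan(cs).any() or np.isnan(pvalue).any():
        raise ClassifyError("missing CRISPR score or p-value")
    sig = pvalue < alpha
    return np.where(sig & (cs > 0), 1, np.where(sig & (cs < 0), -1, 0))


def classify_gene(cs_b, p_b, cs_a, p_a, alpha: float = DEFAULT_ALPHA):
    """Assign group 1-9 from the two cell lines' scores and p-values.

    ``b`` is the transformed line (rows of the table above), ``a`` the
    matched primary line (columns). Accepts scalars or arrays.
    """
    if not 0 < alpha < 1:
        raise ClassifyError(f"alpha must be in (0, 1), got {alpha}")
    state_b = _state(cs_b, p_b, alpha)
    state_a = _state(cs_a, p_a, alpha)
    # row index: B sig-up -> 0, ns -> 1, sig-down -> 2; col: A sig-down -> 0, ns -> 1, sig-up -> 2
    group = 3 * (1 - state_b) + (state_a + 1) + 1
    if np.ndim(group) == 0:
        return int(group)
    return group.astype(np.int64)


def classify_screen(
    scores_b: pd.DataFrame,
    scores_a: pd.DataFrame,
    day: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Classify every shared gene at one day (default: the terminal day).

    Parameters
    ----------
    scores_b, scores_a
        Gene score tables (``gene_id, cell_line, day, cs, pvalue``) for the
        transformed (B) and primary (A) cell lines.

    Returns
    -------
    DataFrame
        One row per shared gene: ``gene_id, cs_a, p_a, cs_b, p_b, group``.
    """
    if day is None:
        day = min(scores_b["day"].max(), scores_a["day"].max())
    b = scores_b[scores_b["day"] == day][["gene_id", "cs", "pvalue"]]
    a = scores_a[scores_a["day"] == day][["gene_id", "cs", "pvalue"]]
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ClassifyError(f"no shared genes between the two screens at day {day}")
    merged = merged.rename(columns={"pvalue_a": "p_a", "pvalue_b": "p_b"})
    merged["group"] = classify_gene(
        merged["cs_b"], merged["p_b"], merged["cs_a"], merged["p_a"], alpha=alpha
    )
    return merged[["gene_id", "cs_a", "p_a", "cs_b", "p_b", "group"]]


def group_sizes(rows: pd.DataFrame) -> pd.Series:
    """Gene count per group 1-9 (all nine entries, zeros included)."""
    sizes = rows["group"].value_counts().reindex(range(1, 10), fill_value=0).sort_index()
    sizes.index.name = "group"
    sizes.name = "n_genes"
    return sizes


@dataclass(frozen=True)
class ScreenCorrelation:
    """Pearson correlation of gene scores between two screens."""

    n_shared_genes: int
    pearson_r: float

    @property
    def r_squared(self) -> float:
        return self.pearson_r**2


def call_strict_essential(
    rows: pd.DataFrame,
    log2_threshold: float = DEFAULT_ESSENTIAL_LOG2_THRESHOLD,
    restrict_to_group8: bool = True,
) -> pd.DataFrame:
    """Strict essential calls: deep terminal depletion in the transformed line.

    A gene is called iff its terminal cs_b <= ``log2_threshold`` (default
    -5, a >= 32-fold drop) and — by default — it sits in group 8 (depleted
    in B only). ``restrict_to_group8=False`` widens the call to any
    significantly depleted-in-B gene (groups 7-9).
    """
    if log2_threshold >= 0:
        raise ClassifyError("log2_threshold must be negative (a depletion bound)")
    if restrict_to_group8:
        eligible = rows["group"] == 8
    else:
        eligible = rows["group"].isin((7, 8, 9))
    out = rows[["gene_id", "group", "cs_b"]].copy()
    out = out.rename(columns={"cs_b": "log2_ratio"})
    out["called"] = eligible.to_numpy() & (out["log2_ratio"] <= log2_threshold).to_numpy()
    return out


def correlate_screens(
    scores_x: pd.DataFrame, scores_y: pd.DataFrame, day: float | None = None
) -> ScreenCorrelation:
    """Pearson r / r^2 of gene CRISPR scores shared between two screens.

    Complete cases only; requires >= 3 shared finite scores and non-zero
    variance in both vectors.
    """
    if day is None:
        day = min(scores_x["day"].max(), scores_y["day"].max())
    x = scores_x[scores_x["day"] == day][["gene_id", "cs"]]
    y = scores_y[scores_y["day"] == day][["gene_id", "cs"]]
    merged = x.merge(y, on="gene_id", suffixes=("_x", "_y"), how="inner").dropna()
    merged = merged[np.isfinite(merged["cs_x"]) & np.isfinite(merged["cs_y"])]
    if len(merged) < 3:
        raise ClassifyError(f"need >= 3 shared genes with finite scores, got {len(merged)}")
    vx = merged["cs_x"].to_numpy()
    vy = merged["cs_y"].to_numpy()
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise ClassifyError("zero variance in one of the score vectors")
    r = stats.pearsonr(vx, vy).statistic
    return ScreenCorrelation(n_shared_genes=len(merged), pearson_r=float(r))
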
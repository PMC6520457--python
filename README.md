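# pairedscreen

Analysis of **paired pooled CRISPR-Cas9 dropout screens**: two matched cell
contexts — a primary cell line and its transformed counterpart — are
transduced with the same genome-wide knockout library and sampled over a
time course. Guides targeting genes a context depends on are outcompeted
and deplete from the sequencing readout; guides hitting growth-suppressive
genes enrich. Comparing the two contexts gene by gene separates
*context-specific vulnerabilities* (candidate therapeutic targets of the
transformed state) from generically essential genes.

The package is aimed at functional-genomics analysts who have a guide
library table and either per-sample FASTQ files or an sgRNA × sample count
matrix, and want scores, significance calls, the differential-essentiality
classification, and a simulator to validate the whole pipeline against
planted ground truth.

## The model

For guide $s$ of gene $g$, sample day $t$, cell line $c$, with
reads-per-million $\mathrm{cpm}$ and pseudocount $\varepsilon = 0.5$:

$$\mathrm{lfc}_{s,c,t} = \log_2\frac{\mathrm{cpm}_{s,c,t}+\varepsilon}{\mathrm{cpm}_{s,c,t_0}+\varepsilon},\qquad
\mathrm{CS}_{g,c,t} = \frac{1}{|S_g|}\sum_{s\in S_g}\mathrm{lfc}_{s,c,t}$$

with $t_0$ the day-1 reference. The log2 fold changes are median-centered
per (cell line, day) by default to remove the composition shift inherent
to relative-abundance sequencing. The **CRISPR score** CS is negative for
depleted (essential) genes and positive for enriched (growth-suppressive)
ones; a gene's two-sided p-value comes from a one-sample t test of its
guide lfc values against 0 (default) or a Kolmogorov–Smirnov test against
the non-targeting controls.

At the terminal day each gene is reduced, per cell line, to one of three
states — sig-up (p < α and CS > 0), sig-down (p < α and CS < 0), or ns —
and the state of the transformed line (B) crossed with the primary line
(A) gives the **nine groups**:

| B \ A        | sig-down | ns | sig-up |
|--------------|----------|----|--------|
| **sig-up**   | 1        | 2  | 3      |
| **ns**       | 4        | 5  | 6      |
| **sig-down** | 7        | 8  | 9      |

Group 8 (depleted only in the transformed line) holds the candidate
vulnerabilities; the **strict essential** call additionally requires a
terminal $\mathrm{CS}_B \le -5$, i.e. at least 32-fold depletion.

The simulator plants per-gene fitness effects from these nine archetypes
(log2 units/day, scaled per guide by a Beta-distributed cutting
efficiency), evolves relative abundances exponentially from a log-normal
baseline, and samples reads multinomially at a configurable coverage —
optionally Dirichlet-multinomial overdispersed — so every stage of the
pipeline can be checked against known truth.

## Worked example

```python
from pairedscreen import SimConfig, simulate_screen, PairedScreenModel, evaluate_recovery

screen = simulate_screen(SimConfig(n_genes=2000, seed=3))   # paired MM/KMM screen
res = PairedScreenModel(screen.counts, screen.library).fit(alpha=0.05)
print(res.summary())
rep = evaluate_recovery(res.classification, screen.truth)
print(f"group-8 precision: {rep.precision[8]:.3f}  recall: {rep.recall[8]:.3f}")
```

prints

```
                  Paired CRISPR Screen Results
================================================================
Primary line (A):     MM           Genes scored:    2,000
Transformed line (B): KMM          sgRNAs:          6,010
Test: one-sample t    alpha: 0.05     day: 21
----------------------------------------------------------------
Group  Description                        Genes
1      B enriched, A depleted                50
2      B enriched, A unchanged              154
3      enriched in both                      55
4      B unchanged, A depleted              146
5      unchanged in both                    956
6      B unchanged, A enriched              101
7      depleted in both                     118
8      B depleted, A unchanged              372
9      B depleted, A enriched                48
----------------------------------------------------------------
Strict essential in B (group 8, log2 <= -5): 7 gene(s)
A-B score correlation: r = +0.116, R^2 = 0.013 (n = 2,000)
================================================================
group-8 precision: 0.968  recall: 0.928
```

The group table partitions all 2,000 genes; the 372 genes called group 8
are dominated by the planted B-essential archetype (precision 0.97), and
7 of them fall below the 32-fold strict-essential bar (the default
per-day effect of 0.25 log2 units × 20 days × mean guide efficiency 0.85
lands most planted genes near −4.3, so only the high-efficiency tail
crosses −5). The near-zero A–B score correlation reflects that the
planted effects of the two lines are drawn independently.

The same analysis runs from the shell:

```bash
pairedscreen simulate --n-genes 2000 --seed 3 --out-dir sim/
pairedscreen run --config run.yaml        # counts -> scores -> groups -> report.json
pairedscreen count --fastq S1.fastq --library sim/library.tsv --sample-id S1 -o counts.tsv
```

## Layout

- `pairedscreen.io_quant` — library validation, FASTQ spacer counting, counts I/O
- `pairedscreen.scoring` — CPM, log2 fold changes, CRISPR scores, t/KS tests, ECDF
- `pairedscreen.classify` — nine-group rules, strict essential calls, screen correlation
- `pairedscreen.simulate` — planted-truth screen simulator and recovery metrics
- `pairedscreen.model` — `PairedScreenModel` / `PairedScreenResults`
- `pairedscreen.pipeline`, `pairedscreen.cli` — end-to-end runs and the `pairedscreen` command

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
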
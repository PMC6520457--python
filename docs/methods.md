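# Methods

## Screen model and scoring

A pooled knockout screen measures *relative* guide abundance: per sample,
counts are scaled to reads per million (CPM) and each guide's signal is the
log2 ratio of its CPM at day *t* to its CPM at the day-1 reference of the
same cell line, with a pseudocount of 0.5 inside the ratio so zero counts
stay finite. Replicates, if present, are averaged on the CPM scale before
the ratio, matching a one-sample-per-timepoint design.

**Composition correction.** Because sequencing renormalizes to a fixed
total, strong depletion or enrichment of a minority of guides shifts the
raw log-ratio of every other guide (e.g. a handful of strongly enriched
guides make all neutral guides appear depleted). The per-(cell line, day)
median lfc is therefore subtracted by default, anchoring the neutral
majority at zero — the same correction family as median normalization in
standard screen-analysis tools. It assumes the median guide is neutral,
which holds whenever well under half the library responds; it is a single
per-sample constant, so gene-to-gene contrasts are unaffected. The raw
(uncentered) ratios remain available via `center=None`, and the low-level
`sgrna_lfc` operation defaults to raw.

**Gene scores and tests.** The per-gene CRISPR score is the arithmetic
mean of its guides' lfc values — chosen over log-of-summed-abundance for
its direct unit interpretation (a score of −5 is a 32-fold mean drop) and
linearity; with 3 guides per gene the two differ negligibly in practice.
Significance is a two-sided one-sample t test of the guide lfc values
against 0 (df = n−1), or a two-sample Kolmogorov–Smirnov test against the
pooled non-targeting-control lfc distribution of the same condition.
Degenerate t cases resolve deterministically and monotonically with the
evidence: zero variance with non-zero mean → p = 0; zero variance with
zero mean → p = 1; a single guide → p = 1 with a warning. No
multiple-testing correction is applied by default, because the downstream
nine-group classification is defined on raw per-gene p-values;
Benjamini–Hochberg q-values are available behind `adjust="bh"`.

## Nine-group classification and strict calls

At the classification day (default: terminal) each cell line's (score,
p-value) pair reduces to sig-up / ns / sig-down using **strict p < α**
(α = 0.05 by default; the boundary p = α is not significant) and the sign
of the score; a score of exactly 0 carries no direction and is forced to
ns regardless of p. The transformed line's state (rows) crossed with the
primary line's state (columns, ordered sig-down / ns / sig-up) yields
groups 1–9; the assignment is a pure function of the four inputs, so the
groups partition any gene universe. Two exact symmetries follow from the
table and are enforced by tests: swapping the cell lines permutes
1↔9, 2↔6, 4↔8 (3, 5, 7 fixed), and negating every score permutes
1↔9, 2↔8, 3↔7, 4↔6 (5 fixed). Shrinking α can only move genes into the
all-ns group 5, never out of it.

Strict essential calls require group 8 (depleted only in the transformed
line) and a terminal score ≤ −5 log2 units, i.e. ≥ 32-fold depletion; the
group restriction can be widened to any depleted-in-B group (7–9).
Cross-screen correlation is Pearson's r (and r²) over the shared gene
identifiers with finite scores; ortholog mapping across species is out of
scope.

## Simulator

The generator emulates the mechanics of a two-context genome-wide dropout
screen; defaults follow the protocol geometry throughout: 19,840 genes ×
3 guides + 10 non-targeting controls (59,530 guides), sampling days
1/4/11/21, 300× sequencing coverage per sample, two cell contexts with
roles primary (A) and transformed (B).

- **Planted effects.** Each gene draws one of nine archetypes — every
  (sign_A, sign_B) pattern over {−, 0, +} — and receives fitness
  f = sign × 0.25 log2 units/day per line. Over the 20 days between
  reference and terminal sampling a fully efficient essential guide thus
  loses 5 log2 units (32-fold), placing planted effects at the strict-call
  scale. Controls are always neutral.
- **Guide efficiency.** Each guide's efficiency e ∈ [0,1] is
  Beta(8.5, 1.5) (mean 0.85) and multiplies the fitness, so partial
  knockouts deplete more slowly and guides of one gene disperse
  realistically — this dispersion is what the t test sees.
- **Dynamics and sampling.** Initial abundances are log-normal (σ = 0.5
  log2 units, mimicking cloning skew); the expected abundance of guide s
  at day t is ∝ π_s · 2^(e_s f_g (t − t₀)). Reads are a single
  multinomial draw of coverage × library-size per sample; dispersion > 0
  switches to Dirichlet-multinomial (α_i = p_i/dispersion), and an
  optional multinomial bottleneck before day 1 summarizes
  transduction/selection losses. All draws are pure functions of
  (config, seed), with per-stage seed streams so regenerating one stage
  never disturbs another.
- **Archetype mixture.** The default mixture is a *benchmark*: 52%
  neutral, 20% B-essential-only, and the remaining archetypes at 2–6%.
  With a calibrated test at α = 0.05, about 2.5% of neutral genes are
  false directional calls per line, so a planted group must outnumber
  that rate for per-group precision to be measurable — rare-archetype
  mixtures cannot support precision estimates at benchmark sizes. A
  `screen_like` preset (≈ 83% neutral, ≈ 6% B-essential, conflict groups
  < 0.1%) reproduces the proportions seen in real genome-wide paired
  screens; under that mixture group-8 precision is bounded near 0.76 at
  α = 0.05 by the same arithmetic, which is a property of raw-p
  classification at genome scale, not of this implementation.
- **What the simulator does not model:** guide-specific off-target
  effects, copy-number artifacts, cell-cycle or density dependence,
  integration-site effects, PCR jackpotting beyond the single dispersion
  parameter, and real biological correlation between the two contexts
  (fitness signs are drawn independently, so simulated cross-screen
  correlations are near zero, unlike matched real screens). Passing
  recovery tests therefore validates the pipeline's statistics and
  bookkeeping, not robustness to those artifacts.

## Numerical and interface choices

- Spacer counting is exact-substring, forward-strand only, any position in
  the read; a read matching guides of ≥ 2 distinct sgRNAs (including via
  a spacer duplicated in the library) is ambiguous and discarded, keeping
  counts integral and order-independent, and
  assigned + unassigned + ambiguous = total reads always.
- ECDF curves keep every observation (fraction i/n at the i-th sorted
  value), so ties appear as repeated values and the curve always ends at 1.
- The t p-value path is vectorized over genes from groupby aggregates
  (mean, sd, n) and verified against numeric integration of the Student-t
  density to 1e−9.
- TSV everywhere (UTF-8, header row, no quoting); the run report is JSON
  with sorted keys and no timestamps, so identical inputs + config
  reproduce byte-identical outputs.
- Problem sizes in the test and acceptance runs: geometry and partition
  checks run at full protocol scale (59,530 guides, 8 samples — a few
  seconds); calibration and recovery use 2,000-gene screens, large enough
  that the ±3-binomial-SE calibration band is ±1.5 percentage points and
  group-8 precision/recall have ~400 planted positives behind them.

## Known limitations

- Exact-match counting undercounts real sequencing data with read errors
  in the spacer; a mismatch-tolerant mode is deliberately out of scope.
- The one-sample t test treats a gene's 3 guides as i.i.d.; with
  heteroscedastic guide noise (low-abundance guides are noisier) the test
  is only approximately calibrated, though the all-neutral simulation
  shows the deviation is within the 3-SE band at protocol coverage.
- Median centering fails if a majority of the library responds in one
  direction (e.g. a library of known essentials); use `center=None` and
  the KS-vs-controls test in that regime.
- The nine-group rule uses raw p-values by design; at genome scale group
  counts include the expected α-level false-call mass, and the strict
  essential call (group 8 ∧ ≤ −32-fold) is the intended high-confidence
  filter on top of it.
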
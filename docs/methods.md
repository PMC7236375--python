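# Methods

This note documents the models, parameter choices and numerical conventions
behind `structvar`, and what the synthetic-data experiments do and do not
demonstrate.

## Reactivity model

The probing signal for a transcript is a pair of per-base count vectors per
library: RT-stop events and base density (coverage). Stops and density are
counted independently; the code never assumes `stops[i] <= density[i]`.

**Sliding-window normalization.** Stops are normalized in windows of
`window` = 200 nt advancing by `step` = 30 nt. Within a window, the
normalizer is the mean of the values whose *nearest-rank* percentile lies in
the inclusive band [`rank_lo` = 90, `rank_hi` = 95]; nearest-rank means the
`ceil(p/100·n)`-th order statistic, chosen because it is exact on small
windows and involves no interpolation convention. Each value is divided by
its window's normalizer and scaled by 100; a position covered by several
windows takes the mean of its per-window values. Geometry: windows start at
0, 30, 60, …; when the stride leaves a 3'-terminal tail, one final
*full-size* window is anchored at `(L − 200, L)` rather than normalizing a
short tail window — a short window's percentile band is estimated from few
values, and its sampling noise measurably inflated false differential calls
at transcript 3' ends. Transcripts shorter than one window use a single
window of their own length. A window whose normalizer is zero contributes
the invalid marker; a position with no valid contribution is invalid.

**Reactivity.** With `T`, `C` the normalized treated/control stops and `d`
the treated base density:

    raw_i = max(0, T_i − alpha_bg · C_i) / max(d_i, 1)       alpha_bg = 0.25

Per transcript, raw values are divided by the mean of the raw values in the
nearest-rank `[winsor_hi − 5, winsor_hi]` = [90, 95] percentile band and
clipped to [0, 1]. All five constants live in `ReactivityParams` and are
CLI-overridable; the defaults follow the published icSHAPE convention.
Positions where the scaling normalizer is zero are invalid, not zero:
absence of signal is not evidence of structure. The transcript-level
inclusion filter (mean raw stop ≥ 2 and mean density ≥ 200, both inclusive,
evaluated on the treated library) is applied before normalization; the
report records each exclusion and the per-transcript valid-base fraction.

An important consequence of normalizing *both* libraries onto their own
~100 scale is that the control term subtracts a near-constant
`alpha_bg · 100` from every base. Paired bases whose treated signal falls
below that offset are floored at zero — low reactivity saturates, which is
the intended reading of "no detectable flexibility".

## Differential structure

Two stages are compared in disjoint 10-nt windows tiled from position 0
(trailing partial window dropped). A window is kept when ≥ 80% of its bases
(`ceil(0.8·10)` = 8) carry valid reactivity in both stages. Kept windows are
tested with a two-sided paired *t*-test over per-base deltas; the compound
call is mean Δ > 0.05 (less structural) or < −0.05 (more structural) with
p < 0.05. Conventions the source procedure leaves open, fixed here:

* pairs are per-base deltas (not per-window replicate means);
* a zero-variance window gets p = 0 if its common delta is nonzero (the
  *t* statistic diverges) and p = 1 if all deltas are zero;
* **no multiple-testing correction is applied to window p-values** — the
  compound raw-p + effect-size cut is reproduced faithfully; users should
  treat single-window calls accordingly and rely on region/hot-region
  aggregation;
* swapping the stages exactly exchanges the two class labels (asserted by
  property test).

Variable windows are extended by 10-nt flanks (clipped to the transcript),
merged when overlapping or book-ended *within the same class* (merging
across classes would destroy the annotation downstream steps need), and
partitioned left-to-right into 30-nt bins with the final partial bin kept.
Hot regions cluster regions of the same transcript and class across
pairwise comparisons when they overlap by ≥ 1 nt (`--min-overlap`
adjustable); each connected cluster reports its footprint and the number of
distinct comparisons (n-way).

Segment assignment gives a region to the segment covering ≥ 0.51 of its
length (ties → unassigned). Enrichment compares observed counts with
expectations proportional to the 150 : 1250 : 460 average segment lengths;
each segment's Fisher exact test uses the 2×2 table
`[observed, total − observed; round(expected), total − round(expected)]`,
recorded in output metadata. Because the second row of that table is a
constant, the test prices in more sampling noise than the data carry: its
p-values are *conservative* (empirically P(p < 0.05) ≈ 0.005 under uniform
placement), never anti-conservative. The enrichment ratio, not the p-value,
is the primary effect measure.

## Motif scanning and enrichment

A motif is a width×4 letter-probability matrix with a 0-order background;
scoring applies the pseudocount blend `(p + pseudo·bg)/(1 + pseudo)`
(`pseudo` = 1e-4) and sums per-position log2 odds. Scores are quantized once
onto a grid of 1/`granularity` bits (`granularity` = 1000; discretization
error ≤ width/2000 bits); both scan scores and the null distribution — a
dynamic-programming convolution of the per-position quantized score
distributions under the background — live on that grid, so the reported
p-value P(score ≥ observed) is *exactly* the enumeration value. Minimum
motif width is 4; below that the score table degenerates. Scanning is
sense-strand only (mRNA), windows containing N are skipped, and the hit
threshold is p < 0.001. Zero-pseudocount motifs have −∞ log-odds cells;
these are floored at −64 bits so the integer DP stays finite (no attainable
threshold is affected).

The background model defaults to 0-order letter frequencies estimated from
the union of test and reference sequences, overridable. Background regions
are sampled uniformly over all legal start positions pooled across the
transcripts carrying the test regions, never overlapping an excluded
region (hard assertion), optionally restricted to given intervals (e.g.
3'UTRs); the default sample size equals the test set. Enrichment counts
*regions with ≥ 1 hit* (not hits), forms the (a/b)/(c/d) ratio (infinite
when b, c or d vanishes with a > 0) and a two-sided Fisher p, BH-corrected
across the motif collection. A diagnostic exhaustive k-mer (k = 5–7)
enrichment report is provided for exploration; it is not a discovery
method.

## Regulome

Binding sites are iCLIP truncation positions extended ±20 nt (clipped),
3'UTR-restricted by default. Metaprofiles average valid reactivity per
offset in [−20, +20] around site centers; the unbound control is every
significant occurrence of the same motif on the same transcripts whose span
avoids all bound sites. Site structural grouping uses the full site span
(not the motif span only — left open by the source, fixed here), requires
≥ 3 jointly valid bases (a paired *t*-test needs variance), and applies the
same |Δ| > 0.05, p < 0.05 compound cut; reactivity dropping at the later
stage is group I (more structural), rising is group II.

Expression: RPKM = count/(length/10³)/(library/10⁶), averaged across
replicates after per-replicate conversion. The differential test is an
exact binomial two-proportion test — for each gene, `count_A` against
`count_A + count_B` with success probability `lib_A/(lib_A + lib_B)` — with
`log2FC = log2((count_A/lib_A + pc)/(count_B/lib_B + pc))` (pc = 1e-8) and
BH FDR across genes. This is a deliberate stand-in for count-package DE
internals; `GeneRecord` accepts user-supplied fold changes and FDRs when a
dedicated DE tool has been run. Orientation: A is the earlier stage, so
decay is positive log2FC. Note that proportion-based fold changes are
compressed during global maternal decay (the later library shrinks, adding
`−log2(lib_A/lib_B)` to every gene); this is inherent to the method class,
not corrected here.

Gene classes (early = 2 h.p.f.-like, late = 6 h.p.f.-like): decay = RPKM
early > 1, log2FC > log2 1.2, FDR < 0.05; stable = RPKM early > 1,
log2FC < log2 1.2, FDR < 0.05 — applied *literally*, so a strongly
up-regulated maternal gene counts as stable unless `symmetric_stable` is
set (which additionally requires log2FC > −log2 1.2); zygotic = RPKM
early < 1 and late > 1; everything else unclassified. Every gene gets
exactly one class.

The structure–stability association reports per-group RNA-level change
distributions (later/earlier orientation, so decay is negative), a
two-sided Wilcoxon *rank-sum* p between groups I and II (the groups are
disjoint transcript sets, so the two-sample form applies, not the
signed-rank test), and each group's decay-class composition.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not probing chemistry. Transcripts are drawn around 1860 nt (sd 200,
minimum 900) with segments in the 150 : 1250 : 460 ratio and uniform ACGU
sequence. Per-base *accessibility* u ∈ [0, 1] is 1 on unpaired stretches
and 0.05 inside hairpin stems (two 10-nt arms around a 5-nt loop, 16
hairpins/kb ≈ one-third of bases paired). RT stops are
Binomial(coverage, rate(u)) with coverage ~ Poisson(200) per replicate and
`rate(u)` linear between `stop_rate_paired` = 0.25 and
`stop_rate_unpaired` = 0.90; the control rate is 0.50. Two replicates per
condition are combined, as the analysis expects.

Those rates are calibrated, not mechanistic: replicate reactivity agreement
at the default coverage must match the quantile behaviour the analysis
cutoffs were derived from (≈ 98.5% of bases with |Δ| < 0.2; ≈ 95% of 10-nt
windows with |Δ of window means| < 0.05). That requires effective stop
counts per base in the hundreds; real experiments achieve this with low
per-read stop probabilities and much deeper coverage, and only the product
matters statistically. The control rate is high for the same reason — the
control library is normalized onto its own ~100 scale before subtraction,
so a rare-stop control would inject dominant, near-discrete background
noise. Measured at defaults: 99.7% of bases below 0.2 and ≈ 98% of windows
below 0.05, with the 98.5th percentile of |Δ| shrinking monotonically as
coverage rises.

Planted features, all in 3'UTRs with a U-rich consensus motif
(`UUUGUUU`, 10% per-base mutation by default) at their centers:

* **switch blocks** (30 nt): accessibility steps between `u_paired` and
  `u_paired + du`, with `du` solved from a first-order model of the
  pipeline — both libraries normalized to a common scale make reactivity
  ≈ `(rate(u)/rate(1) − α)/(1 − α)` — so the realized noiseless reactivity
  shift equals `switch_delta` = 0.3 (verified to ±0.01 by a noiseless
  pipeline run); closing blocks are group-I truth, opening blocks group II;
* **bound sites**: constitutively accessible motif sites, emitted as iCLIP
  truncations together with the switch sites;
* **unbound sites**: motif occurrences buried in paired context.

Expression per gene is log-normal (median 5 units, log-sd 0.8) with
per-stage biological noise of 0.1 log2 units and Poisson replicate counts
at depth 1000 reads/unit/kb; decay genes scale their late mean by
2^−`decay_log2fc` (default 1.0); zygotic genes are planted below the
realized RPKM = 1 line early (the line is library-relative — with hundreds
of genes sharing the per-million normalization it sits far above absolute
silence) and expressed late. A gene whose site closes is a decay gene with
probability `decay_coupling` = 0.6, the mirror for opening sites.

**What passing the synthetic experiments shows — and does not.** The
experiments demonstrate that the implemented statistics recover what was
planted at calibrated noise: they validate the code and the statistical
procedure, not the biology. The generator omits sequence-composition bias,
pseudo-knots and non-hairpin structure, adduct-dropoff chemistry, ligation
bias, positional coverage trends, and RBP competition; real data violate
the homogeneous-coverage and binary-accessibility assumptions, so real
sensitivity/FDR will be worse than the planted-truth numbers.

## Validation experiment design (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes are the package's chosen study conditions: 1000 random
profiles for the normalization oracle; 500 transcripts at 200× coverage for
the null window calibration; 10 seeds × 100 transcripts × 240 planted
switch blocks for recovery (dense planting keeps the denominator of the
FDR meaningful against the caller's ~10⁻³ null call rate); all 4^w words
(w ≤ 8) for PWM exactness; 100 seeded runs of 500 + 500 regions for
enrichment recovery (the mean ratio over runs is compared with the analytic
6.0 — a single run's ratio has ≈ 17% sampling noise from the ~50 background
hits); 30 seeds × 1000 genes/group for the coupling recovery, with
biological dispersion 0.05 log2 units so that classification noise does not
interact with the fold-change compression described above (this experiment
tests linkage recovery; DE robustness is a separate concern). The
structural site groups in the coupling experiment come from generator
truth; their recovery from counts is exercised by the metaprofile/grouping
experiment.

## Known limitations

* The binomial DE stand-in ignores biological overdispersion across
  replicates; with real data, plug in fold changes and FDRs from a
  dedicated DE package.
* Window p-values are uncorrected by design (fidelity to the source
  procedure); genome-scale users should treat the window list as a
  candidate set.
* The segment-enrichment Fisher test is conservative by construction (see
  above).
* Reactivity values saturate at 0 and 1 by construction; analyses sensitive
  to tail shape should work on the raw scale.
* The coordinate convention is strictly 0-based half-open transcript space;
  genomic liftover, GTF parsing and BAM handling are out of scope.
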
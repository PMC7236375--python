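# structvar

Transcriptome-wide analysis of RNA structure dynamics from icSHAPE probing
data, built for studies of developmental transitions such as the zebrafish
maternal-to-zygotic transition (MZT). The package takes per-base
reverse-transcription (RT) stop counts from NAI-treated and DMSO-control
libraries and carries them through to a structure-based posttranscriptional
regulome: per-base reactivities, structurally variable regions between
developmental stages, their enrichment in transcript segments and in
RNA-binding-protein (RBP) motifs, structural metaprofiles at RBP binding
sites, and the link between binding-site structural switches and maternal
mRNA decay.

It is aimed at computational biologists who already have mapped probing
libraries (read mapping and RT-stop extraction are upstream) and want a
tested, scriptable implementation of the downstream statistics, plus a
seeded synthetic-data generator with planted ground truth so every stage can
be validated without sequencing data.

## The statistics at the core

**Reactivity.** RT stops are normalized in 200-nt sliding windows (30-nt
step): each window's values are divided by the mean of the values whose
nearest-rank percentile lies in [90, 95] and scaled by 100; each position
averages over its covering windows. Per-base reactivity is then

```
raw_i = max(0, T_i − α·C_i) / max(d_i, 1),      α = 0.25
r_i   = clip(raw_i / s, 0, 1)
```

with `T`, `C` the normalized treated/control stops, `d` the base density,
and `s` the mean of the raw values in the per-transcript nearest-rank
[90, 95] percentile band. Positions without usable signal carry an explicit
invalid marker (`NULL` on disk), never a zero. Transcripts with mean RT
stop < 2 or mean density < 200 are excluded.

**Differential structure.** Profiles of two stages are compared in disjoint
10-nt windows (≥ 80% jointly valid bases). A window with mean
Δreactivity > 0.05 and two-sided paired *t*-test p < 0.05 is *less
structural* (reactivity up), the mirror image *more structural*. Variable
windows are extended ±10 nt, merged within class, re-partitioned into
≤ 30-nt regions; regions shared by ≥ 2 pairwise stage comparisons (≥ 1 nt
overlap) are n-way "hot" regions. Segment enrichment divides observed
counts by counts expected from the 5'UTR : CDS : 3'UTR ≈ 150 : 1250 : 460
average length ratio, with per-segment Fisher exact tests.

**Motifs.** PWM scanning follows the FIMO convention (sense strand,
0-order background, significance threshold p < 0.001) with *exact* score
p-values from an integer-discretized dynamic-programming convolution —
the null tail equals exhaustive enumeration over all 4^w words to
floating-point precision. Enrichment of a motif in variable regions
against length-matched background regions sampled from the same
transcripts (excluding the test regions) is the region-level 2×2 Fisher
exact test with ratio (a/b)/(c/d) and Benjamini–Hochberg FDR across
motifs.

**Regulome.** iCLIP truncation sites ±20 nt (3'UTR-restricted) define
binding sites; metaprofiles average valid reactivity per offset against
unbound same-motif controls. Sites whose mean reactivity drops between
stages (|Δ| > 0.05, paired *t*-test p < 0.05) form group I ("more
structural"), the mirror group II. Expression-side: RPKM, an exact
binomial two-proportion DE test (log2FC oriented early/late so decay is
positive), the maternal-decay / maternal-stable / zygotic classification
(RPKM > 1 at the early stage, log2FC vs log2 1.2, FDR < 0.05), and a
two-sided Wilcoxon rank-sum comparison of RNA-level changes between the
two site groups.

## Worked example

```python
import numpy as np
from structvar import synthetic_data as sd, reactivity as rx, diffstruct as ds

cfg = sd.SimConfig(n_transcripts=40, n_switch_sites=16, n_bound_sites=8,
                   n_unbound_sites=8, seed=7)
rng = np.random.default_rng(7)
truth = sd.make_transcriptome(cfg, rng)
react_4h = rx.stage_reactivities(
    sd.flatten_pairs(sd.simulate_rtstops(truth, "4hpf", rng)), stage="4hpf")
react_6h = rx.stage_reactivities(
    sd.flatten_pairs(sd.simulate_rtstops(truth, "6hpf", rng)), stage="6hpf")

windows = []
for tid in react_4h:
    windows += ds.window_scan(react_4h[tid], react_6h[tid])
variable = [w for w in windows if w.klass != ds.STABLE]
regions = ds.build_regions(windows, {t: tx.length for t, tx in truth.transcripts.items()},
                           comparison="4hpf_vs_6hpf")
print(f"kept windows: {len(windows)}, variable: {len(variable)}, regions: {len(regions)}")

counts = {s: 0 for s in ("5UTR", "CDS", "3UTR")}
for r in regions:
    seg = ds.assign_segment(r, truth.transcripts[r.transcript_id])
    if seg != "unassigned":
        counts[seg] += 1
for e in ds.segment_enrichment(counts):
    print(f"{e.segment}: observed={e.observed} expected={e.expected:.1f} "
          f"ratio={e.ratio:.2f} fisher_p={e.fisher_p:.2e}")
```

prints

```
kept windows: 7429, variable: 81, regions: 58
5UTR: observed=4 expected=4.7 ratio=0.86 fisher_p=1.00e+00
CDS: observed=15 expected=39.0 ratio=0.38 fisher_p=1.43e-05
3UTR: observed=39 expected=14.3 ratio=2.72 fisher_p=5.61e-06
```

Of 7429 windows passing the validity filter, 81 change structure between
the simulated 4 h.p.f. and 6 h.p.f. stages, collapsing into 58 regions of
≤ 30 nt. The generator plants its structural switches in 3'UTRs, and the
enrichment recovers exactly that: 39 regions observed in 3'UTRs against
14.3 expected under uniform placement (ratio 2.72, Fisher p ≈ 6×10⁻⁶),
with a corresponding depletion in the CDS.

The same workflow is available from the shell:

```
structvar --seed 7 simulate --out fixtures/
structvar reactivity --rtstops fixtures/rtstops_4hpf.tsv \
    --transcripts fixtures/transcripts.tsv --out 4hpf.out --stage 4hpf
structvar diffstruct --a 4hpf.out --b 6hpf.out \
    --transcripts fixtures/transcripts.tsv \
    --out-windows windows.bed --out-regions regions.bed
structvar regulome --a 4hpf.out --b 6hpf.out --sites fixtures/iclip_truncations.bed \
    --motifs fixtures/motif.meme --fasta fixtures/transcripts.fa \
    --transcripts fixtures/transcripts.tsv --expr fixtures/counts.tsv --out report/
```

Every subcommand writes a `manifest.json` with parameters, input digests
and the seed, and reruns with the same seed are byte-identical.

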
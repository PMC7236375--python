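"""Seeded synthetic probing data with planted ground truth.

The generator emulates the statistical structure the analysis assumes,
without pretending to model probing chemistry:

* transcripts ~1.86 kb with 5'UTR : CDS : 3'UTR segment lengths in the
  transcriptome-average ratio 150 : 1250 : 460 and random ACGU sequence;
* per-base *accessibility* u in [0, 1]: hairpin stems are near 0, unpaired
  stretches 1;
* RT-stop counts: per base, coverage ~ Poisson(coverage_mean); treated
  stops ~ Binomial(coverage, rate(u)) with rate(u) linear between the
  paired and unpaired stop rates; control stops ~ Binomial(coverage,
  control_stop_rate);
* planted 30-nt *switch* blocks in 3'UTRs whose accessibility changes
  between the two stages by exactly the amount that maps to a reactivity
  shift of ``switch_delta`` under the default analysis constants, with a
  U-rich motif planted at the block center;
* planted constitutively accessible *bound* motif sites (the RBP binding
  sites emitted as iCLIP truncations) and *unbound* motif occurrences inside
  paired context;
* per-gene expression with maternal decay / stable / zygotic classes,
  coupled to site structural direction: a gene whose site closes between
  stages (group I truth) is a decay gene with probability
  ``decay_coupling``.

The default stop rates are calibrated so that replicate reactivity
agreement at the default coverage matches the quantile behaviour the
cutoffs 0.2 (per base) and 0.05 (per 10-nt window) were derived from; see
docs/methods.md.  Ground truth is consumed only by tests, never by pipeline
modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    MotifModel,
    RegionRecord,
    TranscriptModel,
    consensus_motif,
    write_fasta,
    write_motif_meme,
    write_regions_bed,
    write_transcript_table,
)
from .reactivity import CONTROL, RTStopProfile, TREATED
from .regulome import (
    BindingSite,
    GROUP_I,
    GROUP_II,
    MATERNAL_DECAY,
    MATERNAL_STABLE,
    ZYGOTIC,
)

SWITCH_CLOSE = "close"  # accessible early, paired late -> group I (more structural)
SWITCH_OPEN = "open"


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_transcripts: int = 100
    mean_length: int = 1860
    sd_length: int = 200
    min_length: int = 900
    segment_weights: tuple[float, float, float] = (150.0, 1250.0, 460.0)
    hairpin_density: float = 16.0  # hairpins per kb
    stem_len: int = 10  # paired bases per hairpin arm
    loop_len: int = 5
    motif_consensus: str = "UUUGUUU"
    motif_conc: float = 0.85  # consensus letter probability in the planted PWM
    mutation_rate: float = 0.1  # per-base mutation of planted motif instances
    n_switch_sites: int = 40  # split half close / half open
    n_bound_sites: int = 40
    n_unbound_sites: int = 40
    switch_delta: float = 0.3  # planted reactivity shift
    u_paired: float = 0.05
    u_unpaired: float = 1.0
    coverage_mean: float = 200.0
    stop_rate_unpaired: float = 0.90
    stop_rate_paired: float = 0.25
    control_stop_rate: float = 0.50
    replicates: int = 2
    assumed_alpha_bg: float = 0.25  # background factor assumed when mapping u -> reactivity
    decay_coupling: float = 0.6
    decay_log2fc: float = 1.0
    zygotic_fraction: float = 0.15  # among genes without planted sites
    background_decay_fraction: float = 0.45
    expr_log_mean: float = math.log(5.0)
    expr_log_sd: float = 0.8
    seq_depth: float = 1000.0  # expected reads per expression unit per kb
    dispersion_log2: float = 0.1  # per-gene per-stage biological noise, log2 units
    stages: tuple[str, str] = ("4hpf", "6hpf")
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.stop_rate_unpaired, self.stop_rate_paired, self.control_stop_rate):
            if not 0.0 < r < 1.0:
                raise ValueError("stop rates must lie in (0, 1)")
        if any(w <= 0 for w in self.segment_weights):
            raise ValueError("segment weights must be positive")

    # -- the generator's own accessibility <-> reactivity calibration --------

    def stop_rate(self, u: np.ndarray | float) -> np.ndarray | float:
        return self.stop_rate_paired + u * (self.stop_rate_unpaired - self.stop_rate_paired)

    def expected_reactivity(self, u: np.ndarray | float) -> np.ndarray | float:
        """First-order reactivity the analysis defaults assign to accessibility u.

        Both libraries are window-normalized onto a common ~100 scale before
        the background subtraction, so to first order the control term is a
        constant offset of ``assumed_alpha_bg`` on the normalized axis and
        ``r(u) = (rate(u)/rate(1) - alpha) / (1 - alpha)`` clipped to [0, 1].
        (The percentile-band inflation of the normalizers, a few percent,
        is not modelled; tests that need the exact value use a noiseless
        pipeline run instead.)
        """
        b = self.assumed_alpha_bg
        r = (self.stop_rate(u) / self.stop_rate(1.0) - b) / (1.0 - b)
        return np.clip(r, 0.0, 1.0)

    def switch_du(self) -> float:
        """Accessibility step that realizes a reactivity shift of switch_delta.

        Solves expected_reactivity(u_paired + du) = expected_reactivity(u_paired)
        + switch_delta on the un-clipped branch.
        """
        span = self.stop_rate_unpaired - self.stop_rate_paired
        if span <= 0:  # null mode: no structure contrast, nothing to switch
            return 0.0
        b = self.assumed_alpha_bg
        target = min(1.0, float(self.expected_reactivity(self.u_paired)) + self.switch_delta)
        rate_target = self.stop_rate(1.0) * (b + (1.0 - b) * target)
        u_target = (rate_target - self.stop_rate_paired) / span
        return min(1.0 - self.u_paired, max(0.0, u_target - self.u_paired))


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    center: int
    start: int  # accessibility block bounds
    end: int
    kind: str  # "switch_close" | "switch_open" | "bound" | "unbound"


@dataclass
class GroundTruth:
    """Everything the generator planted; read by tests only."""

    config: SimConfig
    transcripts: dict[str, TranscriptModel]
    base_access: dict[str, np.ndarray]  # stage-independent accessibility
    sites: list[PlantedSite]
    gene_class: dict[str, str]  # gene_id -> maternal_decay / maternal_stable / zygotic
    site_group: dict[str, str]  # transcript_id -> group I / II / unchanged

    def accessibility(self, tid: str, stage: str) -> np.ndarray:
        """Per-base accessibility at one of the two stages."""
        cfg = self.config
        u = self.base_access[tid].copy()
        early = stage == cfg.stages[0]
        du = cfg.switch_du()
        for s in self.sites:
            if s.transcript_id != tid:
                continue
            if s.kind == "switch_close" and early:
                u[s.start : s.end] = cfg.u_paired + du
            elif s.kind == "switch_open" and not early:
                u[s.start : s.end] = cfg.u_paired + du
        return u

    def pairing(self, tid: str, stage: str) -> np.ndarray:
        """Per-base {paired, unpaired, unknown} labels for AUC-style checks."""
        cfg = self.config
        u = self.accessibility(tid, stage)
        out = np.full(u.shape, "unknown", dtype=object)
        out[u <= cfg.u_paired + 1e-9] = "paired"
        out[u >= cfg.u_unpaired - 1e-9] = "unpaired"
        return out

    def switch_regions(self, klass_of: str | None = None) -> list[RegionRecord]:
        """Planted switch blocks as regions labelled with the expected call.

        A closing site (accessible early) loses reactivity at the later
        stage, so the expected differential-structure call is
        ``more_structural``; an opening site is ``less_structural``.
        """
        out = []
        for s in self.sites:
            if s.kind == "switch_close":
                label = "more_structural"
            elif s.kind == "switch_open":
                label = "less_structural"
            else:
                continue
            if klass_of is None or label == klass_of:
                out.append(RegionRecord(s.transcript_id, s.start, s.end, label))
        return out

    def bound_binding_sites(self, flank: int = 20) -> list[BindingSite]:
        out = []
        for s in self.sites:
            if s.kind in ("bound", "switch_close", "switch_open"):
                tx = self.transcripts[s.transcript_id]
                out.append(
                    BindingSite(
                        transcript_id=s.transcript_id,
                        center=s.center,
                        start=max(0, s.center - flank),
                        end=min(tx.length, s.center + flank + 1),
                        source="iclip_truncation",
                        segment=tx.segment_of(s.center),
                    )
                )
        return out

    def constitutive_sites(self, kind: str, flank: int = 20) -> list[BindingSite]:
        out = []
        for s in self.sites:
            if s.kind == kind:
                tx = self.transcripts[s.transcript_id]
                out.append(
                    BindingSite(
                        transcript_id=s.transcript_id,
                        center=s.center,
                        start=max(0, s.center - flank),
                        end=min(tx.length, s.center + flank + 1),
                        source="planted",
                        segment=tx.segment_of(s.center),
                    )
                )
        return out


def _plant_word(seq: list[str], pos: int, word: str, rng: np.random.Generator, mutation_rate: float) -> None:
    bases = "ACGU"
    for i, ch in enumerate(word):
        if mutation_rate > 0 and rng.random() < mutation_rate:
            ch = bases[rng.integers(0, 4)]
        seq[pos + i] = ch


def make_transcriptome(config: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Generate transcripts, accessibility, planted sites and gene classes."""
    rng = rng or np.random.default_rng(config.seed)
    w = np.asarray(config.segment_weights, dtype=float)
    w = w / w.sum()
    motif_w = len(config.motif_consensus)
    block = 30  # planted accessibility-block length (matches the region bin)
    slot_span = 2 * 20 + 1  # site flank context kept clear of other plantings

    transcripts: dict[str, TranscriptModel] = {}
    base_access: dict[str, np.ndarray] = {}
    slot_pool: list[tuple[str, int]] = []  # (transcript_id, center)

    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        gid = f"g{i:04d}"
        length = int(np.clip(round(rng.normal(config.mean_length, config.sd_length)),
                             config.min_length, None))
        utr5_end = int(round(length * w[0]))
        cds_end = utr5_end + int(round(length * w[1]))
        cds_end = min(cds_end, length - 1)
        seq = list("ACGU"[j] for j in rng.integers(0, 4, size=length))

        u = np.full(length, config.u_unpaired)
        # hairpins: two paired arms around a short loop
        n_hp = rng.poisson(config.hairpin_density * length / 1000.0)
        footprint = 2 * config.stem_len + config.loop_len
        occupied = np.zeros(length, dtype=bool)
        for _ in range(n_hp):
            s = int(rng.integers(0, max(1, length - footprint)))
            if occupied[s : s + footprint].any():
                continue
            occupied[s : s + footprint] = True
            u[s : s + config.stem_len] = config.u_paired
            u[s + config.stem_len + config.loop_len : s + footprint] = config.u_paired

        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gid, length=length,
            utr5_end=utr5_end, cds_end=cds_end, sequence="".join(seq),
        )
        base_access[tid] = u

        # candidate site centers in the 3'UTR, spaced to keep flanks disjoint
        c = cds_end + slot_span // 2 + 1
        while c + slot_span // 2 + 1 < length:
            slot_pool.append((tid, c))
            c += slot_span + block

    # assign planted-site kinds to slots
    kinds = (
        ["switch_close"] * (config.n_switch_sites // 2)
        + ["switch_open"] * (config.n_switch_sites - config.n_switch_sites // 2)
        + ["bound"] * config.n_bound_sites
        + ["unbound"] * config.n_unbound_sites
    )
    if config.n_transcripts == 0:
        kinds = []
    if len(kinds) > len(slot_pool):
        raise ValueError(
            f"not enough 3'UTR slots ({len(slot_pool)}) for {len(kinds)} planted sites; "
            "increase n_transcripts or transcript length"
        )
    order = rng.permutation(len(slot_pool))
    sites: list[PlantedSite] = []
    site_group: dict[str, str] = {}
    for kind, slot_idx in zip(kinds, order):
        tid, center = slot_pool[slot_idx]
        tx = transcripts[tid]
        s, e = center - block // 2, center - block // 2 + block
        u = base_access[tid]
        if kind in ("switch_close", "switch_open"):
            u[s:e] = config.u_paired  # closed state; accessibility() opens the right stage
        elif kind == "bound":
            u[s:e] = config.u_unpaired
        else:  # unbound: motif buried in paired context
            u[s:e] = config.u_paired
        seq = list(tx.sequence)  # type: ignore[arg-type]
        _plant_word(seq, center - motif_w // 2, config.motif_consensus, rng, config.mutation_rate)
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=tx.gene_id, length=tx.length,
            utr5_end=tx.utr5_end, cds_end=tx.cds_end, sequence="".join(seq),
        )
        sites.append(PlantedSite(tid, center, s, e, kind))
        if kind == "switch_close":
            site_group[tid] = GROUP_I
        elif kind == "switch_open":
            site_group[tid] = GROUP_II

    # gene classes, coupled to site direction
    gene_class: dict[str, str] = {}
    for tid, tx in transcripts.items():
        gid = tx.gene_id
        grp = site_group.get(tid)
        if grp == GROUP_I:
            gene_class[gid] = MATERNAL_DECAY if rng.random() < config.decay_coupling else MATERNAL_STABLE
        elif grp == GROUP_II:
            gene_class[gid] = MATERNAL_DECAY if rng.random() < 1.0 - config.decay_coupling else MATERNAL_STABLE
        else:
            x = rng.random()
            if x < config.zygotic_fraction:
                gene_class[gid] = ZYGOTIC
            elif x < config.zygotic_fraction + config.background_decay_fraction:
                gene_class[gid] = MATERNAL_DECAY
            else:
                gene_class[gid] = MATERNAL_STABLE

    return GroundTruth(
        config=config,
        transcripts=transcripts,
        base_access=base_access,
        sites=sites,
        gene_class=gene_class,
        site_group=site_group,
    )


def simulate_rtstops(
    truth: GroundTruth,
    stage: str,
    rng: np.random.Generator,
    replicates: int | None = None,
    noiseless: bool = False,
) -> dict[str, list[tuple[RTStopProfile, RTStopProfile]]]:
    """Per transcript, a list of (treated, control) replicate profile pairs.

    ``noiseless`` replaces all sampling by expectations (coverage =
    coverage_mean, stops = coverage * rate) — the infinite-coverage limit
    used as a deterministic oracle.
    """
    cfg = truth.config
    n_rep = replicates if replicates is not None else cfg.replicates
    out: dict[str, list[tuple[RTStopProfile, RTStopProfile]]] = {}
    for tid in truth.transcripts:
        u = truth.accessibility(tid, stage)
        rate_t = np.asarray(cfg.stop_rate(u), dtype=float)
        pairs = []
        for rep in range(1, n_rep + 1):
            if noiseless:
                cov = np.full(u.shape, cfg.coverage_mean)
                stops_t = cov * rate_t
                stops_c = cov * cfg.control_stop_rate
                cov_t = cov_c = cov
            else:
                cov_t = rng.poisson(cfg.coverage_mean, size=u.shape)
                cov_c = rng.poisson(cfg.coverage_mean, size=u.shape)
                stops_t = rng.binomial(cov_t, rate_t)
                stops_c = rng.binomial(cov_c, cfg.control_stop_rate)
            pairs.append(
                (
                    RTStopProfile(tid, stops_t, cov_t, condition=TREATED, replicate=rep, stage=stage),
                    RTStopProfile(tid, stops_c, cov_c, condition=CONTROL, replicate=rep, stage=stage),
                )
            )
        out[tid] = pairs
    return out


def flatten_pairs(
    sim: Mapping[str, list[tuple[RTStopProfile, RTStopProfile]]]
) -> dict[str, list[RTStopProfile]]:
    """(treated, control) pair lists -> flat per-transcript profile lists."""
    return {tid: [p for pair in pairs for p in pair] for tid, pairs in sim.items()}


def simulate_expression(
    truth: GroundTruth,
    rng: np.random.Generator,
    replicates: int = 2,
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per (stage_replicate) gene count tables plus per-gene lengths.

    Baseline expression is log-normal; decay genes have their late-stage
    mean scaled by 2**(-decay_log2fc); zygotic genes are near-silent early
    and expressed late.  Per-gene, per-stage biological noise is log-normal
    with sd ``dispersion_log2`` (log2 units), shared between replicates of a
    stage; replicate counts are independent Poisson draws.
    """
    cfg = truth.config
    early, late = cfg.stages
    lengths: dict[str, int] = {}
    expr_early: dict[str, float] = {}
    expr_late: dict[str, float] = {}
    zygotic: list[str] = []
    for tid, tx in truth.transcripts.items():
        gid = tx.gene_id
        lengths[gid] = tx.length
        klass = truth.gene_class[gid]
        base = float(np.exp(rng.normal(cfg.expr_log_mean, cfg.expr_log_sd)))
        if klass == ZYGOTIC:
            zygotic.append(gid)
            expr_early[gid] = 0.0  # placeholder, set below the RPKM=1 level
            expr_late[gid] = base
        elif klass == MATERNAL_DECAY:
            expr_early[gid] = base
            expr_late[gid] = base * 2.0 ** (-cfg.decay_log2fc)
        else:
            expr_early[gid] = base
            expr_late[gid] = base

    # the RPKM = 1 line sits at expr = sum(expr * kb) / 1e6 for the realized
    # library; plant zygotic early expression safely below it (the line is
    # library-relative because a desk-scale gene set shares the per-million
    # normalization that a full transcriptome would dilute)
    kb = {g: lengths[g] / 1000.0 for g in lengths}
    rpkm1_early = sum(expr_early[g] * kb[g] for g in lengths) / 1e6
    for gid in zygotic:
        expr_early[gid] = float(rng.uniform(0.05, 0.4)) * rpkm1_early

    mean_early: dict[str, float] = {}
    mean_late: dict[str, float] = {}
    for gid in lengths:
        noise_e = 2.0 ** rng.normal(0.0, cfg.dispersion_log2)
        noise_l = 2.0 ** rng.normal(0.0, cfg.dispersion_log2)
        mean_early[gid] = expr_early[gid] * kb[gid] * noise_e
        mean_late[gid] = expr_late[gid] * kb[gid] * noise_l

    counts: dict[str, dict[str, int]] = {}
    scale = cfg.seq_depth
    for stage, means in ((early, mean_early), (late, mean_late)):
        for rep in range(1, replicates + 1):
            tab = {
                gid: int(rng.poisson(scale * m)) for gid, m in means.items()
            }
            counts[f"{stage}_rep{rep}"] = tab
    return counts, lengths


def planted_motif(config: SimConfig) -> MotifModel:
    return consensus_motif("planted", config.motif_consensus, conc=config.motif_conc)


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def _write_rtstops_tsv(path: Path, profiles: Mapping[str, list[tuple[RTStopProfile, RTStopProfile]]]) -> None:
    import pandas as pd

    frames = []
    for tid, pairs in profiles.items():
        for treated, control in pairs:
            for prof in (treated, control):
                frames.append(
                    pd.DataFrame(
                        {
                            "transcript_id": tid,
                            "position": np.arange(prof.length),
                            "stops": prof.stops.astype(np.int64),
                            "density": prof.density.astype(np.int64),
                            "condition": prof.condition,
                            "replicate": prof.replicate,
                        }
                    )
                )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def emit_fixture(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Write a complete on-disk dataset consumable by every CLI subcommand."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = make_transcriptome(config, rng)

    write_transcript_table(truth.transcripts.values(), out / "transcripts.tsv")
    write_fasta(
        {tid: tx.sequence for tid, tx in truth.transcripts.items() if tx.sequence},
        out / "transcripts.fa",
    )
    for stage in config.stages:
        profiles = simulate_rtstops(truth, stage, rng)
        _write_rtstops_tsv(out / f"rtstops_{stage}.tsv", profiles)

    truncations = [
        RegionRecord(s.transcript_id, s.center, s.center + 1, "truncation")
        for s in truth.sites
        if s.kind in ("bound", "switch_close", "switch_open")
    ]
    write_regions_bed(truncations, out / "iclip_truncations.bed")
    write_motif_meme([planted_motif(config)], out / "motif.meme")

    counts, lengths = simulate_expression(truth, rng)
    with open(out / "counts.tsv", "w") as fh:
        fh.write("gene_id\tlength\t" + "\t".join(sorted(counts)) + "\n")
        for gid in sorted(lengths):
            row = [gid, str(lengths[gid])] + [str(counts[k].get(gid, 0)) for k in sorted(counts)]
            fh.write("\t".join(row) + "\n")

    truth_json = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "sites": [asdict(s) for s in truth.sites],
        "gene_class": truth.gene_class,
        "site_group": truth.site_group,
        "paired_intervals": {
            tid: _runs(truth.base_access[tid] <= config.u_paired + 1e-9)
            for tid in truth.transcripts
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return truth


def _runs(mask: np.ndarray) -> list[list[int]]:
    """Maximal True runs of a boolean mask as [start, end) pairs."""
    out: list[list[int]] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append([start, i])
            start = None
    if start is not None:
        out.append([start, len(mask)])
    return out
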
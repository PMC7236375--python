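"""RBP binding sites, structural metaprofiles, and the structure-stability link.

Binding sites come from iCLIP crosslink-induced truncation positions,
extended by 20 nt on each side (and optionally restricted to the 3'UTR), or
from motif scans.  A metaprofile averages valid reactivity at each offset in
[-flank, +flank] around site centers; the matched control is the set of
occurrences of the same motif on the same transcripts outside any bound
site.  A site's structural change between two stages uses the same compound
cut as the window caller (paired t-test over jointly valid bases,
|Δmean| > 0.05, p < 0.05): sites becoming less reactive at the later stage
are group I ("more structural"), the mirror image is group II.

Expression-side: RPKM per gene, an exact binomial two-proportion DE test
(a stand-in for count-based DE packages, with hooks for user-supplied fold
changes), and the maternal/zygotic classification by RPKM and fold-change
thresholds.  ``stability_association`` ties the two sides together: log2
fold-change distributions per site group, a two-sided rank-sum test between
groups, and the decay-class composition of each group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import RegionRecord, SEG_3UTR, TranscriptModel, ValidationError
from .motif_enrich import MotifModel, ScoredMotif, encode_rna, scan_sequence
from .reactivity import ReactivityProfile

GROUP_I = "more_structural"  # reactivity drops at the later stage
GROUP_II = "less_structural"
UNCHANGED = "unchanged"

MATERNAL_DECAY = "maternal_decay"
MATERNAL_STABLE = "maternal_stable"
ZYGOTIC = "zygotic"
UNCLASSIFIED = "unclassified"
GENE_CLASSES = (MATERNAL_DECAY, MATERNAL_STABLE, ZYGOTIC, UNCLASSIFIED)


@dataclass(frozen=True)
class BindingSite:
    transcript_id: str
    center: int
    start: int
    end: int
    source: str = "iclip_truncation"
    segment: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.center < self.end):
            raise ValidationError(
                f"{self.transcript_id}: center {self.center} outside [{self.start}, {self.end})"
            )


@dataclass
class MetaProfile:
    offsets: np.ndarray  # -flank .. +flank
    mean_reactivity: np.ndarray
    n_valid: np.ndarray
    set_label: str = "bound"


@dataclass(frozen=True)
class SiteStructGroup:
    transcript_id: str
    site: BindingSite
    mean_react_a: float
    mean_react_b: float
    p_value: float
    group: str
    n_valid: int = 0


@dataclass
class GeneRecord:
    gene_id: str
    rpkm_by_stage: dict[str, float] = field(default_factory=dict)
    log2fc: float = float("nan")  # earlier / later, so decay => positive
    de_p: float = float("nan")
    de_fdr: float = float("nan")
    klass: str = UNCLASSIFIED


def truncation_to_sites(
    truncations: Sequence[RegionRecord],
    transcripts: Mapping[str, TranscriptModel],
    flank: int = 20,
    restrict_3utr: bool = True,
) -> list[BindingSite]:
    """iCLIP truncation points -> flank-extended binding sites.

    A truncation at position t becomes the site [t - flank, t + flank + 1)
    clipped to the transcript; with ``restrict_3utr`` only sites whose center
    lies in the 3'UTR are kept.
    """
    out: list[BindingSite] = []
    for r in truncations:
        tx = transcripts.get(r.transcript_id)
        if tx is None:
            continue
        t = r.start  # point interval [t, t+1)
        if not 0 <= t < tx.length:
            raise ValidationError(f"{r.transcript_id}: truncation {t} outside transcript")
        seg = tx.segment_of(t)
        if restrict_3utr and seg != SEG_3UTR:
            continue
        out.append(
            BindingSite(
                transcript_id=r.transcript_id,
                center=t,
                start=max(0, t - flank),
                end=min(tx.length, t + flank + 1),
                source="iclip_truncation",
                segment=seg,
            )
        )
    return out


def site_valid_fraction(site: BindingSite, profile: ReactivityProfile) -> float:
    span = profile.values[site.start : site.end]
    return float(np.isfinite(span).mean()) if span.size else 0.0


def metaprofile(
    profiles: Mapping[str, ReactivityProfile],
    sites: Sequence[BindingSite],
    flank: int = 20,
    min_valid_frac: float = 0.0,
    set_label: str = "bound",
) -> MetaProfile:
    """Average valid reactivity per offset in [-flank, +flank] around centers.

    Sites on uncovered transcripts are skipped; sites whose valid-base
    fraction is <= ``min_valid_frac`` are excluded when the filter is
    enabled (> 0).
    """
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(offsets.size)
    cnt = np.zeros(offsets.size, dtype=int)
    used = 0
    for site in sites:
        prof = profiles.get(site.transcript_id)
        if prof is None:
            continue
        if min_valid_frac > 0 and site_valid_fraction(site, prof) <= min_valid_frac:
            continue
        used += 1
        for j, o in enumerate(offsets):
            p = site.center + int(o)
            if 0 <= p < prof.length and math.isfinite(prof.values[p]):
                acc[j] += prof.values[p]
                cnt[j] += 1
    if used == 0:
        raise ValidationError("no usable sites for metaprofile")
    mean = np.full(offsets.size, np.nan)
    mean[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return MetaProfile(offsets=offsets, mean_reactivity=mean, n_valid=cnt, set_label=set_label)


def unbound_controls(
    motif: MotifModel | ScoredMotif,
    transcripts: Mapping[str, TranscriptModel],
    bound: Sequence[BindingSite],
    thresh: float = 0.001,
    flank: int = 20,
) -> list[BindingSite]:
    """Occurrences of the motif on bound transcripts outside any bound site.

    Each control site is centered on the midpoint of a significant motif
    occurrence whose span does not intersect any bound site.
    """
    sm = motif if isinstance(motif, ScoredMotif) else ScoredMotif(motif)
    bound_by_tx: dict[str, list[BindingSite]] = {}
    for s in bound:
        bound_by_tx.setdefault(s.transcript_id, []).append(s)
    out: list[BindingSite] = []
    for tid in sorted(bound_by_tx):
        tx = transcripts.get(tid)
        if tx is None or tx.sequence is None:
            continue
        hits = scan_sequence(sm, encode_rna(tx.sequence), region_id=tid, thresh=thresh)
        for h in hits:
            h_start, h_end = h.offset, h.offset + sm.width
            if any(h_start < b.end and b.start < h_end for b in bound_by_tx[tid]):
                continue
            center = h.offset + sm.width // 2
            out.append(
                BindingSite(
                    transcript_id=tid,
                    center=center,
                    start=max(0, center - flank),
                    end=min(tx.length, center + flank + 1),
                    source="motif_scan",
                    segment=tx.segment_of(center),
                )
            )
    return out


def classify_site_structure(
    prof_a: Mapping[str, ReactivityProfile],
    prof_b: Mapping[str, ReactivityProfile],
    sites: Sequence[BindingSite],
    delta_cut: float = 0.05,
    alpha: float = 0.05,
    min_valid: int = 3,
) -> list[SiteStructGroup]:
    """Group sites by structural change between stage A (earlier) and B (later).

    Group I (more structural): mean reactivity drops by > delta_cut with a
    paired t-test p < alpha over the site's jointly valid bases; group II is
    the mirror image; everything else (including sites with fewer than
    ``min_valid`` jointly valid bases, which cannot support the test) is
    unchanged.
    """
    out: list[SiteStructGroup] = []
    for site in sites:
        pa = prof_a.get(site.transcript_id)
        pb = prof_b.get(site.transcript_id)
        if pa is None or pb is None:
            continue
        a = pa.values[site.start : site.end]
        b = pb.values[site.start : site.end]
        both = np.isfinite(a) & np.isfinite(b)
        n = int(both.sum())
        if n < min_valid:
            out.append(
                SiteStructGroup(site.transcript_id, site, float("nan"), float("nan"),
                                float("nan"), UNCHANGED, n_valid=n)
            )
            continue
        av, bv = a[both], b[both]
        mean_a, mean_b = float(av.mean()), float(bv.mean())
        d = bv - av
        if np.allclose(d.std(ddof=1), 0.0):
            p = 0.0 if abs(float(d.mean())) > 0 else 1.0
        else:
            p = float(stats.ttest_rel(bv, av).pvalue)
        delta = mean_b - mean_a
        if delta < -delta_cut and p < alpha:
            group = GROUP_I
        elif delta > delta_cut and p < alpha:
            group = GROUP_II
        else:
            group = UNCHANGED
        out.append(
            SiteStructGroup(site.transcript_id, site, mean_a, mean_b, p, group, n_valid=n)
        )
    return out


# ---------------------------------------------------------------------------
# expression side
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Read the wide count table (gene_id, length, one column per library).

    Returns ({library_name: {gene: count}}, {gene: length}).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise ValidationError(f"{path}: need gene_id and length columns")
    lengths = dict(zip(df["gene_id"], df["length"].astype(int)))
    counts = {
        col: dict(zip(df["gene_id"], df[col].astype(int)))
        for col in df.columns
        if col not in ("gene_id", "length")
    }
    return counts, lengths


def rpkm(
    counts: Mapping[str, int] | Sequence[Mapping[str, int]],
    lengths: Mapping[str, int],
    library_size: int | Sequence[int] | None = None,
) -> dict[str, float]:
    """Reads per kilobase per million mapped reads.

    When ``counts`` is a sequence of replicate count tables, each replicate
    is converted separately (with its own library size, defaulting to its
    total count) and the per-gene RPKMs are averaged.
    """
    if isinstance(counts, Mapping):
        counts_list = [counts]
        libs = [library_size if isinstance(library_size, (int, float)) and library_size else None]
    else:
        counts_list = list(counts)
        if library_size is None:
            libs = [None] * len(counts_list)
        else:
            libs = list(library_size)  # type: ignore[arg-type]
    per_rep: list[dict[str, float]] = []
    for tab, lib in zip(counts_list, libs):
        total = float(lib) if lib else float(sum(tab.values()))
        if total <= 0:
            raise ValidationError("library size must be positive")
        rep = {}
        for gid, c in tab.items():
            length = lengths[gid]
            if length <= 0:
                raise ValidationError(f"{gid}: nonpositive length")
            rep[gid] = c / (length / 1e3) / (total / 1e6)
        per_rep.append(rep)
    genes = set().union(*[set(r) for r in per_rep])
    return {g: float(np.mean([r.get(g, 0.0) for r in per_rep])) for g in sorted(genes)}


def de_test(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    lib_a: int | None = None,
    lib_b: int | None = None,
    pseudocount: float = 1e-8,
) -> dict[str, tuple[float, float, float]]:
    """Exact binomial two-proportion differential-expression test.

    For each gene, p is the two-sided exact binomial test of count_a against
    count_a + count_b with success probability lib_a / (lib_a + lib_b), and
    log2fc = log2((count_a/lib_a + pc) / (count_b/lib_b + pc)).  With A the
    earlier stage, decay shows as positive log2fc.  Returns gene ->
    (log2fc, p, BH-FDR).
    """
    la = float(lib_a) if lib_a else float(sum(counts_a.values()))
    lb = float(lib_b) if lib_b else float(sum(counts_b.values()))
    if la <= 0 or lb <= 0:
        raise ValidationError("library sizes must be positive")
    genes = sorted(set(counts_a) | set(counts_b))
    prob = la / (la + lb)
    log2fc = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for i, g in enumerate(genes):
        ca, cb = int(counts_a.get(g, 0)), int(counts_b.get(g, 0))
        log2fc[i] = math.log2((ca / la + pseudocount) / (cb / lb + pseudocount))
        n = ca + cb
        pvals[i] = 1.0 if n == 0 else stats.binomtest(ca, n, prob).pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return {g: (float(log2fc[i]), float(pvals[i]), float(fdr[i])) for i, g in enumerate(genes)}


def classify_genes(
    records: Sequence[GeneRecord],
    early_stage: str,
    late_stage: str,
    rpkm_min: float = 1.0,
    fc_cut: float = 1.2,
    fdr_cut: float = 0.05,
    symmetric_stable: bool = False,
) -> list[GeneRecord]:
    """Maternal decay / maternal stable / zygotic classification.

    decay: RPKM(early) > rpkm_min, log2fc > log2(fc_cut), FDR < fdr_cut.
    stable: RPKM(early) > rpkm_min, log2fc < log2(fc_cut), FDR < fdr_cut
    (the literal published rule; with ``symmetric_stable`` the stable class
    additionally requires log2fc > -log2(fc_cut)).
    zygotic: RPKM(early) < rpkm_min and RPKM(late) > rpkm_min.
    Everything else is unclassified; every gene gets exactly one class.
    """
    lfc_cut = math.log2(fc_cut)
    out: list[GeneRecord] = []
    for rec in records:
        early = rec.rpkm_by_stage.get(early_stage, 0.0)
        late = rec.rpkm_by_stage.get(late_stage, 0.0)
        klass = UNCLASSIFIED
        if early > rpkm_min and rec.log2fc > lfc_cut and rec.de_fdr < fdr_cut:
            klass = MATERNAL_DECAY
        elif early > rpkm_min and rec.log2fc < lfc_cut and rec.de_fdr < fdr_cut:
            if not symmetric_stable or rec.log2fc > -lfc_cut:
                klass = MATERNAL_STABLE
        elif early < rpkm_min and late > rpkm_min:
            klass = ZYGOTIC
        out.append(replace_klass(rec, klass))
    return out


def replace_klass(rec: GeneRecord, klass: str) -> GeneRecord:
    return GeneRecord(
        gene_id=rec.gene_id,
        rpkm_by_stage=dict(rec.rpkm_by_stage),
        log2fc=rec.log2fc,
        de_p=rec.de_p,
        de_fdr=rec.de_fdr,
        klass=klass,
    )


@dataclass
class StabilityAssociation:
    """Per-group stability summary (the structure <-> decay linkage)."""

    n_by_group: dict[str, int]
    log2fc_by_group: dict[str, np.ndarray]
    ranksum_p: float  # group I vs group II, two-sided
    class_fractions: dict[str, dict[str, float]]  # group -> gene class -> fraction

    def ecdf(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(self.log2fc_by_group[group])
        return x, np.arange(1, x.size + 1) / x.size


def stability_association(
    groups: Sequence[SiteStructGroup],
    genes: Mapping[str, GeneRecord],
    transcript_gene: Mapping[str, str],
    min_group: int = 2,
) -> StabilityAssociation:
    """Link site structural groups to expression change and decay classes.

    The RNA-level change here is -log2fc (later/earlier orientation, so
    decay shows as negative), matching cumulative-distribution plots where
    the downregulated group sits left.  The group I vs group II comparison
    uses the two-sided Wilcoxon rank-sum test (the groups are disjoint
    transcript sets, so the two-sample form applies).
    """
    fc_by_group: dict[str, list[float]] = {GROUP_I: [], GROUP_II: []}
    klass_by_group: dict[str, list[str]] = {GROUP_I: [], GROUP_II: []}
    seen: set[tuple[str, str]] = set()
    for g in groups:
        if g.group not in (GROUP_I, GROUP_II):
            continue
        gid = transcript_gene.get(g.transcript_id)
        if gid is None or gid not in genes:
            continue
        key = (g.group, gid)
        if key in seen:  # one vote per transcript/gene per group
            continue
        seen.add(key)
        rec = genes[gid]
        fc_by_group[g.group].append(-rec.log2fc)
        klass_by_group[g.group].append(rec.klass)
    for grp, vals in fc_by_group.items():
        if len(vals) < min_group:
            raise ValidationError(f"group {grp} has fewer than {min_group} genes")
    ranksum_p = float(
        stats.ranksums(fc_by_group[GROUP_I], fc_by_group[GROUP_II]).pvalue
    )
    fractions: dict[str, dict[str, float]] = {}
    for grp, klasses in klass_by_group.items():
        n = len(klasses)
        fractions[grp] = {k: klasses.count(k) / n for k in GENE_CLASSES}
    return StabilityAssociation(
        n_by_group={g: len(v) for g, v in fc_by_group.items()},
        log2fc_by_group={g: np.asarray(v) for g, v in fc_by_group.items()},
        ranksum_p=ranksum_p,
        class_fractions=fractions,
    )


def rbp_site_reactivity_compare(
    sites: Sequence[BindingSite],
    shuffled: Sequence[BindingSite],
    profiles: Mapping[str, ReactivityProfile],
    min_valid: float = 0.6,
) -> tuple[dict[str, dict[str, float]], float]:
    """Per-site mean reactivity: RBP sites vs shuffled background.

    Sites are kept only when more than ``min_valid`` of their bases carry
    valid reactivity; returns distribution summaries for both sets and the
    two-sided rank-sum p.
    """

    def site_means(ss: Sequence[BindingSite]) -> np.ndarray:
        vals = []
        for s in ss:
            prof = profiles.get(s.transcript_id)
            if prof is None:
                continue
            span = prof.values[s.start : s.end]
            ok = np.isfinite(span)
            if span.size and ok.mean() > min_valid:
                vals.append(float(span[ok].mean()))
        return np.asarray(vals)

    a, b = site_means(sites), site_means(shuffled)
    if a.size == 0 or b.size == 0:
        raise ValidationError("no sites survive the validity filter")
    p = float(stats.ranksums(a, b).pvalue)
    summary = {
        "sites": {"n": float(a.size), "mean": float(a.mean()), "median": float(np.median(a))},
        "shuffled": {"n": float(b.size), "mean": float(b.mean()), "median": float(np.median(b))},
    }
    return summary, p
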
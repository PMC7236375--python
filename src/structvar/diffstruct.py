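"""Structurally variable nucleotides, windows, regions and "hot" regions.

Two reactivity profiles of the same transcript (two developmental stages)
are compared in disjoint 10-nt windows tiled from position 0.  A window is
kept only when >= 80% of its bases carry valid reactivity in *both* stages;
kept windows are tested with a two-sided paired t-test over per-base deltas
(stage B minus stage A) combined with an effect-size cut:

* mean Δ >  +delta_cut and p < alpha  ->  ``less_structural`` (reactivity up)
* mean Δ <  -delta_cut and p < alpha  ->  ``more_structural`` (reactivity down)
* otherwise                            ->  ``stable``

No multiple-testing correction is applied to window p-values: the caller
replicates the raw p < 0.05 plus effect-size compound cut.  Variable windows
are extended by 10-nt flanks, merged within class, and re-partitioned into
<= 30-nt regions.  Regions shared (>= 1 nt overlap) by several pairwise
comparisons become n-way "hot" regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import RegionRecord, SEGMENTS, TranscriptModel, ValidationError
from .reactivity import ReactivityProfile

LESS_STRUCTURAL = "less_structural"
MORE_STRUCTURAL = "more_structural"
STABLE = "stable"
UNASSIGNED = "unassigned"

#: zebrafish transcriptome-average segment lengths, 5'UTR : CDS : 3'UTR
DEFAULT_SEGMENT_WEIGHTS = (150.0, 1250.0, 460.0)


@dataclass(frozen=True)
class StructWindow:
    transcript_id: str
    start: int
    end: int
    mean_delta: float
    p_value: float
    klass: str
    n_valid: int


@dataclass(frozen=True)
class VariableRegion:
    transcript_id: str
    start: int
    end: int
    klass: str
    comparisons: frozenset[str] = frozenset()

    @property
    def n_way(self) -> int:
        return max(1, len(self.comparisons))


@dataclass(frozen=True)
class SegmentEnrichment:
    segment: str
    observed: int
    expected: float
    ratio: float
    fisher_p: float


def call_variable_nucleotides(
    prof_a: ReactivityProfile, prof_b: ReactivityProfile, cutoff: float = 0.2
) -> list[tuple[int, float]]:
    """Positions valid in both stages with |Δreactivity| > cutoff.

    Returns (position, signed delta) pairs; bases invalid in either profile
    are excluded rather than zero-filled.
    """
    if prof_a.length != prof_b.length:
        raise ValidationError(f"{prof_a.transcript_id}: profile length mismatch")
    both = np.isfinite(prof_a.values) & np.isfinite(prof_b.values)
    delta = prof_b.values - prof_a.values
    hits = both & (np.abs(delta) > cutoff)
    return [(int(i), float(delta[i])) for i in np.flatnonzero(hits)]


def _paired_t_pvalues(deltas: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided paired t-test per window row.

    ``deltas`` is windows x width with NaN at invalid bases, ``mask`` marks
    jointly valid bases.  Zero-variance windows get p=0 for a nonzero mean
    and p=1 for an all-zero mean (the t statistic diverges / vanishes).
    """
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(mask, deltas, 0.0), axis=1) / np.maximum(n, 1), np.nan)
        centered = np.where(mask, deltas - mean[:, None], 0.0)
        ss = (centered**2).sum(axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
        se = np.sqrt(var / np.maximum(n, 1))
        t = mean / se
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1))
    zero_var = (var <= 0) | ~np.isfinite(se) | (se == 0)
    p = np.where(zero_var & (np.abs(mean) > 0), 0.0, p)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    return mean, p, n


def window_scan(
    prof_a: ReactivityProfile,
    prof_b: ReactivityProfile,
    window: int = 10,
    valid_frac: float = 0.8,
    delta_cut: float = 0.05,
    alpha: float = 0.05,
) -> list[StructWindow]:
    """Classify disjoint windows of one transcript between two stages.

    Windows tile from position 0 in disjoint ``window``-nt steps; a trailing
    partial window is dropped.  Windows with fewer than
    ``ceil(valid_frac * window)`` jointly valid bases are omitted entirely.
    """
    if prof_a.length != prof_b.length:
        raise ValidationError(f"{prof_a.transcript_id}: profile length mismatch")
    n_win = prof_a.length // window
    if n_win == 0:
        return []
    a = prof_a.values[: n_win * window].reshape(n_win, window)
    b = prof_b.values[: n_win * window].reshape(n_win, window)
    mask = np.isfinite(a) & np.isfinite(b)
    min_valid = int(np.ceil(valid_frac * window))
    deltas = b - a
    mean, p, n = _paired_t_pvalues(deltas, mask)
    out: list[StructWindow] = []
    for i in range(n_win):
        if n[i] < min_valid:
            continue
        if mean[i] > delta_cut and p[i] < alpha:
            klass = LESS_STRUCTURAL
        elif mean[i] < -delta_cut and p[i] < alpha:
            klass = MORE_STRUCTURAL
        else:
            klass = STABLE
        out.append(
            StructWindow(
                transcript_id=prof_a.transcript_id,
                start=i * window,
                end=(i + 1) * window,
                mean_delta=float(mean[i]),
                p_value=float(p[i]),
                klass=klass,
                n_valid=int(n[i]),
            )
        )
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals."""
    ivals = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_regions(
    windows: Iterable[StructWindow],
    transcript_lengths: Mapping[str, int],
    flank: int = 10,
    bin_size: int = 30,
    comparison: str = "",
) -> list[VariableRegion]:
    """Variable windows -> flank-extended, class-wise merged, 30-nt regions.

    Stable windows are ignored.  Merging never crosses the class boundary
    (a merged less/more-structural region would lose the annotation that
    downstream enrichment requires).  The final partial bin of each merged
    interval is kept, so regions are <= ``bin_size`` nt.
    """
    comparisons = frozenset([comparison]) if comparison else frozenset()
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for w in windows:
        if w.klass == STABLE:
            continue
        length = transcript_lengths[w.transcript_id]
        s = max(0, w.start - flank)
        e = min(length, w.end + flank)
        grouped.setdefault((w.transcript_id, w.klass), []).append((s, e))
    out: list[VariableRegion] = []
    for (tid, klass), ivals in sorted(grouped.items()):
        for s, e in merge_intervals(ivals):
            for b in range(s, e, bin_size):
                out.append(
                    VariableRegion(
                        transcript_id=tid,
                        start=b,
                        end=min(b + bin_size, e),
                        klass=klass,
                        comparisons=comparisons,
                    )
                )
    return out


def hot_regions(
    region_sets: Mapping[str, Sequence[VariableRegion]], min_overlap: int = 1
) -> list[VariableRegion]:
    """Cluster regions across pairwise comparisons into n-way "hot" regions.

    Regions on the same transcript and of the same class are "shared" when
    they overlap by >= ``min_overlap`` nt; each connected cluster of the
    overlap graph yields one region spanning the cluster footprint with
    ``comparisons`` the union of contributing comparison ids.  Regions shared
    by no other comparison pass through unchanged (n_way = 1).
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    pooled: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for comp_id, regions in region_sets.items():
        for r in regions:
            comps = r.comparisons or frozenset([comp_id])
            for c in comps:
                pooled.setdefault((r.transcript_id, r.klass), []).append((r.start, r.end, c))
    out: list[VariableRegion] = []
    for (tid, klass), items in sorted(pooled.items()):
        items.sort()
        cluster: list[tuple[int, int, str]] = []
        cluster_end = None
        for s, e, c in items:
            # >= min_overlap nt of overlap with the current cluster footprint
            if cluster and cluster_end is not None and s <= cluster_end - min_overlap:
                cluster.append((s, e, c))
                cluster_end = max(cluster_end, e)
            else:
                if cluster:
                    out.append(_finish_cluster(tid, klass, cluster))
                cluster = [(s, e, c)]
                cluster_end = e
        if cluster:
            out.append(_finish_cluster(tid, klass, cluster))
    return out


def _finish_cluster(tid: str, klass: str, cluster: list[tuple[int, int, str]]) -> VariableRegion:
    return VariableRegion(
        transcript_id=tid,
        start=min(s for s, _, _ in cluster),
        end=max(e for _, e, _ in cluster),
        klass=klass,
        comparisons=frozenset(c for _, _, c in cluster),
    )


def assign_segment(
    region: RegionRecord | VariableRegion, tx: TranscriptModel, min_frac: float = 0.51
) -> str:
    """Assign a region to the transcript segment covering >= min_frac of it."""
    if region.start < 0 or region.end > tx.length:
        raise ValidationError(
            f"{region.transcript_id}: region [{region.start}, {region.end}) outside transcript"
        )
    length = region.end - region.start
    for seg in SEGMENTS:
        lo, hi = tx.segment_bounds(seg)
        overlap = max(0, min(region.end, hi) - max(region.start, lo))
        if overlap / length >= min_frac:
            return seg
    return UNASSIGNED


def segment_enrichment(
    observed: Mapping[str, int],
    length_weights: Sequence[float] = DEFAULT_SEGMENT_WEIGHTS,
) -> list[SegmentEnrichment]:
    """Observed/expected segment ratios with a per-segment Fisher exact test.

    Expected counts distribute the total over segments proportionally to the
    transcriptome-average segment lengths; each segment's 2x2 table compares
    [observed_s, total - observed_s] against [round(expected_s),
    total - round(expected_s)] (two-sided).
    """
    total = sum(observed.get(s, 0) for s in SEGMENTS)
    if total <= 0:
        raise ValidationError("no assigned regions to test")
    weights = np.asarray(length_weights, dtype=float)
    if weights.shape != (3,) or np.any(weights <= 0):
        raise ValidationError("length_weights must be three positive numbers")
    probs = weights / weights.sum()
    out: list[SegmentEnrichment] = []
    for seg, p in zip(SEGMENTS, probs):
        obs = int(observed.get(seg, 0))
        exp = float(total * p)
        exp_round = int(round(exp))
        table = [[obs, total - obs], [exp_round, total - exp_round]]
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        out.append(
            SegmentEnrichment(
                segment=seg,
                observed=obs,
                expected=exp,
                ratio=obs / exp,
                fisher_p=fisher_p,
            )
        )
    return out


def windows_to_records(windows: Iterable[StructWindow]) -> list[RegionRecord]:
    return [
        RegionRecord(w.transcript_id, w.start, w.end, w.klass, w.mean_delta) for w in windows
    ]


def regions_to_records(regions: Iterable[VariableRegion]) -> list[RegionRecord]:
    return [
        RegionRecord(r.transcript_id, r.start, r.end, r.klass, float(r.n_way)) for r in regions
    ]
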
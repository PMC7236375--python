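"""PWM scanning with exact p-values and motif enrichment statistics.

Scanning follows the FIMO convention: each offset of a region is scored by
the motif's log-odds sum against a 0-order background, the score's p-value
is the exact tail probability of that score under the background model, and
offsets with p < 0.001 are significant hits.  Scanning is sense-strand only
(mRNA).  Exactness comes from integer score discretization: log-odds are
quantized once onto a 1/granularity grid and both the scan scores and the
null distribution (a dynamic-programming convolution of per-position score
distributions) live on that grid, so the DP tail equals exhaustive
enumeration over all 4^width words to floating-point precision.

Enrichment of a motif in a test region set against a matched background set
is the region-level 2x2 Fisher exact test with the odds-style ratio
(a/b)/(c/d): a/b regions with/without a hit in the test set, c/d in the
reference set.  p-values are Benjamini-Hochberg corrected across the motif
collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MotifModel, RegionRecord, TranscriptModel, ValidationError

_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int
    score: float  # log2 odds (bits)
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    a: int  # test regions with >= 1 hit
    b: int  # test regions without
    c: int  # reference regions with >= 1 hit
    d: int  # reference regions without
    ratio: float
    p_value: float
    fdr: float = float("nan")
    pct_test_with_hit: float = float("nan")


def encode_rna(seq: str) -> np.ndarray:
    """ACGU -> 0..3 with -1 for N/unknown."""
    return np.array([_BASE_INDEX.get(ch, -1) for ch in seq.upper().replace("T", "U")], dtype=np.int64)


class ScoredMotif:
    """A motif with its quantized score matrix and exact null tail table.

    ``granularity`` is the number of grid steps per bit of log-odds score;
    the discretization error of any word score is at most
    ``width * 0.5 / granularity`` bits.
    """

    def __init__(self, motif: MotifModel, granularity: int = 1000):
        if granularity < 1:
            raise ValidationError("granularity must be >= 1")
        self.motif = motif
        self.granularity = int(granularity)
        lods = motif.log_odds()  # width x 4, bits
        # a zero-pseudocount motif has -inf log-odds at forbidden letters;
        # floor at -64 bits so the integer DP stays finite (any word using a
        # floored letter scores far below every usable threshold)
        lods = np.where(np.isfinite(lods), lods, -64.0)
        self.qscores = np.rint(lods * granularity).astype(np.int64)  # width x 4
        self._tail, self._offset = self._dp_tail(self.qscores, motif.background)

    @staticmethod
    def _dp_tail(q: np.ndarray, bg: np.ndarray) -> tuple[np.ndarray, int]:
        """Exact pmf of the quantized score sum under the background, by
        convolution position by position; returns (tail array, index offset)
        where ``tail[s - offset] = P(score >= s)``."""
        # running pmf indexed from the running minimum so indices stay nonnegative
        cur = np.zeros(1)
        cur[0] = 1.0
        cur_lo = 0
        for i in range(q.shape[0]):
            row = q[i]
            row_lo = int(row.min())
            new_lo = cur_lo + row_lo
            new_size = cur.size + int(row.max()) - row_lo
            new = np.zeros(new_size)
            for a in range(4):
                shift = int(row[a]) - row_lo
                new[shift : shift + cur.size] += bg[a] * cur
            cur = new
            cur_lo = new_lo
        # cur[k] = P(score == cur_lo + k)
        tail = np.cumsum(cur[::-1])[::-1]
        return tail, cur_lo

    @property
    def width(self) -> int:
        return self.motif.width

    def quantized_score(self, word_idx: np.ndarray) -> int:
        return int(self.qscores[np.arange(self.width), word_idx].sum())

    def tail_probability(self, qscore: int) -> float:
        """P(quantized score >= qscore) under the background model."""
        idx = qscore - self._offset
        if idx <= 0:
            return 1.0
        if idx >= self._tail.size:
            return 0.0
        return float(self._tail[idx])

    def score_pvalue_table(self) -> dict[float, float]:
        """Mapping score threshold (bits) -> exact tail probability."""
        return {
            (self._offset + k) / self.granularity: float(self._tail[k])
            for k in range(self._tail.size)
        }

    def pvalue_threshold_qscore(self, thresh: float) -> int:
        """Smallest quantized score whose tail probability is < thresh."""
        below = np.flatnonzero(self._tail < thresh)
        if below.size == 0:
            return self._offset + self._tail.size  # unreachable score
        return int(self._offset + below[0])


def score_pvalue_table(motif: MotifModel, granularity: int = 1000) -> dict[float, float]:
    """Exact score -> tail-probability table (see :class:`ScoredMotif`)."""
    return ScoredMotif(motif, granularity).score_pvalue_table()


def scan_sequence(
    sm: ScoredMotif, seq_idx: np.ndarray, region_id: str = "", thresh: float = 0.001
) -> list[MotifHit]:
    """All offsets of one encoded sequence whose score p-value is < thresh.

    Windows containing N (index -1) are skipped; sequences shorter than the
    motif yield no hits.
    """
    w = sm.width
    n = seq_idx.size - w + 1
    if n <= 0:
        return []
    scores = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(w):
        col = seq_idx[i : i + n]
        ok &= col >= 0
        scores += sm.qscores[i, np.clip(col, 0, 3)]
    qcut = sm.pvalue_threshold_qscore(thresh)
    hits = np.flatnonzero(ok & (scores >= qcut))
    return [
        MotifHit(
            region_id=region_id,
            offset=int(o),
            score=float(scores[o] / sm.granularity),
            p_value=sm.tail_probability(int(scores[o])),
        )
        for o in hits
    ]


def scan_regions(
    motif: MotifModel | ScoredMotif,
    regions: Mapping[str, str],
    thresh: float = 0.001,
    granularity: int = 1000,
) -> tuple[list[MotifHit], dict[str, bool]]:
    """Scan a mapping region_id -> sequence; returns (hits, has-hit flags)."""
    sm = motif if isinstance(motif, ScoredMotif) else ScoredMotif(motif, granularity)
    hits: list[MotifHit] = []
    flags: dict[str, bool] = {}
    for rid, seq in regions.items():
        h = scan_sequence(sm, encode_rna(seq), region_id=rid, thresh=thresh)
        hits.extend(h)
        flags[rid] = bool(h)
    return hits, flags


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order letter frequencies over a sequence collection (N excluded)."""
    counts = np.zeros(4)
    for seq in sequences:
        idx = encode_rna(seq)
        idx = idx[idx >= 0]
        counts += np.bincount(idx, minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def region_sequence(region: RegionRecord, tx: TranscriptModel) -> str:
    if tx.sequence is None:
        raise ValidationError(f"{tx.transcript_id}: no sequence available")
    if region.end > tx.length:
        raise ValidationError(f"{region.transcript_id}: region outside transcript")
    return tx.sequence[region.start : region.end]


def sample_background_regions(
    transcripts: Mapping[str, TranscriptModel],
    exclude: Sequence[RegionRecord],
    length: int = 30,
    n: int | None = None,
    seed: int = 0,
    within: Sequence[RegionRecord] | None = None,
) -> list[RegionRecord]:
    """Uniformly sample background regions avoiding excluded intervals.

    Placement is uniform over all legal start positions pooled across the
    transcript set (the set of transcripts carrying the test regions); a
    legal start leaves the sampled region disjoint from every excluded
    interval and, when ``within`` is given (e.g. 3'UTRs when the test set is
    3'UTR-restricted), inside one allowed interval.  ``n`` defaults to the
    number of excluded (test) regions; sampling is with replacement and
    reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    excl_by_tx: dict[str, list[tuple[int, int]]] = {}
    for r in exclude:
        excl_by_tx.setdefault(r.transcript_id, []).append((r.start, r.end))
    within_by_tx: dict[str, list[tuple[int, int]]] | None = None
    if within is not None:
        within_by_tx = {}
        for r in within:
            within_by_tx.setdefault(r.transcript_id, []).append((r.start, r.end))

    source_tx = sorted(excl_by_tx) if excl_by_tx else sorted(transcripts)
    tx_ids: list[str] = []
    starts: list[np.ndarray] = []
    for tid in source_tx:
        tx = transcripts.get(tid)
        if tx is None:
            continue
        if within_by_tx is None:
            allowed_ivals = [(0, tx.length)]
        else:
            allowed_ivals = within_by_tx.get(tid, [])
        legal: list[int] = []
        for lo, hi in allowed_ivals:
            for s in range(lo, min(hi, tx.length) - length + 1):
                e = s + length
                if all(e <= xs or s >= xe for xs, xe in excl_by_tx.get(tid, [])):
                    legal.append(s)
        if legal:
            tx_ids.append(tid)
            starts.append(np.asarray(legal))
    if not starts:
        raise ValidationError("no legal background placement on any transcript")
    pool = np.concatenate(
        [np.stack([np.full(s.size, i), s], axis=1) for i, s in enumerate(starts)]
    )
    n_draw = n if n is not None else len(exclude)
    pick = rng.integers(0, pool.shape[0], size=n_draw)
    out = []
    for k, row in enumerate(pool[pick]):
        tid = tx_ids[int(row[0])]
        s = int(row[1])
        out.append(RegionRecord(tid, s, s + length, label=f"background_{k}"))
    # hard guarantee: background never touches an excluded interval
    for r in out:
        for xs, xe in excl_by_tx.get(r.transcript_id, []):
            if r.start < xe and xs < r.end:
                raise AssertionError("background region overlaps an excluded interval")
    return out


def motif_enrichment(
    motif: str, test_hits: Mapping[str, bool], ref_hits: Mapping[str, bool]
) -> EnrichmentResult:
    """Region-level 2x2 Fisher exact enrichment of one motif."""
    if not test_hits or not ref_hits:
        raise ValidationError("test and reference sets must be nonempty")
    a = sum(test_hits.values())
    b = len(test_hits) - a
    c = sum(ref_hits.values())
    d = len(ref_hits) - c
    if b > 0 and c > 0 and d > 0:
        ratio = (a / b) / (c / d)
    elif a > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(
        motif=motif,
        a=a,
        b=b,
        c=c,
        d=d,
        ratio=ratio,
        p_value=p,
        pct_test_with_hit=100.0 * a / len(test_hits),
    )


def add_fdr(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini-Hochberg FDR across a motif collection."""
    if not results:
        return []
    pvals = [r.p_value for r in results]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    from dataclasses import replace

    return [replace(r, fdr=float(q)) for r, q in zip(results, fdr)]


def enrich_motifs(
    motifs: Sequence[MotifModel],
    test_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    thresh: float = 0.001,
    granularity: int = 1000,
    background: np.ndarray | None = None,
) -> list[EnrichmentResult]:
    """Scan + Fisher + BH for a motif collection against a background set.

    Unless ``background`` is supplied, the 0-order background is estimated
    from the union of test and reference sequences.
    """
    if background is None:
        background = estimate_background(list(test_seqs.values()) + list(ref_seqs.values()))
    results = []
    for m in motifs:
        m_bg = MotifModel(name=m.name, probs=m.probs, background=background, pseudo=m.pseudo)
        sm = ScoredMotif(m_bg, granularity)
        _, tflags = scan_regions(sm, test_seqs, thresh)
        _, rflags = scan_regions(sm, ref_seqs, thresh)
        results.append(motif_enrichment(m.name, tflags, rflags))
    return add_fdr(results)


def kmer_enrichment_report(
    test_seqs: Mapping[str, str],
    ref_seqs: Mapping[str, str],
    k_range: Sequence[int] = (5, 6, 7),
    top: int = 20,
) -> list[EnrichmentResult]:
    """Diagnostic exhaustive k-mer enrichment (region-level Fisher + BH).

    A simple substitute for de novo motif discovery: every k-mer present in
    the test set is tested for region-level enrichment against the
    reference set.  This is a package diagnostic, not a discovery method.
    """

    def flags_for(seqs: Mapping[str, str], k: int) -> dict[str, set[str]]:
        out = {}
        for rid, seq in seqs.items():
            s = seq.upper().replace("T", "U")
            out[rid] = {s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]}
        return out

    results: list[EnrichmentResult] = []
    for k in k_range:
        test_k = flags_for(test_seqs, k)
        ref_k = flags_for(ref_seqs, k)
        kmers = set().union(*test_k.values()) if test_k else set()
        for km in sorted(kmers):
            t = {rid: km in s for rid, s in test_k.items()}
            r = {rid: km in s for rid, s in ref_k.items()}
            if sum(t.values()) < 2:
                continue
            results.append(motif_enrichment(km, t, r))
    results = add_fdr(results)
    results.sort(key=lambda r: (r.p_value, -r.ratio if np.isfinite(r.ratio) else 0))
    return results[:top]
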
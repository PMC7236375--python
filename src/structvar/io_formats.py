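"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based half-open **transcript** coordinates; nothing in
this package ever works in genomic space.  Sequences are stored over the RNA
alphabet ``ACGU`` (``T`` is accepted on input and converted, ``N`` is allowed
and treated as unknown).

Formats
-------
* transcript table — TSV with columns ``transcript_id, gene_id, length,
  utr5_end, cds_end``; an optional companion FASTA supplies sequences.
* reactivity ``.out`` — one line per transcript: id, length, a coverage
  proxy, then one value per base with the literal token ``NULL`` marking an
  invalid base.
* BED-like region files — 5 columns in transcript space
  (``transcript_id, start, end, label, score``).
* MEME minimal motif files (``ALPHABET= ACGU`` accepted as a synonym of
  ``ACGT``).

Every writer emits a ``#`` header comment recording the tool version and the
parameters used, and every ``read(write(x))`` round-trips exactly (floats at
6 significant digits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import __version__

_RNA_COMPLETE = set("ACGUN")

SEG_5UTR = "5UTR"
SEG_CDS = "CDS"
SEG_3UTR = "3UTR"
SEGMENTS = (SEG_5UTR, SEG_CDS, SEG_3UTR)


class FormatError(ValueError):
    """A file does not conform to its declared on-disk dialect."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


def _clean_rna(seq: str, *, context: str = "") -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA_COMPLETE
    if bad:
        raise ValidationError(f"non-RNA characters {sorted(bad)} in sequence {context}")
    return s


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its segment boundaries.

    ``utr5_end`` and ``cds_end`` are offsets splitting the transcript into
    the three non-overlapping segments: position ``p`` lies in the 5'UTR when
    ``p < utr5_end``, in the CDS when ``utr5_end <= p < cds_end`` and in the
    3'UTR otherwise.
    """

    transcript_id: str
    length: int
    utr5_end: int
    cds_end: int
    gene_id: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.transcript_id}: length must be positive")
        if not (0 <= self.utr5_end <= self.cds_end <= self.length):
            raise ValidationError(
                f"{self.transcript_id}: require 0 <= utr5_end ({self.utr5_end}) "
                f"<= cds_end ({self.cds_end}) <= length ({self.length})"
            )
        if self.sequence is not None:
            object.__setattr__(self, "sequence", _clean_rna(self.sequence, context=self.transcript_id))
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} != declared length {self.length}"
                )

    def segment_of(self, pos: int) -> str:
        if not 0 <= pos < self.length:
            raise ValidationError(f"{self.transcript_id}: position {pos} outside [0, {self.length})")
        if pos < self.utr5_end:
            return SEG_5UTR
        if pos < self.cds_end:
            return SEG_CDS
        return SEG_3UTR

    def segment_bounds(self, segment: str) -> tuple[int, int]:
        """Half-open bounds of one of the three segments."""
        if segment == SEG_5UTR:
            return 0, self.utr5_end
        if segment == SEG_CDS:
            return self.utr5_end, self.cds_end
        if segment == SEG_3UTR:
            return self.cds_end, self.length
        raise ValueError(f"unknown segment {segment!r}")


@dataclass(frozen=True)
class RegionRecord:
    """A labelled interval on a transcript (windows, regions, binding sites)."""

    transcript_id: str
    start: int
    end: int
    label: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.transcript_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _header_comment(kind: str, **params) -> str:
    extras = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# structvar v{__version__} {kind}" + (f" {extras}" if extras else "") + "\n"


def _fmt(x: float) -> str:
    """Floats at 6 significant digits; integral values without exponent noise."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# transcript table
# ---------------------------------------------------------------------------

_TX_COLUMNS = ["transcript_id", "gene_id", "length", "utr5_end", "cds_end"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file of transcript sequences, converting to ACGU."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record {rec.id}")
        out[rec.id] = _clean_rna(str(rec.seq), context=rec.id)
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_transcript_table(
    path: str | Path, fasta: str | Path | None = None
) -> dict[str, TranscriptModel]:
    """Read the transcript-model TSV (and optional companion FASTA).

    Raises :class:`FormatError` naming the offending line for malformed rows,
    :class:`ValidationError` for invariant violations, and rejects duplicate
    transcript ids.
    """
    seqs = read_fasta(fasta) if fasta is not None else {}
    out: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[: len(_TX_COLUMNS)] != _TX_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {_TX_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) < len(_TX_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(_TX_COLUMNS)} fields")
            tid, gid = fields[0], fields[1]
            try:
                length, utr5_end, cds_end = (int(x) for x in fields[2:5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate ({exc})") from exc
            if tid in out:
                raise ValidationError(f"{path}:{lineno}: duplicate transcript_id {tid!r}")
            out[tid] = TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=length,
                utr5_end=utr5_end,
                cds_end=cds_end,
                sequence=seqs.get(tid),
            )
    if header is None:
        raise FormatError(f"{path}: empty transcript table")
    return out


def write_transcript_table(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment("transcript_table"))
        fh.write("\t".join(_TX_COLUMNS) + "\n")
        for tx in transcripts:
            fh.write(
                f"{tx.transcript_id}\t{tx.gene_id}\t{tx.length}\t{tx.utr5_end}\t{tx.cds_end}\n"
            )


# ---------------------------------------------------------------------------
# reactivity ".out" dialect
# ---------------------------------------------------------------------------


def read_reactivity_out(path: str | Path) -> dict[str, "np.ndarray"]:
    """Read an icSHAPE-style ``.out`` reactivity file.

    Returns a mapping ``transcript_id -> float array`` with ``NaN`` marking
    invalid (``NULL``) bases; all finite values are validated into [0, 1].
    """
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected id, length, coverage, values")
            tid = fields[0]
            try:
                length = int(fields[1])
                float(fields[2])  # coverage proxy, kept only on disk
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad length/coverage field ({exc})") from exc
            tokens = fields[3:]
            if len(tokens) != length:
                raise FormatError(
                    f"{path}:{lineno}: declared length {length} but {len(tokens)} values"
                )
            vals = np.empty(length, dtype=float)
            for i, tok in enumerate(tokens):
                if tok == "NULL":
                    vals[i] = np.nan
                    continue
                try:
                    v = float(tok)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric token {tok!r}") from exc
                if not 0.0 <= v <= 1.0:
                    raise FormatError(f"{path}:{lineno}: reactivity {v} outside [0, 1]")
                vals[i] = v
            if tid in out:
                raise ValidationError(f"{path}:{lineno}: duplicate transcript {tid!r}")
            out[tid] = vals
    return out


def write_reactivity_out(
    profiles: Mapping[str, "np.ndarray"], path: str | Path, **params
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment("reactivity_out", **params))
        for tid, vals in profiles.items():
            arr = np.asarray(vals, dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError(f"{tid}: reactivity values outside [0, 1]")
            cov = float(np.isfinite(arr).mean()) if arr.size else 0.0
            toks = ["NULL" if not math.isfinite(v) else _fmt(v) for v in arr]
            fh.write("\t".join([tid, str(arr.size), _fmt(round(cov, 6))] + toks) + "\n")


# ---------------------------------------------------------------------------
# BED-like region files (transcript space)
# ---------------------------------------------------------------------------


def read_regions_bed(path: str | Path) -> list[RegionRecord]:
    out: list[RegionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            tid = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            out.append(RegionRecord(tid, start, end, label, score))
    return out


def write_regions_bed(regions: Iterable[RegionRecord], path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment("regions_bed", **params))
        for r in regions:
            score = "." if r.score is None else _fmt(r.score)
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.label}\t{score}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

MIN_MOTIF_WIDTH = 4  # below this the exact score p-value table degenerates


@dataclass
class MotifModel:
    """A position weight matrix over ACGU with a 0-order background.

    ``probs`` rows are letter probabilities; scoring applies the pseudocount
    blend ``(p + pseudo * bg) / (1 + pseudo)`` so zero entries stay finite in
    log-odds space.
    """

    name: str
    probs: "np.ndarray"  # width x 4, columns A C G U
    background: "np.ndarray" = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudo: float = 1e-4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError(f"{self.name}: PWM must be width x 4")
        if self.probs.shape[0] < MIN_MOTIF_WIDTH:
            raise ValidationError(
                f"{self.name}: motif width {self.probs.shape[0]} < minimum {MIN_MOTIF_WIDTH}"
            )
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise FormatError(f"{self.name}: PWM rows must sum to 1 within 1e-3")
        self.probs = self.probs / sums[:, None]
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError(f"{self.name}: background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def smoothed_probs(self) -> "np.ndarray":
        """Row-stochastic matrix after the pseudocount blend (rows sum to 1 ± 1e-6)."""
        p = (self.probs + self.pseudo * self.background[None, :]) / (1.0 + self.pseudo)
        return p

    def log_odds(self) -> "np.ndarray":
        """Per-position log2 odds against the background (-inf for zero cells)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.smoothed_probs() / self.background[None, :])


def read_motif_meme(path: str | Path) -> list[MotifModel]:
    """Parse a MEME minimal-format motif file (RNA or DNA alphabet)."""
    motifs: list[MotifModel] = []
    background = np.full(4, 0.25)
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j].upper().replace("T", "U"): float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in "ACGU"])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # seek the letter-probability header
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: MOTIF {name} lacks a letter-probability matrix")
            header = lines[i]
            width = None
            if "w=" in header:
                try:
                    width = int(header.split("w=")[1].split()[0])
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}: bad letter-probability header for {name}") from exc
            rows: list[list[float]] = []
            i += 1
            while i < len(lines):
                row = lines[i].split()
                if len(row) != 4:
                    break
                try:
                    rows.append([float(x) for x in row])
                except ValueError:
                    break
                i += 1
            if width is not None and len(rows) != width:
                raise FormatError(f"{path}: MOTIF {name} declares w={width} but has {len(rows)} rows")
            motifs.append(MotifModel(name=name, probs=np.array(rows), background=background.copy()))
            continue
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def write_motif_meme(motifs: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGU\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6g}" for i, b in enumerate("ACGU")) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def consensus_motif(name: str, consensus: str, conc: float = 1.0, background=None) -> MotifModel:
    """Build a PWM from a consensus word.

    ``conc`` is the probability mass on the consensus letter at each
    position; the remainder is spread over the other three letters.
    """
    consensus = _clean_rna(consensus, context=name)
    rows = []
    for ch in consensus:
        row = [(1.0 - conc) / 3.0] * 4
        row["ACGU".index(ch)] = conc
        rows.append(row)
    kwargs = {} if background is None else {"background": np.asarray(background, float)}
    return MotifModel(name=name, probs=np.array(rows), **kwargs)
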
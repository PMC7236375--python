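"""Per-base icSHAPE reactivity from RT-stop counts.

The probing signal is a pair of per-base count vectors per library: RT-stop
events (reverse transcription terminating at the base, the chemical-adduct
readout) and base density (read coverage).  Reactivity computation follows
the icSHAPE convention:

1. RT stops are normalized in 200-nt sliding windows (30-nt step): each
   window's values are divided by the mean of the values whose nearest-rank
   percentile lies in [90, 95], scaled by 100, and each position takes the
   mean of its value over all windows covering it.
2. Raw reactivity is ``max(0, treated - alpha_bg * control) / max(density, 1)``
   with background factor ``alpha_bg`` (default 0.25).
3. Per transcript, raw values are scaled by the mean of the raw values in the
   nearest-rank [90, 95] percentile band and clipped to [0, 1].

Positions with no usable signal carry an explicit invalid marker (NaN);
absence of signal is never reported as structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError

TREATED = "treated"
CONTROL = "control"
MERGED_REPLICATE = -1

INVALID = np.nan


def is_valid(values: np.ndarray) -> np.ndarray:
    """Boolean mask of valid (non-NaN) entries."""
    return np.isfinite(np.asarray(values, dtype=float))


@dataclass
class RTStopProfile:
    """Raw probing signal for one transcript / condition / replicate.

    ``stops`` and ``density`` are independent per-base counts; stops are not
    bounded by density (they are counted from read 5' ends, density from
    coverage).
    """

    transcript_id: str
    stops: np.ndarray
    density: np.ndarray
    condition: str = TREATED
    replicate: int = 1
    stage: str = ""

    def __post_init__(self) -> None:
        self.stops = np.asarray(self.stops, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.stops.shape != self.density.shape or self.stops.ndim != 1:
            raise ValidationError(
                f"{self.transcript_id}: stops and density must be 1-D and equal length"
            )
        if np.any(self.stops < 0) or np.any(self.density < 0):
            raise ValidationError(f"{self.transcript_id}: negative counts")
        if self.condition not in (TREATED, CONTROL):
            raise ValidationError(f"{self.transcript_id}: unknown condition {self.condition!r}")

    @property
    def length(self) -> int:
        return int(self.stops.size)


@dataclass
class ReactivityProfile:
    """Per-base reactivity in [0, 1] with NaN as the invalid marker."""

    transcript_id: str
    values: np.ndarray
    stage: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError(f"{self.transcript_id}: reactivity outside [0, 1]")

    @property
    def length(self) -> int:
        return int(self.values.size)

    def valid_fraction(self) -> float:
        return float(np.isfinite(self.values).mean()) if self.values.size else 0.0


@dataclass
class ReactivityParams:
    """Tunable constants of the reactivity calculation.

    window/step
        sliding-window normalization geometry (nt).
    rank_lo, rank_hi
        percentile band whose mean is the per-window normalizer.
    scale
        multiplier bringing most normalized stops into [0, 100].
    alpha_bg
        background (control library) subtraction factor.
    min_avg_stop, min_density
        transcript-level inclusion filters on the treated library.
    winsor_hi
        upper percentile of the per-transcript scaling band
        [winsor_hi - 5, winsor_hi] used to map raw reactivity onto [0, 1].
    winsor_lo
        lower reference percentile; with the hard floor at 0 applied by the
        background subtraction it does not move the default computation, and
        is kept as an explicit knob.
    """

    window: int = 200
    step: int = 30
    rank_lo: float = 90.0
    rank_hi: float = 95.0
    scale: float = 100.0
    alpha_bg: float = 0.25
    min_avg_stop: float = 2.0
    min_density: float = 200.0
    winsor_hi: float = 95.0
    winsor_lo: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.rank_lo < self.rank_hi <= 100):
            raise ValidationError("require 0 <= rank_lo < rank_hi <= 100")
        if self.window <= 0 or self.step <= 0:
            raise ValidationError("window and step must be positive")


def nearest_rank_band(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Values whose nearest-rank percentile lies in the inclusive band [lo, hi].

    The nearest-rank convention maps percentile p on n sorted values to the
    ceil(p/100*n)-th order statistic (1-based); the band is the slice between
    the two ranks, inclusive.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return v
    r_lo = max(1, int(np.ceil(lo / 100.0 * n)))
    r_hi = max(1, int(np.ceil(hi / 100.0 * n)))
    return v[r_lo - 1 : r_hi]


def combine_replicates(profiles: Sequence[RTStopProfile]) -> RTStopProfile:
    """Element-wise sum of replicate RT-stop profiles.

    All profiles must share transcript, condition, stage and length; the
    result carries the merged-replicate sentinel.
    """
    if not profiles:
        raise ValidationError("no profiles to combine")
    first = profiles[0]
    for p in profiles[1:]:
        if (
            p.transcript_id != first.transcript_id
            or p.condition != first.condition
            or p.stage != first.stage
        ):
            raise ValidationError("profiles differ in transcript, condition or stage")
        if p.length != first.length:
            raise ValidationError(
                f"{first.transcript_id}: replicate lengths differ ({p.length} vs {first.length})"
            )
    return RTStopProfile(
        transcript_id=first.transcript_id,
        stops=np.sum([p.stops for p in profiles], axis=0),
        density=np.sum([p.density for p in profiles], axis=0),
        condition=first.condition,
        replicate=MERGED_REPLICATE,
        stage=first.stage,
    )


def _window_starts(length: int, window: int, step: int) -> list[int]:
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    # keep the 3' tail valued: anchor one final full-size window at the end
    # rather than normalizing a short tail window with a noisy band
    if starts[-1] + window < length:
        starts.append(length - window)
    return starts


def normalize_rtstops(profile: RTStopProfile, params: ReactivityParams | None = None) -> np.ndarray:
    """Sliding-window percentile normalization of RT stops.

    Each window divides its values by the mean of its nearest-rank
    [rank_lo, rank_hi] percentile band and multiplies by ``scale``; each
    position's output is the mean over all covering windows.  Windows whose
    normalizer is 0 contribute the invalid marker; positions with no valid
    contribution are invalid.
    """
    params = params or ReactivityParams()
    stops = np.asarray(profile.stops, dtype=float)
    n = stops.size
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    for s in _window_starts(n, params.window, params.step):
        e = min(s + params.window, n)
        w = stops[s:e]
        band = nearest_rank_band(w, params.rank_lo, params.rank_hi)
        norm = float(band.mean()) if band.size else 0.0
        if norm <= 0:
            continue  # invalid contribution
        acc[s:e] += w / norm * params.scale
        cnt[s:e] += 1
    out = np.full(n, INVALID)
    covered = cnt > 0
    out[covered] = acc[covered] / cnt[covered]
    return out


def compute_reactivity(
    treated_norm: np.ndarray,
    control_norm: np.ndarray,
    density: np.ndarray,
    params: ReactivityParams | None = None,
    transcript_id: str = "",
    stage: str = "",
) -> ReactivityProfile:
    """Background-subtract, density-correct, winsor-scale and clip to [0, 1]."""
    params = params or ReactivityParams()
    t = np.asarray(treated_norm, dtype=float)
    c = np.asarray(control_norm, dtype=float)
    d = np.asarray(density, dtype=float)
    if not (t.shape == c.shape == d.shape):
        raise ValidationError(f"{transcript_id}: treated/control/density length mismatch")
    valid = np.isfinite(t) & np.isfinite(c) & (d > 0)
    raw = np.full(t.shape, INVALID)
    raw[valid] = np.maximum(0.0, t[valid] - params.alpha_bg * c[valid]) / np.maximum(
        d[valid], 1.0
    )
    values = np.full(t.shape, INVALID)
    rv = raw[valid]
    if rv.size:
        band = nearest_rank_band(rv, params.winsor_hi - 5.0, params.winsor_hi)
        norm = float(band.mean()) if band.size else 0.0
        if norm > 0:
            values[valid] = np.clip(rv / norm, 0.0, 1.0)
    return ReactivityProfile(transcript_id=transcript_id, values=values, stage=stage)


def reactivity_pipeline(
    treated: Sequence[RTStopProfile],
    control: Sequence[RTStopProfile],
    params: ReactivityParams | None = None,
) -> ReactivityProfile:
    """Replicate combination + normalization + reactivity for one transcript."""
    params = params or ReactivityParams()
    t = combine_replicates(list(treated))
    c = combine_replicates(list(control))
    if t.length != c.length:
        raise ValidationError(f"{t.transcript_id}: treated/control length mismatch")
    t_norm = normalize_rtstops(t, params)
    c_norm = normalize_rtstops(c, params)
    return compute_reactivity(
        t_norm, c_norm, t.density, params, transcript_id=t.transcript_id, stage=t.stage
    )


@dataclass
class FilterReport:
    retained: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # transcript -> reason
    valid_fraction: dict[str, float] = field(default_factory=dict)
    density_filter_library: str = TREATED  # the density filter is applied to the treated library


def filter_transcripts(
    treated: Mapping[str, RTStopProfile],
    params: ReactivityParams | None = None,
    reactivities: Mapping[str, ReactivityProfile] | None = None,
) -> tuple[dict[str, RTStopProfile], FilterReport]:
    """Transcript-level inclusion filter on the treated library.

    A transcript is retained iff its mean raw RT stop >= ``min_avg_stop`` and
    mean base density >= ``min_density`` (both inclusive).  The report lists
    each exclusion with its reason and, when reactivity profiles are
    supplied, the per-transcript fraction of valid bases.
    """
    params = params or ReactivityParams()
    report = FilterReport()
    kept: dict[str, RTStopProfile] = {}
    for tid, prof in treated.items():
        avg_stop = float(prof.stops.mean()) if prof.length else 0.0
        avg_density = float(prof.density.mean()) if prof.length else 0.0
        if avg_stop < params.min_avg_stop:
            report.excluded[tid] = "avg_stop"
        elif avg_density < params.min_density:
            report.excluded[tid] = "density"
        else:
            kept[tid] = prof
            report.retained.append(tid)
        if reactivities and tid in reactivities:
            report.valid_fraction[tid] = reactivities[tid].valid_fraction()
    return kept, report


@dataclass
class NoiseReport:
    """Replicate-agreement summary used to calibrate |Δreactivity| cutoffs."""

    n_bases: int
    n_windows: int
    base_frac_below: dict[float, float]
    window_frac_below: dict[float, float]
    base_quantile: dict[float, float]
    window_quantile: dict[float, float]
    empty: bool = False


def replicate_noise_quantiles(
    rep_a: Mapping[str, ReactivityProfile],
    rep_b: Mapping[str, ReactivityProfile],
    window: int = 10,
    base_thresholds: Sequence[float] = (0.2,),
    window_thresholds: Sequence[float] = (0.05,),
    quantiles: Sequence[float] = (0.95, 0.985),
) -> NoiseReport:
    """Per-base and per-window |Δreactivity| between two replicate runs.

    Only positions valid in both replicates enter; windows are disjoint
    ``window``-nt tiles scored by |difference of the window-average
    reactivity| over jointly valid bases — the same statistic the window
    caller thresholds (windows with no valid base are skipped).
    """
    base_deltas: list[np.ndarray] = []
    win_deltas: list[float] = []
    for tid, pa in rep_a.items():
        pb = rep_b.get(tid)
        if pb is None or pb.length != pa.length:
            continue
        both = np.isfinite(pa.values) & np.isfinite(pb.values)
        signed = pb.values - pa.values
        base_deltas.append(np.abs(signed[both]))
        for s in range(0, pa.length - window + 1, window):
            m = both[s : s + window]
            if m.any():
                win_deltas.append(abs(float(np.mean(signed[s : s + window][m]))))
    bases = np.concatenate(base_deltas) if base_deltas else np.empty(0)
    wins = np.asarray(win_deltas)
    if bases.size == 0:
        return NoiseReport(0, 0, {}, {}, {}, {}, empty=True)
    return NoiseReport(
        n_bases=int(bases.size),
        n_windows=int(wins.size),
        base_frac_below={t: float((bases < t).mean()) for t in base_thresholds},
        window_frac_below={
            t: float((wins < t).mean()) if wins.size else float("nan") for t in window_thresholds
        },
        base_quantile={q: float(np.quantile(bases, q)) for q in quantiles},
        window_quantile={
            q: float(np.quantile(wins, q)) if wins.size else float("nan") for q in quantiles
        },
    )


def read_rtstops_tsv(path) -> dict[str, list[RTStopProfile]]:
    """Read the long-format RT-stop TSV
    (transcript_id, position, stops, density, condition, replicate).

    Returns transcript_id -> list of profiles (one per condition/replicate).
    Positions must tile 0..length-1 for each profile.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "position", "stops", "density", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[RTStopProfile]] = {}
    for (tid, cond, rep), grp in df.groupby(["transcript_id", "condition", "replicate"], sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 0 or not np.array_equal(pos, np.arange(pos.size)):
            raise ValidationError(f"{path}: positions of {tid}/{cond}/rep{rep} do not tile from 0")
        out.setdefault(str(tid), []).append(
            RTStopProfile(
                transcript_id=str(tid),
                stops=grp["stops"].to_numpy(dtype=float),
                density=grp["density"].to_numpy(dtype=float),
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return out


def stage_reactivities(
    profiles: dict[str, list[RTStopProfile]],
    params: ReactivityParams | None = None,
    stage: str = "",
) -> dict[str, ReactivityProfile]:
    """Full per-stage pipeline over a transcript -> profiles mapping."""
    params = params or ReactivityParams()
    out: dict[str, ReactivityProfile] = {}
    for tid, plist in profiles.items():
        treated = [p for p in plist if p.condition == TREATED]
        control = [p for p in plist if p.condition == CONTROL]
        if not treated or not control:
            continue
        prof = reactivity_pipeline(treated, control, params)
        prof.stage = stage
        out[tid] = prof
    return out


PAIRED, UNPAIRED, UNKNOWN = "paired", "unpaired", "unknown"


def structure_auc(
    profile: ReactivityProfile, pairing: Sequence[str]
) -> tuple[float, float]:
    """ROC AUC of reactivity as a classifier of unpaired bases, plus t-test p.

    The positive class is ``unpaired`` (high reactivity expected); ties are
    handled by midranks (the AUC equals the Mann-Whitney U statistic scaled
    by the number of pairs).  The second value is the two-sided unpaired
    t-test p for paired vs unpaired reactivity.
    """
    pairing = np.asarray(pairing, dtype=object)
    if pairing.shape[0] != profile.length:
        raise ValidationError("pairing annotation length mismatch")
    valid = np.isfinite(profile.values)
    up = profile.values[valid & (pairing == UNPAIRED)]
    dn = profile.values[valid & (pairing == PAIRED)]
    if up.size == 0 or dn.size == 0:
        raise ValidationError("need at least one valid paired and one unpaired base")
    u_stat = stats.mannwhitneyu(up, dn, alternative="two-sided").statistic
    auc = float(u_stat / (up.size * dn.size))
    t_p = float(stats.ttest_ind(dn, up).pvalue) if (up.size > 1 and dn.size > 1) else float("nan")
    return auc, t_p
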
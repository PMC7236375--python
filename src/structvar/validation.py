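"""Planted-truth validation experiments for the whole pipeline.

Each function runs one controlled experiment on generator output and returns
the measured recovery/calibration metrics as a plain dict.  They are used by
the test suite and by ``scripts/acceptance.py``; pipeline code never calls
them.  Every experiment takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from . import diffstruct as ds
from . import motif_enrich as me
from . import regulome as rg
from . import reactivity as rx
from . import synthetic_data as sd
from .io_formats import MotifModel, RegionRecord, TranscriptModel, consensus_motif


# ---------------------------------------------------------------------------
# normalization oracle
# ---------------------------------------------------------------------------


def _brute_force_normalize(stops: np.ndarray, params: rx.ReactivityParams) -> np.ndarray:
    """Plain per-window re-implementation of the sliding normalization."""
    n = len(stops)
    window, step = params.window, params.step
    if n <= window:
        starts = [0]
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] + window < n:
            starts.append(n - window)
    contrib: list[list[float]] = [[] for _ in range(n)]
    for s in starts:
        w = list(stops[s : s + window])
        v = sorted(w)
        m = len(v)
        r_lo = max(1, math.ceil(params.rank_lo / 100 * m))
        r_hi = max(1, math.ceil(params.rank_hi / 100 * m))
        band = v[r_lo - 1 : r_hi]
        norm = sum(band) / len(band) if band else 0.0
        if norm <= 0:
            continue
        for i, x in enumerate(w):
            contrib[s + i].append(x / norm * params.scale)
    out = np.full(n, np.nan)
    for i, c in enumerate(contrib):
        if c:
            out[i] = sum(c) / len(c)
    return out


def normalization_oracle_check(n_profiles: int = 1000, seed: int = 0) -> dict:
    """Max |difference| between normalize_rtstops and the brute-force oracle."""
    rng = np.random.default_rng(seed)
    params = rx.ReactivityParams()
    worst = 0.0
    for _ in range(n_profiles):
        n = int(rng.integers(5, 600))
        stops = rng.poisson(rng.uniform(1, 50), size=n).astype(float)
        got = rx.normalize_rtstops(rx.RTStopProfile("t", stops, np.ones(n)), params)
        want = _brute_force_normalize(stops, params)
        both = np.isfinite(got) & np.isfinite(want)
        if (np.isfinite(got) != np.isfinite(want)).any():
            worst = float("inf")
            break
        if both.any():
            worst = max(worst, float(np.abs(got[both] - want[both]).max()))
    return {"max_abs_diff": worst, "n_profiles": n_profiles}


# ---------------------------------------------------------------------------
# stage-pair experiments
# ---------------------------------------------------------------------------


def _stage_profiles(truth: sd.GroundTruth, stage: str, rng: np.random.Generator):
    return rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(truth, stage, rng)), stage=stage
    )


def null_window_calibration(n_transcripts: int = 500, seed: int = 0) -> dict:
    """Type-I behaviour of the window caller on a true null stage pair.

    The same ground truth is probed twice with independent count noise; every
    variable call is a false positive.
    """
    cfg = sd.SimConfig(
        n_transcripts=n_transcripts, n_switch_sites=0, n_bound_sites=0,
        n_unbound_sites=0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    truth = sd.make_transcriptome(cfg, rng)
    ra = _stage_profiles(truth, "4hpf", rng)
    rb = _stage_profiles(truth, "4hpf", rng)  # same stage, independent noise
    n_kept = n_called = 0
    for tid in ra:
        for w in ds.window_scan(ra[tid], rb[tid]):
            n_kept += 1
            n_called += w.klass != ds.STABLE
    return {
        "null_call_fraction": n_called / max(1, n_kept),
        "n_windows": n_kept,
    }


def segment_fisher_null(n_sims: int = 1000, total: int = 400, seed: int = 0) -> dict:
    """Distribution of segment-enrichment Fisher p under uniform placement."""
    rng = np.random.default_rng(seed)
    p = np.asarray(ds.DEFAULT_SEGMENT_WEIGHTS) / sum(ds.DEFAULT_SEGMENT_WEIGHTS)
    pvals: list[float] = []
    ratios: list[float] = []
    for _ in range(n_sims):
        obs = rng.multinomial(total, p)
        for e in ds.segment_enrichment(dict(zip(ds.SEGMENTS, obs.tolist()))):
            pvals.append(e.fisher_p)
            ratios.append(e.ratio)
    arr = np.asarray(pvals)
    return {
        "ks_p": float(stats.kstest(arr, "uniform").pvalue),
        "frac_below_0.05": float((arr < 0.05).mean()),
        "mean_ratio": float(np.mean(ratios)),
        "n_sims": n_sims,
    }


def _region_overlaps(r, s) -> bool:
    return r.transcript_id == s.transcript_id and r.start < s.end and s.start < r.end


def switch_recovery(
    n_seeds: int = 10,
    n_transcripts: int = 100,
    n_switch_sites: int = 240,
    seed: int = 0,
) -> dict:
    """Sensitivity/FDR of the differential caller on planted 0.3-shift blocks.

    Counts are pooled across seeds; a planted block is recovered when a
    called region of the matching class overlaps it, and a called region is
    false when it overlaps no planted block.
    """
    tp = fp = n_planted = n_recovered = 0
    for k in range(n_seeds):
        cfg = sd.SimConfig(
            n_transcripts=n_transcripts, n_switch_sites=n_switch_sites,
            n_bound_sites=0, n_unbound_sites=0, seed=seed + k,
        )
        rng = np.random.default_rng(seed + k)
        truth = sd.make_transcriptome(cfg, rng)
        ra = _stage_profiles(truth, "4hpf", rng)
        rb = _stage_profiles(truth, "6hpf", rng)
        wins = []
        for tid in ra:
            wins.extend(ds.window_scan(ra[tid], rb[tid]))
        regions = ds.build_regions(
            wins, {t: tx.length for t, tx in truth.transcripts.items()}
        )
        planted = truth.switch_regions()
        n_planted += len(planted)
        n_recovered += sum(
            any(_region_overlaps(r, s) and r.klass == s.label for r in regions)
            for s in planted
        )
        for r in regions:
            if any(_region_overlaps(r, s) for s in planted):
                tp += 1
            else:
                fp += 1
    return {
        "sensitivity": n_recovered / max(1, n_planted),
        "fdr": fp / max(1, tp + fp),
        "n_planted": n_planted,
        "n_called_regions": tp + fp,
    }


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------


def pwm_exactness_check(widths=(4, 5, 6, 7, 8), seed: int = 0) -> dict:
    """DP tail probabilities vs exhaustive enumeration over all 4^w words."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for width in widths:
        m = MotifModel("rand", rng.dirichlet(np.ones(4), size=width))
        sm = me.ScoredMotif(m)
        words = np.array(list(itertools.product(range(4), repeat=width)))
        scores = sm.qscores[np.arange(width), words].sum(axis=1)
        bgp = np.prod(m.background[words], axis=1)
        order = np.argsort(scores)[::-1]
        cum = np.cumsum(bgp[order])
        uniq_scores = scores[order]
        for t in np.unique(scores):
            enum_tail = float(cum[np.searchsorted(-uniq_scores, -t, side="right") - 1])
            worst = max(worst, abs(sm.tail_probability(int(t)) - enum_tail))
    single = consensus_motif("U5", "UUUUU", conc=1.0)
    single.pseudo = 0.0
    sm = me.ScoredMotif(single)
    p_max = sm.tail_probability(int(sm.qscores.max(axis=1).sum()))
    return {"max_abs_error": worst, "single_word_width5_max_score_p": p_max}


def _random_regions(rng, n, length=30):
    return ["".join("ACGU"[i] for i in rng.integers(0, 4, size=length)) for _ in range(n)]


def _plant(seqs, frac, word, rng):
    out = list(seqs)
    k = int(round(frac * len(out)))
    for i in rng.choice(len(out), size=k, replace=False):
        s = out[i]
        pos = int(rng.integers(0, len(s) - len(word) + 1))
        out[i] = s[:pos] + word + s[pos + len(word) :]
    return out


def enrichment_recovery(
    n_runs: int = 100,
    n_regions: int = 500,
    test_frac: float = 0.4,
    ref_frac: float = 0.1,
    seed: int = 0,
) -> dict:
    """Motif-enrichment ratio recovery on planted region sets.

    The analytic region-level target is (0.4/0.6)/(0.1/0.9) = 6.0; scanning
    false positives on unplanted regions bias the measured ratio slightly
    downward, so the mean over runs is compared, not each run's draw.
    """
    motif = consensus_motif("planted", "UUUGUUU", conc=0.85)
    ratios, sig = [], []
    for k in range(n_runs):
        rng = np.random.default_rng(seed + k)
        test = _plant(_random_regions(rng, n_regions), test_frac, "UUUGUUU", rng)
        ref = _plant(_random_regions(rng, n_regions), ref_frac, "UUUGUUU", rng)
        res = me.enrich_motifs(
            [motif],
            {f"t{i}": s for i, s in enumerate(test)},
            {f"r{i}": s for i, s in enumerate(ref)},
        )[0]
        ratios.append(res.ratio)
        sig.append(res.fdr < 0.05)
    return {
        "mean_ratio": float(np.mean(ratios)),
        "analytic_ratio": (test_frac / (1 - test_frac)) / (ref_frac / (1 - ref_frac)),
        "frac_runs_significant": float(np.mean(sig)),
        "n_runs": n_runs,
    }


def enrichment_null(n_sims: int = 10, n_motifs: int = 20, n_regions: int = 300, seed: int = 0) -> dict:
    """Fraction of random motifs called enriched when test == reference generator."""
    frac_sig = []
    for k in range(n_sims):
        rng = np.random.default_rng(seed + 1000 + k)
        motifs = [
            MotifModel(f"m{i}", rng.dirichlet(np.ones(4) * 2, size=6)) for i in range(n_motifs)
        ]
        test = {f"t{i}": s for i, s in enumerate(_random_regions(rng, n_regions))}
        ref = {f"r{i}": s for i, s in enumerate(_random_regions(rng, n_regions))}
        res = me.enrich_motifs(motifs, test, ref)
        frac_sig.append(np.mean([r.fdr < 0.05 for r in res]))
    return {"null_sig_fraction": float(np.mean(frac_sig)), "n_sims": n_sims}


# ---------------------------------------------------------------------------
# regulome experiments
# ---------------------------------------------------------------------------


def metaprofile_recovery(seed: int = 0) -> dict:
    """Bound vs unbound-control metaprofile margin, against the noiseless oracle.

    The planted margin is defined by a deterministic (expectation-valued)
    pipeline run on the same ground truth; the noisy margin must agree
    within Monte-Carlo error.  Also verifies that swapping the stages
    exchanges group I and II site labels exactly.
    """
    cfg = sd.SimConfig(
        n_transcripts=60, n_switch_sites=20, n_bound_sites=40, n_unbound_sites=40,
        mutation_rate=0.0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    truth = sd.make_transcriptome(cfg, rng)
    motif = sd.planted_motif(cfg)
    bound = truth.bound_binding_sites()
    controls = rg.unbound_controls(motif, truth.transcripts, bound)

    def margin(profiles):
        mp_b = rg.metaprofile(profiles, bound, set_label="bound")
        mp_u = rg.metaprofile(profiles, controls, set_label="unbound_control")
        mid = len(mp_b.offsets) // 2
        return float(mp_b.mean_reactivity[mid] - mp_u.mean_reactivity[mid])

    noiseless = rx.stage_reactivities(
        sd.flatten_pairs(sd.simulate_rtstops(truth, "4hpf", rng, replicates=1, noiseless=True))
    )
    noisy_a = _stage_profiles(truth, "4hpf", rng)
    noisy_b = _stage_profiles(truth, "6hpf", rng)

    fwd = rg.classify_site_structure(noisy_a, noisy_b, bound)
    rev = rg.classify_site_structure(noisy_b, noisy_a, bound)
    swap = {rg.GROUP_I: rg.GROUP_II, rg.GROUP_II: rg.GROUP_I, rg.UNCHANGED: rg.UNCHANGED}
    symmetric = all(gr.group == swap[gf.group] for gf, gr in zip(fwd, rev))

    return {
        "margin_noiseless": margin(noiseless),
        "margin_noisy": margin(noisy_a),
        "n_bound": len(bound),
        "n_controls": len(controls),
        "stage_swap_symmetric": bool(symmetric),
    }


def stability_recovery(
    n_seeds: int = 30,
    n_genes_per_group: int = 1000,
    decay_coupling: float = 0.6,
    seed: int = 0,
) -> dict:
    """Recovery of the structure-stability coupling through the expression side.

    Site structural groups come from the generator's planted truth (their
    recovery from probing counts is exercised separately); expression counts
    are simulated and pushed through RPKM, the exact DE test, gene
    classification and the group association.  Short transcripts keep the
    experiment light: only the expression machinery is under test.
    """
    n_tx = 2 * n_genes_per_group + max(100, n_genes_per_group // 5)
    within, sig, fracs = [], [], []
    for k in range(n_seeds):
        cfg = sd.SimConfig(
            n_transcripts=n_tx, n_switch_sites=2 * n_genes_per_group,
            n_bound_sites=0, n_unbound_sites=0,
            mean_length=320, sd_length=20, min_length=260, hairpin_density=0.0,
            seq_depth=300.0, dispersion_log2=0.05,
            decay_coupling=decay_coupling, seed=seed + k,
        )
        rng = np.random.default_rng(seed + k)
        truth = sd.make_transcriptome(cfg, rng)
        counts, lengths = sd.simulate_expression(truth, rng)
        early = ["4hpf_rep1", "4hpf_rep2"]
        late = ["6hpf_rep1", "6hpf_rep2"]
        rpkm_early = rg.rpkm([counts[c] for c in early], lengths)
        rpkm_late = rg.rpkm([counts[c] for c in late], lengths)
        sum_early = {g: counts[early[0]].get(g, 0) + counts[early[1]].get(g, 0) for g in lengths}
        sum_late = {g: counts[late[0]].get(g, 0) + counts[late[1]].get(g, 0) for g in lengths}
        de = rg.de_test(sum_early, sum_late)
        records = [
            rg.GeneRecord(g, {"4hpf": rpkm_early[g], "6hpf": rpkm_late[g]},
                          log2fc=de[g][0], de_p=de[g][1], de_fdr=de[g][2])
            for g in sorted(lengths)
        ]
        records = rg.classify_genes(records, "4hpf", "6hpf")
        genes = {r.gene_id: r for r in records}
        tx_gene = {t: tx.gene_id for t, tx in truth.transcripts.items()}
        groups = [
            rg.SiteStructGroup(tid, rg.BindingSite(tid, 10, 0, 21), 0.5, 0.4, 0.01, grp)
            for tid, grp in truth.site_group.items()
        ]
        assoc = rg.stability_association(groups, genes, tx_gene)
        frac = assoc.class_fractions[rg.GROUP_I][rg.MATERNAL_DECAY]
        fracs.append(frac)
        within.append(abs(frac - decay_coupling) <= 0.05)
        sig.append(assoc.ranksum_p < 0.01)
    return {
        "mean_groupI_decay_fraction": float(np.mean(fracs)),
        "frac_seeds_within_5pts": float(np.mean(within)),
        "frac_seeds_ranksum_sig": float(np.mean(sig)),
        "n_seeds": n_seeds,
        "n_genes_per_group": n_genes_per_group,
    }


# ---------------------------------------------------------------------------
# interval calculus oracle
# ---------------------------------------------------------------------------


def _brute_force_merge(intervals):
    ivals = [list(i) for i in intervals]
    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for s, e in ivals:
            for o in out:
                if s <= o[1] and o[0] <= e:
                    o[0], o[1] = min(o[0], s), max(o[1], e)
                    changed = True
                    break
            else:
                out.append([s, e])
        ivals = out
    return sorted(tuple(i) for i in ivals)


def interval_oracle_check(n_sets: int = 1000, seed: int = 0) -> dict:
    """build_regions vs brute-force merging; segment rule on boundary sweep."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_sets):
        starts = rng.integers(0, 40, size=rng.integers(1, 15))
        wins = [
            ds.StructWindow("t", int(s) * 10, int(s) * 10 + 10, 0.1, 0.01,
                            ds.LESS_STRUCTURAL, 10)
            for s in starts
        ]
        regions = ds.build_regions(wins, {"t": 500})
        merged = _brute_force_merge(
            [(max(0, w.start - 10), min(500, w.end + 10)) for w in wins]
        )
        want = []
        for s, e in merged:
            for b in range(s, e, 30):
                want.append((b, min(b + 30, e)))
        if sorted((r.start, r.end) for r in regions) != sorted(want):
            mismatches += 1

    tx = TranscriptModel("t", 1860, 150, 1400)
    rule_errors = 0
    for start in range(1370, 1401):  # 30-nt regions sweeping the CDS/3'UTR boundary
        region = RegionRecord("t", start, start + 30)
        got = ds.assign_segment(region, tx)
        in_3utr = max(0, start + 30 - 1400)
        in_cds = 30 - in_3utr
        if in_3utr / 30 >= 0.51:
            want_seg = "3UTR"
        elif in_cds / 30 >= 0.51:
            want_seg = "CDS"
        else:
            want_seg = ds.UNASSIGNED
        rule_errors += got != want_seg
    return {"merge_mismatches": mismatches, "segment_rule_errors": rule_errors, "n_sets": n_sets}
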
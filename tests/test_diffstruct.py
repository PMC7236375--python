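"""Differential-structure calls: windows, regions, hot regions, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from structvar import diffstruct as ds
from structvar.io_formats import RegionRecord, TranscriptModel, ValidationError
from structvar.reactivity import ReactivityProfile


def prof(values, tid="t"):
    return ReactivityProfile(tid, np.asarray(values, dtype=float))


class TestVariableNucleotides:
    def test_identical_profiles_empty(self):
        p = prof([0.1, 0.5, 0.9])
        assert ds.call_variable_nucleotides(p, p) == []

    def test_threshold_and_sign(self):
        a = prof([0.1, 0.1])
        b = prof([0.35, 0.2])
        assert ds.call_variable_nucleotides(a, b) == [(0, pytest.approx(0.25))]

    def test_invalid_in_either_profile_excluded(self):
        a = prof([0.1, 0.1])
        b = prof([np.nan, 0.9])
        assert [i for i, _ in ds.call_variable_nucleotides(a, b)] == [1]


class TestWindowScan:
    def test_identical_profiles_all_stable(self):
        vals = np.linspace(0.05, 0.95, 30)
        wins = ds.window_scan(prof(vals), prof(vals))
        assert len(wins) == 3
        assert all(w.klass == ds.STABLE for w in wins)

    def test_known_deltas_called_less_structural(self):
        # 8 valid bases with deltas spread around +0.1: clear effect and p
        base = np.full(10, 0.4)
        deltas = np.array([0.08, 0.09, 0.095, 0.10, 0.10, 0.105, 0.11, 0.12, np.nan, np.nan])
        a = base.copy()
        b = base + deltas
        wins = ds.window_scan(prof(a), prof(b))
        (w,) = wins
        ok = ~np.isnan(deltas)
        t_oracle = stats.ttest_rel(b[ok], a[ok])
        assert w.klass == ds.LESS_STRUCTURAL
        assert w.mean_delta == pytest.approx(np.nanmean(deltas))
        assert w.p_value == pytest.approx(t_oracle.pvalue)
        assert w.n_valid == 8

    def test_window_below_validity_count_omitted(self):
        a = np.full(10, 0.4)
        a[:3] = np.nan  # 7 of 10 jointly valid < 8
        assert ds.window_scan(prof(a), prof(np.full(10, 0.5))) == []

    def test_trailing_partial_window_dropped(self):
        wins = ds.window_scan(prof(np.full(27, 0.4)), prof(np.full(27, 0.4)))
        assert [w.end for w in wins] == [10, 20]

    def test_zero_variance_nonzero_mean_is_significant(self):
        a = np.full(10, 0.3)
        b = np.full(10, 0.5)
        (w,) = ds.window_scan(prof(a), prof(b))
        assert (w.p_value, w.klass) == (0.0, ds.LESS_STRUCTURAL)

    def test_stage_swap_mirrors_labels(self, small_stage_pair):
        ra, rb = small_stage_pair
        flip = {ds.LESS_STRUCTURAL: ds.MORE_STRUCTURAL,
                ds.MORE_STRUCTURAL: ds.LESS_STRUCTURAL, ds.STABLE: ds.STABLE}
        for tid in list(ra)[:10]:
            fwd = ds.window_scan(ra[tid], rb[tid])
            rev = ds.window_scan(rb[tid], ra[tid])
            assert [w.klass for w in rev] == [flip[w.klass] for w in fwd]
            np.testing.assert_allclose(
                [w.mean_delta for w in rev], [-w.mean_delta for w in fwd], atol=1e-12
            )


def brute_force_merge(intervals):
    """O(n^2) fixed-point interval merging oracle."""
    ivals = [list(i) for i in intervals]
    changed = True
    while changed:
        changed = False
        out = []
        for s, e in ivals:
            for o in out:
                if s <= o[1] and o[0] <= e:  # overlap or book-ended
                    o[0], o[1] = min(o[0], s), max(o[1], e)
                    changed = True
                    break
            else:
                out.append([s, e])
        ivals = out
    return sorted(tuple(i) for i in ivals)


class TestBuildRegions:
    LEN = {"t": 60}

    def _win(self, start, end, klass=ds.LESS_STRUCTURAL, tid="t"):
        return ds.StructWindow(tid, start, end, 0.1, 0.01, klass, 10)

    def test_merge_and_rebin_example(self):
        regions = ds.build_regions([self._win(10, 20), self._win(25, 35)], self.LEN)
        assert [(r.start, r.end) for r in regions] == [(0, 30), (30, 45)]

    def test_single_window_extends_to_one_bin(self):
        regions = ds.build_regions([self._win(30, 40)], {"t": 100})
        assert [(r.start, r.end) for r in regions] == [(20, 50)]

    def test_opposite_classes_never_merge(self):
        regions = ds.build_regions(
            [self._win(10, 20, ds.MORE_STRUCTURAL), self._win(15, 25, ds.LESS_STRUCTURAL)],
            {"t": 100},
        )
        assert len(regions) == 2
        assert {r.klass for r in regions} == {ds.MORE_STRUCTURAL, ds.LESS_STRUCTURAL}

    def test_stable_windows_ignored(self):
        assert ds.build_regions([self._win(10, 20, ds.STABLE)], self.LEN) == []

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 40), min_size=1, max_size=15))
    def test_matches_bruteforce_interval_merging(self, starts):
        wins = [self._win(s * 10, s * 10 + 10, tid="t") for s in starts]
        length = {"t": 500}
        regions = ds.build_regions(wins, length)
        merged = brute_force_merge(
            [(max(0, w.start - 10), min(500, w.end + 10)) for w in wins]
        )
        want = []
        for s, e in merged:
            for b in range(s, e, 30):
                want.append((b, min(b + 30, e)))
        assert sorted((r.start, r.end) for r in regions) == sorted(want)
        assert all(r.end - r.start <= 30 for r in regions)


class TestHotRegions:
    def _reg(self, start, end, tid="t", klass=ds.LESS_STRUCTURAL):
        return ds.VariableRegion(tid, start, end, klass)

    def test_identical_region_in_two_comparisons(self):
        hot = ds.hot_regions({"c1": [self._reg(0, 30)], "c2": [self._reg(0, 30)]})
        (r,) = hot
        assert (r.start, r.end, r.n_way) == (0, 30, 2)
        assert r.comparisons == frozenset({"c1", "c2"})

    def test_disjoint_regions_stay_one_way(self):
        hot = ds.hot_regions({"c1": [self._reg(0, 30)], "c2": [self._reg(40, 70)]})
        assert sorted(r.n_way for r in hot) == [1, 1]

    def test_chained_cluster_footprint(self):
        hot = ds.hot_regions(
            {"c1": [self._reg(0, 30)], "c2": [self._reg(25, 55)], "c3": [self._reg(50, 80)]}
        )
        (r,) = hot
        assert (r.start, r.end, r.n_way) == (0, 80, 3)

    def test_connected_components_oracle_on_random_sets(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(30):
            regions = {
                f"c{k}": [
                    self._reg(int(s), int(s) + 30)
                    for s in rng.integers(0, 300, size=rng.integers(1, 6))
                ]
                for k in range(3)
            }
            hot = ds.hot_regions(regions)
            g = nx.Graph()
            flat = [(c, r) for c, rs in regions.items() for r in rs]
            g.add_nodes_from(range(len(flat)))
            for i, (ci, ri) in enumerate(flat):
                for j, (cj, rj) in enumerate(flat):
                    if i < j and ri.start < rj.end and rj.start < ri.end:
                        g.add_edge(i, j)
            comps = [
                (
                    min(flat[i][1].start for i in comp),
                    max(flat[i][1].end for i in comp),
                    len({flat[i][0] for i in comp}),
                )
                for comp in nx.connected_components(g)
            ]
            assert sorted((r.start, r.end, r.n_way) for r in hot) == sorted(comps)

    def test_book_ended_regions_do_not_share(self):
        hot = ds.hot_regions({"c1": [self._reg(0, 30)], "c2": [self._reg(30, 60)]})
        assert sorted(r.n_way for r in hot) == [1, 1]


class TestAssignSegment:
    TX = TranscriptModel("t", 1860, 150, 1400)

    def test_fully_inside_cds(self):
        assert ds.assign_segment(RegionRecord("t", 500, 530), self.TX) == "CDS"

    def test_majority_fraction_rule(self):
        # 16 nt in 3UTR, 14 in CDS -> 3UTR (16/30 >= 0.51)
        assert ds.assign_segment(RegionRecord("t", 1386, 1416), self.TX) == "3UTR"

    def test_even_split_unassigned(self):
        assert ds.assign_segment(RegionRecord("t", 1385, 1415), self.TX) == ds.UNASSIGNED

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            ds.assign_segment(RegionRecord("t", 1850, 1870), self.TX)


class TestSegmentEnrichment:
    def test_null_ratios_are_one(self):
        enr = ds.segment_enrichment({"5UTR": 150, "CDS": 1250, "3UTR": 460})
        assert [e.ratio for e in enr] == pytest.approx([1.0, 1.0, 1.0])

    def test_pure_3utr_ratio(self):
        enr = {e.segment: e for e in ds.segment_enrichment({"5UTR": 0, "CDS": 0, "3UTR": 200})}
        assert enr["3UTR"].ratio == pytest.approx(1860 / 460)

    def test_uniform_placement_mean_ratio_one(self):
        rng = np.random.default_rng(2)
        p = np.array([150, 1250, 460]) / 1860
        ratios = []
        for _ in range(300):
            obs = rng.multinomial(400, p)
            enr = ds.segment_enrichment(dict(zip(ds.SEGMENTS, obs.tolist())))
            ratios.append([e.ratio for e in enr])
        np.testing.assert_allclose(np.mean(ratios, axis=0), 1.0, atol=0.05)

    def test_fisher_never_anticonservative_under_null(self):
        # the observed-vs-rounded-expected table prices in two rows of
        # sampling noise while only one row is random, so P(p < t) <= t
        rng = np.random.default_rng(4)
        p = np.array([150, 1250, 460]) / 1860
        pvals = []
        for _ in range(300):
            obs = rng.multinomial(400, p)
            pvals.extend(e.fisher_p for e in ds.segment_enrichment(dict(zip(ds.SEGMENTS, obs.tolist()))))
        pvals = np.array(pvals)
        for t in (0.01, 0.05, 0.1):
            assert (pvals < t).mean() <= t + 0.01

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            ds.segment_enrichment({"5UTR": 0, "CDS": 0, "3UTR": 0})
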
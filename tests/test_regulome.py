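"""Binding sites, metaprofiles, site structural groups, and the decay linkage."""

import math

import numpy as np
import pytest
from scipy import stats

from structvar import regulome as rg
from structvar.io_formats import RegionRecord, TranscriptModel, ValidationError, consensus_motif
from structvar.reactivity import ReactivityProfile


def tx(tid="t", length=1000, utr5=100, cds=700, seq=None):
    return TranscriptModel(tid, length, utr5, cds, sequence=seq)


def prof(values, tid="t", stage=""):
    return ReactivityProfile(tid, np.asarray(values, dtype=float), stage=stage)


class TestTruncationToSites:
    def test_flank_extension(self):
        sites = rg.truncation_to_sites(
            [RegionRecord("t", 800, 801)], {"t": tx()}, flank=20
        )
        (s,) = sites
        assert (s.start, s.center, s.end) == (780, 800, 821)
        assert s.segment == "3UTR"

    def test_boundary_clipping(self):
        sites = rg.truncation_to_sites(
            [RegionRecord("t", 5, 6)], {"t": tx()}, flank=20, restrict_3utr=False
        )
        assert (sites[0].start, sites[0].end) == (0, 26)

    def test_cds_truncation_dropped_when_restricted(self):
        assert rg.truncation_to_sites([RegionRecord("t", 300, 301)], {"t": tx()}) == []


class TestMetaprofile:
    def test_flat_reactivity_gives_flat_profile(self):
        profiles = {"t": prof(np.full(1000, 0.5))}
        site = rg.BindingSite("t", 500, 480, 521)
        mp = rg.metaprofile(profiles, [site], flank=20)
        assert mp.offsets.tolist() == list(range(-20, 21))
        np.testing.assert_allclose(mp.mean_reactivity, 0.5)
        assert (mp.n_valid == 1).all()

    def test_mean_over_two_sites(self):
        vals = np.full(1000, np.nan)
        vals[500] = 0.2
        vals[700] = 0.8
        profiles = {"t": prof(vals)}
        sites = [rg.BindingSite("t", 500, 480, 521), rg.BindingSite("t", 700, 680, 721)]
        mp = rg.metaprofile(profiles, sites, flank=20)
        mid = 20
        assert mp.mean_reactivity[mid] == pytest.approx(0.5)
        assert mp.n_valid[mid] == 2

    def test_validity_filter_excludes_sparse_sites(self):
        vals = np.full(1000, np.nan)
        vals[500] = 0.9  # 1/41 valid
        profiles = {"t": prof(vals)}
        site = rg.BindingSite("t", 500, 480, 521)
        with pytest.raises(ValidationError):
            rg.metaprofile(profiles, [site], flank=20, min_valid_frac=0.6)


class TestUnboundControls:
    def test_other_occurrence_becomes_control(self):
        motif = consensus_motif("m", "UUUGUUU", conc=1.0)
        motif.pseudo = 0.0
        seq = list("ACGU" * 250)
        seq[100:107] = "UUUGUUU"
        seq[800:807] = "UUUGUUU"
        t = tx(seq="".join(seq))
        bound = [rg.BindingSite("t", 103, 83, 124)]
        controls = rg.unbound_controls(motif, {"t": t}, bound)
        assert [c.center for c in controls] == [803]

    def test_all_occurrences_bound_gives_empty(self):
        motif = consensus_motif("m", "UUUGUUU", conc=1.0)
        motif.pseudo = 0.0
        seq = list("ACGU" * 250)
        seq[100:107] = "UUUGUUU"
        t = tx(seq="".join(seq))
        assert rg.unbound_controls(motif, {"t": t}, [rg.BindingSite("t", 103, 83, 124)]) == []

    def test_control_purity_over_random_cases(self):
        rng = np.random.default_rng(3)
        motif = consensus_motif("m", "UGUGU", conc=1.0)
        motif.pseudo = 0.0
        for _ in range(50):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=600))
            t = tx(length=600, utr5=50, cds=300, seq=seq)
            centers = rng.integers(0, 600, size=3)
            bound = [
                rg.BindingSite("t", int(c), max(0, int(c) - 20), min(600, int(c) + 21))
                for c in centers
            ]
            for c in rg.unbound_controls(motif, {"t": t}, bound):
                h_start, h_end = c.center - 2, c.center + 3
                for b in bound:
                    assert h_end <= b.start or h_start >= b.end


class TestClassifySiteStructure:
    def _profiles(self, a_vals, b_vals):
        pa = {"t": prof(a_vals)}
        pb = {"t": prof(b_vals)}
        return pa, pb

    def test_no_change_all_unchanged(self):
        vals = np.linspace(0, 1, 50)
        pa, pb = self._profiles(vals, vals)
        site = rg.BindingSite("t", 25, 10, 40)
        (g,) = rg.classify_site_structure(pa, pb, [site])
        assert g.group == rg.UNCHANGED

    def test_paired_ttest_oracle_on_four_bases(self):
        a = np.full(50, np.nan)
        b = np.full(50, np.nan)
        a[10:14] = [0.8, 0.7, 0.9, 0.8]
        b[10:14] = [0.2, 0.1, 0.3, 0.25]
        pa, pb = self._profiles(a, b)
        (g,) = rg.classify_site_structure(pa, pb, [rg.BindingSite("t", 12, 10, 14)])
        deltas = b[10:14] - a[10:14]
        t_stat = deltas.mean() / (deltas.std(ddof=1) / math.sqrt(4))
        p_oracle = 2 * stats.t.sf(abs(t_stat), 3)
        assert g.group == rg.GROUP_I
        assert g.mean_react_b - g.mean_react_a == pytest.approx(-0.5875)
        assert g.p_value == pytest.approx(p_oracle)

    def test_mirrored_values_give_group_two(self):
        a = np.full(50, np.nan)
        b = np.full(50, np.nan)
        a[10:14] = [0.2, 0.1, 0.3, 0.25]
        b[10:14] = [0.8, 0.7, 0.9, 0.8]
        pa, pb = self._profiles(a, b)
        (g,) = rg.classify_site_structure(pa, pb, [rg.BindingSite("t", 12, 10, 14)])
        assert g.group == rg.GROUP_II

    def test_too_few_valid_bases_flagged_unchanged(self):
        a = np.full(50, np.nan)
        a[10:12] = 0.5
        pa, pb = self._profiles(a, a)
        (g,) = rg.classify_site_structure(pa, pb, [rg.BindingSite("t", 12, 10, 40)])
        assert g.group == rg.UNCHANGED and g.n_valid == 2

    def test_stage_swap_exchanges_groups(self, small_truth, small_stage_pair):
        ra, rb = small_stage_pair
        sites = small_truth.bound_binding_sites()
        fwd = rg.classify_site_structure(ra, rb, sites)
        rev = rg.classify_site_structure(rb, ra, sites)
        swap = {rg.GROUP_I: rg.GROUP_II, rg.GROUP_II: rg.GROUP_I, rg.UNCHANGED: rg.UNCHANGED}
        assert [g.group for g in rev] == [swap[g.group] for g in fwd]


class TestRpkm:
    def test_unit_definition(self):
        out = rg.rpkm({"g": 10}, {"g": 1000}, library_size=1_000_000)
        assert out["g"] == pytest.approx(10.0)

    def test_zero_count(self):
        assert rg.rpkm({"g": 0}, {"g": 500}, library_size=10_000)["g"] == 0.0

    def test_replicate_averaging(self):
        reps = [{"g": 4}, {"g": 6}]
        out = rg.rpkm(reps, {"g": 1000}, library_size=[1_000_000, 1_000_000])
        assert out["g"] == pytest.approx(5.0)


class TestDeTest:
    def test_equal_proportions_give_zero_fc(self):
        res = rg.de_test({"g": 50, "h": 10}, {"g": 50, "h": 10})
        assert res["g"][0] == pytest.approx(0.0, abs=1e-6)

    def test_one_sided_extreme_closed_form(self):
        res = rg.de_test({"g": 100}, {"g": 0}, lib_a=1000, lib_b=1000)
        assert res["g"][1] == pytest.approx(2 * 0.5**100, rel=1e-9)

    def test_bh_adjustment_over_genes(self):
        # construct counts whose binomial p-values differ, then check BH ordering
        res = rg.de_test({"a": 80, "b": 60, "c": 50}, {"a": 20, "b": 40, "c": 50},
                         lib_a=1000, lib_b=1000)
        ps = np.array([res[g][1] for g in ("a", "b", "c")])
        fdrs = np.array([res[g][2] for g in ("a", "b", "c")])
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(fdrs, multipletests(ps, method="fdr_bh")[1])


class TestClassifyGenes:
    def _rec(self, rpkm2, rpkm6, log2fc, fdr):
        return rg.GeneRecord("g", {"2hpf": rpkm2, "6hpf": rpkm6}, log2fc=log2fc, de_fdr=fdr)

    @pytest.mark.parametrize(
        "rpkm2, rpkm6, log2fc, fdr, expect",
        [
            (5.0, 2.0, 1.0, 0.01, rg.MATERNAL_DECAY),
            (5.0, 5.0, 0.1, 0.01, rg.MATERNAL_STABLE),
            (0.5, 3.0, -2.0, 0.5, rg.ZYGOTIC),
            (5.0, 4.0, 0.1, 0.5, rg.UNCLASSIFIED),  # not significant
            (0.5, 0.5, 0.0, 0.9, rg.UNCLASSIFIED),
        ],
    )
    def test_rule_application(self, rpkm2, rpkm6, log2fc, fdr, expect):
        (rec,) = rg.classify_genes([self._rec(rpkm2, rpkm6, log2fc, fdr)], "2hpf", "6hpf")
        assert rec.klass == expect

    def test_literal_stable_rule_admits_upregulated_unless_symmetric(self):
        rec = self._rec(5.0, 40.0, -3.0, 0.001)  # strongly up-regulated
        (lit,) = rg.classify_genes([rec], "2hpf", "6hpf")
        (sym,) = rg.classify_genes([rec], "2hpf", "6hpf", symmetric_stable=True)
        assert lit.klass == rg.MATERNAL_STABLE
        assert sym.klass == rg.UNCLASSIFIED

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(1)
        recs = [
            rg.GeneRecord(
                f"g{i}",
                {"2hpf": float(rng.uniform(0, 10)), "6hpf": float(rng.uniform(0, 10))},
                log2fc=float(rng.normal(0, 1)),
                de_fdr=float(rng.uniform(0, 1)),
            )
            for i in range(200)
        ]
        out = rg.classify_genes(recs, "2hpf", "6hpf")
        counts = {k: sum(r.klass == k for r in out) for k in rg.GENE_CLASSES}
        assert sum(counts.values()) == 200


class TestStabilityAssociation:
    def _groups(self, n_i, n_ii):
        sites = []
        for i in range(n_i + n_ii):
            grp = rg.GROUP_I if i < n_i else rg.GROUP_II
            site = rg.BindingSite(f"t{i}", 10, 0, 21)
            sites.append(rg.SiteStructGroup(f"t{i}", site, 0.5, 0.4, 0.01, grp))
        return sites

    def _genes(self, fcs, klasses=None):
        recs = {}
        for i, fc in enumerate(fcs):
            klass = klasses[i] if klasses else rg.MATERNAL_DECAY
            recs[f"g{i}"] = rg.GeneRecord(f"g{i}", {}, log2fc=fc, klass=klass)
        return recs

    def test_identical_distributions_give_p_one(self):
        groups = self._groups(5, 5)
        genes = self._genes([1.0] * 10)
        tx_gene = {f"t{i}": f"g{i}" for i in range(10)}
        assoc = rg.stability_association(groups, genes, tx_gene)
        assert assoc.ranksum_p == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        groups = self._groups(20, 20)
        # group I decays (log2fc early/late = +2), group II stable (0)
        genes = self._genes([2.0] * 20 + [0.0] * 20)
        tx_gene = {f"t{i}": f"g{i}" for i in range(40)}
        assoc = rg.stability_association(groups, genes, tx_gene)
        oracle = stats.mannwhitneyu(
            assoc.log2fc_by_group[rg.GROUP_I], assoc.log2fc_by_group[rg.GROUP_II],
            alternative="two-sided", method="exact",
        )
        assert assoc.ranksum_p < 1e-6
        assert oracle.pvalue < 1e-6
        # decay shows as negative RNA-level change for group I
        assert assoc.log2fc_by_group[rg.GROUP_I].mean() < assoc.log2fc_by_group[rg.GROUP_II].mean()

    def test_class_fractions(self):
        groups = self._groups(4, 2)
        klasses = [rg.MATERNAL_DECAY] * 3 + [rg.MATERNAL_STABLE] + [rg.MATERNAL_STABLE] * 2
        genes = self._genes([1.0, 2.0, 3.0, 0.0, 0.1, -0.1], klasses)
        tx_gene = {f"t{i}": f"g{i}" for i in range(6)}
        assoc = rg.stability_association(groups, genes, tx_gene)
        assert assoc.class_fractions[rg.GROUP_I][rg.MATERNAL_DECAY] == pytest.approx(0.75)
        assert assoc.class_fractions[rg.GROUP_II][rg.MATERNAL_STABLE] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        groups = self._groups(1, 5)
        genes = self._genes([1.0] * 6)
        tx_gene = {f"t{i}": f"g{i}" for i in range(6)}
        with pytest.raises(ValidationError):
            rg.stability_association(groups, genes, tx_gene)


class TestRbpSiteCompare:
    def test_sixty_percent_validity_filter(self):
        vals = np.full(100, np.nan)
        vals[:50] = 0.5  # site [0,100) is exactly 50% valid -> filtered
        vals2 = np.full(100, 0.8)
        profiles = {"a": prof(vals, "a"), "b": prof(vals2, "b")}
        sites = [rg.BindingSite("a", 50, 0, 100)]
        shuffled = [rg.BindingSite("b", 50, 0, 100)]
        with pytest.raises(ValidationError):
            rg.rbp_site_reactivity_compare(sites, shuffled, profiles)

    def test_planted_accessible_sites_detected(self):
        rng = np.random.default_rng(6)
        profiles = {}
        sites, shuffled = [], []
        for i in range(40):
            v = np.clip(rng.normal(0.8, 0.05, 41), 0, 1)
            profiles[f"s{i}"] = prof(v, f"s{i}")
            sites.append(rg.BindingSite(f"s{i}", 20, 0, 41))
            w = np.clip(rng.normal(0.3, 0.05, 41), 0, 1)
            profiles[f"b{i}"] = prof(w, f"b{i}")
            shuffled.append(rg.BindingSite(f"b{i}", 20, 0, 41))
        summary, p = rg.rbp_site_reactivity_compare(sites, shuffled, profiles)
        assert summary["sites"]["mean"] > summary["shuffled"]["mean"] + 0.4
        assert p < 1e-6
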
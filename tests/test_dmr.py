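"""Empirical-null significance, site/DMR construction and the replicate
intersection and average analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import medipchip as mc
from medipchip.dmr import pairwise_shared_site_counts

from conftest import toy_signal


def _sites_for(m_values, **kw):
    sig = toy_signal(m_values, **kw)
    null = mc.NullModel(0.0, 1.0, len(m_values))
    sigs = mc.probe_significance(sig, null)
    return mc.call_sites(sigs, sig), sig


class TestFitNull:
    def test_hand_computed_mean_and_sample_sd(self):
        sig = toy_signal([-1.0, 0.0, 1.0])
        null = mc.fit_null(sig)
        assert null.mu == pytest.approx(0.0)
        assert null.sigma == pytest.approx(1.0)   # sample SD, ddof=1
        assert null.n == 3

    def test_degenerate_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mc.fit_null(toy_signal([0.3, 0.3, 0.3]))

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 50)
        a = mc.fit_null(toy_signal(vals))
        b = mc.fit_null(toy_signal(vals[::-1]))
        assert a.mu == pytest.approx(b.mu) and a.sigma == pytest.approx(b.sigma)

    def test_undefined_values_excluded(self):
        vals = [0.0, 1.0, np.nan, -1.0]
        null = mc.fit_null(toy_signal(vals))
        assert null.n == 3


class TestProbeSignificance:
    def test_center_gives_p_one(self):
        sig = toy_signal([5.0, 5.0, 6.0])
        out = mc.probe_significance(sig, mc.NullModel(5.0, 1.0, 3))
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["z"].iloc[0] == pytest.approx(0.0)

    def test_z_3_8906_sits_at_the_1e4_cutoff(self):
        # 2 * (1 - Phi(3.8906)) ~= 1.0e-4: the z that the p<1e-4 rule implies
        sig = toy_signal([3.8906])
        out = mc.probe_significance(sig, mc.NullModel(0.0, 1.0, 100))
        assert out["p"].iloc[0] == pytest.approx(1.0e-4, rel=5e-3)

    @given(st.floats(-6, 6))
    def test_two_sided_symmetry(self, z):
        sig = toy_signal([z, -z])
        out = mc.probe_significance(sig, mc.NullModel(0.0, 1.0, 10))
        assert out["p"].iloc[0] == pytest.approx(out["p"].iloc[1])

    def test_undefined_probes_omitted(self):
        sig = toy_signal([0.0, np.nan, 1.0])
        out = mc.probe_significance(sig, mc.NullModel(0.0, 1.0, 10))
        assert len(out) == 2


class TestCallSites:
    def test_no_significant_probes_empty(self):
        sites, _ = _sites_for([0.0, 0.5, -0.5, 1.0])
        assert sites == []

    def test_single_significant_probe_600bp_site(self):
        sites, _ = _sites_for([0.0, 6.0, 0.0])
        assert len(sites) == 1
        assert sites[0].length == 600
        assert sites[0].probe_ids == ["P0_001"]

    def test_two_adjacent_significant_probes_700bp_site(self):
        # interval union of midpoint+/-300 windows 100 bp apart
        sites, _ = _sites_for([0.0, 6.0, 6.5, 0.0])
        assert len(sites) == 1
        assert sites[0].length == 700

    def test_nonadjacent_significant_probes_two_sites(self):
        sites, _ = _sites_for([6.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 6.0])
        assert len(sites) == 2

    def test_strict_inequality_at_cutoff(self):
        sig = toy_signal([0.0, 3.89, 0.0])
        sigs = pd.DataFrame({"z": [0.0, 3.89, 0.0], "p": [1.0, 1e-4, 1.0]},
                            index=sig.data.index)
        assert mc.call_sites(sigs, sig, p_cutoff=1e-4) == []  # p < cutoff is strict
        assert len(mc.call_sites(sigs, sig, p_cutoff=1.0001e-4)) == 1

    def test_direction_recorded(self):
        sites, _ = _sites_for([0.0, -6.0, 0.0])
        assert sites[0].direction == -1


class TestMergeSites:
    def test_two_sites_one_promoter_merge(self):
        sites, _ = _sites_for([6.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 6.0])
        calls = mc.merge_sites_to_dmrs(sites)
        assert len(calls) == 1
        assert len(calls[0].sites) == 2
        assert calls[0].region_size == calls[0].end - calls[0].start

    def test_sites_in_different_promoters_never_merge(self):
        s1, _ = _sites_for([0.0, 6.0, 0.0], promoter="PA")
        s2, _ = _sites_for([0.0, 6.0, 0.0], promoter="PB")
        calls = mc.merge_sites_to_dmrs(s1 + s2)
        assert len(calls) == 2

    def test_dmr_p_is_min_member_p(self):
        sites, _ = _sites_for([6.0, 7.0, 0.0, 0.0, 0.0, 0.0, 0.0, 5.0])
        calls = mc.merge_sites_to_dmrs(sites)
        assert calls[0].p_value == pytest.approx(min(s.min_p for s in sites))


class TestIntersectionAnalysis:
    def _site_set(self, promoters):
        sites = []
        for p in promoters:
            s, _ = _sites_for([0.0, 6.0, 0.0], promoter=p)
            sites += s
        return sites

    def test_three_identical_sets_idempotent(self):
        sets = {f"C{i}": self._site_set(["PA", "PB"]) for i in range(3)}
        calls, _ = mc.intersection_analysis(sets)
        assert sorted(c.promoter_id for c in calls) == ["PA", "PB"]

    def test_disjoint_pair_empty(self):
        sets = {"C1": self._site_set(["PA"]), "C2": self._site_set(["PB"]),
                "C3": self._site_set(["PA"])}
        calls, _ = mc.intersection_analysis(sets)
        assert calls == []

    def test_common_promoter_survives(self):
        # {A,B}, {A,C}, {A,D} over distinct promoters -> {A}
        sets = {"C1": self._site_set(["PA", "PB"]),
                "C2": self._site_set(["PA", "PC"]),
                "C3": self._site_set(["PA", "PD"])}
        calls, shared = mc.intersection_analysis(sets)
        assert [c.promoter_id for c in calls] == ["PA"]
        assert shared == {"C1-C2": 1, "C1-C3": 1, "C2-C3": 1}

    def test_fewer_than_two_comparisons_rejected(self):
        with pytest.raises(ValueError):
            mc.intersection_analysis({"C1": self._site_set(["PA"])})

    def test_pairwise_counts_count_overlapping_site_pairs(self):
        a, _ = _sites_for([6.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 6.0])
        b, _ = _sites_for([6.0, 6.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        counts = pairwise_shared_site_counts({"X": a, "Y": b})
        assert counts == {"X-Y": 1}


class TestAverageAnalysis:
    def test_identical_signals_match_single_comparison(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.1, 60)
        vals[30] = 2.0
        sig = toy_signal(vals)
        single = mc.single_comparison_dmrs(sig)
        averaged = mc.average_analysis([toy_signal(vals, analysis_id=f"C{i}")
                                        for i in range(3)])
        assert [(c.start, c.end) for c in averaged] == \
               [(c.start, c.end) for c in single]

    def test_inconsistent_signal_diluted_below_cutoff(self):
        # a spike present in one of three comparisons keeps only a third of
        # its z after averaging (m, 0, 0 -> m/3) and drops under the cutoff
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1.0, 100)
        spike = base.copy()
        spike[50] = 6.0
        signals = [toy_signal(spike, analysis_id="C1"),
                   toy_signal(base, analysis_id="C2"),
                   toy_signal(base, analysis_id="C3")]
        # in C1 alone the spike is called ...
        assert len(mc.single_comparison_dmrs(toy_signal(spike))) == 1
        # ... but the averaged z falls well under the cutoff
        calls = mc.average_analysis(signals)
        assert calls == []

    def test_probe_defined_only_if_defined_everywhere(self):
        a = toy_signal([0.0, 1.0, 2.0])
        b = toy_signal([0.0, np.nan, 2.0])
        avg = mc.average_signal([a, b])
        assert avg.data["m_smoothed"].isna().tolist() == [False, True, False]


@pytest.fixture(scope="module")
def planted_run():
    cfg = mc.SimConfig(n_promoters=80, dmr_fraction=0.1, effect_size=1.0, seed=17)
    design = mc.generate_design(cfg)
    arrays, manifest = mc.generate_medip_experiment(design, cfg)
    res = mc.run_medip_pipeline(arrays, design, mode="intersection")
    return res, manifest


class TestStructuralProperties:
    def test_intersection_subset_of_each_single_comparison(self, planted_run):
        res, _ = planted_run
        inter = {c.promoter_id for c in res.calls}
        for cid, calls in res.per_comparison_dmrs.items():
            assert inter <= {c.promoter_id for c in calls}

    def test_every_call_at_least_600bp(self, planted_run):
        res, _ = planted_run
        assert all(c.region_size >= 600 for c in res.calls)
        for sites in res.per_comparison_sites.values():
            assert all(s.length >= 600 for s in sites)

    def test_lowering_cutoff_never_adds_calls(self, planted_run):
        res, _ = planted_run
        sig = next(iter(res.per_comparison_signals.values()))
        loose = {c.promoter_id for c in mc.single_comparison_dmrs(sig, 1e-4)}
        strict = {c.promoter_id for c in mc.single_comparison_dmrs(sig, 1e-6)}
        assert strict <= loose

    def test_overlap_dmr_sets_symmetry(self, planted_run):
        res, _ = planted_run
        a = res.calls
        b = res.per_comparison_dmrs["C1"]
        assert mc.overlap_dmr_sets(a, b) == mc.overlap_dmr_sets(b, a)
        assert mc.overlap_dmr_sets(a, []) == []
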
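"""Enzyme specificity models: registry, methylation accounting, thresholds."""

from itertools import product

import pytest
from hypothesis import given

from mdresim.enzymes import (
    TIER_ORDER,
    MethylationConfig,
    builtin_enzymes,
    builtin_registry_text,
    evaluate_site,
    get_enzyme,
    load_registry,
    min_m5c_for_cleavage,
    relevant_c_positions,
)
from mdresim.seqmodel import MethylatedDuplex, ModType, reverse_complement

from conftest import duplexes

GCNGC_ENZYMES = [e for e in builtin_enzymes()
                 if e.counting == "canonical" and not e.methylation_independent]


def site_with(config):
    """A GCAGC site carrying a chosen subset of its 4 canonical m5C.

    ``config`` is a 4-bit tuple over (top 1, top 4, bottom 0, bottom 3).
    """
    t1, t4, b0, b3 = config
    top = {i: ModType.M5C for i, on in ((1, t1), (4, t4)) if on}
    bottom = {i: ModType.M5C for i, on in ((0, b0), (3, b3)) if on}
    return MethylatedDuplex("GCAGC", top_mods=top, bottom_mods=bottom)


ALL_CONFIGS = list(product([0, 1], repeat=4))


class TestRegistry:
    def test_expected_membership_and_groups(self):
        by_name = {e.name: e for e in builtin_enzymes()}
        group_i = {"BisI", "Bce95I", "BceYI", "Rfl17I", "Vsp586I", "KasKI", "CbuDI",
                   "Pps170I", "VspHI", "MspAK21I", "AspTB23I", "LsaM18I"}
        group_ii = {"NhoI", "Eco15I", "Sde240I", "Pan13I", "Pru4541I", "AlaI",
                    "Sve396I", "Dsp20IU", "SmaAUI", "MbaR4I"}
        assert group_i == {e.name for e in builtin_enzymes() if e.group == "I"}
        assert group_ii == {e.name for e in builtin_enzymes() if e.group == "II"}
        assert by_name["SqiI"].group == "all4"
        assert by_name["Esp638I"].group == "esp638"
        assert {e.name for e in builtin_enzymes() if e.methylation_independent} == \
            {"Bce1273I", "Bth171I"}

    def test_cut_geometries(self):
        bisi = get_enzyme("BisI")
        assert (bisi.geometry.top_offset, bisi.geometry.bottom_offset) == (2, 2)
        assert bisi.overhang == 1  # 1-nt 5' extension
        esp = get_enzyme("Esp638I")
        assert esp.recognition == "RCNNGY"
        assert esp.overhang == 0  # blunt
        assert get_enzyme("Bce1273I").recognition == "RGNCY"
        assert get_enzyme("Bth171I").recognition == "RSNSY"

    def test_star_specs(self):
        nhoi = get_enzyme("NhoI")
        assert [s.recognition for s in nhoi.star_specs] == ["RCNGC"]
        assert not nhoi.star_specs[0].methylation_independent
        sve = get_enzyme("Sve396I")
        assert [s.recognition for s in sve.star_specs] == ["GCGAC"]
        assert sve.star_specs[0].methylation_independent

    def test_registry_text_round_trip(self):
        assert load_registry(builtin_registry_text()) == builtin_enzymes()

    def test_unknown_enzyme_lists_known_names(self):
        with pytest.raises(KeyError, match="BisI"):
            get_enzyme("NoSuchEnzyme")


class TestRelevantCPositions:
    def test_four_canonical_positions(self):
        d = MethylatedDuplex("GCAGC")
        assert set(relevant_c_positions(0, "GCNGC", d)) == \
            {("top", 1), ("top", 4), ("bottom", 0), ("bottom", 3)}

    def test_n_position_cytosine_excluded(self):
        d = MethylatedDuplex("GCCGC")
        positions = set(relevant_c_positions(0, "GCNGC", d))
        assert positions == {("top", 1), ("top", 4), ("bottom", 0), ("bottom", 3)}
        assert ("top", 2) not in positions

    def test_window_counting_sees_all_cytosines(self):
        d = MethylatedDuplex("GCGCGC")  # RCNNGY instance, maximal C content
        positions = relevant_c_positions(0, "RCNNGY", d, counting="window")
        assert len(positions) == 6  # C at 1,3,5 on top; C opposite 0,2,4 on bottom
        d2 = MethylatedDuplex("GCGCGT")
        assert len(relevant_c_positions(0, "RCNNGY", d2, counting="window")) == 5

    def test_no_match_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            relevant_c_positions(0, "GCNGC", MethylatedDuplex("AAAAA"))


class TestEvaluateSite:
    def test_bisi_cuts_fully_methylated_site(self):
        act = evaluate_site(site_with((1, 1, 1, 1)), 0, get_enzyme("BisI"))
        assert (act.action, act.tier) == ("CUT", "full")

    def test_bisi_ignores_unmodified_site(self):
        act = evaluate_site(MethylatedDuplex("GCTGC"), 0, get_enzyme("BisI"))
        assert act.action == "NONE"

    def test_nhoi_rejects_hemi(self):
        act = evaluate_site(site_with((1, 1, 0, 0)), 0, get_enzyme("NhoI"))
        assert act.action == "NONE"

    def test_sqii_poor_on_three_m5c(self):
        act = evaluate_site(site_with((1, 1, 0, 1)), 0, get_enzyme("SqiI"))
        assert (act.action, act.tier) == ("CUT", "poor")

    def test_nhoi_nick_intermediate_on_two_mod_strand(self):
        act = evaluate_site(site_with((1, 1, 0, 1)), 0, get_enzyme("NhoI"))
        assert (act.action, act.tier, act.nick_intermediate) == ("CUT", "full", "top")
        act2 = evaluate_site(site_with((1, 0, 1, 1)), 0, get_enzyme("NhoI"))
        assert act2.nick_intermediate == "bottom"

    def test_vsp586i_hemi_moderate_with_nick(self):
        act = evaluate_site(site_with((1, 1, 0, 0)), 0, get_enzyme("Vsp586I"))
        assert (act.action, act.tier, act.nick_intermediate) == ("CUT", "moderate", "top")

    def test_independent_enzyme_cuts_unmodified(self):
        d = MethylatedDuplex("GCTGC")  # an RSNSY instance
        act = evaluate_site(d, 0, get_enzyme("Bth171I"))
        assert (act.action, act.tier) == ("CUT", "full")

    def test_esp638i_threshold_at_four(self):
        d = MethylatedDuplex("GCGCGT")
        from mdresim.seqmodel import fully_modify
        act = evaluate_site(fully_modify(d), 0, get_enzyme("Esp638I"))
        assert (act.action, act.tier) == ("CUT", "full")
        # three modifications are not enough
        partial = MethylatedDuplex("GCGCGT",
                                   top_mods={1: ModType.M5C, 3: ModType.M5C},
                                   bottom_mods={0: ModType.M5C})
        assert evaluate_site(partial, 0, get_enzyme("Esp638I")).action == "NONE"

    def test_hm5c_capped_at_enzyme_tier(self):
        hm = MethylatedDuplex("GCAGC",
                              top_mods={1: ModType.HM5C, 4: ModType.HM5C},
                              bottom_mods={0: ModType.HM5C, 3: ModType.HM5C})
        assert evaluate_site(hm, 0, get_enzyme("NhoI")).tier == "poor"
        assert evaluate_site(hm, 0, get_enzyme("Bce95I")).tier == "moderate"
        assert evaluate_site(hm, 0, get_enzyme("BisI")).tier == "poor"

    def test_m5c_not_limited_by_hm5c_tier(self):
        assert evaluate_site(site_with((1, 1, 1, 1)), 0, get_enzyme("NhoI")).tier == "full"

    def test_star_site_only_in_star_mode(self):
        d = MethylatedDuplex("ACAGC",
                             top_mods={1: ModType.M5C, 4: ModType.M5C},
                             bottom_mods={3: ModType.M5C})
        with pytest.raises(ValueError, match="no recognition match"):
            evaluate_site(d, 0, get_enzyme("NhoI"), star=False)
        act = evaluate_site(d, 0, get_enzyme("NhoI"), star=True)
        assert act.action == "CUT"

    def test_w_site_bump_is_opt_in(self):
        # GCTGC (W at the degenerate position), three m5C, for an enzyme
        # with the GCWGC preference the tier can only go up with w_bump
        d = MethylatedDuplex("GCTGC",
                             top_mods={1: ModType.M5C, 4: ModType.M5C},
                             bottom_mods={3: ModType.M5C})
        spec = get_enzyme("NhoI")
        base = evaluate_site(d, 0, spec)
        bumped = evaluate_site(d, 0, spec, w_bump=True)
        assert TIER_ORDER[bumped.tier] >= TIER_ORDER[base.tier]


class TestExhaustiveProperties:
    @pytest.mark.parametrize("spec", GCNGC_ENZYMES, ids=lambda e: e.name)
    def test_monotone_in_total_modification(self, spec):
        """Adding an m5C never demotes the action tier (all 16 configs)."""
        tier_of = {}
        for cfg in ALL_CONFIGS:
            act = evaluate_site(site_with(cfg), 0, spec)
            tier_of[cfg] = TIER_ORDER[act.tier]
        for cfg in ALL_CONFIGS:
            for k in range(4):
                if cfg[k] == 0:
                    more = tuple(c | (1 if i == k else 0) for i, c in enumerate(cfg))
                    assert tier_of[more] >= tier_of[cfg], (spec.name, cfg, more)

    @pytest.mark.parametrize("g2", [e for e in GCNGC_ENZYMES if e.group in ("II", "all4")],
                             ids=lambda e: e.name)
    def test_group_ii_cut_set_within_group_i(self, g2):
        """Any site a Group II model cuts, the Group I model cuts too."""
        g1 = get_enzyme("BisI")
        for cfg in ALL_CONFIGS:
            d = site_with(cfg)
            a2 = evaluate_site(d, 0, g2)
            if a2.action == "CUT" and TIER_ORDER[a2.tier] >= TIER_ORDER["moderate"]:
                a1 = evaluate_site(d, 0, g1)
                assert a1.action == "CUT" and TIER_ORDER[a1.tier] >= TIER_ORDER["moderate"]

    @pytest.mark.parametrize("spec", GCNGC_ENZYMES, ids=lambda e: e.name)
    def test_strand_symmetry(self, spec):
        """Evaluation commutes with reverse-complement, nick strands swap."""
        for cfg in ALL_CONFIGS:
            d = site_with(cfg)
            a = evaluate_site(d, 0, spec)
            a_rc = evaluate_site(reverse_complement(d), 0, spec)
            assert (a.action, a.tier) == (a_rc.action, a_rc.tier)
            if a.nick_intermediate and cfg != (1, 1, 1, 1) and \
                    sum(cfg[:2]) != sum(cfg[2:]):
                swap = {"top": "bottom", "bottom": "top"}
                assert a_rc.nick_intermediate == swap[a.nick_intermediate]


class TestMinM5C:
    @pytest.mark.parametrize("name,instance,expected", [
        ("BisI", "GCAGC", 2),
        ("NhoI", "GCAGC", 3),
        ("SqiI", "GCAGC", 4),
        ("Bth171I", "GCTGC", 0),
        ("Esp638I", "GCGCGT", 4),
    ])
    def test_reported_minima(self, name, instance, expected):
        spec = get_enzyme(name)
        assert min_m5c_for_cleavage(spec, MethylatedDuplex(instance)) == expected

    @pytest.mark.parametrize("spec", GCNGC_ENZYMES, ids=lambda e: e.name)
    def test_matches_requirement_table_oracle(self, spec):
        """Brute-force oracle re-derived straight from the requirement table."""
        best = None
        for cfg in ALL_CONFIGS:
            mc = MethylationConfig(sum(cfg[:2]), sum(cfg[2:]))
            entry = spec.requirement[mc.klass]
            if entry.action == "CUT" and TIER_ORDER[entry.tier] >= TIER_ORDER["moderate"]:
                best = mc.n_total if best is None else min(best, mc.n_total)
        assert min_m5c_for_cleavage(spec, MethylatedDuplex("GCAGC")) == best
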
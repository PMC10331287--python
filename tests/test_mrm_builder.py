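"""MRM transition derivation, isomer enumeration, IS matching, co-elution."""

import itertools

import pytest

from oddlipid.chem_core import FattyAcyl, make_species
from oddlipid.mrm_builder import (
    ADDUCTS,
    CoelutionVerdict,
    ISRecord,
    assign_acquisition_params,
    build_transitions,
    isomer_candidates,
    phospholipid_transitions,
    precursor_mz,
    sphingo_ffa_transitions,
    tag_dag_transitions,
    transitions_table,
    validate_by_coelution,
)


def _species(sub, *cd):
    return make_species(sub, [FattyAcyl(c, d) for c, d in cd])


class TestPrecursor:
    def test_ammoniated_tripentadecanoin(self):
        tag = _species("TAG", (15, 0), (15, 0), (15, 0))
        assert precursor_mz(tag, "[M+NH4]+") == pytest.approx(782.7232, abs=1e-4)

    def test_deprotonated_ffa(self):
        ffa = _species("FFA", (17, 0))
        assert precursor_mz(ffa, "[M-H]-") == pytest.approx(269.2486, abs=1e-4)

    def test_incompatible_polarity_rejected(self):
        tag = _species("TAG", (15, 0), (15, 0), (15, 0))
        with pytest.raises(ValueError):
            precursor_mz(tag, "[M-H]-")

    def test_degenerate_neutral_mass_rejected(self):
        with pytest.raises(ValueError):
            ADDUCTS["[M+H]+"].mz(0.0)


class TestTagDagTransitions:
    @pytest.mark.parametrize("carbons,nominal_nl", [(15, 259), (17, 287), (19, 315)])
    def test_tag_neutral_losses_match_printed_values(self, carbons, nominal_nl):
        tag = _species("TAG", (carbons, 0), (carbons, 0), (carbons, 0))
        (t,) = tag_dag_transitions(tag)
        assert round(t.q1 - t.q3) == nominal_nl

    def test_tag_exact_q3(self):
        tag = _species("TAG", (15, 0), (15, 0), (15, 0))
        (t,) = tag_dag_transitions(tag)
        assert t.q1 == pytest.approx(782.7232, abs=1e-4)
        assert t.q3 == pytest.approx(523.4721, abs=1e-3)

    @pytest.mark.parametrize("carbons,nominal_q3", [(15, 299), (17, 327), (19, 355)])
    def test_dag_daughter_ions_match_printed_values(self, carbons, nominal_q3):
        dag = _species("DAG", (carbons, 0), (carbons, 0))
        (t,) = tag_dag_transitions(dag)
        assert round(t.q3) == nominal_q3

    def test_unsaturated_nl_drops_2_da_per_double_bond(self):
        sat = tag_dag_transitions(_species("TAG", (15, 0), (15, 0), (15, 0)))[0]
        mono = tag_dag_transitions(_species("TAG", (15, 1), (15, 0), (15, 0)))
        nl_mono = next(
            t.q1 - t.q3 for t in mono if "15:1" in t.annotation
        )
        assert round((sat.q1 - sat.q3) - nl_mono) == 2

    def test_tag_distinct_acyls_give_up_to_three_channels(self):
        assert len(tag_dag_transitions(_species("TAG", (15, 0), (17, 0), (19, 0)))) == 3
        assert len(tag_dag_transitions(_species("TAG", (15, 0), (15, 0), (17, 0)))) == 2
        assert len(tag_dag_transitions(_species("TAG", (15, 0), (15, 0), (15, 0)))) == 1

    def test_nl_equals_fa_plus_ammonia_oracle(self, small_library):
        """Q1 - Q3 of every TAG channel equals mass(FA) + mass(NH3) to 1e-3."""
        nh3 = 14.0030740052 + 3 * 1.0078250319
        checked = 0
        for s in small_library:
            if s.subclass != "TAG":
                continue
            for t in tag_dag_transitions(s):
                acyl = next(a for a in set(s.acyls) if f"FA{a}" in t.annotation)
                fa_mass = (
                    12.0 * acyl.carbons
                    + 1.0078250319 * (2 * acyl.carbons - 2 * acyl.double_bonds)
                    + 2 * 15.9949146221
                )
                assert t.q1 - t.q3 == pytest.approx(fa_mass + nh3, abs=1e-3)
                checked += 1
        assert checked > 20

    def test_wrong_subclass_rejected(self):
        with pytest.raises(ValueError):
            tag_dag_transitions(_species("PC", (15, 0), (15, 0)))


class TestPhospholipidTransitions:
    def test_pi_17_0_18_1_channels(self):
        pi = _species("PI", (17, 0), (18, 1))
        ts = phospholipid_transitions(pi)
        assert [t.q1 for t in ts] == [pytest.approx(849.5499, abs=1e-4)] * 2
        q3s = sorted(t.q3 for t in ts)
        assert q3s[0] == pytest.approx(269.2486, abs=1e-4)  # 17:0 carboxylate
        assert q3s[1] == pytest.approx(281.2486, abs=1e-4)  # 18:1 carboxylate

    def test_identical_acyls_merge_with_both_sites_annotated(self):
        pa = _species("PA", (15, 0), (15, 0))
        ts = phospholipid_transitions(pa)
        assert len(ts) == 1
        assert "sn-1/sn-2" in ts[0].annotation

    def test_lyso_single_transition(self):
        assert len(phospholipid_transitions(_species("LPE", (17, 0)))) == 1

    def test_pc_uses_acetate_adduct(self):
        pc = _species("PC", (17, 0), (18, 1))
        pe = _species("PE", (17, 0), (18, 1))
        # acetate adds 59.013305 - (-1.007825) = 60.02113 more than [M-H]-
        delta = phospholipid_transitions(pc)[0].q1 - (
            pc.neutral_mass - pe.neutral_mass
            + phospholipid_transitions(pe)[0].q1
        )
        assert delta == pytest.approx(60.021130, abs=1e-4)

    def test_q3_is_free_acid_minus_proton_for_all_diacyls(self, small_library):
        for s in small_library:
            if s.info.family != "phospholipid" or s.info.arity != 2:
                continue
            expected = sorted(
                12.0 * a.carbons
                + 1.0078250319 * (2 * a.carbons - 2 * a.double_bonds)
                + 2 * 15.9949146221
                - 1.0078250319
                + 0.000549
                for a in set(s.acyls)
            )
            got = sorted(t.q3 for t in phospholipid_transitions(s))
            assert got == pytest.approx(expected, abs=1e-3)

    def test_transition_count_rule(self, small_library):
        """TAG <= 3 channels, diacyl GPL = distinct acyls <= 2, single-chain = 1."""
        for s in small_library:
            ts = build_transitions(s)
            if s.subclass == "TAG":
                assert 1 <= len(ts) <= 3
            elif s.subclass == "DAG" or (
                s.info.family == "phospholipid" and s.info.arity == 2
            ):
                assert len(ts) == len(set(s.acyls)) <= 2
            else:
                assert len(ts) == 1


class TestSphingoFfa:
    def test_sm_phosphocholine_fragment(self):
        (t,) = sphingo_ffa_transitions(_species("SM", (17, 0)))
        assert t.q3 == pytest.approx(184.0733, abs=1e-4)

    def test_ceramide_base_fragments(self):
        (cer,) = sphingo_ffa_transitions(_species("Cer", (17, 0)))
        (dh,) = sphingo_ffa_transitions(_species("dhCer", (17, 0)))
        assert cer.q3 == pytest.approx(264.2686, abs=1e-4)
        assert dh.q3 == pytest.approx(266.2842, abs=1e-4)

    def test_ffa_pseudo_transition(self):
        (t,) = sphingo_ffa_transitions(_species("FFA", (15, 0)))
        assert t.q1 == t.q3 == pytest.approx(241.2173, abs=1e-4)


class TestIsomerCandidates:
    def test_tag_45_0_contains_known_combinations(self):
        pool = [FattyAcyl(c, 0) for c in (13, 15, 17, 19)]
        combos = isomer_candidates("TAG", 45, 0, pool)
        as_sets = [tuple((a.carbons, a.double_bonds) for a in c) for c in combos]
        assert ((15, 0), (15, 0), (15, 0)) in as_sets
        assert ((13, 0), (15, 0), (17, 0)) in as_sets

    def test_tag_51_3_includes_printed_isomer(self):
        pool = [FattyAcyl(c, d) for c in (13, 15, 17, 19, 21) for d in (0, 1, 2, 3)]
        combos = isomer_candidates("TAG", 51, 3, pool)
        as_sets = {frozenset(str(a) for a in c) for c in combos}
        assert frozenset({"15:0", "17:1", "19:2"}) in as_sets
        assert frozenset({"15:0", "17:0", "19:3"}) in as_sets

    def test_forced_single_combination(self):
        combos = isomer_candidates("DAG", 30, 0, [FattyAcyl(15, 0)])
        assert combos == [(FattyAcyl(15, 0), FattyAcyl(15, 0))]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            isomer_candidates("TAG", 45, 0, [])

    def test_matches_exhaustive_search_oracle(self):
        pool = [FattyAcyl(c, d) for c in (13, 15, 16, 18) for d in (0, 1)]
        for total_c, total_d in [(44, 1), (46, 0), (47, 2), (49, 1)]:
            got = {
                tuple(sorted((a.carbons, a.double_bonds) for a in combo))
                for combo in isomer_candidates("TAG", total_c, total_d, pool)
            }
            brute = set()
            for combo in itertools.product(pool, repeat=3):
                key = tuple(sorted((a.carbons, a.double_bonds) for a in combo))
                if (
                    sum(a.carbons for a in combo) == total_c
                    and sum(a.double_bonds for a in combo) == total_d
                    and any(a.in_odd_pool for a in combo)
                ):
                    brute.add(key)
            assert got == brute


PANEL = [
    ISRecord("IS TAG 45:0-d", "TAG", 45, 0, 12.0, 38.0, 100.0, 5.0),
    ISRecord("IS TAG 51:0-d", "TAG", 51, 0, 13.5, 40.0, 100.0, 5.0),
    ISRecord("IS PI 34:1-d", "PI", 34, 1, 8.0, -48.0, -110.0, 5.0),
]


class TestParamAssignment:
    def test_exact_match(self):
        tag = _species("TAG", (15, 0), (15, 0), (15, 0))
        out = assign_acquisition_params(tag, PANEL)
        assert out.matched_is.name == "IS TAG 45:0-d"
        assert (out.ce, out.dp, out.dwell_ms) == (38.0, 100.0, 5.0)

    def test_nearest_by_carbon_count(self):
        tag = _species("TAG", (15, 0), (15, 0), (17, 1))  # 47:1
        out = assign_acquisition_params(tag, PANEL)
        assert out.matched_is.name == "IS TAG 45:0-d"  # |dC|=2 beats |dC|=4

    def test_tie_broken_toward_lower_carbons(self):
        tag = _species("TAG", (16, 0), (16, 0), (16, 0))  # 48:0, equidistant
        out = assign_acquisition_params(tag, PANEL)
        assert out.matched_is.name == "IS TAG 45:0-d"

    def test_missing_subclass_flagged_not_defaulted(self):
        pg = _species("PG", (17, 0), (18, 1))
        out = assign_acquisition_params(pg, PANEL)
        assert out.unparameterized and out.matched_is is None
        assert out.ce is None

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_acquisition_params(_species("FFA", (15, 0)), [])


class TestCoelution:
    def test_within_tolerance_validated(self):
        res = validate_by_coelution({"a": 12.31, "b": 12.33})
        assert res.verdict is CoelutionVerdict.VALIDATED
        assert res.max_delta_rt == pytest.approx(0.02)

    def test_outside_tolerance_names_offender(self):
        res = validate_by_coelution({"a": 12.31, "b": 12.80})
        assert res.verdict is CoelutionVerdict.NOT_VALIDATED
        assert res.offending_channels

    def test_single_channel_untestable(self):
        res = validate_by_coelution({"a": 12.31})
        assert res.verdict is CoelutionVerdict.UNTESTABLE

    def test_sn_floor_enforced(self):
        res = validate_by_coelution(
            {"a": 12.31, "b": 12.33}, channel_sn={"a": 50.0, "b": 9.0}
        )
        assert res.verdict is CoelutionVerdict.NOT_VALIDATED
        assert res.offending_channels == ("b",)

    def test_doublet_peaks_reported_as_two_isomer_groups(self):
        res = validate_by_coelution({"a": [12.31, 13.05], "b": [12.33, 13.02]})
        assert res.verdict is CoelutionVerdict.ISOMERS
        assert len(res.isomer_groups) == 2
        for group in res.isomer_groups:
            assert {c for c, _ in group} == {"a", "b"}


def test_transitions_table_layout(small_library):
    rows = [t for s in small_library[:10] for t in build_transitions(s)]
    df = transitions_table(rows)
    assert list(df.columns[:5]) == ["Q1", "Q3", "polarity", "species", "annotation"]
    assert len(df) == len(rows)
    # neutral-loss / carboxylate channels always fragment downward
    assert (df["Q1"] >= df["Q3"]).all()
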
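"""Gene-function catalog, presence/absence detection, pathway completeness."""

import itertools

import numpy as np
import pytest

from phazscan.io_formats import AnnotationFeature, SignalPeptideCall
from phazscan.profiler import (
    ALL_KEYS,
    CORE_KEYS,
    GeneFunction,
    ProfileError,
    build_function_catalog,
    call_pathways,
    call_pathways_for_matrix,
    detect_functions,
    load_reference_matrix,
    profile_genomes,
)

CATALOG = build_function_catalog()
BY_KEY = {f.key: f for f in CATALOG}


class TestCatalog:
    def test_sixteen_functions(self):
        assert tuple(f.key for f in CATALOG) == ALL_KEYS

    @pytest.mark.parametrize(
        "key,ec",
        [
            ("phaA_bktB", "2.3.1.9"), ("phaA_bktB", "2.3.1.16"),
            ("fabG", "1.1.1.100"), ("hbd", "1.1.1.157"), ("phaB", "1.1.1.36"),
            ("phaY_e", "3.1.1.22"), ("phaZ_e", "3.1.1.75"), ("phaZ_i", "3.1.1.76"),
            ("bdh", "1.1.1.30"), ("aacS", "6.2.1.16"), ("scoAB", "2.8.3.5"),
            ("phaJ", "4.2.1.119"), ("hpd", "1.1.1.59"), ("hibdh", "1.1.1.31"),
        ],
    )
    def test_default_ec_assignments(self, key, ec):
        assert ec in BY_KEY[key].ec_numbers

    def test_phaZ_variants_share_ecs_differ_in_localization(self):
        assert BY_KEY["phaZ_e"].ec_numbers == BY_KEY["phaZ_i"].ec_numbers
        assert BY_KEY["phaZ_e"].localization == "extracellular"
        assert BY_KEY["phaZ_i"].localization == "intracellular"

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ProfileError, match="duplicate"):
            build_function_catalog([GeneFunction("bdh"), GeneFunction("bdh")])


class TestDetect:
    def test_ec_match(self):
        feats = [AnnotationFeature("g", "f1", "3-hydroxybutyrate dehydrogenase", ("1.1.1.30",))]
        presence = detect_functions(feats)
        assert presence["bdh"]
        assert not any(v for k, v in presence.items() if k != "bdh")

    def test_secreted_phaZ_is_extracellular(self):
        feats = [AnnotationFeature("g", "f1", "PHA depolymerase", ("3.1.1.75",), "prot1")]
        calls = [SignalPeptideCall("prot1", True, 22)]
        presence = detect_functions(feats, sp_calls=calls)
        assert presence["phaZ_e"] and not presence["phaZ_i"]

    def test_phaZ_without_signal_peptide_is_intracellular(self):
        feats = [AnnotationFeature("g", "f1", "PHA depolymerase", ("3.1.1.75",), "prot1")]
        presence = detect_functions(feats, sp_calls=[SignalPeptideCall("prot1", False)])
        assert presence["phaZ_i"] and not presence["phaZ_e"]

    def test_single_sco_subunit_is_not_enough(self):
        feats = [
            AnnotationFeature("g", "f1", "3-oxoacid CoA-transferase subunit A", ("2.8.3.5",))
        ]
        assert not detect_functions(feats)["scoAB"]
        feats.append(
            AnnotationFeature("g", "f2", "3-oxoacid CoA-transferase subunit B", ("2.8.3.5",))
        )
        assert detect_functions(feats)["scoAB"]

    def test_catalog_ec_wildcard_is_one_field(self):
        cat = [GeneFunction("phaZ_e", ("3.1.1.-",), localization="any")]
        feats = [AnnotationFeature("g", "f1", "esterase-like protein", ("3.1.1.99",))]
        assert detect_functions(feats, cat)["phaZ_e"]
        feats2 = [AnnotationFeature("g", "f1", "esterase-like protein", ("3.1.2.1",))]
        assert not detect_functions(feats2, cat)["phaZ_e"]

    def test_phaC_gate_rejects_bare_ec(self):
        # the coarse acyltransferase EC alone must not imply a synthase
        feats = [AnnotationFeature("g", "f1", "Acetyl-CoA acetyltransferase", ("2.3.1.9",))]
        presence = detect_functions(feats)
        assert presence["phaA_bktB"] and not presence["phaC"]

    def test_phaC_keyword_with_consistent_ec(self):
        feats = [AnnotationFeature("g", "f1", "Polyhydroxyalkanoate synthase PhaC", ("2.3.1.-",))]
        assert detect_functions(feats)["phaC"]


class TestPathways:
    @staticmethod
    def _presence(**true_keys):
        return {k: True for k in true_keys if true_keys[k]}

    def test_missing_synthase_blocks_biosynthesis(self):
        ref = load_reference_matrix()
        row = ref.matrix.row("Bacillus sp. NTK071")
        call = call_pathways(row, genome_id="NTK071")
        assert call.monomer_supply and not call.biosynthesis_complete

    def test_full_cycle_consortium_rhodobacter(self):
        ref = load_reference_matrix()
        call = call_pathways(ref.matrix.row("Rhodobacter sp. NTK016B"))
        assert call.full_intracellular_cycle

    def test_vibrio_lacks_monomer_oxidation(self):
        ref = load_reference_matrix()
        call = call_pathways(ref.matrix.row("Vibrio alginolyticus ATCC 33787"))
        assert call.monomer_oxidation == "no"
        assert not call.intracellular_utilization

    def test_hibdh_gives_only_partial_oxidation(self):
        presence = {"phaA_bktB": True, "phaB": True, "phaC": True, "hibdh": True,
                    "aacS": True, "phaZ_i": True}
        call = call_pathways(presence)
        assert call.monomer_oxidation == "partial_3C"
        assert not call.intracellular_utilization
        assert not call.full_intracellular_cycle

    def test_alternate_monomer_supply_via_phaJ(self):
        call = call_pathways({"phaJ": True, "phaC": True})
        assert call.monomer_supply and call.biosynthesis_complete

    def test_unknown_key_is_an_error(self):
        with pytest.raises(ProfileError, match="unknown"):
            call_pathways({"bogus": True})

    def test_adding_genes_never_revokes_capability(self):
        """Monotone rule set: gene gain cannot flip a flag true -> false."""
        rng = np.random.default_rng(11)
        rank = {"no": 0, "partial_3C": 1, "yes": 2}
        bool_flags = [
            "monomer_supply", "biosynthesis_complete", "depoly_extracellular",
            "coa_activation", "intracellular_utilization", "full_intracellular_cycle",
        ]
        for _ in range(200):
            keys = list(ALL_KEYS)
            base = {k: bool(rng.integers(2)) for k in keys}
            absent = [k for k in keys if not base[k]]
            if not absent:
                continue
            added = dict(base)
            added[absent[int(rng.integers(len(absent)))]] = True
            a, b = call_pathways(base), call_pathways(added)
            for flag in bool_flags:
                assert getattr(a, flag) <= getattr(b, flag)
            assert rank[a.monomer_oxidation] <= rank[b.monomer_oxidation]


class TestReferenceMatrix:
    def test_dimensions_and_members(self):
        ref = load_reference_matrix()
        assert len(ref.matrix.genome_ids) == 33
        assert ref.matrix.function_keys == CORE_KEYS
        assert len(ref.members) == 6

    def test_exactly_nine_full_intracellular_cycles(self):
        ref = load_reference_matrix()
        calls = call_pathways_for_matrix(ref)
        full = {c.genome_id for c in calls if c.full_intracellular_cycle}
        assert full == {
            "Bacillus infantis NRRL B-14911",
            "Bacillus vietnamensis NBRC 101237",
            "Bacillus vietnamensis 151-6",
            "Rhodobacter sphaeroides 2.4.1",
            "Defluviimonas alba cai42",
            "Roseicitreum antarcticum ZS2-28",
            "Rhodobacter sp. NTK016B",
            "Pararhodobacter sp. CIC4N-9",
            "Pararhodobacter sp. CCB-MM2",
        }

    def test_extracellular_depolymerase_rows(self):
        ref = load_reference_matrix()
        calls = call_pathways_for_matrix(ref)
        ext = {c.genome_id for c in calls if c.depoly_extracellular}
        # the footnoted no-signal-peptide depolymerase does not count
        assert ext == {
            "Bacillus infantis NRRL B-14911",
            "Anaerobacillus macyae DSM 16346",
            "Vibrio natriegens NBRC 15636",
        }

    def test_ntk034_lacks_intracellular_depolymerase(self):
        ref = load_reference_matrix()
        row = ref.matrix.row("Bacillus sp. NTK034")
        assert not row["phaZ_i"]
        assert not call_pathways(row).full_intracellular_cycle

    def test_all_vibrios_lack_intracellular_utilization(self):
        ref = load_reference_matrix()
        calls = call_pathways_for_matrix(ref)
        vibrios = [c for c in calls if c.genome_id.startswith("Vibrio")]
        assert len(vibrios) == 12
        assert all(not c.intracellular_utilization for c in vibrios)


class TestProfileGenomes:
    def test_empty_input(self):
        matrix, calls = profile_genomes({})
        assert matrix.genome_ids == () and calls == []

    def test_matrix_covers_core_keys_plus_detected_alternates(self):
        tables = {
            "g1": [AnnotationFeature("g1", "f1", "3-hydroxyisobutyrate dehydrogenase",
                                     ("1.1.1.31",))],
            "g2": [AnnotationFeature("g2", "f1", "3-hydroxybutyrate dehydrogenase",
                                     ("1.1.1.30",))],
        }
        matrix, calls = profile_genomes(tables)
        assert matrix.function_keys == CORE_KEYS + ("hibdh",)
        assert matrix.row("g1")["hibdh"] and not matrix.row("g2")["hibdh"]
        assert calls[0].monomer_oxidation == "partial_3C"
        assert calls[1].monomer_oxidation == "yes"
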
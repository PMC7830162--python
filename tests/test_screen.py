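"""The extracellular-depolymerase screen: filters, selection, classification."""

import pytest

from phazscan.io_formats import DomainHit, ProteinRecord, SignalPeptideCall
from phazscan.motif_engine import default_patterns
from phazscan.screen import (
    CLASS_AHSXG,
    CLASS_GHSXH,
    CLASS_NONE,
    ScreenConfig,
    ScreenError,
    _toy_signal_peptide,
    classify_lipase_box,
    has_abh_fold,
    is_secreted,
    screen_protein,
    screen_proteome,
    write_reports,
)

FOLD_HIT = DomainHit("p1", "SUPERFAMILY", "SSF53474", "alpha/beta-Hydrolases", 10, 200)


def protein_with(mature: str, pid: str = "p1") -> ProteinRecord:
    """Prefix a standard signal peptide; mature region starts at residue 19."""
    return ProteinRecord(pid, "MKRLLLLLLLLLLVVAQA" + mature)


SECRETED = SignalPeptideCall("p1", True, cleavage_site=19)

# mature region with canonical feature chain:
# oxyanion at mature 11-17, AHSXG box at mature 31-35, D at 51, H at 71
CHAIN = (
    "A" * 10 + "PAAAAHG" + "A" * 13 + "AHSMG" + "A" * 15 + "D" + "A" * 19 + "H" + "A" * 30
)


class TestIsSecreted:
    def test_existing_call_wins(self):
        p = protein_with(CHAIN)
        assert is_secreted(p, [SECRETED], ScreenConfig()) == (True, 19)

    def test_no_call_no_fallback(self):
        p = protein_with(CHAIN)
        assert is_secreted(p, [], ScreenConfig()) == (False, None)

    def test_conflicting_duplicate_calls_error(self):
        p = protein_with(CHAIN)
        calls = [SECRETED, SignalPeptideCall("p1", False)]
        with pytest.raises(ScreenError, match="conflicting"):
            is_secreted(p, calls, ScreenConfig())

    def test_identical_duplicate_calls_tolerated(self):
        p = protein_with(CHAIN)
        assert is_secreted(p, [SECRETED, SECRETED], ScreenConfig()) == (True, 19)

    def test_fallback_heuristic_hand_computed(self):
        # M, K within first 5, then 10 Leu starting at residue 3.
        # First qualifying window: residues 3-10 (KD mean of R+7L = 2.76),
        # so the predicted first mature residue is 10 + 5 = 15.
        seq = "MKR" + "L" * 10 + "QQTNENSAGAELKAGAELKAGAELKAGNE" * 3
        assert _toy_signal_peptide(seq) == (True, 15)

    def test_fallback_requires_leading_met_and_charge(self):
        assert _toy_signal_peptide("AKR" + "L" * 10 + "A" * 40) == (False, None)
        assert _toy_signal_peptide("MAAAA" + "L" * 10 + "A" * 40) == (False, None)

    def test_fallback_requires_hydrophobic_window(self):
        assert _toy_signal_peptide("MKR" + "Q" * 40) == (False, None)


class TestFoldFilter:
    def test_signature_id_match(self):
        assert has_abh_fold("p1", [FOLD_HIT], ScreenConfig())

    def test_description_keyword_match(self):
        hit = DomainHit("p1", "Pfam", "PF12697", "Alpha/Beta hydrolase fold", 5, 120)
        assert has_abh_fold("p1", [hit], ScreenConfig())

    def test_no_hits_is_false(self):
        assert not has_abh_fold("p1", [], ScreenConfig())

    def test_unrelated_hit_is_false(self):
        hit = DomainHit("p1", "Pfam", "PF00001", "7 transmembrane receptor", 5, 120)
        assert not has_abh_fold("p1", [hit], ScreenConfig())


class TestScreenProtein:
    def test_full_chain_passes_and_classifies(self):
        p = protein_with(CHAIN)
        r = screen_protein(p, [SECRETED], [FOLD_HIT], ScreenConfig())
        assert r.passes and r.order_ok
        assert r.oxyanion.start == 18 + 11 and r.oxyanion.end == 18 + 17
        assert r.lipase_box.start == 18 + 31
        assert r.triad.asp_pos == 18 + 51 and r.triad.his_pos == 18 + 71
        assert r.classification == CLASS_AHSXG

    def test_not_secreted_fails_but_features_reported(self):
        p = protein_with(CHAIN)
        r = screen_protein(p, [], [FOLD_HIT], ScreenConfig())
        assert not r.passes and not r.secreted
        assert r.lipase_box is not None and r.order_ok
        assert r.classification == CLASS_NONE

    def test_wrong_order_fails(self):
        # box before oxyanion
        mature = "A" * 10 + "AHSMG" + "A" * 13 + "PAAAAHG" + "A" * 15 + "D" + "A" * 19 + "H"
        p = protein_with(mature)
        r = screen_protein(p, [SECRETED], [FOLD_HIT], ScreenConfig())
        assert not r.passes and not r.order_ok
        assert r.oxyanion is not None and r.lipase_box is not None and r.triad is not None

    def test_ghsxh_box_classification(self):
        mature = "A" * 10 + "PAAAAHG" + "A" * 13 + "GHSAH" + "A" * 15 + "D" + "A" * 19 + "H"
        p = protein_with(mature)
        r = screen_protein(p, [SECRETED], [FOLD_HIT], ScreenConfig())
        assert r.passes and r.classification == CLASS_GHSXH

    def test_mature_region_excludes_signal_peptide_motifs(self):
        # a lipase box hidden inside the signal peptide must not be searched
        seq = "MKRGASAG" + "LLLLLLVVAQA" + CHAIN
        p = ProteinRecord("p1", seq)
        call = SignalPeptideCall("p1", True, cleavage_site=20)
        r = screen_protein(p, [call], [FOLD_HIT], ScreenConfig())
        assert r.passes
        assert r.lipase_box.start > 20

    def test_full_region_mode_sees_whole_sequence(self):
        # whole feature chain upstream of the (deliberately late) cleavage
        # site: invisible in mature mode, visible in full mode
        p = ProteinRecord("p1", CHAIN)
        call = SignalPeptideCall("p1", True, cleavage_site=80)
        mature = screen_protein(p, [call], [FOLD_HIT], ScreenConfig())
        full = screen_protein(p, [call], [FOLD_HIT], ScreenConfig(search_region="full"))
        assert not mature.passes
        assert full.passes and full.lipase_box.start == 31

    def test_classify_requires_passing_report(self):
        p = protein_with(CHAIN)
        r = screen_protein(p, [], [FOLD_HIT], ScreenConfig())
        with pytest.raises(ScreenError):
            classify_lipase_box(r)


class TestScreenProteome:
    def test_empty_proteome(self):
        reports, summary = screen_proteome([], [], [])
        assert reports == []
        assert summary == {
            "n_proteins": 0, "n_secreted": 0, "n_fold_positive": 0, "n_passing": 0,
        }

    def test_perfect_recovery_on_default_benchmark(self, default_proteome, default_screen):
        reports, summary = default_screen
        truth = {t.protein_id: t.label for t in default_proteome.truths}
        passing = {r.protein_id for r in reports if r.passes}
        candidates = {pid for pid, label in truth.items() if label == "candidate"}
        assert passing == candidates
        assert summary["n_passing"] == len(candidates) == 20

    def test_decoy_failure_flags_match_class(self, default_proteome, default_screen):
        reports, _ = default_screen
        truth = {t.protein_id: t.label for t in default_proteome.truths}
        flag_of = {
            "no_sp": lambda r: not r.secreted,
            "no_fold": lambda r: not r.has_fold,
            "missing_oxyanion": lambda r: r.oxyanion is None,
            "missing_lipase_box": lambda r: r.lipase_box is None,
            "missing_asp": lambda r: r.triad is None,
            "missing_his": lambda r: r.triad is None,
            "wrong_order": lambda r: (not r.order_ok)
            and r.oxyanion is not None and r.triad is not None,
        }
        for r in reports:
            label = truth[r.protein_id]
            if label == "candidate":
                continue
            assert flag_of[label](r), (r.protein_id, label)

    def test_removing_patterns_is_monotone(self, default_proteome):
        """A smaller pattern library can only shrink the passing set."""
        full = ScreenConfig()
        n_full = screen_proteome(
            default_proteome.proteins, default_proteome.sp_calls,
            default_proteome.domain_hits, full,
        )[1]["n_passing"]
        for dropped in ("GHSXH", "AHSXG", "GXSXG", "HGC"):
            lib = tuple(p for p in default_patterns() if p.name != dropped)
            cfg = ScreenConfig(pattern_library=lib)
            n = screen_proteome(
                default_proteome.proteins, default_proteome.sp_calls,
                default_proteome.domain_hits, cfg,
            )[1]["n_passing"]
            assert n <= n_full

    def test_report_tsv_is_deterministic(self, default_proteome, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for path in (a, b):
            reports, _ = screen_proteome(
                default_proteome.proteins, default_proteome.sp_calls,
                default_proteome.domain_hits,
            )
            write_reports(reports, path)
        assert a.read_bytes() == b.read_bytes()
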
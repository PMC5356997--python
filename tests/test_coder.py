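"""SDL loading, code assignment, ranking and the confidence policy."""

import pytest

from lcscoder.coder import (
    EmptyQueryError,
    SDLFormatError,
    apply_confidence_policy,
    assign_code,
    build_sdl,
    load_sdl,
)
from lcscoder.fixtures import TABLE1_ROWS, fixture_config, fixture_ontology
from lcscoder.ontology import TermOntology
from lcscoder.tokenizer import SegmenterConfig


@pytest.fixture(scope="module")
def sdl():
    return build_sdl([(n, c) for n, c, _ in TABLE1_ROWS], fixture_config())


class TestLoadSDL:
    def test_table1_file_loads_four_entries(self, tmp_path):
        p = tmp_path / "sdl.tsv"
        p.write_text("".join(f"{n}\t{c}\n" for n, c, _ in TABLE1_ROWS))
        lib = load_sdl(p, fixture_config())
        assert len(lib) == 4
        assert sorted(lib.index) == ["B15.000", "B15.001", "B15.002", "B15.003"]
        # entries are pre-tokenized with stop words filtered
        assert lib.index["B15.000"].tokens.surfaces == (
            "jia xing", "bing du xing gan yan", "gan hun mi"
        )

    def test_duplicate_code_rejected(self, tmp_path):
        p = tmp_path / "sdl.tsv"
        p.write_text("NAME A\tB15.000\nNAME B\tB15.000\n")
        with pytest.raises(SDLFormatError, match="duplicate"):
            load_sdl(p, fixture_config())

    def test_malformed_code_names_line(self, tmp_path):
        p = tmp_path / "sdl.tsv"
        p.write_text("NAME A\tB15.000\nNAME B\t15B.000\n")
        with pytest.raises(SDLFormatError, match=":2"):
            load_sdl(p, fixture_config())

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "sdl.tsv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            load_sdl(p, fixture_config())


class TestAssignCode:
    def test_exact_standard_name_codes_itself_at_full_confidence(self, sdl):
        result = assign_code(TABLE1_ROWS[0][0], sdl, fixture_ontology())
        top = result.candidates[0]
        assert (top.code, top.confidence) == ("B15.000", 1.0)
        assert result.decision == "auto_output"

    def test_abbreviated_query_recovers_code_through_ontology(self, sdl):
        result = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        assert result.candidates[0].code == "B15.000"

    def test_abbreviated_query_fails_without_ontology(self, sdl):
        with_onto = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        without = assign_code("JIA GAN BAN GAN HUN MI", sdl, TermOntology())
        assert without.candidates[0].confidence < with_onto.candidates[0].confidence

    def test_disjoint_vocabulary_gives_zero_confidence_manual_review(self, sdl):
        result = assign_code("WEI YAN", sdl, fixture_ontology())
        assert all(c.confidence == 0.0 for c in result.candidates)
        assert result.decision == "manual_review"

    def test_self_retrieval_all_measures(self, sdl):
        for measure in ("lcs", "tlcs", "wlcs", "word-match", "bigram"):
            for name, code, _ in TABLE1_ROWS:
                result = assign_code(name, sdl, fixture_ontology(), measure=measure)
                top = result.candidates[0]
                assert (top.code, top.confidence) == (code, 1.0), measure

    def test_ranking_is_deterministic(self, sdl):
        a = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        b = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        assert a == b

    def test_tie_break_shorter_name_then_lexicographic_code(self):
        cfg = SegmenterConfig()
        lib = build_sdl(
            [("GAN YAN MI XX", "C00.003"), ("GAN BBB", "C00.002"), ("GAN AAA", "C00.001")],
            cfg,
        )
        # "GAN BBB"/"GAN AAA" tie on T-LCS (lcsl 1, lb 2): lexicographic code;
        # "GAN YAN MI XX" scores 2*1/5 = 0.4 < 0.5 despite equal lcsl.
        result = assign_code("GAN", lib, measure="tlcs", top_k=3)
        assert [c.code for c in result.candidates] == ["C00.001", "C00.002", "C00.003"]

    def test_empty_query_raises(self, sdl):
        with pytest.raises(EmptyQueryError):
            assign_code("BAN", sdl, fixture_ontology())

    def test_top_k_limits_candidates(self, sdl):
        result = assign_code(TABLE1_ROWS[0][0], sdl, fixture_ontology(), top_k=2)
        assert len(result.candidates) == 2

    def test_unknown_measure_rejected(self, sdl):
        with pytest.raises(ValueError, match="unknown measure"):
            assign_code("GAN", sdl, measure="xyz")


class TestConfidencePolicy:
    def test_above_operating_point_auto_outputs(self, sdl):
        result = assign_code(TABLE1_ROWS[0][0], sdl, fixture_ontology())
        assert apply_confidence_policy(result, 0.803).decision == "auto_output"

    def test_below_threshold_routes_to_manual_review(self, sdl):
        result = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        assert result.candidates[0].confidence < 0.9
        assert apply_confidence_policy(result, 0.9).decision == "manual_review"

    def test_zero_threshold_auto_outputs_any_positive_confidence(self, sdl):
        result = assign_code("JIA GAN BAN GAN HUN MI", sdl, fixture_ontology())
        assert apply_confidence_policy(result, 0.0).decision == "auto_output"

    def test_threshold_validated(self, sdl):
        result = assign_code(TABLE1_ROWS[0][0], sdl, fixture_ontology())
        with pytest.raises(ValueError):
            apply_confidence_policy(result, 1.5)
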
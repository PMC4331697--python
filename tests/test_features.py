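"""Feature extraction: shapes, orthography, affixes, lexicon, context."""

import pytest
from hypothesis import given, settings, strategies as st

from chemner.features import (
    ALL_GROUPS,
    BEST_GROUPS,
    FeatureConfig,
    Lexicon,
    build_features,
    context_features,
    dictionary_features,
    feature_group,
    morphological_features,
    orthographic_features,
    word_shape,
)
from chemner.linguistic import FallbackTagger, annotate_linguistics, tokenize
from chemner.types import Sentence, Token


def _tokens(text, tag=False):
    s = Sentence("D", "A", 0, len(text), text)
    tokenize(s)
    if tag:
        annotate_linguistics(s.tokens, FallbackTagger())
    return s.tokens


class TestWordShape:
    @pytest.mark.parametrize("surface,shape", [
        ("Abc:1234", "Aaa#1111"),
        ("aspirin", "aaaaaaa"),
        ("CaCl2", "AaAa1"),
        ("α-2", "a#1"),  # Greek minuscules are Unicode lowercase letters
    ])
    def test_examples(self, surface, shape):
        assert word_shape(surface) == shape

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            word_shape("")

    @given(st.text(min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_shape_length_and_alphabet(self, s):
        shape = word_shape(s)
        assert len(shape) == len(s)
        assert set(shape) <= set("Aa1#")


class TestOrthographic:
    def _feats(self, surface, groups=("capitalization", "counting",
                                      "symbols", "greek")):
        cfg = FeatureConfig(enabled_groups=frozenset(groups))
        return set(orthographic_features(Token(0, len(surface), surface), cfg))

    def test_mixed_case_with_caps_and_no_digit(self):
        feats = self._feats("NSAIDs")
        assert "CAP=MixedCase" in feats
        assert "COUNT=NoDigit" in feats
        assert "COUNT=ThreeOrMoreCap" in feats

    def test_greek_dash_digit(self):
        feats = self._feats("alpha-2")
        assert {"GREEK=alpha", "SYM=Dash", "COUNT=OneDigit"} <= feats

    def test_plain_lowercase(self):
        feats = self._feats("aspirin")
        assert {"CAP=LowerCase", "COUNT=NoDigit", "COUNT=NoCap"} <= feats
        assert not any(f.startswith("SYM=") for f in feats)

    def test_greek_glyph(self):
        assert "GREEK=glyph" in self._feats("α")

    @pytest.mark.parametrize("surface,cap", [
        ("K", "SingleCap"), ("DNA", "AllCaps"), ("Aspirin", "StartCap"),
    ])
    def test_capitalization_classes(self, surface, cap):
        assert f"CAP={cap}" in self._feats(surface)


class TestMorphological:
    def test_affixes_and_ngrams_enumeration(self):
        cfg = FeatureConfig(
            enabled_groups=frozenset({"prefix", "suffix", "char_ngrams"}),
            ngram_lengths=(2, 3), affix_lengths=(2, 3),
        )
        feats = set(morphological_features(Token(0, 4, "acid"), cfg))
        assert feats == {
            "PRE2=ac", "PRE3=aci", "SUF2=id", "SUF3=cid",
            "NG2=ac", "NG2=ci", "NG2=id", "NG3=aci", "NG3=cid",
        }

    def test_length_guard_on_short_token(self):
        cfg = FeatureConfig(
            enabled_groups=frozenset({"prefix", "suffix", "char_ngrams"}),
        )
        feats = set(morphological_features(Token(0, 2, "Na"), cfg))
        assert feats == {"PRE2=Na", "SUF2=Na", "NG2=Na"}

    def test_single_character_shape_only(self):
        cfg = FeatureConfig(
            enabled_groups=frozenset(
                {"prefix", "suffix", "char_ngrams", "word_shape"}
            ),
        )
        assert morphological_features(Token(0, 1, "K"), cfg) == ["SHAPE=A"]


class TestLexicon:
    def test_multiword_longest_match(self):
        lex = Lexicon(["acetylsalicylic acid"])
        toks = _tokens("given acetylsalicylic acid today")
        feats = dictionary_features(toks, lex)
        assert feats == [[], ["LEXICON=B"], ["LEXICON=I"], []]

    def test_longest_match_beats_shorter(self):
        lex = Lexicon(["acid", "acetylsalicylic acid"])
        toks = _tokens("given acetylsalicylic acid today")
        feats = dictionary_features(toks, lex)
        assert feats == [[], ["LEXICON=B"], ["LEXICON=I"], []]

    def test_empty_lexicon_no_features(self):
        toks = _tokens("given aspirin today")
        assert dictionary_features(toks, Lexicon()) == [[], [], []]

    def test_case_insensitive(self):
        lex = Lexicon(["Aspirin"])
        toks = _tokens("ASPIRIN helps")
        assert dictionary_features(toks, lex)[0] == ["LEXICON=B"]

    def test_file_round_trip(self, tmp_path):
        lex = Lexicon(["aspirin", "acetylsalicylic acid"])
        path = tmp_path / "lex.txt"
        lex.to_file(path)
        back = Lexicon.from_file(path)
        assert len(back) == 2


class TestContext:
    def test_conjunction_concatenation(self):
        toks = _tokens("tested aspirin", tag=True)
        cfg = FeatureConfig(context_windows=((-1, 0),))
        feats = context_features(1, toks, "conjunctions", cfg)
        assert "CONJ[-1,0]lemma=tested|aspirin" in feats
        assert "CONJ[-1,0]pos=VBD|NN" in feats

    def test_window_eos_placeholder(self):
        toks = _tokens("tested aspirin", tag=True)
        cfg = FeatureConfig(context_windows=((0, 1),))
        feats = context_features(1, toks, "windows", cfg)
        assert "WIN[0,1]lemma@1=EOS" in feats

    def test_all_placeholders_before_sentence(self):
        toks = _tokens("tested aspirin", tag=True)
        cfg = FeatureConfig(context_windows=((-3, -1),))
        feats = context_features(0, toks, "conjunctions", cfg)
        assert "CONJ[-3,-1]lemma=BOS|BOS|BOS" in feats


class TestBuildFeatures:
    def test_token_only_config(self):
        toks = _tokens("We tested aspirin")
        cfg = FeatureConfig(enabled_groups=frozenset({"token"}))
        feats = build_features(toks, None, cfg)
        assert feats == [["W=We"], ["W=tested"], ["W=aspirin"]]

    def test_purity(self, small_corpus):
        docs, _, lex = small_corpus
        toks = _tokens(docs[0].abstract.split(".")[0], tag=True)
        a = build_features(toks, lex, FeatureConfig())
        b = build_features(toks, lex, FeatureConfig())
        assert a == b

    def test_disabling_commutes_with_extraction(self):
        toks = _tokens("Treatment with 2-chlorophenol helped", tag=True)
        lex = Lexicon(["2-chlorophenol"])
        full = build_features(toks, lex, FeatureConfig())
        reduced = build_features(
            toks, lex, FeatureConfig().without("suffix")
        )
        filtered = [
            [f for f in fs if feature_group(f) != "suffix"] for fs in full
        ]
        assert reduced == filtered

    def test_every_group_producible(self):
        toks = _tokens(
            "Treatment with alpha-Chloro2 aspirin (3/4) worked", tag=True
        )
        for t in toks:
            t.dep_label = "dobj"
            t.dep_head = 0
        lex = Lexicon(["aspirin"])
        cfg = FeatureConfig(
            enabled_groups=ALL_GROUPS - {"context_windows"}
        )
        feats = build_features(toks, lex, cfg)
        produced = {feature_group(f) for fs in feats for f in fs}
        assert produced == ALL_GROUPS - {"context_windows"}

    def test_best_config_has_no_dependency_or_capitalization(self):
        toks = _tokens("Treatment with Aspirin worked", tag=True)
        for t in toks:
            t.dep_label = "dobj"
            t.dep_head = 0
        feats = build_features(toks, Lexicon(["aspirin"]), FeatureConfig())
        groups = {feature_group(f) for fs in feats for f in fs}
        assert "dependency" not in groups
        assert "capitalization" not in groups
        assert "context_conjunctions" in groups

    def test_windows_and_conjunctions_mutually_exclusive(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            FeatureConfig(enabled_groups=ALL_GROUPS)

    def test_best_groups_definition(self):
        assert BEST_GROUPS == ALL_GROUPS - {
            "dependency", "capitalization", "context_windows"
        }
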
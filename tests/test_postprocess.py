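"""Post-processing: parentheses parity, abbreviations, exclusion list."""

import math

import pytest

from chemner.postprocess import (
    ExclusionList,
    abbreviation_resolution,
    apply_exclusion_list,
    build_exclusion_list,
    detect_abbreviations,
    mention_log_odds,
    parentheses_filter,
    tune_exclusion_thresholds,
)
from chemner.synthetic import corrupt_predictions
from chemner.types import Annotation, Document, Sentence


def _ann(text, start, conf=0.9, doc="D1", sec="A", source="m"):
    return Annotation(doc, sec, start, start + len(text), text,
                      confidence=conf, source=source)


class TestParentheses:
    @pytest.mark.parametrize("text,kept", [
        ("1-(2-chlorophenyl)", True),
        ("2-(chloro", False),
        ("aspirin", True),
        ("[3H]thymidine", True),
        ("2-{amino", False),
        ("(R)-(+)-limonene", True),
    ])
    def test_parity_rule(self, text, kept):
        anns = [_ann(text, 0)]
        assert (parentheses_filter(anns) == anns) is kept

    def test_never_adds_or_modifies(self):
        anns = [_ann("aspirin", 0), _ann("2-(chloro", 20)]
        out = parentheses_filter(anns)
        assert out == [anns[0]]
        assert out[0] is anns[0]


class TestAbbrevDetection:
    def _detect(self, text):
        s = Sentence("D1", "A", 0, len(text), text)
        return detect_abbreviations(s)

    def test_nsaids_worked_example(self):
        pairs = self._detect(
            "Patients took non-steroidal anti-inflammatory drugs (NSAIDs)."
        )
        assert len(pairs) == 1
        assert pairs[0].long_text == "non-steroidal anti-inflammatory drugs"
        assert pairs[0].short_text == "NSAIDs"

    def test_etoh_worked_example(self):
        pairs = self._detect("Cells were fixed in ethanol (EtOH) overnight.")
        assert [(p.long_text, p.short_text) for p in pairs] == [
            ("ethanol", "EtOH")
        ]

    def test_non_abbreviation_parenthetical_ignored(self):
        assert self._detect("This was reported before (see Figure 1).") == []

    @pytest.mark.parametrize("text", [
        "No candidate here (x).",            # too short
        "Numbers only (1234).",              # no letter
        "Too many words (a b c d).",         # > 2 words
        "Starts with symbol (-OH).",         # first char not alphanumeric
    ])
    def test_short_form_validity_rules(self, text):
        assert self._detect(text) == []

    def test_offsets_are_section_frame(self):
        text = "Filler start. Then gamma aminobutyric acid (GABA) rose."
        s = Sentence("D1", "A", 10, 10 + len(text), text)
        (pair,) = detect_abbreviations(s)
        assert text[pair.long_start - 10 : pair.long_end - 10] == (
            "gamma aminobutyric acid"
        )
        assert text[pair.short_start - 10 : pair.short_end - 10] == "GABA"


class TestAbbrevResolution:
    text = "non-steroidal anti-inflammatory drugs (NSAIDs) were tested."

    def _pair(self):
        s = Sentence("D1", "A", 0, len(self.text), self.text)
        (pair,) = detect_abbreviations(s)
        return pair

    def test_short_annotated_adds_long(self):
        short = _ann("NSAIDs", self.text.index("NSAIDs"), conf=0.8)
        out = abbreviation_resolution([short], [self._pair()], self.text)
        texts = {a.text for a in out}
        assert "non-steroidal anti-inflammatory drugs" in texts
        added = next(a for a in out if a.text != "NSAIDs")
        assert added.source == "abbrev"
        assert added.confidence == pytest.approx(0.8)

    def test_partial_coverage_expanded(self):
        partial = _ann(
            "anti-inflammatory drugs",
            self.text.index("anti-inflammatory"),
        )
        out = abbreviation_resolution([partial], [self._pair()], self.text)
        longs = [a for a in out if a.start == 0]
        assert longs[0].text == "non-steroidal anti-inflammatory drugs"

    def test_neither_form_annotated_is_identity(self):
        other = _ann("tested", self.text.index("tested"))
        out = abbreviation_resolution([other], [self._pair()], self.text)
        assert out == [other]

    def test_never_removes_annotations(self):
        anns = [
            _ann("NSAIDs", self.text.index("NSAIDs")),
            _ann("tested", self.text.index("tested")),
        ]
        out = abbreviation_resolution(anns, [self._pair()], self.text)
        assert {a.text for a in anns} <= {a.text for a in out}
        assert all(0 <= a.start < a.end <= len(self.text) for a in out)


class TestExclusionList:
    def test_log_odds_formula(self):
        assert mention_log_odds(0, 3) == pytest.approx(
            math.log(0.5 / 3.5)
        )

    def _preds(self, mention, tp, fp):
        """tp exact-matching and fp spurious predictions of one string."""
        golds, preds = [], []
        pos = 0
        for i in range(tp + fp):
            a = _ann(mention, pos, doc=f"D{i}")
            preds.append(a)
            if i < tp:
                golds.append(
                    Annotation(a.doc_id, "A", a.start, a.end, a.text)
                )
            pos += len(mention) + 1
        return golds, preds

    def test_zero_tp_mention_excluded(self):
        golds, preds = self._preds("was", 0, 3)
        excl = build_exclusion_list(golds, preds, theta=0.3, min_fp=2)
        assert excl.entries == {"was"}

    def test_min_fp_guard(self):
        golds, preds = self._preds("rare", 10, 1)
        excl = build_exclusion_list(golds, preds, theta=0.3, min_fp=2)
        assert excl.entries == set()

    def test_good_mention_kept_out(self):
        golds, preds = self._preds("aspirin", 50, 2)
        excl = build_exclusion_list(golds, preds, theta=0.3, min_fp=2)
        assert excl.entries == set()
        assert mention_log_odds(50, 2) > 0.3

    def test_theta_monotonicity(self):
        golds, preds = self._preds("was", 2, 4)
        sizes = [
            len(build_exclusion_list(golds, preds, theta, 0).entries)
            for theta in (-100.0, 0.0, 100.0)
        ]
        assert sizes == sorted(sizes)
        assert sizes[0] == 0  # theta -> -inf gives the empty list
        assert sizes[-1] == 1  # theta -> +inf admits every mention

    def test_min_fp_monotonicity(self):
        golds, preds = self._preds("was", 0, 3)
        sizes = [
            len(build_exclusion_list(golds, preds, 100.0, k).entries)
            for k in (0, 2, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_apply_is_case_insensitive_filter_only(self):
        excl = ExclusionList({"was"})
        anns = [_ann("WAS", 0), _ann("aspirin", 10)]
        out = apply_exclusion_list(anns, excl)
        assert [a.text for a in out] == ["aspirin"]
        assert apply_exclusion_list(anns, ExclusionList(set())) == anns

    def test_file_round_trip(self, tmp_path):
        excl = ExclusionList({"was", "were"}, 0.5, 3)
        path = tmp_path / "excl.txt"
        excl.to_file(path)
        back = ExclusionList.from_file(path)
        assert back.entries == excl.entries
        assert back.theta_logodds == 0.5
        assert back.min_fp == 3


class TestThresholdTuning:
    def test_singleton_grid_returned(self, small_corpus):
        docs, gold, _ = small_corpus
        preds = corrupt_predictions(
            gold, docs, seed=5, fp_rate=0.9, fn_rate=0.1
        )
        theta, min_fp, _ = tune_exclusion_thresholds(
            docs, gold, preds, theta_grid=[0.3], min_fp_grid=[2], seed=1
        )
        assert (theta, min_fp) == (0.3, 2)

    def test_perfect_predictions_favor_empty_list(self, small_corpus):
        docs, gold, _ = small_corpus
        preds = [
            Annotation(g.doc_id, g.section, g.start, g.end, g.text,
                       confidence=0.9, source="m")
            for g in gold
        ]
        theta, min_fp, delta = tune_exclusion_thresholds(
            docs, gold, preds, theta_grid=[0.3], min_fp_grid=[2], seed=1
        )
        assert delta <= 0.0
        excl = build_exclusion_list(gold, preds, theta, min_fp)
        assert excl.entries == set()

    def test_planted_bad_mention_improves_f1(self, small_corpus):
        docs, gold, _ = small_corpus
        preds = corrupt_predictions(
            gold, docs, seed=5, fp_rate=1.0, fn_rate=0.0
        )
        theta, min_fp, delta = tune_exclusion_thresholds(
            docs, gold, preds, theta_grid=[0.3], min_fp_grid=[2], seed=1
        )
        excl = build_exclusion_list(gold, preds, theta, min_fp)
        assert delta > 0.0
        assert excl.entries  # the trap homographs enter the list

    def test_too_few_documents_rejected(self, small_corpus):
        docs, gold, _ = small_corpus
        with pytest.raises(ValueError, match="folds"):
            tune_exclusion_thresholds(docs[:5], gold, [], folds=10)
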
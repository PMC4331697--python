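"""CRF engine: training, decoding, confidences, harmonization."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from chemner.crf import (
    AnnotationSet,
    CRFModel,
    harmonize,
    labels_to_states,
    train_crf,
)
from chemner.types import Annotation


def _enumerated_span_prob(model, feats, start_tok, end_tok):
    """Independent oracle: score every label sequence explicitly.

    Enumeration runs over labellings in the original token order; scoring
    uses the model's internal representation (reversed for backward
    models), mirroring how the model defines its distribution.
    """
    feats_int, _ = model._internalize(list(feats))
    E, M, init, end = model._lattice(feats_int)
    state_of = {n: i for i, n in enumerate(model._states.names)}
    T = len(feats)
    scores, constrained = [], []
    for labs in itertools.product("OBI", repeat=T):
        labs_int = (
            labs[::-1] if model.direction == "backward" else labs
        )
        try:
            y = [
                state_of[s] for s in labels_to_states(labs_int, model.order)
            ]
        except KeyError:
            continue
        sc = init[y[0]] + E[0, y[0]]
        for t in range(1, T):
            sc += M[y[t - 1], y[t]] + E[t, y[t]]
        sc += end[y[-1]]
        if sc < -1e20:
            continue
        scores.append(sc)
        want = all(
            labs[t] == ("B" if t == start_tok else "I")
            for t in range(start_tok, end_tok)
        )
        if want:
            constrained.append(sc)
    if not constrained:
        return 0.0
    return float(np.exp(logsumexp(constrained) - logsumexp(scores)))


class TestTraining:
    def test_overfit_sanity_order1(self, toy_model, toy_sequences):
        correct = total = 0
        for feats, labels in toy_sequences:
            pred = toy_model.predict(feats)
            correct += sum(p == g for p, g in zip(pred, labels))
            total += len(labels)
        assert correct / total >= 0.95

    def test_order2_label_transform(self):
        assert labels_to_states(["O", "B", "I"], 2) == [
            "^|O", "O|B", "B|I"
        ]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_crf([])

    def test_invalid_bio_rejected(self):
        with pytest.raises(ValueError, match="invalid BIO"):
            train_crf([([["W=a"], ["W=b"]], ["O", "I"])])

    def test_training_deterministic(self, toy_sequences):
        a = train_crf(toy_sequences, max_iter=50)
        b = train_crf(toy_sequences, max_iter=50)
        assert np.array_equal(a._w_emit, b._w_emit)

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_backward_direction_learns_too(self, toy_sequences, direction):
        m = train_crf(toy_sequences, direction=direction, max_iter=100)
        assert m.predict(
            [["W=we"], ["W=tested"], ["W=chem1ol", "SUF2=ol"], ["W=."]]
        ) == ["O", "O", "B", "O"]


class TestConfidence:
    def test_confidences_are_probabilities(self, toy_model, toy_sequences):
        for feats, _ in toy_sequences:
            for i in range(len(feats)):
                for j in range(i + 1, min(i + 3, len(feats)) + 1):
                    p = toy_model.span_probability(feats, i, j)
                    assert 0.0 <= p <= 1.0

    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_constrained_marginal_matches_enumeration(
        self, toy_sequences, order, direction
    ):
        model = train_crf(
            toy_sequences, order=order, direction=direction, max_iter=60
        )
        feats = [
            ["W=we"], ["W=tested"], ["W=chem2ol", "SUF2=ol"],
            ["W=and"], ["W=chem3ol", "SUF2=ol"], ["W=."],
        ]
        for (i, j) in [(2, 3), (2, 5), (0, 2), (4, 5)]:
            brute = _enumerated_span_prob(model, feats, i, j)
            fb = model.span_probability(feats, i, j)
            assert fb == pytest.approx(brute, abs=1e-9)

    def test_token_marginals_sum_to_one(self, toy_model):
        feats = [["W=we"], ["W=tested"], ["W=chem0ol", "SUF2=ol"]]
        marg = toy_model.token_marginals(feats)
        assert np.allclose(marg.sum(axis=1), 1.0)

    def test_token_product_confidence_available(self, toy_sequences):
        m = train_crf(
            toy_sequences, max_iter=60, confidence_method="token_product"
        )
        from chemner.linguistic import tokenize
        from chemner.types import Sentence

        text = "we tested chem1ol ."
        s = Sentence("D", "A", 0, len(text), text)
        tokenize(s)
        feats = [["W=" + t.surface] + (
            ["SUF2=ol"] if t.surface.endswith("ol") else []
        ) for t in s.tokens]
        anns = m.decode(s, feats, text)
        assert all(0.0 <= a.confidence <= 1.0 for a in anns)


class TestProjectionConsistency:
    def test_tied_order2_decodes_like_order1(self, toy_model, toy_sequences):
        """An order-2 model whose pair-state weights copy the order-1
        weights defines the same distribution, hence the same decoding."""
        m2 = CRFModel(order=2, direction="forward")
        m2._feat_index = dict(toy_model._feat_index)
        S2 = m2._states.n
        F = toy_model._w_emit.shape[0]
        lab_idx = {l: i for i, l in enumerate(toy_model._states.names)}
        m2._w_emit = np.zeros((F, S2))
        m2._w_trans = np.zeros((S2, S2))
        m2._w_init = np.zeros(S2)
        m2._w_end = np.zeros(S2)
        pairs = [n.split("|") for n in m2._states.names]
        for s, (p, c) in enumerate(pairs):
            ci = lab_idx[c]
            m2._w_emit[:, s] = toy_model._w_emit[:, ci]
            m2._w_end[s] = toy_model._w_end[ci]
            if p == "^":
                m2._w_init[s] = toy_model._w_init[ci]
        for s1, (_, c1) in enumerate(pairs):
            for s2, (p2, c2) in enumerate(pairs):
                if p2 == c1:
                    m2._w_trans[s1, s2] = toy_model._w_trans[
                        lab_idx[c1], lab_idx[c2]
                    ]
        for feats, _ in toy_sequences:
            assert m2.predict(feats) == toy_model.predict(feats)
            assert m2.span_probability(feats, 2, 3) == pytest.approx(
                toy_model.span_probability(feats, 2, 3), abs=1e-9
            ) if len(feats) > 3 else True


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, toy_model, toy_sequences):
        path = tmp_path / "model.npz"
        toy_model.save(path)
        back = CRFModel.load(path)
        assert back.order == toy_model.order
        assert back.model_id == toy_model.model_id
        for feats, _ in toy_sequences:
            assert back.predict(feats) == toy_model.predict(feats)


def _ann(start, end, conf, doc="D1", sec="A"):
    return Annotation(doc, sec, start, end, "x" * (end - start),
                      confidence=conf, source="m")


class TestHarmonize:
    def test_overlap_keeps_highest_confidence(self):
        s1 = AnnotationSet([_ann(5, 10, 0.9)], "m1")
        s2 = AnnotationSet([_ann(8, 12, 0.7)], "m2")
        out = harmonize([s1, s2]).annotations
        assert [(a.start, a.end) for a in out] == [(5, 10)]

    def test_disjoint_all_kept(self):
        s1 = AnnotationSet([_ann(0, 4, 0.5)], "m1")
        s2 = AnnotationSet([_ann(10, 14, 0.4)], "m2")
        out = harmonize([s1, s2]).annotations
        assert len(out) == 2

    def test_three_way_chain_resolved_as_one_group(self):
        s1 = AnnotationSet([_ann(0, 5, 0.6), _ann(8, 12, 0.7)], "m1")
        s2 = AnnotationSet([_ann(4, 9, 0.8)], "m2")
        out = harmonize([s1, s2]).annotations
        assert [(a.start, a.end) for a in out] == [(4, 9)]

    def test_single_set_identity(self):
        s = AnnotationSet([_ann(0, 4, 0.5), _ann(10, 14, 0.9)], "m1")
        out = harmonize([s]).annotations
        assert [(a.start, a.end) for a in out] == [(0, 4), (10, 14)]

    def test_tie_break_earlier_start_then_longer(self):
        s1 = AnnotationSet([_ann(5, 9, 0.8)], "m1")
        s2 = AnnotationSet([_ann(3, 9, 0.8)], "m2")
        out = harmonize([s1, s2]).annotations
        assert [(a.start, a.end) for a in out] == [(3, 9)]

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_idempotence_and_validity(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for mid in ("m1", "m2", "m3"):
            anns, cursor = [], 0
            while cursor < 80:
                cursor += int(rng.integers(0, 8))
                length = int(rng.integers(1, 6))
                if rng.random() < 0.5:
                    anns.append(
                        _ann(cursor, cursor + length,
                             float(rng.uniform(0, 1)))
                    )
                cursor += length
            sets.append(AnnotationSet(anns, mid))
        merged = harmonize(sets)
        spans = [(a.start, a.end) for a in merged.annotations]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))
        again = harmonize([merged])
        assert [
            (a.start, a.end, a.confidence) for a in again.annotations
        ] == [
            (a.start, a.end, a.confidence) for a in merged.annotations
        ]
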
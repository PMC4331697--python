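"""Linear-chain conditional random fields for BIO chemical-mention tagging.

The engine trains maximum-likelihood linear-chain CRFs with L2 regularization
(L-BFGS optimization, log-space forward-backward batched across sentences).
Two model orders are supported:

* order 1 — states are the BIO labels themselves;
* order 2 — states are consecutive label pairs ("O|B", "B|I", ...), trained
  as a first-order chain over the expanded alphabet and projected back to
  BIO at decode time.  This is the classic state-expansion realization of a
  second-order chain.

Either parsing direction is available: ``backward`` reverses every sequence
before training and re-reverses at decode time.  A hard label grammar
(no ``I`` without a preceding ``B``/``I``, stated in the model's internal
direction) guarantees that decoding emits only valid BIO sequences.

Each decoded annotation carries a confidence in [0, 1]: by default the
marginal posterior probability of its exact label subsequence over its span,
computed by constrained forward-backward; a cheaper product-of-token-
marginals alternative is available via ``confidence_method``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from . import corpus_io
from .features import FeatureConfig
from .types import Annotation, Sentence

NEG_INF = -1e30  # effective -inf that survives arithmetic

_LABELS = ("O", "B", "I")


# ---------------------------------------------------------------------------
# label grammar and state spaces
# ---------------------------------------------------------------------------


def _grammar(direction: str) -> tuple[set, set, set]:
    """(start, transition, end) constraints over BIO in internal order.

    Forward: a sequence cannot start with I and O->I is forbidden.
    Backward (sequences reversed internally): I->O is forbidden and the
    internal last label (the original first) cannot be I.
    """
    if direction == "forward":
        start = {"O", "B"}
        trans = {(a, b) for a in _LABELS for b in _LABELS} - {("O", "I")}
        end = {"O", "B", "I"}
    elif direction == "backward":
        start = {"O", "B", "I"}
        trans = {(a, b) for a in _LABELS for b in _LABELS} - {("I", "O")}
        end = {"O", "B"}
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return start, trans, end


@dataclass
class _StateSpace:
    names: list[str]            # human-readable state names
    cur: list[str]              # BIO label emitted by each state
    start_mask: np.ndarray      # (S,) 0 / NEG_INF
    trans_mask: np.ndarray      # (S, S) 0 / NEG_INF
    end_mask: np.ndarray        # (S,) 0 / NEG_INF

    @property
    def n(self) -> int:
        return len(self.names)


def _build_states(order: int, direction: str) -> _StateSpace:
    start, trans, end = _grammar(direction)
    if order == 1:
        names = list(_LABELS)
        cur = list(_LABELS)
        start_mask = np.array(
            [0.0 if l in start else NEG_INF for l in names]
        )
        trans_mask = np.full((3, 3), NEG_INF)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if (a, b) in trans:
                    trans_mask[i, j] = 0.0
        end_mask = np.array([0.0 if l in end else NEG_INF for l in names])
        return _StateSpace(names, cur, start_mask, trans_mask, end_mask)

    if order == 2:
        pairs = [("^", c) for c in _LABELS if c in start]
        pairs += [(p, c) for p in _LABELS for c in _LABELS if (p, c) in trans]
        names = [f"{p}|{c}" for p, c in pairs]
        cur = [c for _, c in pairs]
        start_mask = np.array(
            [0.0 if p == "^" else NEG_INF for p, _ in pairs]
        )
        S = len(pairs)
        trans_mask = np.full((S, S), NEG_INF)
        for i, (_, c1) in enumerate(pairs):
            for j, (p2, _) in enumerate(pairs):
                if p2 == c1:
                    trans_mask[i, j] = 0.0
        end_mask = np.array([0.0 if c in end else NEG_INF for _, c in pairs])
        return _StateSpace(names, cur, start_mask, trans_mask, end_mask)

    raise ValueError(f"unsupported CRF order {order} (expected 1 or 2)")


def labels_to_states(labels: Sequence[str], order: int) -> list[str]:
    """Map a BIO sequence to state names (identity for order 1)."""
    if order == 1:
        return list(labels)
    out = []
    prev = "^"
    for lab in labels:
        out.append(f"{prev}|{lab}")
        prev = lab
    return out


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(m <= NEG_INF / 2, 0.0, m)
    with np.errstate(divide="ignore"):
        out = np.squeeze(m_safe, axis=axis) + np.log(
            np.sum(np.exp(a - m_safe), axis=axis)
        )
    return np.where(
        np.squeeze(m, axis=axis) <= NEG_INF / 2, NEG_INF, out
    )


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class CRFModel:
    """A trainable/decodable linear-chain CRF of order 1 or 2.

    Parameters
    ----------
    order : 1 or 2
    direction : "forward" or "backward" parsing
    l2 : inverse variance of the Gaussian prior (1.0 = variance 1)
    max_iter : optimizer iteration cap
    seed : recorded for provenance (training itself is deterministic)
    confidence_method : "span_marginal" (constrained forward-backward) or
        "token_product" (product of per-token marginals)
    """

    order: int = 1
    direction: str = "forward"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    l2: float = 1.0
    max_iter: int = 500
    seed: int = 42
    confidence_method: str = "span_marginal"
    model_id: Optional[str] = None

    def __post_init__(self) -> None:
        self._states = _build_states(self.order, self.direction)
        self._feat_index: dict[str, int] = {}
        self._w_emit: Optional[np.ndarray] = None   # (F, S)
        self._w_trans: Optional[np.ndarray] = None  # (S, S)
        self._w_init: Optional[np.ndarray] = None   # (S,)
        self._w_end: Optional[np.ndarray] = None    # (S,)
        self.training_meta: dict = {}
        if self.model_id is None:
            self.model_id = f"crf-o{self.order}-{self.direction}"

    # -- data preparation ---------------------------------------------------

    def _internalize(self, feats, labels=None):
        """Reverse sequences for backward models."""
        if self.direction == "backward":
            feats = list(reversed(feats))
            labels = list(reversed(labels)) if labels is not None else None
        return feats, labels

    def _rows(self, feats: Sequence[Sequence[str]], grow: bool) -> sp.csr_matrix:
        indptr = [0]
        indices: list[int] = []
        for token_feats in feats:
            cols = set()
            for f in token_feats:
                idx = self._feat_index.get(f)
                if idx is None and grow:
                    idx = len(self._feat_index)
                    self._feat_index[f] = idx
                if idx is not None:
                    cols.add(idx)
            indices.extend(sorted(cols))
            indptr.append(len(indices))
        data = np.ones(len(indices))
        n_feat = max(len(self._feat_index), 1)
        return sp.csr_matrix(
            (data, indices, indptr), shape=(len(feats), n_feat)
        )

    # -- training -----------------------------------------------------------

    def fit(
        self,
        sequences: Sequence[tuple[Sequence[Sequence[str]], Sequence[str]]],
        tol: float = 1e-3,
    ) -> "CRFModel":
        """Train on (per-token feature lists, BIO labels) pairs."""
        if not sequences:
            raise ValueError("cannot train on an empty corpus")
        S = self._states.n
        state_of = {name: i for i, name in enumerate(self._states.names)}

        xs: list[sp.csr_matrix] = []
        ys: list[np.ndarray] = []
        for feats, labels in sequences:
            if len(feats) != len(labels):
                raise ValueError("feature/label length mismatch")
            if not feats:
                continue
            prev = "O"
            for lab in labels:
                if lab not in _LABELS or (lab == "I" and prev == "O"):
                    raise ValueError(
                        f"invalid BIO sequence {list(labels)}"
                    )
                prev = lab
            feats, labels = self._internalize(list(feats), list(labels))
            try:
                y = np.array(
                    [state_of[s] for s in labels_to_states(labels, self.order)]
                )
            except KeyError as exc:
                raise ValueError(
                    f"invalid BIO sequence {list(labels)}"
                ) from exc
            xs.append(self._rows(feats, grow=True))
            ys.append(y)
        if not xs:
            raise ValueError("cannot train on an empty corpus")

        F = len(self._feat_index)
        xs = [
            sp.csr_matrix((x.data, x.indices, x.indptr), shape=(x.shape[0], F))
            for x in xs
        ]
        X = sp.vstack(xs, format="csr")
        lengths = np.array([x.shape[0] for x in xs])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        N = int(offsets[-1])
        n_seq = len(xs)
        T_max = int(lengths.max())

        # empirical sufficient statistics
        y_flat = np.concatenate(ys)
        Y = np.zeros((N, S))
        Y[np.arange(N), y_flat] = 1.0
        emp_emit = np.asarray((X.T @ Y))
        emp_trans = np.zeros((S, S))
        emp_init = np.zeros(S)
        emp_end = np.zeros(S)
        for y in ys:
            emp_init[y[0]] += 1
            emp_end[y[-1]] += 1
            np.add.at(emp_trans, (y[:-1], y[1:]), 1.0)

        # padded index grid: pos_idx[k, t] = flat index of token t of seq k
        pos_idx = np.zeros((n_seq, T_max), dtype=np.int64)
        active = np.zeros((n_seq, T_max), dtype=bool)
        for k, L in enumerate(lengths):
            pos_idx[k, :L] = np.arange(offsets[k], offsets[k] + L)
            active[k, :L] = True
        last_t = lengths - 1

        start_m = self._states.start_mask
        trans_m = self._states.trans_mask
        end_m = self._states.end_mask

        n_params = F * S + S * S + 2 * S

        def unpack(w):
            we = w[: F * S].reshape(F, S)
            wt = w[F * S : F * S + S * S].reshape(S, S)
            wi = w[F * S + S * S : F * S + S * S + S]
            wn = w[F * S + S * S + S :]
            return we, wt, wi, wn

        gold_scores_cache = {}

        def objective(w):
            we, wt, wi, wn = unpack(w)
            E_flat = np.asarray(X @ we)                    # (N, S)
            E = np.where(active[:, :, None], E_flat[pos_idx], 0.0)
            M = wt + trans_m

            # batched forward
            alpha = np.empty((n_seq, T_max, S))
            alpha[:, 0] = wi + start_m + E[:, 0]
            for t in range(1, T_max):
                step = _logsumexp(
                    alpha[:, t - 1, :, None] + M[None], axis=1
                ) + E[:, t]
                alpha[:, t] = np.where(
                    active[:, t, None], step, alpha[:, t - 1]
                )
            final = alpha[np.arange(n_seq), last_t] + (wn + end_m)[None]
            logZ = _logsumexp(final, axis=1)

            # batched backward; padded tail stays at NEG_INF (exp -> 0)
            beta = np.full((n_seq, T_max, S), NEG_INF)
            beta[np.arange(n_seq), last_t] = wn + end_m
            for t in range(T_max - 2, -1, -1):
                nxt = E[:, t + 1] + beta[:, t + 1]
                step = _logsumexp(M[None] + nxt[:, None, :], axis=2)
                is_before_end = (t < last_t)[:, None]
                beta[:, t] = np.where(is_before_end, step, beta[:, t])

            # marginals and expectations
            gamma = np.exp(alpha + beta - logZ[:, None, None])
            gamma = np.where(active[:, :, None], gamma, 0.0)
            P_flat = np.zeros((N, S))
            P_flat[pos_idx[active]] = gamma[active]

            exp_trans = np.zeros((S, S))
            for t in range(1, T_max):
                live = active[:, t]
                if not live.any():
                    break
                xi = np.exp(
                    alpha[live, t - 1, :, None]
                    + M[None]
                    + (E[live, t] + beta[live, t])[:, None, :]
                    - logZ[live, None, None]
                )
                exp_trans += xi.sum(axis=0)
            exp_init = gamma[:, 0].sum(axis=0)
            exp_end = gamma[np.arange(n_seq), last_t].sum(axis=0)

            # gold path scores
            gold = (
                emp_emit.ravel() @ we.ravel()
                + (emp_trans * wt).sum()
                + emp_init @ wi
                + emp_end @ wn
            )
            nll = float(logZ.sum() - gold)
            grad_emit = np.asarray(X.T @ P_flat) - emp_emit
            grad = np.concatenate([
                grad_emit.ravel(),
                (exp_trans - emp_trans).ravel(),
                exp_init - emp_init,
                exp_end - emp_end,
            ])
            nll += 0.5 * self.l2 * float(w @ w)
            grad += self.l2 * w
            return nll, grad

        w0 = np.zeros(n_params)
        res = scipy.optimize.minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": tol, "ftol": 1e-9},
        )
        we, wt, wi, wn = unpack(res.x)
        self._w_emit, self._w_trans = we, wt
        self._w_init, self._w_end = wi, wn
        self.training_meta = {
            "iterations": int(res.nit),
            "converged": bool(res.success),
            "final_nll": float(res.fun),
            "n_sequences": n_seq,
            "n_features": F,
            "l2": self.l2,
            "seed": self.seed,
        }
        return self

    # -- lattice helpers ----------------------------------------------------

    def _require_fitted(self):
        if self._w_emit is None:
            raise RuntimeError("model is not trained")

    def _emissions(self, feats: Sequence[Sequence[str]]) -> np.ndarray:
        """(T, S) emission scores in internal order (already reversed)."""
        X = self._rows(feats, grow=False)
        return np.asarray(X @ self._w_emit)

    def _lattice(self, feats):
        E = self._emissions(feats)
        M = self._w_trans + self._states.trans_mask
        init = self._w_init + self._states.start_mask
        end = self._w_end + self._states.end_mask
        return E, M, init, end

    def _forward_logZ(self, E, M, init, end, pin=None) -> float:
        """log partition; ``pin`` maps internal position -> required BIO."""
        T, S = E.shape
        cur = np.array(self._states.cur)
        a = init + E[0]
        if pin and 0 in pin:
            a = np.where(cur == pin[0], a, NEG_INF)
        for t in range(1, T):
            a = _logsumexp(a[:, None] + M, axis=0) + E[t]
            if pin and t in pin:
                a = np.where(cur == pin[t], a, NEG_INF)
        return float(_logsumexp((a + end)[None], axis=1)[0])

    def sequence_logprob(self, feats, labels) -> float:
        """Log probability of a full BIO labeling (internal reversal applied)."""
        self._require_fitted()
        feats, labels = self._internalize(list(feats), list(labels))
        E, M, init, end = self._lattice(feats)
        state_of = {n: i for i, n in enumerate(self._states.names)}
        y = [state_of[s] for s in labels_to_states(labels, self.order)]
        score = init[y[0]] + E[0, y[0]]
        for t in range(1, len(y)):
            score += M[y[t - 1], y[t]] + E[t, y[t]]
        score += end[y[-1]]
        return float(score - self._forward_logZ(E, M, init, end))

    def span_probability(self, feats, start_tok: int, end_tok: int) -> float:
        """Posterior probability that tokens [start_tok, end_tok) form one
        mention labeled exactly B I ... I (constrained forward-backward)."""
        self._require_fitted()
        T = len(feats)
        pattern = {start_tok: "B"}
        for t in range(start_tok + 1, end_tok):
            pattern[t] = "I"
        if self.direction == "backward":
            pattern = {T - 1 - t: lab for t, lab in pattern.items()}
        feats, _ = self._internalize(list(feats))
        E, M, init, end = self._lattice(feats)
        logZ = self._forward_logZ(E, M, init, end)
        logZc = self._forward_logZ(E, M, init, end, pin=pattern)
        return float(np.exp(min(logZc - logZ, 0.0)))

    def token_marginals(self, feats) -> np.ndarray:
        """(T, 3) per-token posterior over BIO labels (original order)."""
        self._require_fitted()
        feats, _ = self._internalize(list(feats))
        E, M, init, end = self._lattice(feats)
        T, S = E.shape
        alpha = np.empty((T, S))
        beta = np.empty((T, S))
        alpha[0] = init + E[0]
        for t in range(1, T):
            alpha[t] = _logsumexp(alpha[t - 1][:, None] + M, axis=0) + E[t]
        beta[T - 1] = end
        for t in range(T - 2, -1, -1):
            beta[t] = _logsumexp(M + (E[t + 1] + beta[t + 1])[None, :], axis=1)
        logZ = _logsumexp((alpha[T - 1] + end)[None], axis=1)[0]
        post = np.exp(alpha + beta - logZ)
        out = np.zeros((T, 3))
        for s, lab in enumerate(self._states.cur):
            out[:, _LABELS.index(lab)] += post[:, s]
        if self.direction == "backward":
            out = out[::-1]
        return out

    # -- decoding -----------------------------------------------------------

    def predict(self, feats: Sequence[Sequence[str]]) -> list[str]:
        """Viterbi-best BIO labeling (original token order)."""
        self._require_fitted()
        if not feats:
            return []
        feats, _ = self._internalize(list(feats))
        E, M, init, end = self._lattice(feats)
        T, S = E.shape
        delta = init + E[0]
        back = np.zeros((T, S), dtype=np.int64)
        for t in range(1, T):
            scores = delta[:, None] + M
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(S)] + E[t]
        delta = delta + end
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        labels = [self._states.cur[s] for s in path]
        if self.direction == "backward":
            labels.reverse()
        return labels

    def decode(
        self,
        sentence: Sentence,
        feats: Sequence[Sequence[str]],
        section_text: str,
    ) -> list[Annotation]:
        """Annotate one sentence: Viterbi spans with posterior confidences."""
        labels = self.predict(feats)
        anns = corpus_io.decode_bio(
            sentence, labels, section_text, source=self.model_id
        )
        tok_start = {t.start: i for i, t in enumerate(sentence.tokens)}
        tok_end = {t.end: i for i, t in enumerate(sentence.tokens)}
        if self.confidence_method == "token_product":
            marg = self.token_marginals(feats)
        for ann in anns:
            i = tok_start[ann.start]
            j = tok_end[ann.end] + 1
            if self.confidence_method == "span_marginal":
                conf = self.span_probability(feats, i, j)
            elif self.confidence_method == "token_product":
                conf = float(marg[i, 1])
                for t in range(i + 1, j):
                    conf *= float(marg[t, 2])
            else:
                raise ValueError(
                    f"unknown confidence method {self.confidence_method!r}"
                )
            ann.confidence = min(max(conf, 0.0), 1.0)
        return anns

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self._require_fitted()
        feats = np.array(
            sorted(self._feat_index, key=self._feat_index.get), dtype=object
        )
        meta = {
            "format_version": 1,
            "order": self.order,
            "direction": self.direction,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "confidence_method": self.confidence_method,
            "model_id": self.model_id,
            "training_meta": self.training_meta,
            "feature_config": {
                "enabled_groups": sorted(self.feature_config.enabled_groups),
                "ngram_lengths": list(self.feature_config.ngram_lengths),
                "affix_lengths": list(self.feature_config.affix_lengths),
                "context_windows": [
                    list(w) for w in self.feature_config.context_windows
                ],
            },
        }
        np.savez_compressed(
            path,
            meta=np.array(json.dumps(meta)),
            features=feats,
            w_emit=self._w_emit,
            w_trans=self._w_trans,
            w_init=self._w_init,
            w_end=self._w_end,
        )

    @classmethod
    def load(cls, path) -> "CRFModel":
        with np.load(path, allow_pickle=True) as z:
            meta = json.loads(str(z["meta"]))
            fc = meta["feature_config"]
            model = cls(
                order=meta["order"],
                direction=meta["direction"],
                feature_config=FeatureConfig(
                    enabled_groups=frozenset(fc["enabled_groups"]),
                    ngram_lengths=tuple(fc["ngram_lengths"]),
                    affix_lengths=tuple(fc["affix_lengths"]),
                    context_windows=tuple(
                        tuple(w) for w in fc["context_windows"]
                    ),
                ),
                l2=meta["l2"],
                max_iter=meta["max_iter"],
                seed=meta["seed"],
                confidence_method=meta["confidence_method"],
                model_id=meta["model_id"],
            )
            model.training_meta = meta["training_meta"]
            model._feat_index = {
                str(f): i for i, f in enumerate(z["features"])
            }
            model._w_emit = z["w_emit"]
            model._w_trans = z["w_trans"]
            model._w_init = z["w_init"]
            model._w_end = z["w_end"]
        return model


def train_crf(
    sequences,
    order: int = 1,
    direction: str = "forward",
    feature_config: Optional[FeatureConfig] = None,
    l2: float = 1.0,
    max_iter: int = 500,
    seed: int = 42,
    **kwargs,
) -> CRFModel:
    """Convenience wrapper: build and fit a :class:`CRFModel`."""
    model = CRFModel(
        order=order,
        direction=direction,
        feature_config=feature_config or FeatureConfig(),
        l2=l2,
        max_iter=max_iter,
        seed=seed,
        **kwargs,
    )
    return model.fit(sequences)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Annotations produced by one model; internally non-overlapping."""

    annotations: list[Annotation]
    model_id: str


def harmonize(sets: Sequence[AnnotationSet]) -> AnnotationSet:
    """Merge annotation sets from several models.

    Annotations that intersect nothing from any other set are all kept; in
    each maximal group of mutually chain-overlapping annotations exactly the
    highest-confidence one survives, ties broken by earlier start, then
    longer span, then lexicographically smaller model id.
    """
    tagged: list[tuple[Annotation, str]] = []
    for s in sets:
        from .types import check_non_overlapping

        check_non_overlapping(s.annotations)
        tagged.extend((a, s.model_id) for a in s.annotations)

    by_key: dict[tuple[str, str], list[tuple[Annotation, str]]] = {}
    for a, mid in tagged:
        by_key.setdefault((a.doc_id, a.section), []).append((a, mid))

    kept: list[Annotation] = []
    for group in by_key.values():
        group.sort(key=lambda am: (am[0].start, am[0].end))
        cluster: list[tuple[Annotation, str]] = []
        cluster_end = -1
        for a, mid in group:
            if cluster and a.start >= cluster_end:
                kept.append(_pick(cluster))
                cluster = []
                cluster_end = -1
            cluster.append((a, mid))
            cluster_end = max(cluster_end, a.end)
        if cluster:
            kept.append(_pick(cluster))
    kept.sort(key=lambda a: (a.doc_id, a.section, a.start, a.end))
    return AnnotationSet(kept, model_id="harmonized")


def _pick(cluster: list[tuple[Annotation, str]]) -> Annotation:
    best = min(
        cluster,
        key=lambda am: (
            -am[0].confidence,
            am[0].start,
            -(am[0].end - am[0].start),
            am[1],
        ),
    )
    return best[0]
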
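"""Synthetic CHEMDNER-style corpora for download-free training and testing.

The generator emits abstracts built from sentence templates with planted
chemical mentions of all seven annotation classes, exact gold offsets, and a
matching lexicon.  Mention context carries learnable signal ("treatment with
X", "levels of X"), mention surfaces carry class-typical morphology
(locant-dash-stem systematic names, element-count formulas, pluralized
family suffixes), and homograph trap terms ("lead", "gold", ...) appear both
as chemicals and as ordinary words to exercise the exclusion-list machinery.

``corrupt_predictions`` derives simulated system output from gold by seeded
span deletion (false negatives), trap-term injection (false positives) and
token-snapped boundary jitter, for evaluation and threshold-tuning tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import Lexicon
from .linguistic import _load_resource_lines
from .types import Annotation, Document

DEFAULT_CLASS_MIX = {
    "SYSTEMATIC": 0.25,
    "TRIVIAL": 0.30,
    "ABBREVIATION": 0.12,
    "FAMILY": 0.15,
    "FORMULA": 0.10,
    "IDENTIFIER": 0.05,
    "MULTIPLE": 0.03,
}

DEFAULT_TRAP_TERMS = ("lead", "gold", "iron", "mercury")


@dataclass
class GeneratorConfig:
    n_docs: int = 200
    seed: int = 0
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    #: (mean, dispersion) of the per-document mention count; dispersion 0
    #: gives a Poisson, larger values overdisperse (negative binomial).
    mentions_per_doc: tuple = (6.0, 0.3)
    abbrev_rate: float = 0.3
    fp_trap_terms: tuple = DEFAULT_TRAP_TERMS
    #: fraction of generated non-trivial mention surfaces added to the lexicon
    lexicon_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6 or any(
            v < 0 for v in self.class_mix.values()
        ):
            raise ValueError(f"class_mix must be a distribution (sum={total})")
        if not 0.0 <= self.abbrev_rate <= 1.0:
            raise ValueError("abbrev_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# mention grammars
# ---------------------------------------------------------------------------

_LOCANTS = ["1", "2", "3", "4", "5", "6", "1,2", "1,3", "2,4", "3,5", "N"]
_SUBSTITUENTS = [
    "methyl", "ethyl", "propyl", "butyl", "chloro", "bromo", "fluoro",
    "hydroxy", "amino", "nitro", "acetyl", "benzyl", "phenyl", "methoxy",
    "dimethyl", "diethyl", "dichloro", "acetoxy",
]
_CORES = [
    "benzene", "phenol", "aniline", "toluene", "pyridine", "indole",
    "imidazole", "furan", "pyrrole", "quinoline", "benzoic acid",
    "propanoic acid", "butanamide", "hexanoate", "pyrimidine",
]
_FAMILIES = [
    "benzodiazepines", "statins", "sulfonamides", "opioids", "barbiturates",
    "phenothiazines", "quinolones", "corticosteroids", "prostaglandins",
    "flavonoids", "alkaloids", "terpenoids", "catecholamines", "polyphenols",
    "anthracyclines", "taxanes", "nitrosamines", "porphyrins",
]
_ABBREV_PAIRS = [
    ("gamma aminobutyric acid", "GABA"),
    ("nitric oxide", "NO"),
    ("carbon monoxide", "CO"),
    ("adenosine triphosphate", "ATP"),
    ("polyethylene glycol", "PEG"),
    ("dimethyl sulfoxide", "DMSO"),
    ("ethylenediaminetetraacetic acid", "EDTA"),
    ("bovine serum albumin", "BSA"),
    ("nonsteroidal anti-inflammatory drugs", "NSAIDs"),
    ("reactive oxygen species", "ROS"),
    ("ethanol", "EtOH"),
    ("docosahexaenoic acid", "DHA"),
]
_STANDALONE_ABBREVS = [
    "DNA", "RNA", "LPS", "THC", "PCB", "TNT", "DDT", "MSG", "BPA", "PFOA",
]


def _load_trivial_names() -> list[str]:
    return _load_resource_lines("trivial_names.txt")


def _load_elements() -> list[tuple[str, str]]:
    out = []
    for line in _load_resource_lines("elements.txt"):
        symbol, name = line.split("\t")
        out.append((symbol, name))
    return out


class _MentionFactory:
    def __init__(self, rng: np.random.Generator, trap_terms: Sequence[str]):
        self.rng = rng
        self.trivial = _load_trivial_names()
        self.elements = _load_elements()
        self.trap_terms = list(trap_terms)

    def _choice(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def systematic(self) -> str:
        loc = self._choice(_LOCANTS)
        sub = self._choice(_SUBSTITUENTS)
        core = self._choice(_CORES)
        if self.rng.random() < 0.25:
            inner = self._choice(_SUBSTITUENTS)
            return f"{loc}-({inner}amino){core}"
        return f"{loc}-{sub}{core}"

    def formula(self) -> str:
        n = int(self.rng.integers(2, 4))
        parts = []
        for _ in range(n):
            sym, _name = self._choice(self.elements)
            count = int(self.rng.integers(1, 13))
            parts.append(sym + (str(count) if count > 1 else ""))
        return "".join(parts)

    def trivial_name(self) -> str:
        if self.trap_terms and self.rng.random() < 0.10:
            return self._choice(self.trap_terms)
        return self._choice(self.trivial)

    def family(self) -> str:
        return self._choice(_FAMILIES)

    def identifier(self) -> str:
        kind = self.rng.random()
        if kind < 0.4:
            return f"CHEBI:{int(self.rng.integers(1000, 99999))}"
        if kind < 0.7:
            return f"CID{int(self.rng.integers(100, 999999))}"
        return (
            f"{int(self.rng.integers(50, 9999))}-"
            f"{int(self.rng.integers(10, 99))}-"
            f"{int(self.rng.integers(0, 9))}"
        )

    def multiple(self) -> str:
        l1, l2 = self._choice(_LOCANTS[:6]), self._choice(_LOCANTS[:6])
        sub = self._choice(_SUBSTITUENTS)
        core = self._choice(_CORES)
        return f"{l1}- and {l2}-{sub}{core}"

    def abbreviation(self) -> str:
        pool = [sf for _, sf in _ABBREV_PAIRS] + _STANDALONE_ABBREVS
        return self._choice(pool)

    def make(self, cls: str) -> str:
        return {
            "SYSTEMATIC": self.systematic,
            "TRIVIAL": self.trivial_name,
            "FAMILY": self.family,
            "FORMULA": self.formula,
            "IDENTIFIER": self.identifier,
            "MULTIPLE": self.multiple,
            "ABBREVIATION": self.abbreviation,
        }[cls]()


# ---------------------------------------------------------------------------
# sentence templates
# ---------------------------------------------------------------------------

_TITLE_TEMPLATES = [
    "Effects of {M} on hepatic function in rats.",
    "Randomized trial of {M} in chronic disease.",
    "Quantification of {M} in human plasma.",
    "{M} modulates oxidative stress in vivo.",
    "Interaction between {M} and {M2} in cell culture.",
]
_TITLE_PLAIN = [
    "A prospective cohort study of dietary patterns.",
    "Outcomes after elective surgery in older adults.",
    "Imaging findings in early disease stages.",
]
_MENTION_TEMPLATES = [
    "Treatment with {M} significantly reduced plasma marker levels.",
    "The effects of {M} on liver function were investigated.",
    "{M} was administered at a dose of {num} mg/kg daily.",
    "Exposure to {M} increased the activity of hepatic enzymes.",
    "We measured the concentration of {M} in serum samples.",
    "Pretreatment with {M} attenuated the response induced by {M2}.",
    "{M} inhibited the oxidation of {M2} in vitro.",
    "Levels of {M} increased after treatment with {M2}.",
    "Cells were incubated with {M} for 24 h.",
    "Co-administration of {M} and {M2} improved survival rates.",
    "Serum concentrations of {M} were elevated in treated animals.",
    "Dietary supplementation with {M} restored enzyme activity.",
]
_FILLER_TEMPLATES = [
    "The study included {num} participants from three centers.",
    "Samples were collected after an overnight fast.",
    "Statistical analysis was performed using standard methods.",
    "The results were consistent across all treatment groups.",
    "Baseline characteristics did not differ between groups.",
    "Follow-up examinations were scheduled every four weeks.",
]
_TRAP_SENTENCES = {
    "lead": "Participants were asked to lead a normal life during follow-up.",
    "gold": "The gold standard method was used for validation.",
    "iron": "The investigators had to iron out several protocol issues.",
    "mercury": "The mercury column of the manometer was read twice daily.",
}
_ABBREV_TEMPLATE = "{LONG} ({SHORT}) was evaluated for safety and efficacy."

_SLOT_RE = re.compile(r"\{(\w+)\}")


def _fill(
    template: str, values: dict[str, tuple[str, Optional[str]]]
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """Render a template; return text and (start, end, text, cls) spans."""
    out: list[str] = []
    spans: list[tuple[int, int, str, str]] = []
    pos = 0
    length = 0
    for m in _SLOT_RE.finditer(template):
        out.append(template[pos : m.start()])
        length += m.start() - pos
        text, cls = values[m.group(1)]
        if cls is not None:
            spans.append((length, length + len(text), text, cls))
        out.append(text)
        length += len(text)
        pos = m.end()
    out.append(template[pos:])
    return "".join(out), spans


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _mention_count(rng: np.random.Generator, mean: float, disp: float) -> int:
    if disp <= 0:
        n = rng.poisson(mean)
    else:
        r = 1.0 / disp
        p = r / (r + mean)
        n = rng.negative_binomial(r, p)
    return max(1, int(n))


class _SectionBuilder:
    def __init__(self) -> None:
        self.text = ""
        self.spans: list[tuple[int, int, str, str]] = []

    def add(self, sent_text: str, spans) -> None:
        if self.text:
            self.text += " "
        base = len(self.text)
        self.text += sent_text
        self.spans.extend(
            (base + s, base + e, t, c) for s, e, t, c in spans
        )


def generate_corpus(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[Document], list[Annotation], Lexicon]:
    """Deterministically generate (documents, gold annotations, lexicon)."""
    rng = np.random.default_rng(config.seed)
    factory = _MentionFactory(rng, config.fp_trap_terms)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    probs = probs / probs.sum()
    mean, disp = config.mentions_per_doc

    docs: list[Document] = []
    gold: list[Annotation] = []
    lexicon_extra: set[str] = set()

    def sample_mention() -> tuple[str, str]:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        text = factory.make(cls)
        if (
            cls in ("SYSTEMATIC", "FAMILY", "FORMULA")
            and rng.random() < config.lexicon_fraction
        ):
            lexicon_extra.add(text)
        return text, cls

    for i in range(config.n_docs):
        doc_id = f"SYN{i:05d}"

        # --- title ---
        title_b = _SectionBuilder()
        if rng.random() < 0.7:
            tmpl = _TITLE_TEMPLATES[int(rng.integers(len(_TITLE_TEMPLATES)))]
            values = {}
            for slot in _SLOT_RE.findall(tmpl):
                if slot.startswith("M"):
                    values[slot] = sample_mention()
            title_b.add(*_fill(tmpl, values))
        else:
            title_b.add(
                _TITLE_PLAIN[int(rng.integers(len(_TITLE_PLAIN)))], []
            )

        # --- abstract ---
        ab = _SectionBuilder()
        target = _mention_count(rng, mean, disp)
        placed = 0

        if rng.random() < config.abbrev_rate:
            long_form, short_form = _ABBREV_PAIRS[
                int(rng.integers(len(_ABBREV_PAIRS)))
            ]
            sent, spans = _fill(
                _ABBREV_TEMPLATE,
                {
                    "LONG": (long_form, "TRIVIAL"),
                    "SHORT": (short_form, "ABBREVIATION"),
                },
            )
            ab.add(sent, spans)
            placed += 2

        while placed < target and len(ab.spans) < 40:
            if rng.random() < 0.3:
                ab.add(*_filler(rng, factory, config))
                continue
            tmpl = _MENTION_TEMPLATES[
                int(rng.integers(len(_MENTION_TEMPLATES)))
            ]
            values: dict[str, tuple[str, Optional[str]]] = {}
            for slot in _SLOT_RE.findall(tmpl):
                if slot.startswith("M"):
                    values[slot] = sample_mention()
                    placed += 1
                elif slot == "num":
                    num = ["0.5", "1", "2.5", "10", "25", "100"]
                    values[slot] = (
                        num[int(rng.integers(len(num)))], None,
                    )
            ab.add(*_fill(tmpl, values))
        if rng.random() < 0.5:
            ab.add(*_filler(rng, factory, config))

        docs.append(Document(doc_id, title_b.text, ab.text))
        for section, builder in (("T", title_b), ("A", ab)):
            for s, e, t, c in builder.spans:
                gold.append(
                    Annotation(doc_id, section, s, e, t, cls=c,
                               confidence=1.0, source="gold")
                )

    lexicon = Lexicon(factory.trivial)
    for _sym, name in factory.elements:
        lexicon.add(name)
    for term in sorted(lexicon_extra):
        lexicon.add(term)
    for distractor in ("standard", "normal", "baseline"):
        lexicon.add(distractor)
    return docs, gold, lexicon


def _filler(rng, factory, config) -> tuple[str, list]:
    """A sentence with no gold mention, occasionally a trap homograph."""
    if config.fp_trap_terms and rng.random() < 0.35:
        term = config.fp_trap_terms[
            int(rng.integers(len(config.fp_trap_terms)))
        ]
        sent = _TRAP_SENTENCES.get(
            term, f"The term {term} appeared in the study questionnaire."
        )
        return sent, []
    tmpl = _FILLER_TEMPLATES[int(rng.integers(len(_FILLER_TEMPLATES)))]
    num = str(int(rng.integers(20, 500)))
    sent, _ = _fill(tmpl, {"num": (num, None)})
    return sent, []


# ---------------------------------------------------------------------------
# prediction corruption
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\S+")


def _jitter_span(
    text: str, start: int, end: int, rng: np.random.Generator
) -> Optional[tuple[int, int]]:
    """Shift one boundary to an adjacent word boundary."""
    words = [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    if rng.random() < 0.5:
        prev = [w for w in words if w[1] <= start]
        if prev:
            return prev[-1][0], end
    nxt = [w for w in words if w[0] >= end]
    if nxt:
        return start, nxt[0][1]
    prev = [w for w in words if w[1] <= start]
    if prev:
        return prev[-1][0], end
    return None


def corrupt_predictions(
    gold: Sequence[Annotation],
    documents: Sequence[Document],
    seed: int = 0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    boundary_jitter: float = 0.0,
    trap_terms: Sequence[str] = DEFAULT_TRAP_TERMS,
) -> list[Annotation]:
    """Simulate system output from gold annotations.

    Gold spans are dropped with probability ``fn_rate``; non-gold trap-term
    occurrences are injected with probability ``fp_rate``; surviving spans
    have one boundary moved to an adjacent word boundary with probability
    ``boundary_jitter``.  Confidences are synthetic: kept spans high,
    injected spans low, with overlapping ranges.
    """
    for rate in (fp_rate, fn_rate, boundary_jitter):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {d.doc_id: d for d in documents}
    preds: list[Annotation] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def free(doc_id, section, s, e) -> bool:
        return all(
            not (s < oe and os_ < e)
            for os_, oe in occupied.get((doc_id, section), ())
        )

    def claim(doc_id, section, s, e) -> None:
        occupied.setdefault((doc_id, section), []).append((s, e))

    for g in gold:
        claim(g.doc_id, g.section, g.start, g.end)

    for g in gold:
        if rng.random() < fn_rate:
            continue
        text = by_id[g.doc_id].section_text(g.section)
        s, e = g.start, g.end
        conf = float(rng.uniform(0.6, 0.99))
        if boundary_jitter > 0 and rng.random() < boundary_jitter:
            moved = _jitter_span(text, s, e, rng)
            if moved is not None:
                ns, ne = moved
                # only move into territory not claimed by another span
                widened_ok = all(
                    (os_, oe) == (s, e) or not (ns < oe and os_ < ne)
                    for os_, oe in occupied.get((g.doc_id, g.section), ())
                )
                if widened_ok:
                    s, e = ns, ne
                    conf = float(rng.uniform(0.4, 0.8))
        preds.append(
            Annotation(g.doc_id, g.section, s, e, text[s:e],
                       confidence=conf, source="synthetic")
        )

    if fp_rate > 0:
        trap_re = re.compile(
            r"\b(" + "|".join(re.escape(t) for t in trap_terms) + r")\b",
            re.IGNORECASE,
        )
        for doc in documents:
            for section in ("T", "A"):
                text = doc.section_text(section)
                for m in trap_re.finditer(text):
                    if not free(doc.doc_id, section, m.start(), m.end()):
                        continue
                    if rng.random() < fp_rate:
                        claim(doc.doc_id, section, m.start(), m.end())
                        preds.append(
                            Annotation(
                                doc.doc_id, section, m.start(), m.end(),
                                m.group(),
                                confidence=float(rng.uniform(0.05, 0.7)),
                                source="synthetic-fp",
                            )
                        )
    preds.sort(key=lambda a: (a.doc_id, a.section, a.start, a.end))
    return preds


def write_corpus(docs, gold, lexicon, outdir) -> None:
    """Emit abstracts TSV, annotations TSV and lexicon file to a directory."""
    from pathlib import Path

    from . import corpus_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus_io.write_abstracts(docs, outdir / "abstracts.tsv")
    corpus_io.write_annotations(gold, outdir / "annotations.tsv")
    lexicon.to_file(outdir / "lexicon.txt")
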
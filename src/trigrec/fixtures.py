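"""Deterministic synthetic corpora plus the canonical worked-example
sentence.

:func:`worked_example_fixture` freezes one fully parsed, annotated sentence
("Down-regulation of interferon regulatory factor 4 gene expression in
leukemic cells.") whose tokenization, lemmas, POS tags, chunks and
dependency edges were calibrated once so that every documented feature
example is reproduced; only the calibrated fragments are relied on by
tests, the remaining edges are frozen arbitrary choices.

:func:`generate_corpus` emulates a trigger-annotated corpus at toy scale:
event-trigger words drawn from per-type lexicons are placed either in a
trigger context (followed by "of" plus a concept mention, and gold-labeled)
or, at the configured noise rate, in a non-trigger context; every trigger's
sentence contains at least one concept annotation.  Everything is
reproducible under the configured seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .core import Annotation
from .io_standoff import Document, attach_annotations, read_a1, \
    read_parsed_corpus

__all__ = ["FixtureSpec", "worked_example_fixture", "generate_corpus",
           "random_parse"]

WORKED_EXAMPLE_TEXT = (
    "Down-regulation of interferon regulatory factor 4 gene expression in "
    "leukemic cells."
)

# columns: index text start end lemma pos chunk_bio head(1-based; 0=root) label
_WORKED_EXAMPLE_CONLL = """\
0\tDown\t0\t4\tdown\tNN\tB-NP\t2\tNMOD
1\t-\t4\t5\t-\tHYPH\tO\t0\tROOT
2\tregulation\t5\t15\tregulation\tNN\tB-NP\t2\tOBJ
3\tof\t16\t18\tof\tIN\tB-PP\t3\tNMOD
4\tinterferon\t19\t29\tinterferon\tNN\tB-NP\t8\tNMOD
5\tregulatory\t30\t40\tregulatory\tJJ\tI-NP\t8\tNMOD
6\tfactor\t41\t47\tfactor\tNN\tI-NP\t8\tNMOD
7\t4\t48\t49\t4\tCD\tI-NP\t10\tNMOD
8\tgene\t50\t54\tgene\tNN\tI-NP\t10\tNMOD
9\texpression\t55\t65\texpression\tNN\tI-NP\t4\tPMOD
10\tin\t66\t68\tin\tPP\tB-PP\t3\tNMOD
11\tleukemic\t69\t77\tleukemic\tJJ\tB-NP\t13\tNMOD
12\tcells\t78\t83\tcell\tNNS\tI-NP\t11\tPMOD
13\t.\t83\t84\t.\t.\tO\t13\tP
"""

_WORKED_EXAMPLE_A1 = "T1\tProtein 19 49\tinterferon regulatory factor 4\n"

_WORKED_EXAMPLE_TRIGGERS = (
    "T2\tNegative_regulation 0 15\tDown-regulation\n"
    "T3\tGene_expression 55 65\texpression\n"
)


def worked_example_fixture(with_triggers: bool = True) -> Document:
    """The frozen worked-example document: one sentence, one Protein
    concept, and (optionally) its two gold triggers."""
    doc = read_parsed_corpus(
        io.StringIO(WORKED_EXAMPLE_TEXT), io.StringIO(_WORKED_EXAMPLE_CONLL),
        doc_id="example",
    )
    attach_annotations(
        doc, read_a1(io.StringIO(_WORKED_EXAMPLE_A1), doc.text, kind="concept")
    )
    if with_triggers:
        attach_annotations(
            doc, read_a1(io.StringIO(_WORKED_EXAMPLE_TRIGGERS), doc.text,
                         kind="trigger")
        )
    return doc


# --------------------------------------------------------------------------
# synthetic corpus generation
# --------------------------------------------------------------------------

_DEFAULT_TRIGGER_LEXICONS = {
    "Gene_expression": (
        "expression", "coexpression", "overexpression", "production",
        "synthesis",
    ),
    "Positive_regulation": (
        "activation", "induction", "upregulation", "stimulation",
        "enhancement",
    ),
}

_DEFAULT_CONCEPTS = (
    "IL-2", "STAT1", "interferon regulatory factor 4", "NF-kappaB",
    "TNF-alpha", "CD40 ligand", "IkB alpha", "c-Fos", "GATA3", "Bcl-2",
)

_SUBJECTS = ("cells", "monocytes", "lymphocytes", "fibroblasts", "thymocytes")
_VERBS = ("showed", "induced", "required", "mediated", "revealed")
_FILLERS = ("levels", "assays", "analysis", "studies", "profiles")
_TAILS = ("in", "culture", "during", "differentiation", "after", "treatment")
_FUNCTION_WORDS = frozenset(
    {"the", "of", "."} | set(_SUBJECTS) | set(_VERBS) | set(_FILLERS)
    | set(_TAILS)
)

_DEP_LABELS = ("SUB", "OBJ", "NMOD", "PMOD", "VMOD")


@dataclass
class FixtureSpec:
    """Conditions for a generated corpus.

    ``noise_rate`` is the fraction of trigger-lexicon emissions placed in
    non-trigger contexts; ``p_lexicon`` the fraction of sentences carrying a
    lexicon word at all.  Defaults give roughly 300 short sentences with two
    event types at 20% lexical noise.
    """

    n_documents: int = 60
    sentences_per_doc: int = 5
    trigger_lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_TRIGGER_LEXICONS)
    )
    concept_lexicon: tuple[str, ...] = _DEFAULT_CONCEPTS
    noise_rate: float = 0.2
    p_lexicon: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise rate must be in [0, 1]")
        for etype, lexicon in self.trigger_lexicons.items():
            if not lexicon:
                raise ValueError(f"empty trigger lexicon for {etype}")
            clash = set(lexicon) & _FUNCTION_WORDS
            if clash:
                raise ValueError(
                    f"lexicon for {etype} collides with function words: "
                    f"{sorted(clash)}"
                )


def random_parse(n: int, rng: np.random.Generator) -> list[tuple[int, int, str]]:
    """A random projective-style dependency tree over ``n`` tokens: each
    token attaches to an earlier one, so |E| = |V| - 1 and the graph is
    connected."""
    edges = []
    for i in range(1, n):
        head = int(rng.integers(0, i))
        label = _DEP_LABELS[int(rng.integers(0, len(_DEP_LABELS)))]
        edges.append((head, i, label))
    return edges


def _pos_of(word: str, role: str) -> str:
    if role == "det":
        return "DT"
    if role == "verb":
        return "VBD"
    if role == "prep":
        return "IN"
    if role == "punct":
        return "."
    if word.isdigit():
        return "CD"
    return "NN"


def _sentence_tokens(spec: FixtureSpec, rng: np.random.Generator):
    """Return (words, roles, trigger_slice|None, trigger_type|None,
    concept_slice|None, concept_name|None)."""

    def pick(seq):
        return seq[int(rng.integers(0, len(seq)))]

    words = ["the", pick(_SUBJECTS), pick(_VERBS)]
    roles = ["det", "noun", "verb"]
    trigger = concept = None
    trig_type = concept_name = None
    if rng.random() < spec.p_lexicon:
        trig_type = sorted(spec.trigger_lexicons)[
            int(rng.integers(0, len(spec.trigger_lexicons)))
        ]
        lex_word = pick(spec.trigger_lexicons[trig_type])
        is_noise = rng.random() < spec.noise_rate
        if not is_noise:
            # trigger context: "<trigger> of <concept>"
            trigger = (len(words), len(words) + 1)
            words.append(lex_word)
            roles.append("noun")
            words.append("of")
            roles.append("prep")
            concept_name = pick(spec.concept_lexicon)
            cwords = concept_name.split(" ")
            concept = (len(words), len(words) + len(cwords))
            words.extend(cwords)
            roles.extend(["noun"] * len(cwords))
        else:
            # noise context: lexicon word followed by a filler, no "of"
            words.append(lex_word)
            roles.append("noun")
            words.append(pick(_FILLERS))
            roles.append("noun")
            trig_type = None
    else:
        words.append(pick(_FILLERS))
        roles.append("noun")
    if concept is None and rng.random() < 0.5:
        words.append("in")
        roles.append("prep")
        concept_name = pick(spec.concept_lexicon)
        cwords = concept_name.split(" ")
        concept = (len(words), len(words) + len(cwords))
        words.extend(cwords)
        roles.extend(["noun"] * len(cwords))
    if rng.random() < 0.5:
        words.append(pick(_TAILS))
        roles.append("noun")
    words.append(".")
    roles.append("punct")
    return words, roles, trigger, trig_type, concept, concept_name


def generate_corpus(spec: FixtureSpec) -> list[Document]:
    """Generate a deterministic annotated toy corpus under ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    docs: list[Document] = []
    for d in range(spec.n_documents):
        text_parts: list[str] = []
        conll_lines: list[str] = []
        concept_lines: list[str] = []
        trigger_lines: list[str] = []
        offset = 0
        ann_counter = 0
        for _s in range(spec.sentences_per_doc):
            words, roles, trigger, trig_type, concept, _cname = \
                _sentence_tokens(spec, rng)
            starts, ends = [], []
            for i, w in enumerate(words):
                if text_parts:
                    text_parts.append(" ")
                    offset += 1
                starts.append(offset)
                offset += len(w)
                ends.append(offset)
                text_parts.append(w)
            n = len(words)
            edges = random_parse(n, rng)
            heads = {dep: (head + 1, label) for head, dep, label in edges}
            for i, w in enumerate(words):
                head, label = heads.get(i, (0, "ROOT"))
                chunk = "O" if roles[i] == "punct" else (
                    "B-PP" if roles[i] == "prep" else
                    "B-VP" if roles[i] == "verb" else "B-NP"
                )
                conll_lines.append(
                    "\t".join([
                        str(i), w, str(starts[i]), str(ends[i]), w.lower(),
                        _pos_of(w, roles[i]), chunk, str(head), label,
                    ])
                )
            conll_lines.append("")
            if concept is not None:
                ann_counter += 1
                cs, ce = starts[concept[0]], ends[concept[1] - 1]
                covered = "".join(text_parts)[cs:ce]
                concept_lines.append(f"T{ann_counter}\tProtein {cs} {ce}\t{covered}")
            if trigger is not None:
                ann_counter += 1
                ts, te = starts[trigger[0]], ends[trigger[1] - 1]
                covered = "".join(text_parts)[ts:te]
                trigger_lines.append(
                    f"T{ann_counter}\t{trig_type} {ts} {te}\t{covered}"
                )
        text = "".join(text_parts)
        doc = read_parsed_corpus(
            io.StringIO(text), io.StringIO("\n".join(conll_lines) + "\n"),
            doc_id=f"doc{d:03d}",
        )
        attach_annotations(
            doc,
            read_a1(io.StringIO("\n".join(concept_lines) + "\n"), text,
                    kind="concept") if concept_lines else [],
        )
        attach_annotations(
            doc,
            read_a1(io.StringIO("\n".join(trigger_lines) + "\n"), text,
                    kind="trigger") if trigger_lines else [],
        )
        docs.append(doc)
    return docs
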
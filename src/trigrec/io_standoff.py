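"""Readers and writers for the pipeline's external formats.

The canonical preprocessed input is a pair of files per document: the raw
UTF-8 text, and a CoNLL-style token table (one token per line, blank line
between sentences) with nine tab-separated columns::

    index  text  start  end  lemma  pos  chunk_bio  head  dep_label

``index`` is the 0-based position within the sentence; ``start``/``end`` are
document-absolute character offsets (end-exclusive); ``head`` is 1-based with
0 marking the root.  Concept and trigger annotations travel in BioNLP A1
standoff ("T<id> TAB type start end TAB text"); trigger dictionaries are TSV
with an identifier and a |-separated list of names; trigger output can be
written as A1, JSON or XML.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .core import Annotation, MalformedInputError, Sentence, build_sentence

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Dictionary",
    "ParseError",
    "IntegrityError",
    "read_parsed_corpus",
    "write_parsed_corpus",
    "read_a1",
    "write_a1",
    "read_dictionary_tsv",
    "write_dictionary_tsv",
    "write_output",
    "load_corpus_dir",
    "write_corpus_dir",
]

N_COLUMNS = 9


class ParseError(ValueError):
    """Malformed line in an input file; message carries the line number."""


class IntegrityError(ValueError):
    """Annotation offsets disagree with the document text."""


@dataclass
class Document:
    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def annotations(self, kind: str | None = None) -> list[Annotation]:
        out = []
        for s in self.sentences:
            for a in s.annotations:
                if kind is None or a.kind == kind:
                    out.append(a)
        return out

    def sentence_at(self, start: int, end: int) -> Sentence | None:
        for s in self.sentences:
            if s.start <= start and end <= s.end:
                return s
        return None


@dataclass
class Dictionary:
    """Trigger dictionary: identifier -> list of surface names, all tagging
    one event type."""

    event_type: str
    entries: dict[str, list[str]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        seen, out = set(), []
        for names in self.entries.values():
            for n in names:
                if n not in seen:
                    seen.add(n)
                    out.append(n)
        return out


def read_parsed_corpus(text_stream, conll_stream, doc_id: str = "doc") -> Document:
    """Build a :class:`Document` from raw text and its CoNLL-style table."""
    text = text_stream.read()
    sentences: list[Sentence] = []
    rows: list[tuple] = []
    edges: list[tuple[int, int, str]] = []
    chunk_tags: list[str] = []

    def flush() -> None:
        if not rows:
            return
        start, end = rows[0][2], rows[-1][3]
        sent = build_sentence(rows, edges, chunk_tags, sentence_text=text[start:end])
        sentences.append(sent)
        rows.clear()
        edges.clear()
        chunk_tags.clear()

    for lineno, line in enumerate(conll_stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush()
            continue
        cols = line.split("\t")
        if len(cols) != N_COLUMNS:
            raise ParseError(
                f"line {lineno}: expected {N_COLUMNS} columns, got {len(cols)}"
            )
        try:
            index = int(cols[0])
            start, end = int(cols[2]), int(cols[3])
            head = int(cols[7])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
        tok_text = cols[1]
        if text[start:end] != tok_text:
            raise ParseError(
                f"line {lineno}: token {tok_text!r} does not match document "
                f"text {text[start:end]!r} at [{start},{end})"
            )
        rows.append((index, tok_text, start, end, cols[4], cols[5]))
        chunk_tags.append(cols[6])
        if head > 0:
            edges.append((head - 1, index, cols[8]))
    flush()
    return Document(id=doc_id, text=text, sentences=sentences)


def write_parsed_corpus(doc: Document, conll_stream) -> None:
    """Serialize a document's sentences back to the CoNLL-style table."""
    for sent in doc.sentences:
        heads = {t.index: (0, "ROOT") for t in sent.tokens}
        for u, v, label, head in sent.graph.edges:
            dep = v if head == u else u
            heads[dep] = (head + 1, label)
        for t in sent.tokens:
            head, label = heads[t.index]
            conll_stream.write(
                "\t".join(
                    [
                        str(t.index),
                        t.text,
                        str(t.start),
                        str(t.end),
                        t.feature("LEMMA", ""),
                        t.feature("POS", ""),
                        sent.chunk_bio(t.index),
                        str(head),
                        label,
                    ]
                )
                + "\n"
            )
        conll_stream.write("\n")


def read_a1(stream, doc_text: str | None = None, kind: str = "concept"
            ) -> list[Annotation]:
    """Parse A1 standoff lines into annotations.

    Lines not starting with ``T`` (relations, events, comments) are skipped
    with a logged warning.  When ``doc_text`` is given, each annotation's
    covered text is checked against the document slice.
    """
    anns: list[Annotation] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("a1 line %d ignored (not a text-bound annotation)", lineno)
            continue
        try:
            ann_id, middle, covered = line.split("\t", 2)
            ann_type, start_s, end_s = middle.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(f"line {lineno}: malformed a1 record") from None
        if doc_text is not None and doc_text[start:end] != covered:
            raise IntegrityError(
                f"annotation {ann_id}: text {covered!r} does not match document "
                f"slice {doc_text[start:end]!r}"
            )
        anns.append(Annotation(ann_id, ann_type, start, end, covered, kind=kind))
    return anns


def write_a1(annotations: list[Annotation], stream) -> None:
    """One A1 line per annotation, ordered by start offset."""
    for ann in sorted(annotations, key=lambda a: (a.start, a.end, a.type)):
        stream.write(f"{ann.id}\t{ann.type} {ann.start} {ann.end}\t{ann.text}\n")


def next_annotation_id(existing: list[Annotation]) -> int:
    """Trigger ids continue after the highest numeric T-id already present."""
    highest = 0
    for ann in existing:
        if ann.id.startswith("T") and ann.id[1:].isdigit():
            highest = max(highest, int(ann.id[1:]))
    return highest + 1


def read_dictionary_tsv(stream, event_type: str) -> Dictionary:
    """Read a trigger dictionary: ``identifier<TAB>name|name|...`` per line."""
    entries: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if "\t" not in line:
            raise ParseError(f"line {lineno}: expected two tab-separated fields")
        ident, names_field = line.split("\t", 1)
        ident = ident.strip()
        names = [n.strip() for n in names_field.split("|") if n.strip()]
        if not names:
            raise ParseError(f"line {lineno}: entry {ident!r} has no names")
        if ident in entries:
            raise ParseError(f"line {lineno}: duplicate identifier {ident!r}")
        entries[ident] = names
    return Dictionary(event_type=event_type, entries=entries)


def write_dictionary_tsv(dictionary: Dictionary, stream) -> None:
    for ident, names in dictionary.entries.items():
        stream.write(f"{ident}\t{'|'.join(names)}\n")


def write_output(annotations: list[Annotation], fmt: str, stream) -> None:
    """Write annotations as ``a1``, ``json`` or ``xml``."""
    if fmt == "a1":
        write_a1(annotations, stream)
    elif fmt == "json":
        records = [
            {"id": a.id, "type": a.type, "start": a.start, "end": a.end,
             "text": a.text}
            for a in sorted(annotations, key=lambda a: (a.start, a.end, a.type))
        ]
        json.dump(records, stream, indent=1)
        stream.write("\n")
    elif fmt == "xml":
        root = ET.Element("annotations")
        for a in sorted(annotations, key=lambda a: (a.start, a.end, a.type)):
            ET.SubElement(
                root, "annotation",
                id=a.id, type=a.type, start=str(a.start), end=str(a.end),
                text=a.text,
            )
        ET.indent(root)
        stream.write(ET.tostring(root, encoding="unicode") + "\n")
    else:
        raise ValueError(f"unknown output format {fmt!r} (expected a1|json|xml)")


# -- directory-level corpus helpers ------------------------------------------

def load_corpus_dir(path: str | Path, with_triggers: bool = False) -> list[Document]:
    """Load every ``<id>.txt`` + ``<id>.conll`` pair under ``path``.

    Concepts are read from ``<id>.a1`` and gold triggers from
    ``<id>.trig.a1`` when present; annotations are attached to the sentence
    covering their span.
    """
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        doc_id = txt.stem
        conll = path / f"{doc_id}.conll"
        if not conll.exists():
            logger.warning("no .conll for %s; skipped", doc_id)
            continue
        with open(txt, encoding="utf-8") as ts, open(conll, encoding="utf-8") as cs:
            doc = read_parsed_corpus(ts, cs, doc_id=doc_id)
        a1 = path / f"{doc_id}.a1"
        if a1.exists():
            with open(a1, encoding="utf-8") as fh:
                attach_annotations(doc, read_a1(fh, doc.text, kind="concept"))
        trig = path / f"{doc_id}.trig.a1"
        if with_triggers and trig.exists():
            with open(trig, encoding="utf-8") as fh:
                attach_annotations(doc, read_a1(fh, doc.text, kind="trigger"))
        docs.append(doc)
    return docs


def attach_annotations(doc: Document, annotations: list[Annotation]) -> None:
    for ann in annotations:
        sent = doc.sentence_at(ann.start, ann.end)
        if sent is None:
            logger.warning(
                "annotation %s [%d,%d) crosses sentence boundaries; dropped",
                ann.id, ann.start, ann.end,
            )
            continue
        sent.annotations.insert(ann)


def write_corpus_dir(docs: list[Document], path: str | Path) -> None:
    """Emit text/.conll/.a1/.trig.a1 files for a corpus (fixture export)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (path / f"{doc.id}.txt").write_text(doc.text, encoding="utf-8")
        with open(path / f"{doc.id}.conll", "w", encoding="utf-8") as fh:
            write_parsed_corpus(doc, fh)
        with open(path / f"{doc.id}.a1", "w", encoding="utf-8") as fh:
            write_a1(doc.annotations("concept"), fh)
        with open(path / f"{doc.id}.trig.a1", "w", encoding="utf-8") as fh:
            write_a1(doc.annotations("trigger"), fh)
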
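"""Exact-match span evaluation with micro-averaged precision/recall/F1.

A predicted trigger counts as a true positive only when a gold trigger of
the same type has identical start and end offsets (one-to-one matching);
scores pool TP/FP/FN counts over documents and types before applying

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2 * P * R / (P + R),

reported on a 0-100 scale, with empty denominators yielding 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .core import Annotation
from .io_standoff import Document

__all__ = ["EvalMatrix", "match_exact", "micro_prf", "evaluate_documents",
           "GROUPS", "report"]

# BioNLP'09 trigger-type grouping
GROUPS = {
    "simple": (
        "Gene_expression", "Transcription", "Protein_catabolism",
        "Phosphorylation", "Localization",
    ),
    "binding": ("Binding",),
    "regulation": ("Regulation", "Positive_regulation", "Negative_regulation"),
}


@dataclass
class EvalMatrix:
    """Per-event-type TP/FP/FN tallies; additive across documents."""

    counts: dict[str, list[int]] = field(default_factory=dict)

    def add(self, event_type: str, tp: int = 0, fp: int = 0, fn: int = 0
            ) -> None:
        row = self.counts.setdefault(event_type, [0, 0, 0])
        row[0] += tp
        row[1] += fp
        row[2] += fn

    def merge(self, other: "EvalMatrix") -> "EvalMatrix":
        for etype, (tp, fp, fn) in other.counts.items():
            self.add(etype, tp, fp, fn)
        return self

    @property
    def types(self) -> list[str]:
        return sorted(self.counts)


def match_exact(gold: list[Annotation], pred: list[Annotation]) -> EvalMatrix:
    """One-to-one exact span matching per event type."""
    matrix = EvalMatrix()
    types = {a.type for a in gold} | {a.type for a in pred}
    for etype in sorted(types):
        g = Counter(a.span for a in gold if a.type == etype)
        p = Counter(a.span for a in pred if a.type == etype)
        tp = sum(min(g[s], p[s]) for s in g.keys() & p.keys())
        matrix.add(etype, tp=tp, fp=sum(p.values()) - tp,
                   fn=sum(g.values()) - tp)
    return matrix


def micro_prf(
    matrix: EvalMatrix, types: tuple[str, ...] | None = None
) -> tuple[float, float, float]:
    """Micro-averaged (P, R, F1) on a 0-100 scale over the requested types
    (all types when ``types`` is None)."""
    selected = matrix.types if types is None else [
        t for t in matrix.types if t in types
    ]
    tp = sum(matrix.counts[t][0] for t in selected)
    fp = sum(matrix.counts[t][1] for t in selected)
    fn = sum(matrix.counts[t][2] for t in selected)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return 100.0 * p, 100.0 * r, 100.0 * f1


def evaluate_documents(
    gold_docs: list[Document], pred_docs: list[Document]
) -> EvalMatrix:
    """Corpus-level matrix from paired documents (matched by id)."""
    pred_by_id = {d.id: d for d in pred_docs}
    matrix = EvalMatrix()
    for gold_doc in gold_docs:
        pred_doc = pred_by_id.get(gold_doc.id)
        pred = pred_doc.annotations("trigger") if pred_doc else []
        matrix.merge(match_exact(gold_doc.annotations("trigger"), pred))
    return matrix


def report(matrix: EvalMatrix, tsv: bool = False) -> str:
    """Per-type, per-group and total P/R/F1 as an aligned table (or TSV)."""
    rows: list[tuple[str, float, float, float]] = []
    for etype in matrix.types:
        rows.append((etype, *micro_prf(matrix, (etype,))))
    for group, types in GROUPS.items():
        if any(t in matrix.counts for t in types):
            rows.append((f"[{group}]", *micro_prf(matrix, types)))
    rows.append(("TOTAL", *micro_prf(matrix)))
    if tsv:
        lines = ["type\tprecision\trecall\tf1"]
        lines += [f"{n}\t{p:.2f}\t{r:.2f}\t{f:.2f}" for n, p, r, f in rows]
        return "\n".join(lines) + "\n"
    width = max(len(r[0]) for r in rows)
    lines = [f"{'type':<{width}}  {'P':>6}  {'R':>6}  {'F1':>6}"]
    lines += [
        f"{n:<{width}}  {p:>6.2f}  {r:>6.2f}  {f:>6.2f}"
        for n, p, r, f in rows
    ]
    return "\n".join(lines) + "\n"
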
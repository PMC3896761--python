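"""Dictionary-based trigger tagging and rule-based post-processing.

Matching is case-insensitive exact multi-pattern search over a compiled
Aho–Corasick automaton; hits are kept only when both ends coincide with
token boundaries (the whole-token reading of "exact matching").  Two
post-processing filters remove likely false positives: annotations whose
text has an odd number of brackets of any family, and triggers in sentences
without any concept annotation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .core import Annotation, Sentence
from .io_standoff import Dictionary

__all__ = [
    "Matcher",
    "compile_dictionary",
    "match",
    "filter_parentheses",
    "filter_no_concept",
]


class _AhoCorasick:
    """Minimal Aho–Corasick automaton over case-folded patterns."""

    def __init__(self, patterns: list[str]) -> None:
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]
        self._fail: list[int] = [0]
        self.patterns = patterns
        for pid, pat in enumerate(patterns):
            state = 0
            for ch in pat:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(pid)
        queue = deque()
        for ch, s in self._goto[0].items():
            queue.append(s)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0) if self._goto[f].get(
                    ch, 0) != nxt else 0
                self._out[nxt].extend(self._out[self._fail[nxt]])

    def find(self, text: str):
        """Yield (start, end, pattern_id) for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pid in self._out[state]:
                yield i + 1 - len(self.patterns[pid]), i + 1, pid


@dataclass
class Matcher:
    """A compiled dictionary: automaton over case-folded names plus the
    event type its hits are tagged with."""

    event_type: str
    automaton: _AhoCorasick


def compile_dictionary(dictionary: Dictionary) -> Matcher:
    """Compile a dictionary into a deterministic case-insensitive matcher."""
    names = dictionary.names
    if not names:
        raise ValueError(f"dictionary for {dictionary.event_type!r} is empty")
    folded = sorted({n.casefold() for n in names})
    return Matcher(dictionary.event_type, _AhoCorasick(folded))


def match(matcher: Matcher, sentence: Sentence) -> list[Annotation]:
    """All maximal token-boundary-aligned dictionary hits in a sentence.

    Both match ends must coincide with token starts/ends; matches strictly
    contained in a longer match of the same dictionary are dropped.
    """
    starts = {t.start for t in sentence.tokens}
    ends = {t.end for t in sentence.tokens}
    base = sentence.start
    text = sentence.text.casefold()
    hits: list[tuple[int, int]] = []
    for s, e, _pid in matcher.automaton.find(text):
        start, end = base + s, base + e
        if start in starts and end in ends:
            hits.append((start, end))
    hits = sorted(set(hits), key=lambda h: (h[0], -h[1]))
    kept: list[tuple[int, int]] = []
    for start, end in hits:
        if any(ks <= start and end <= ke and (ks, ke) != (start, end)
               for ks, ke in kept):
            continue
        kept.append((start, end))
    return [
        Annotation(
            id=f"TM{i + 1}",
            type=matcher.event_type,
            start=start,
            end=end,
            text=sentence.text[start - base:end - base],
            kind="trigger",
        )
        for i, (start, end) in enumerate(kept)
    ]


_BRACKET_FAMILIES = ("()", "[]", "{}")


def filter_parentheses(annotations: list[Annotation]) -> list[Annotation]:
    """Remove annotations whose text carries an odd count of round, square
    or curly brackets (counted per family); such spans indicate a tagging
    mistake."""
    kept = []
    for ann in annotations:
        odd = any(
            sum(ann.text.count(c) for c in fam) % 2 == 1
            for fam in _BRACKET_FAMILIES
        )
        if not odd:
            kept.append(ann)
    return kept


def filter_no_concept(
    annotations: list[Annotation], sentence: Sentence
) -> list[Annotation]:
    """Drop every trigger of a sentence that holds no concept annotation."""
    if sentence.concepts():
        return list(annotations)
    return []
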
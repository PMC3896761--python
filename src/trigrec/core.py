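"""Corpus data structures: sentences, tokens, chunks, dependency graphs and
annotation trees.

A :class:`Sentence` bundles everything later stages need: an offset-anchored
token sequence, shallow-parse chunks, an undirected labeled dependency graph
with shortest-path queries, and a nesting-aware tree of concept and trigger
annotations.  Character offsets are 0-based and end-exclusive throughout,
matching BioNLP standoff conventions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MalformedInputError",
    "Token",
    "Chunk",
    "DependencyGraph",
    "Annotation",
    "AnnotationTree",
    "Sentence",
    "TokenPath",
    "build_sentence",
    "shortest_path",
    "closest_concept_path",
]


class MalformedInputError(ValueError):
    """Raised when input token rows, offsets or edges are inconsistent."""


@dataclass
class Token:
    """A single token anchored to the document text.

    ``features`` is a multimap: a feature key maps to the ordered list of
    values emitted for it (several values per key are legal, e.g. multiple
    character n-grams).
    """

    index: int
    text: str
    start: int
    end: int
    features: dict[str, list[str]] = field(default_factory=dict)

    def add_feature(self, key: str, value: str) -> None:
        self.features.setdefault(key, []).append(value)

    def feature(self, key: str, default: str | None = None) -> str | None:
        """First value stored under ``key``, or ``default``."""
        vals = self.features.get(key)
        return vals[0] if vals else default


@dataclass
class Chunk:
    """Shallow-parse phrase: a label (NP, VP, PP, ...) over an inclusive
    token-index range."""

    label: str
    first: int
    last: int

    def __contains__(self, token_index: int) -> bool:
        return self.first <= token_index <= self.last


class DependencyGraph:
    """Undirected labeled graph over a sentence's token indices.

    Path queries treat the graph as undirected; the head->dependent direction
    of each grammatical relation is kept as edge metadata because some feature
    families need it.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    def add_vertex(self, index: int) -> None:
        self._g.add_node(index)

    def add_edge(self, head: int, dependent: int, label: str) -> None:
        if head == dependent:
            raise MalformedInputError(f"self-loop on token {head}")
        self._g.add_edge(head, dependent, label=label, head=head)

    @property
    def vertices(self) -> list[int]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[int, int, str, int]]:
        """(u, v, label, head) with u < v."""
        out = []
        for u, v, data in self._g.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            out.append((a, b, data["label"], data["head"]))
        return sorted(out)

    def neighbors(self, index: int) -> list[int]:
        return sorted(self._g.neighbors(index))

    def label(self, a: int, b: int) -> str:
        return self._g.edges[a, b]["label"]

    def head_of_edge(self, a: int, b: int) -> int:
        return self._g.edges[a, b]["head"]

    def has_vertex(self, index: int) -> bool:
        return self._g.has_node(index)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()


@dataclass
class Annotation:
    """A text-bound annotation: a concept (e.g. Protein) or an event trigger
    (e.g. Gene_expression) over a character span of the document."""

    id: str
    type: str
    start: int
    end: int
    text: str
    kind: str = "concept"  # "concept" or "trigger"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, other: "Annotation") -> bool:
        """Strict containment: covers ``other`` and spans differ."""
        return (
            self.start <= other.start
            and other.end <= self.end
            and self.span != other.span
        )

    def intersects(self, other: "Annotation") -> bool:
        """Partial overlap: spans cross but neither contains the other."""
        overlap = self.start < other.end and other.start < self.end
        return overlap and not self.contains(other) and not other.contains(self) \
            and self.span != other.span


class _TreeNode:
    __slots__ = ("annotation", "children", "ambiguous")

    def __init__(self, annotation: Annotation | None) -> None:
        self.annotation = annotation
        self.children: list[_TreeNode] = []
        self.ambiguous = False


class AnnotationTree:
    """Nesting-aware container for annotations of one sentence.

    Containment is maintained automatically: inserting a span that covers
    existing siblings re-parents them under the new node; duplicates (same
    span and type) collapse; partially overlapping spans are both retained as
    siblings and flagged ambiguous.
    """

    def __init__(self, start: int, end: int) -> None:
        self.start = start
        self.end = end
        self._root = _TreeNode(None)

    def insert(self, ann: Annotation) -> "AnnotationTree":
        if ann.start < self.start or ann.end > self.end or ann.start >= ann.end:
            raise MalformedInputError(
                f"annotation {ann.id} [{ann.start},{ann.end}) outside sentence "
                f"[{self.start},{self.end})"
            )
        self._insert(self._root, ann)
        return self

    def _insert(self, node: _TreeNode, ann: Annotation) -> None:
        for child in node.children:
            ca = child.annotation
            if ca.span == ann.span and ca.type == ann.type and ca.kind == ann.kind:
                return  # duplicate
            if ca.contains(ann):
                self._insert(child, ann)
                return
            # same span, different type: falls through and becomes a sibling
        new = _TreeNode(ann)
        absorbed, kept = [], []
        for child in node.children:
            if ann.contains(child.annotation):
                absorbed.append(child)
            else:
                kept.append(child)
                if ann.intersects(child.annotation):
                    child.ambiguous = True
                    new.ambiguous = True
        new.children = absorbed
        kept.append(new)
        kept.sort(key=lambda n: (n.annotation.start, -n.annotation.end))
        node.children = kept

    def remove(self, ann: Annotation) -> bool:
        """Remove the node for ``ann`` (matched by span/type/kind), splicing
        its children into its parent. Returns True if found."""

        def walk(node: _TreeNode) -> bool:
            for i, child in enumerate(node.children):
                ca = child.annotation
                if ca.span == ann.span and ca.type == ann.type and ca.kind == ann.kind:
                    node.children[i : i + 1] = child.children
                    node.children.sort(
                        key=lambda n: (n.annotation.start, -n.annotation.end)
                    )
                    return True
                if walk(child):
                    return True
            return False

        return walk(self._root)

    def __iter__(self):
        """Pre-order traversal of annotations."""
        stack = list(reversed(self._root.children))
        while stack:
            node = stack.pop()
            yield node.annotation
            stack.extend(reversed(node.children))

    def __len__(self) -> int:
        return sum(1 for _ in self)

    def parent_child_pairs(self) -> list[tuple[Annotation, Annotation]]:
        pairs = []

        def walk(node: _TreeNode) -> None:
            for child in node.children:
                if node.annotation is not None:
                    pairs.append((node.annotation, child.annotation))
                walk(child)

        walk(self._root)
        return pairs


@dataclass
class TokenPath:
    """A path through the dependency graph: ordered token indices plus the
    dependency labels of the traversed edges."""

    vertices: list[int]
    edge_labels: list[str]

    @property
    def hops(self) -> int:
        return len(self.edge_labels)

    def __post_init__(self) -> None:
        if len(self.vertices) != len(self.edge_labels) + 1:
            raise ValueError("path length mismatch")


@dataclass
class Sentence:
    """One sentence of a document with all attached linguistic structure."""

    tokens: list[Token]
    chunks: list[Chunk]
    graph: DependencyGraph
    annotations: AnnotationTree
    start: int
    end: int
    text: str = ""

    def chunk_of(self, token_index: int) -> Chunk | None:
        for chunk in self.chunks:
            if token_index in chunk:
                return chunk
        return None

    def chunk_bio(self, token_index: int) -> str:
        chunk = self.chunk_of(token_index)
        if chunk is None:
            return "O"
        return ("B-" if token_index == chunk.first else "I-") + chunk.label

    def concepts(self) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == "concept"]

    def triggers(self, event_type: str | None = None) -> list[Annotation]:
        anns = [a for a in self.annotations if a.kind == "trigger"]
        if event_type is not None:
            anns = [a for a in anns if a.type == event_type]
        return anns

    def tokens_in_span(self, start: int, end: int) -> list[Token]:
        """Tokens overlapping the character span [start, end)."""
        return [t for t in self.tokens if t.start < end and t.end > start]

    def token_at(self, text: str) -> Token:
        """First token with the given surface text (test/fixture helper)."""
        for t in self.tokens:
            if t.text == text:
                return t
        raise KeyError(text)


def build_sentence(
    token_rows: list[tuple],
    dep_edges: list[tuple[int, int, str]],
    chunk_tags: list[str],
    sentence_text: str | None = None,
) -> Sentence:
    """Assemble a :class:`Sentence` from reader output.

    ``token_rows`` are ``(index, text, start, end, lemma, pos)`` tuples with
    document-absolute offsets; ``dep_edges`` are ``(head, dependent, label)``
    token-index triples; ``chunk_tags`` are per-token BIO chunk tags that get
    collapsed into :class:`Chunk` records.
    """
    if len(chunk_tags) != len(token_rows):
        raise MalformedInputError("chunk tag count differs from token count")
    tokens: list[Token] = []
    prev_end = -1
    for i, row in enumerate(token_rows):
        index, text, start, end, lemma, pos = row
        if index != i:
            raise MalformedInputError(f"token {i}: non-contiguous index {index}")
        if start >= end:
            raise MalformedInputError(f"token {i}: empty span [{start},{end})")
        if start < prev_end:
            raise MalformedInputError(f"token {i}: offset overlap at {start}")
        prev_end = end
        tok = Token(index=i, text=text, start=start, end=end)
        if lemma:
            tok.add_feature("LEMMA", lemma)
        if pos:
            tok.add_feature("POS", pos)
        tokens.append(tok)
    if not tokens:
        raise MalformedInputError("sentence with no tokens")

    n = len(tokens)
    graph = DependencyGraph()
    for t in tokens:
        graph.add_vertex(t.index)
    for head, dep, label in dep_edges:
        for idx in (head, dep):
            if not 0 <= idx < n:
                raise MalformedInputError(
                    f"token {dep}: head/dependent index {idx} out of range"
                )
        graph.add_edge(head, dep, label)

    chunks: list[Chunk] = []
    for i, tag in enumerate(chunk_tags):
        tokens[i].add_feature("CHUNK", tag)
        if tag == "O" or not tag:
            continue
        prefix, _, label = tag.partition("-")
        if prefix == "B" or not chunks or chunks[-1].last != i - 1 \
                or chunks[-1].label != label:
            chunks.append(Chunk(label=label, first=i, last=i))
        else:
            chunks[-1].last = i

    start, end = tokens[0].start, tokens[-1].end
    if sentence_text is None:
        # reconstruct with single spaces in inter-token gaps
        parts = []
        for i, t in enumerate(tokens):
            if i and t.start > tokens[i - 1].end:
                parts.append(" " * (t.start - tokens[i - 1].end))
            parts.append(t.text)
        sentence_text = "".join(parts)
    tree = AnnotationTree(start, end)
    return Sentence(
        tokens=tokens, chunks=chunks, graph=graph, annotations=tree,
        start=start, end=end, text=sentence_text,
    )


def _bfs_distances(graph: DependencyGraph, source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path(graph: DependencyGraph, a: int, b: int) -> TokenPath | None:
    """Minimum-hop path between tokens ``a`` and ``b`` (unit edge weights).

    Among equal-length paths the lexicographically smallest vertex-index
    sequence is returned, which makes downstream path features deterministic.
    Returns ``None`` for disconnected pairs.
    """
    if not (graph.has_vertex(a) and graph.has_vertex(b)):
        raise KeyError(f"vertex {a if not graph.has_vertex(a) else b} not in graph")
    if a == b:
        return TokenPath([a], [])
    dist_to_b = _bfs_distances(graph, b)
    if a not in dist_to_b:
        return None
    vertices = [a]
    labels: list[str] = []
    current = a
    while current != b:
        step = min(
            v for v in graph.neighbors(current)
            if dist_to_b.get(v, -1) == dist_to_b[current] - 1
        )
        labels.append(graph.label(current, step))
        vertices.append(step)
        current = step
    return TokenPath(vertices, labels)


def closest_concept_path(sentence: Sentence, token_index: int) -> TokenPath | None:
    """Shortest path from a token to the nearest concept-annotation token.

    Considers every token belonging to any concept annotation; minimum hop
    count wins, ties broken toward the smallest target token index.  A token
    already inside a concept yields a 0-hop path.  Returns ``None`` when the
    sentence has no concepts or all concept tokens are unreachable.
    """
    concept_tokens: set[int] = set()
    for ann in sentence.concepts():
        for tok in sentence.tokens_in_span(ann.start, ann.end):
            concept_tokens.add(tok.index)
    if not concept_tokens:
        return None
    if token_index in concept_tokens:
        return TokenPath([token_index], [])
    dist = _bfs_distances(sentence.graph, token_index)
    reachable = [(dist[c], c) for c in sorted(concept_tokens) if c in dist]
    if not reachable:
        return None
    _, target = min(reachable)
    return shortest_path(sentence.graph, token_index, target)
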
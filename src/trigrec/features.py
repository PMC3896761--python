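"""The feature catalogue for trigger recognition.

Nine switchable feature families (token, orthographic, morphological,
sentence, concepts, dictionary, modifier, dependency-edge, shortest-path)
emit per-token ``KEY=value`` strings; three context modes (local windows,
dependency windows, conjunctions) augment them with neighborhood
information.  Which families run, with which n-gram sizes, hop limits and
vertex information, is governed by a :class:`ModelConfiguration` — the unit
the per-event-type optimizer searches over.

Every emitted key belongs to exactly one family's declared key set, which is
what makes the union-then-filter extraction strategy possible: a corpus is
featurized once with the union of several configurations, and each model's
exact feature set is recovered by filtering strings by key.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

from .core import Sentence, TokenPath, closest_concept_path

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfiguration",
    "ConfigurationError",
    "FAMILIES",
    "NGRAM_FAMILIES",
    "HOP_FAMILIES",
    "VERTEX_FAMILIES",
    "CONTEXT_MODES",
    "VERTEX_TYPES",
    "extract",
    "union_and_filter",
    "token_features",
    "orthographic_features",
    "morphological_features",
    "sentence_length_feature",
    "concept_features",
    "dictionary_features",
    "modifier_features",
    "dependency_edge_features",
    "path_features",
    "shortest_path_features",
    "apply_conjunctions",
    "apply_local_windows",
    "apply_dependency_windows",
    "word_shape",
]

# catalogue order is also the optimizer's default greedy order
FAMILIES = (
    "token",
    "orthographic",
    "morphological",
    "sentence",
    "concepts",
    "dictionary",
    "modifier",
    "dependency_edge",
    "shortest_path",
)
NGRAM_FAMILIES = frozenset({"morphological", "shortest_path"})
HOP_FAMILIES = frozenset({"shortest_path"})
VERTEX_FAMILIES = frozenset({"shortest_path"})
CONTEXT_MODES = ("none", "window", "dependency_window", "conjunctions")
VERTEX_TYPES = ("lemma", "token", "pos", "chunk")

# key prefixes per family, longest-prefix-wins (CONCEPT_NAME and the dynamic
# CONCEPT_<TYPE>_HEAD / NUM_<TYPE> keys all belong to the concepts family)
_KEY_PREFIXES: list[tuple[str, str]] = [
    ("W", "token"), ("LEMMA", "token"), ("POS", "token"), ("CHUNK", "token"),
    ("CAP", "orthographic"), ("COUNT_UPPER", "orthographic"),
    ("COUNT_DIGIT", "orthographic"), ("LENGTH", "orthographic"),
    ("SYMBOL", "orthographic"),
    ("PREFIX", "morphological"), ("SUFFIX", "morphological"),
    ("CHARNGRAM", "morphological"), ("SHAPE", "morphological"),
    ("SENT_SIZE", "sentence"),
    ("CONCEPT", "concepts"), ("NUM_", "concepts"),
    ("Trigger", "dictionary"),
    ("SUBJ_OF_VERB", "modifier"), ("OBJ_OF_VERB", "modifier"),
    ("MODIFIES_NOUN", "modifier"), ("MODIFIER", "modifier"),
    ("IN_DEP_", "dependency_edge"), ("OUT_DEP_", "dependency_edge"),
    ("SP_", "shortest_path"), ("SPDistance", "shortest_path"),
    ("CONJ", "context"), ("LW_", "context"), ("DW_", "context"),
]
_KEY_PREFIXES.sort(key=lambda kv: -len(kv[0]))

# Calibration switch for input/output dependency orientation: with True, a
# token's "input" dependencies are the edges arriving from its own
# dependents, and its single "output" dependency is the edge to its head.
_IN_MEANS_HEAD = True

_SUBJECT_LABELS = frozenset({"SUB", "SUBJ", "NSUBJ", "CSUBJ"})
_OBJECT_LABELS = frozenset({"OBJ", "DOBJ", "IOBJ", "POBJ"})
_MODIFIER_LABELS = frozenset({"NMOD", "AMOD", "PMOD", "VMOD", "MOD"})

_WINDOW_PAIRS = ((-3, -1), (-2, -1), (-1, 0), (-1, 1), (0, 1))
_WINDOW_OFFSETS = (-3, -2, -1, 1)


class ConfigurationError(ValueError):
    pass


def _default_ngrams() -> dict[str, frozenset[int]]:
    return {fam: frozenset({2, 3}) for fam in sorted(NGRAM_FAMILIES)}


def _default_hops() -> dict[str, int]:
    return {"shortest_path": 3, "dependency_window": 3}


def _default_vertex() -> dict[str, str]:
    return {fam: "lemma" for fam in sorted(VERTEX_FAMILIES)}


@dataclass
class ModelConfiguration:
    """Per-event-type recipe: which feature families run and with which
    parameters, which context mode applies, and the CRF model order."""

    event_type: str = ""
    active_features: set[str] = field(default_factory=set)
    context_mode: str = "none"
    ngram_sizes: dict[str, frozenset[int]] = field(default_factory=_default_ngrams)
    hop_limits: dict[str, int] = field(default_factory=_default_hops)
    vertex_feature: dict[str, str] = field(default_factory=_default_vertex)
    order: int = 1

    def validate(self) -> None:
        unknown = self.active_features - set(FAMILIES)
        if unknown:
            raise ConfigurationError(f"unknown feature families: {sorted(unknown)}")
        if self.context_mode not in CONTEXT_MODES:
            raise ConfigurationError(f"unknown context mode {self.context_mode!r}")
        for fam, sizes in self.ngram_sizes.items():
            if any(n < 2 for n in sizes):
                raise ConfigurationError(f"{fam}: n-gram sizes must be >= 2")
        for fam, hops in self.hop_limits.items():
            if hops < 1:
                raise ConfigurationError(f"{fam}: hop limit must be >= 1")
        for fam, vf in self.vertex_feature.items():
            vals = {vf} if isinstance(vf, str) else set(vf)
            if not vals <= set(VERTEX_TYPES):
                raise ConfigurationError(f"{fam}: unknown vertex feature {vf!r}")
        if self.order < 1:
            raise ConfigurationError("model order must be >= 1")

    def _vertex_set(self, fam: str) -> tuple[str, ...]:
        vf = self.vertex_feature.get(fam, "lemma")
        return (vf,) if isinstance(vf, str) else tuple(sorted(vf))

    def copy(self) -> "ModelConfiguration":
        return replace(
            self,
            active_features=set(self.active_features),
            ngram_sizes=dict(self.ngram_sizes),
            hop_limits=dict(self.hop_limits),
            vertex_feature=dict(self.vertex_feature),
        )

    def to_dict(self) -> dict:
        return {
            "event_type": self.event_type,
            "active_features": sorted(self.active_features),
            "context_mode": self.context_mode,
            "ngram_sizes": {k: sorted(v) for k, v in self.ngram_sizes.items()},
            "hop_limits": dict(self.hop_limits),
            "vertex_feature": dict(self.vertex_feature),
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfiguration":
        cfg = cls(
            event_type=data.get("event_type", ""),
            active_features=set(data.get("active_features", ())),
            context_mode=data.get("context_mode", "none"),
            ngram_sizes={
                k: frozenset(v) for k, v in data.get(
                    "ngram_sizes", {}).items()
            } or _default_ngrams(),
            hop_limits=dict(data.get("hop_limits", _default_hops())),
            vertex_feature=dict(data.get("vertex_feature", _default_vertex())),
            order=int(data.get("order", 1)),
        )
        cfg.validate()
        return cfg


def family_of_key(key: str) -> str | None:
    for prefix, family in _KEY_PREFIXES:
        if key.startswith(prefix):
            return family
    return None


def _value(text: str) -> str:
    return text.replace(" ", "_")


# --------------------------------------------------------------------------
# feature families
# --------------------------------------------------------------------------

def token_features(sentence: Sentence) -> list[list[str]]:
    """Surface form, lemma, POS tag and BIO chunk tag of each token."""
    out = []
    warned = False
    for tok in sentence.tokens:
        feats = [f"W={_value(tok.text)}"]
        lemma, pos = tok.feature("LEMMA"), tok.feature("POS")
        if lemma is None or pos is None:
            if not warned:
                logger.warning("token %r lacks lemma/POS; emitting text only",
                               tok.text)
                warned = True
        if lemma is not None:
            feats.append(f"LEMMA={_value(lemma)}")
        if pos is not None:
            feats.append(f"POS={pos}")
        feats.append(f"CHUNK={sentence.chunk_bio(tok.index)}")
        out.append(feats)
    return out


_SYMBOL_NAMES = (
    (".", "Dot"), (",", "Comma"), (";", "SemiColon"), (":", "Colon"),
    ("-", "Hyphen"), ("/", "Slash"), ("(", "OpenParen"), (")", "CloseParen"),
    ("[", "OpenBracket"), ("]", "CloseBracket"), ("{", "OpenBrace"),
    ("}", "CloseBrace"), ("%", "Percent"), ("'", "Apostrophe"),
    ('"', "Quote"), ("+", "Plus"), ("=", "Equal"), ("_", "Underscore"),
    ("*", "Asterisk"),
)


def orthographic_features(sentence: Sentence) -> list[list[str]]:
    """Capitalization tags, character counts and symbol-occurrence tags."""
    out = []
    for tok in sentence.tokens:
        text = tok.text
        feats = []
        has_upper = any(c.isupper() for c in text)
        has_lower = any(c.islower() for c in text)
        if text[:1].isupper():
            feats.append("CAP=InitUpp")
        if has_upper and not has_lower:
            feats.append("CAP=AllUpp")
        if has_upper and has_lower:
            feats.append("CAP=MixCase")
        if has_lower and not has_upper:
            feats.append("CAP=AllLow")
        feats.append(f"COUNT_UPPER={sum(c.isupper() for c in text)}")
        feats.append(f"COUNT_DIGIT={sum(c.isdigit() for c in text)}")
        feats.append(f"LENGTH={len(text)}")
        for sym, name in _SYMBOL_NAMES:
            if sym in text:
                feats.append(f"SYMBOL={name}")
        out.append(feats)
    return out


def word_shape(text: str) -> str:
    """Character-class pattern: uppercase->A, lowercase->a, digit->1,
    anything else->#; e.g. 'Abc:1234' -> 'Aaa#1111'."""
    return "".join(
        "A" if c.isupper() else "a" if c.islower() else "1" if c.isdigit()
        else "#"
        for c in text
    )


def morphological_features(
    sentence: Sentence, ngram_sizes: frozenset[int] = frozenset({2, 3})
) -> list[list[str]]:
    """Affixes (lengths 2-4), character n-grams and the word-shape pattern."""
    out = []
    for tok in sentence.tokens:
        text = tok.text
        feats = []
        for n in (2, 3, 4):
            if len(text) >= n:
                feats.append(f"PREFIX{n}={text[:n]}")
        for n in (2, 3, 4):
            if len(text) >= n:
                feats.append(f"SUFFIX{n}={text[-n:]}")
        for n in sorted(ngram_sizes):
            for i in range(len(text) - n + 1):
                feats.append(f"CHARNGRAM_{n}={text[i:i + n]}")
        feats.append(f"SHAPE={word_shape(text)}")
        out.append(feats)
    return out


_LENGTH_BINS = ("<15", "[15,20)", "[20,25)", "[25,30)", "[30,35)", "[35,40)",
                ">=40")


def sentence_length_feature(sentence: Sentence) -> list[list[str]]:
    """One of seven token-count bins, attached to every token."""
    n = len(sentence.tokens)
    if n < 15:
        label = _LENGTH_BINS[0]
    elif n >= 40:
        label = _LENGTH_BINS[6]
    else:
        label = _LENGTH_BINS[1 + (n - 15) // 5]
    return [[f"SENT_SIZE={label}"] for _ in sentence.tokens]


def _concept_head_token(sentence: Sentence, ann) -> str:
    toks = sentence.tokens_in_span(ann.start, ann.end)
    if toks:
        return toks[0].text
    return ann.text.split()[0] if ann.text.split() else ann.text


def concept_features(sentence: Sentence) -> list[list[str]]:
    """Concept tags, names, head tokens and per-type counts.

    Tag features mark tokens inside a concept; name, head and counting
    features are attached to every token of the sentence.
    """
    concepts = sentence.concepts()
    out: list[list[str]] = [[] for _ in sentence.tokens]
    if not concepts:
        return out
    concepts = sorted(concepts, key=lambda a: (a.start, a.end, a.type))
    for ann in concepts:
        for tok in sentence.tokens_in_span(ann.start, ann.end):
            out[tok.index].append(f"CONCEPT={ann.type}")
    sentence_wide: list[str] = []
    for ann in concepts:
        sentence_wide.append(f"CONCEPT_NAME={_value(ann.text)}")
    for ann in concepts:
        head = _concept_head_token(sentence, ann)
        sentence_wide.append(
            f"CONCEPT_{ann.type.upper()}_HEAD={_value(head)}"
        )
    counts: dict[str, int] = {}
    for ann in concepts:
        counts[ann.type] = counts.get(ann.type, 0) + 1
    for ctype in sorted(counts):
        sentence_wide.append(f"NUM_{ctype.upper()}={counts[ctype]}")
    for feats in out:
        feats.extend(sentence_wide)
    return out


def dictionary_features(sentence: Sentence, matchers=()) -> list[list[str]]:
    """Tokens covered by a dictionary match get ``Trigger=<event_type>``."""
    from .matching import match as dict_match  # local import, avoids cycle

    out: list[list[str]] = [[] for _ in sentence.tokens]
    for matcher in matchers:
        for ann in dict_match(matcher, sentence):
            for tok in sentence.tokens_in_span(ann.start, ann.end):
                feat = f"Trigger={ann.type}"
                if feat not in out[tok.index]:
                    out[tok.index].append(feat)
    return out


def _directed_edges(sentence: Sentence):
    """Yield (head_index, dependent_index, label)."""
    for u, v, label, head in sentence.graph.edges:
        dep = v if head == u else u
        yield head, dep, label


def modifier_features(sentence: Sentence) -> list[list[str]]:
    """Grammatical-role features read off the directed edge metadata: the
    verbs a token is subject/object of, the nouns it modifies, and the
    token's own modifiers (all as lemmas)."""
    out: list[list[str]] = [[] for _ in sentence.tokens]

    def lemma(i: int) -> str:
        tok = sentence.tokens[i]
        return _value(tok.feature("LEMMA", tok.text))

    def pos(i: int) -> str:
        return sentence.tokens[i].feature("POS", "")

    for head, dep, label in sorted(_directed_edges(sentence)):
        if label in _SUBJECT_LABELS and pos(head).startswith("V"):
            out[dep].append(f"SUBJ_OF_VERB={lemma(head)}")
        if label in _OBJECT_LABELS and pos(head).startswith("V"):
            out[dep].append(f"OBJ_OF_VERB={lemma(head)}")
        if label in _MODIFIER_LABELS and pos(head).startswith("N"):
            out[dep].append(f"MODIFIES_NOUN={lemma(head)}")
        out[head].append(f"MODIFIER={lemma(dep)}")
    return out


def _chunk_label(sentence: Sentence, i: int) -> str:
    chunk = sentence.chunk_of(i)
    return chunk.label if chunk is not None else "O"


def dependency_edge_features(sentence: Sentence) -> list[list[str]]:
    """Input/output dependency features: label, lemma, POS and chunk of the
    other endpoint of every edge incident to the token."""
    out: list[list[str]] = [[] for _ in sentence.tokens]

    def endpoint_feats(direction: str, other: int, label: str) -> list[str]:
        tok = sentence.tokens[other]
        return [
            f"{direction}_DEP_LABEL={label}",
            f"{direction}_DEP_LEMMA={_value(tok.feature('LEMMA', tok.text))}",
            f"{direction}_DEP_POS={tok.feature('POS', '')}",
            f"{direction}_DEP_CHUNK={_chunk_label(sentence, other)}",
        ]

    for head, dep, label in sorted(_directed_edges(sentence)):
        if _IN_MEANS_HEAD:
            out[head].extend(endpoint_feats("IN", dep, label))
            out[dep].extend(endpoint_feats("OUT", head, label))
        else:
            out[dep].extend(endpoint_feats("IN", head, label))
            out[head].extend(endpoint_feats("OUT", dep, label))
    return out


def _vertex_value(sentence: Sentence, index: int, vertex_feature: str) -> str:
    tok = sentence.tokens[index]
    if vertex_feature == "lemma":
        return _value(tok.feature("LEMMA", tok.text))
    if vertex_feature == "token":
        return _value(tok.text)
    if vertex_feature == "pos":
        return tok.feature("POS", "")
    if vertex_feature == "chunk":
        return _chunk_label(sentence, index)
    raise ConfigurationError(f"unknown vertex feature {vertex_feature!r}")


def path_features(
    path: TokenPath,
    sentence: Sentence,
    vertex_features: tuple[str, ...] = ("lemma",),
    ngram_sizes: frozenset[int] = frozenset({2, 3}),
) -> list[str]:
    """Edge-path, edge-type, vertex-path and n-gram features of one
    dependency path.  A 0-hop path emits nothing."""
    if path.hops == 0:
        return []
    labels = path.edge_labels
    feats = [
        f"SP_EDGE_PATH={'-'.join(labels)}",
        f"SP_EDGE_TYPE={labels[0]}_{path.hops}",
    ]
    vertex_values = {
        vf: [_vertex_value(sentence, i, vf) for i in path.vertices]
        for vf in vertex_features
    }
    for vf in vertex_features:
        feats.append(f"SP_VERTEX_PATH_{vf.upper()}={'-'.join(vertex_values[vf])}")
    for n in sorted(ngram_sizes):
        for i in range(len(labels) - n + 1):
            feats.append(f"SP_EDGE_NGRAM_{n}={'_'.join(labels[i:i + n])}")
    for n in sorted(ngram_sizes):
        for vf in vertex_features:
            vals = vertex_values[vf]
            for i in range(len(vals) - n + 1):
                feats.append(
                    f"SP_VERTEX_NGRAM_{n}_{vf.upper()}={'_'.join(vals[i:i + n])}"
                )
    return feats


def shortest_path_features(
    sentence: Sentence, config: ModelConfiguration
) -> list[list[str]]:
    """Features of each token's shortest dependency path to the closest
    concept annotation, including the ``SPDistance`` hop count, within the
    configured hop limit."""
    limit = config.hop_limits.get("shortest_path", 3)
    vfs = config._vertex_set("shortest_path")
    sizes = config.ngram_sizes.get("shortest_path", frozenset({2, 3}))
    out: list[list[str]] = []
    for tok in sentence.tokens:
        path = closest_concept_path(sentence, tok.index)
        if path is None or path.hops > limit:
            out.append([])
            continue
        feats = path_features(path, sentence, vfs, sizes)
        feats.append(f"SPDistance={path.hops}")
        out.append(feats)
    return out


# --------------------------------------------------------------------------
# context modes
# --------------------------------------------------------------------------

def _stream(sentence: Sentence, which: str) -> list[str]:
    vals = []
    for tok in sentence.tokens:
        if which == "lemma":
            vals.append(_value(tok.feature("LEMMA", tok.text)))
        elif which == "pos":
            vals.append(tok.feature("POS", ""))
        elif which == "token":
            vals.append(_value(tok.text))
        else:
            vals.append(sentence.chunk_bio(tok.index))
    return vals


def apply_conjunctions(
    features: list[list[str]], sentence: Sentence
) -> list[list[str]]:
    """Conjoin lemma and POS values of surrounding tokens, e.g.
    ``interferon@-1_&_factor@1``; windows with any out-of-range offset are
    skipped for that token."""
    n = len(sentence.tokens)
    streams = {"lemma": _stream(sentence, "lemma"), "pos": _stream(sentence, "pos")}
    out = [list(f) for f in features]
    for i in range(n):
        for name in ("lemma", "pos"):
            vals = streams[name]
            for o1, o2 in _WINDOW_PAIRS:
                j1, j2 = i + o1, i + o2
                if not (0 <= j1 < n and 0 <= j2 < n):
                    continue
                out[i].append(f"CONJ={vals[j1]}@{o1}_&_{vals[j2]}@{o2}")
    return out


def apply_local_windows(
    features: list[list[str]], sentence: Sentence
) -> list[list[str]]:
    """Copy token, lemma, POS and chunk features of neighboring tokens,
    key-tagged with their relative offset."""
    n = len(sentence.tokens)
    streams = {
        "W": _stream(sentence, "token"),
        "LEMMA": _stream(sentence, "lemma"),
        "POS": _stream(sentence, "pos"),
        "CHUNK": _stream(sentence, "chunk"),
    }
    out = [list(f) for f in features]
    for i in range(n):
        for o in _WINDOW_OFFSETS:
            j = i + o
            if not 0 <= j < n:
                continue
            for key in ("W", "LEMMA", "POS", "CHUNK"):
                out[i].append(f"LW_{key}@{o}={streams[key][j]}")
    return out


def apply_dependency_windows(
    features: list[list[str]], sentence: Sentence, max_hops: int = 3
) -> list[list[str]]:
    """Copy lemma, POS and chunk features of every token within ``max_hops``
    dependency-graph hops of the current token."""
    out = [list(f) for f in features]
    for tok in sentence.tokens:
        dist = {tok.index: 0}
        queue = deque([tok.index])
        while queue:
            u = queue.popleft()
            if dist[u] >= max_hops:
                continue
            for v in sentence.graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for j in sorted(dist):
            if j == tok.index:
                continue
            other = sentence.tokens[j]
            out[tok.index].append(
                f"DW_LEMMA={_value(other.feature('LEMMA', other.text))}"
            )
            out[tok.index].append(f"DW_POS={other.feature('POS', '')}")
            out[tok.index].append(f"DW_CHUNK={sentence.chunk_bio(j)}")
    return out


def _apply_context(
    features: list[list[str]], sentence: Sentence, config: ModelConfiguration
) -> list[list[str]]:
    mode = config.context_mode
    if mode == "none":
        return features
    if mode == "window":
        return apply_local_windows(features, sentence)
    if mode == "dependency_window":
        return apply_dependency_windows(
            features, sentence, config.hop_limits.get("dependency_window", 3)
        )
    if mode == "conjunctions":
        return apply_conjunctions(features, sentence)
    raise ConfigurationError(f"unknown context mode {mode!r}")


# --------------------------------------------------------------------------
# extraction and union/filter
# --------------------------------------------------------------------------

def _extract_base(
    sentence: Sentence, config: ModelConfiguration, matchers=()
) -> list[list[str]]:
    per_token: list[list[str]] = [[] for _ in sentence.tokens]
    for family in FAMILIES:
        if family not in config.active_features:
            continue
        if family == "token":
            emitted = token_features(sentence)
        elif family == "orthographic":
            emitted = orthographic_features(sentence)
        elif family == "morphological":
            emitted = morphological_features(
                sentence, config.ngram_sizes.get("morphological",
                                                 frozenset({2, 3}))
            )
        elif family == "sentence":
            emitted = sentence_length_feature(sentence)
        elif family == "concepts":
            emitted = concept_features(sentence)
        elif family == "dictionary":
            emitted = dictionary_features(sentence, matchers)
        elif family == "modifier":
            emitted = modifier_features(sentence)
        elif family == "dependency_edge":
            emitted = dependency_edge_features(sentence)
        elif family == "shortest_path":
            emitted = shortest_path_features(sentence, config)
        else:  # pragma: no cover - guarded by validate()
            raise ConfigurationError(f"unknown feature family {family!r}")
        for feats, new in zip(per_token, emitted):
            feats.extend(new)
    return per_token


def extract(
    sentence: Sentence, config: ModelConfiguration, matchers=()
) -> list[list[str]]:
    """Run exactly the families active in ``config`` with its parameters,
    then the configured context mode.  Output order is deterministic."""
    config.validate()
    unknown = config.active_features - set(FAMILIES)
    if unknown:
        raise ConfigurationError(f"unknown feature families: {sorted(unknown)}")
    base = _extract_base(sentence, config, matchers)
    return _apply_context(base, sentence, config)


def union_configuration(configs: list[ModelConfiguration]) -> ModelConfiguration:
    """The superset configuration: every family any config activates, with
    per-family parameter sets unioned.  Context modes are not unioned —
    context is applied per model during filtering."""
    union = ModelConfiguration(event_type="__union__", context_mode="none")
    union.active_features = set()
    ngrams: dict[str, set[int]] = {}
    hops: dict[str, int] = {}
    vertex: dict[str, set[str]] = {}
    for cfg in configs:
        cfg.validate()
        union.active_features |= cfg.active_features
        for fam, sizes in cfg.ngram_sizes.items():
            ngrams.setdefault(fam, set()).update(sizes)
        for fam, h in cfg.hop_limits.items():
            hops[fam] = max(hops.get(fam, 0), h)
        for fam in VERTEX_FAMILIES:
            vertex.setdefault(fam, set()).update(cfg._vertex_set(fam))
    union.ngram_sizes = {k: frozenset(v) for k, v in ngrams.items()} \
        or _default_ngrams()
    union.hop_limits = hops or _default_hops()
    union.vertex_feature = {k: frozenset(v) for k, v in vertex.items()} \
        or _default_vertex()
    return union


def _keep_string(feat: str, config: ModelConfiguration) -> bool:
    key, _, _ = feat.partition("=")
    family = family_of_key(key)
    if family is None or family == "context":
        return False
    if family not in config.active_features:
        return False
    if key.startswith("CHARNGRAM_"):
        n = int(key.split("_")[1])
        return n in config.ngram_sizes.get("morphological", frozenset({2, 3}))
    if key.startswith("SP_EDGE_NGRAM_"):
        n = int(key.rsplit("_", 1)[1])
        return n in config.ngram_sizes.get("shortest_path", frozenset({2, 3}))
    if key.startswith("SP_VERTEX_NGRAM_"):
        _, _, _, n, vf = key.split("_", 4)
        return (
            int(n) in config.ngram_sizes.get("shortest_path", frozenset({2, 3}))
            and vf.lower() == config._vertex_set("shortest_path")[0]
        )
    if key.startswith("SP_VERTEX_PATH_"):
        vf = key[len("SP_VERTEX_PATH_"):]
        return vf.lower() == config._vertex_set("shortest_path")[0]
    return True


def filter_instance(
    instance: list[list[str]],
    sentence: Sentence,
    config: ModelConfiguration,
) -> list[list[str]]:
    """Reduce a superset extraction to exactly what ``config`` would have
    produced, then apply the config's own context mode."""
    sp_limit = config.hop_limits.get("shortest_path", 3)
    filtered: list[list[str]] = []
    for feats in instance:
        drop_sp = False
        for feat in feats:
            if feat.startswith("SPDistance="):
                if int(feat.partition("=")[2]) > sp_limit:
                    drop_sp = True
                break
        kept = []
        for feat in feats:
            key = feat.partition("=")[0]
            if drop_sp and family_of_key(key) == "shortest_path":
                continue
            if _keep_string(feat, config):
                kept.append(feat)
        filtered.append(kept)
    return _apply_context(filtered, sentence, config)


def union_and_filter(configs: list[ModelConfiguration]):
    """One extraction pass for many models.

    Returns the superset configuration and a filter callable
    ``f(instance, sentence, config) -> instance`` recovering each original
    configuration's exact feature strings.
    """
    return union_configuration(configs), filter_instance
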
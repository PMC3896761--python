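"""Feature families, context modes, and the union/filter machinery."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trigrec.core import Annotation, build_sentence
from trigrec.features import (FAMILIES, ConfigurationError,
                              ModelConfiguration, apply_conjunctions,
                              apply_dependency_windows, apply_local_windows,
                              extract, morphological_features, path_features,
                              sentence_length_feature, union_and_filter,
                              word_shape)
from trigrec.fixtures import FixtureSpec, generate_corpus


def _mini_sentence(words, pos=None, edges=(), chunks=None):
    rows, offset = [], 0
    pos = pos or ["NN"] * len(words)
    for i, w in enumerate(words):
        rows.append((i, w, offset, offset + len(w), w.lower(), pos[i]))
        offset += len(w) + 1
    return build_sentence(rows, list(edges), chunks or ["O"] * len(words))


class TestWorkedExampleStrings:
    """Every documented feature example reproduces verbatim on the frozen
    worked-example sentence."""

    @pytest.mark.parametrize("token_text,feature", [
        ("regulation", "IN_DEP_LABEL=NMOD"),
        ("regulation", "IN_DEP_LEMMA=in"),
        ("regulation", "IN_DEP_POS=PP"),
        ("regulation", "IN_DEP_CHUNK=PP"),
        ("regulation", "OUT_DEP_LABEL=OBJ"),
        ("regulation", "OUT_DEP_LEMMA=-"),
        ("regulation", "OUT_DEP_POS=HYPH"),
        ("regulation", "OUT_DEP_CHUNK=O"),
        ("regulation", "SP_EDGE_PATH=NMOD-PMOD-NMOD"),
        ("regulation", "SP_EDGE_TYPE=NMOD_3"),
        ("regulation", "SP_VERTEX_PATH_LEMMA=regulation-of-expression-4"),
        ("regulation", "SP_EDGE_NGRAM_2=NMOD_PMOD"),
        ("regulation", "SP_EDGE_NGRAM_2=PMOD_NMOD"),
        ("regulation", "SP_VERTEX_NGRAM_2_LEMMA=regulation_of"),
        ("regulation", "SP_VERTEX_NGRAM_2_LEMMA=of_expression"),
        ("regulation", "SP_VERTEX_NGRAM_2_LEMMA=expression_4"),
        ("regulation", "SPDistance=3"),
        ("regulation", "CONCEPT_NAME=interferon_regulatory_factor_4"),
        ("regulation", "CONCEPT_PROTEIN_HEAD=interferon"),
        ("expression", "CONCEPT_NAME=interferon_regulatory_factor_4"),
        ("interferon", "CONCEPT=Protein"),
        ("interferon", "CHUNK=B-NP"),
        ("regulatory", "CHUNK=I-NP"),
        ("Down", "CAP=InitUpp"),
        ("regulatory", "CONJ=interferon@-1_&_factor@1"),
    ])
    def test_feature_string_present(self, example_sentence, full_config,
                                    token_text, feature):
        instance = extract(example_sentence, full_config)
        tok = example_sentence.token_at(token_text)
        assert feature in instance[tok.index]

    def test_dependency_window_one_hop_neighbors(self, example_sentence):
        dw = apply_dependency_windows(
            [[] for _ in example_sentence.tokens], example_sentence, max_hops=1
        )
        reg = example_sentence.token_at("regulation")
        lemmas = {f.split("=", 1)[1] for f in dw[reg.index]
                  if f.startswith("DW_LEMMA=")}
        assert lemmas == {"of", "-", "in"}


class TestMorphological:
    def test_three_char_prefix(self):
        sent = _mini_sentence(["coexpression"])
        feats = morphological_features(sent)[0]
        assert "PREFIX3=coe" in feats

    def test_word_shape_pattern(self):
        assert word_shape("Abc:1234") == "Aaa#1111"

    def test_short_token_emits_no_long_affixes_or_ngrams(self):
        sent = _mini_sentence(["ab"])
        feats = morphological_features(sent, frozenset({3}))[0]
        assert not any(f.startswith(("PREFIX3", "SUFFIX3", "CHARNGRAM_3"))
                       for f in feats)
        assert "PREFIX2=ab" in feats

    @given(st.text(alphabet=st.characters(codec="ascii",
                                          exclude_characters="\x00 \t\n\r="),
                   min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_char_ngram_count_matches_tally(self, token):
        sent = _mini_sentence([token])
        feats = morphological_features(sent, frozenset({2, 3}))[0]
        for n in (2, 3):
            emitted = [f for f in feats if f.startswith(f"CHARNGRAM_{n}=")]
            assert len(emitted) == max(0, len(token) - n + 1)


class TestOrthographic:
    @given(st.text(alphabet=st.characters(codec="ascii",
                                          exclude_characters="\x00 \t\n\r="),
                   min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_counting_features_match_character_tallies(self, token):
        from trigrec.features import orthographic_features

        sent = _mini_sentence([token])
        feats = orthographic_features(sent)[0]
        assert f"COUNT_UPPER={sum(c.isupper() for c in token)}" in feats
        assert f"COUNT_DIGIT={sum(c.isdigit() for c in token)}" in feats
        assert f"LENGTH={len(token)}" in feats

    def test_lowercase_token_counts(self):
        from trigrec.features import orthographic_features

        feats = orthographic_features(_mini_sentence(["abc"]))[0]
        assert {"COUNT_UPPER=0", "COUNT_DIGIT=0", "LENGTH=3"} <= set(feats)
        assert "CAP=InitUpp" not in feats


class TestSentenceLength:
    def test_worked_example_is_under_15(self, example_sentence):
        assert sentence_length_feature(example_sentence)[0] == ["SENT_SIZE=<15"]

    def test_boundary_is_lower_inclusive(self):
        sent = _mini_sentence([f"w{i}" for i in range(15)])
        assert sentence_length_feature(sent)[0] == ["SENT_SIZE=[15,20)"]

    def test_sweep_yields_exactly_seven_bins(self):
        seen = set()
        for n in range(1, 61):
            sent = _mini_sentence([f"w{i}" for i in range(n)])
            seen.add(sentence_length_feature(sent)[0][0])
        assert len(seen) == 7


class TestConcepts:
    def test_counts_per_type(self):
        sent = _mini_sentence(["A", "binds", "B", "near", "C"])
        sent.annotations.insert(Annotation("T1", "Protein", 0, 1, "A"))
        sent.annotations.insert(Annotation("T2", "Protein", 8, 9, "B"))
        sent.annotations.insert(Annotation("T3", "Chemical", 15, 16, "C"))
        from trigrec.features import concept_features

        feats = concept_features(sent)
        for per_token in feats:
            assert "NUM_PROTEIN=2" in per_token
            assert "NUM_CHEMICAL=1" in per_token

    def test_no_concepts_emits_nothing(self):
        from trigrec.features import concept_features

        sent = _mini_sentence(["no", "entities", "here"])
        assert concept_features(sent) == [[], [], []]


class TestModifier:
    def test_subject_and_object_of_verb(self):
        sent = _mini_sentence(
            ["cells", "express", "IL2"],
            pos=["NNS", "VBP", "NN"],
            edges=[(1, 0, "SUB"), (1, 2, "OBJ")],
        )
        from trigrec.features import modifier_features

        feats = modifier_features(sent)
        assert "SUBJ_OF_VERB=express" in feats[0]
        assert "OBJ_OF_VERB=express" in feats[2]
        assert "MODIFIER=cells" in feats[1]

    def test_isolated_token_has_no_modifier_features(self):
        from trigrec.features import modifier_features

        sent = _mini_sentence(["alone"])
        assert modifier_features(sent) == [[]]


class TestPathFeatures:
    def test_single_edge_path_ngram_length_guard(self, example_sentence):
        from trigrec.core import shortest_path

        path = shortest_path(example_sentence.graph, 2, 3)
        feats = path_features(path, example_sentence, ("lemma",),
                              frozenset({2}))
        # one edge cannot form an edge 2-gram; its two vertices form one
        assert not any(f.startswith("SP_EDGE_NGRAM") for f in feats)
        assert sum(f.startswith("SP_VERTEX_NGRAM_2") for f in feats) == 1
        assert not any("NGRAM_3" in f for f in feats)
        assert "SP_EDGE_PATH=NMOD" in feats

    def test_zero_hop_path_emits_nothing(self, example_sentence):
        from trigrec.core import TokenPath

        assert path_features(TokenPath([4], []), example_sentence) == []

    def test_hop_limit_suppresses_long_paths(self, example_sentence):
        cfg = ModelConfiguration(
            event_type="x", active_features={"shortest_path"},
            hop_limits={"shortest_path": 2, "dependency_window": 3},
        )
        instance = extract(example_sentence, cfg)
        reg = example_sentence.token_at("regulation")
        assert instance[reg.index] == []  # 3 hops > limit 2


class TestContextModes:
    def test_first_token_window_skipped(self, example_sentence):
        conj = apply_conjunctions([[] for _ in example_sentence.tokens],
                                  example_sentence)
        first = conj[0]
        assert not any("@-1" in f for f in first)

    def test_single_token_sentence_no_window_features(self):
        sent = _mini_sentence(["solo"])
        assert apply_local_windows([[]], sent) == [[]]
        assert apply_conjunctions([[]], sent) == [[]]

    def test_conjunction_count_matches_enumeration(self, example_sentence):
        n = len(example_sentence.tokens)
        conj = apply_conjunctions([[] for _ in range(n)], example_sentence)
        windows = ((-3, -1), (-2, -1), (-1, 0), (-1, 1), (0, 1))
        for i in range(n):
            expected = 2 * sum(
                1 for o1, o2 in windows
                if 0 <= i + o1 < n and 0 <= i + o2 < n
            )  # lemma and POS streams
            assert len(conj[i]) == expected

    def test_local_window_count_matches_enumeration(self, example_sentence):
        n = len(example_sentence.tokens)
        lw = apply_local_windows([[] for _ in range(n)], example_sentence)
        for i in range(n):
            neighbors = sum(1 for o in (-3, -2, -1, 1) if 0 <= i + o < n)
            assert len(lw[i]) == 4 * neighbors

    def test_dependency_window_matches_bfs_oracle(self, small_corpus):
        for doc in small_corpus[:4]:
            for sent in doc.sentences:
                nxg = nx.Graph()
                nxg.add_nodes_from(t.index for t in sent.tokens)
                nxg.add_edges_from((u, v) for u, v, _, _ in sent.graph.edges)
                for k in (1, 2):
                    dw = apply_dependency_windows(
                        [[] for _ in sent.tokens], sent, max_hops=k
                    )
                    for tok in sent.tokens:
                        reach = {
                            v for v, d in nx.single_source_shortest_path_length(
                                nxg, tok.index, cutoff=k).items()
                            if v != tok.index
                        }
                        lemmas = {f.split("=", 1)[1] for f in dw[tok.index]
                                  if f.startswith("DW_LEMMA=")}
                        expected = {
                            sent.tokens[v].feature("LEMMA") for v in reach
                        }
                        assert lemmas == expected


class TestExtractAndUnion:
    def test_family_switch_respected(self, example_sentence):
        cfg = ModelConfiguration(event_type="x", active_features={"token"})
        instance = extract(example_sentence, cfg)
        for feats in instance:
            assert all(f.split("=")[0] in
                       {"W", "LEMMA", "POS", "CHUNK"} for f in feats)

    def test_unknown_family_rejected(self, example_sentence):
        cfg = ModelConfiguration(event_type="x",
                                 active_features={"embeddings"})
        with pytest.raises(ConfigurationError):
            extract(example_sentence, cfg)

    def test_extraction_is_deterministic(self, example_sentence, full_config):
        a = extract(example_sentence, full_config)
        b = extract(example_sentence, full_config)
        assert a == b

    def test_subset_union_equals_larger_config(self):
        a = ModelConfiguration(event_type="A", active_features={"token"})
        b = ModelConfiguration(event_type="B",
                               active_features={"token", "orthographic"})
        union, _ = union_and_filter([a, b])
        assert union.active_features == {"token", "orthographic"}

    def test_filter_equivalence_over_random_corpus(self):
        """Filtering the union extraction by each configuration reproduces
        that configuration's direct extraction byte-for-byte (the central
        property of single-pass multi-model annotation)."""
        docs = generate_corpus(FixtureSpec(n_documents=13,
                                           sentences_per_doc=4, seed=3))
        configs = [
            ModelConfiguration(
                event_type="A",
                active_features={"token", "morphological", "shortest_path"},
                context_mode="conjunctions",
                ngram_sizes={"morphological": frozenset({2}),
                             "shortest_path": frozenset({2})},
                hop_limits={"shortest_path": 2, "dependency_window": 1},
                vertex_feature={"shortest_path": "pos"},
            ),
            ModelConfiguration(
                event_type="B",
                active_features={"token", "orthographic", "dependency_edge",
                                 "shortest_path"},
                context_mode="dependency_window",
                ngram_sizes={"morphological": frozenset({3, 4}),
                             "shortest_path": frozenset({2, 3})},
                hop_limits={"shortest_path": 3, "dependency_window": 2},
                vertex_feature={"shortest_path": "lemma"},
            ),
            ModelConfiguration(
                event_type="C",
                active_features=set(FAMILIES) - {"dictionary"},
                context_mode="window",
            ),
        ]
        union, filt = union_and_filter(configs)
        n_sentences = 0
        for doc in docs:
            for sent in doc.sentences:
                superset = extract(sent, union)
                for cfg in configs:
                    assert extract(sent, cfg) == filt(superset, sent, cfg)
                n_sentences += 1
        assert n_sentences >= 50
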
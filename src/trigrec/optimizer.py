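"""Greedy per-event-type model-configuration search.

For each event type the search (a) makes a greedy forward pass over the
feature-family catalogue, keeping a family only when it strictly improves
micro-F1 on a held-out development split, (b) picks the best local-context
mode, then (c)-(e) refines n-gram sizes, dependency hop limits and vertex
information for the families that survived (a) — every candidate evaluated
across all requested model orders, ties resolved toward the lowest order.
Families rejected in (a) are skipped by the later refinement steps.  The
accepted-trial F1 sequence is non-decreasing by construction, and the whole
search is reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .crf import TriggerModel, decode, train
from .evaluation import EvalMatrix, match_exact, micro_prf
from .features import (CONTEXT_MODES, FAMILIES, HOP_FAMILIES, NGRAM_FAMILIES,
                       VERTEX_FAMILIES, VERTEX_TYPES, ModelConfiguration,
                       extract)
from .io_standoff import Document

logger = logging.getLogger(__name__)

__all__ = ["OptimizationSpace", "TrialRecord", "split_dataset",
           "train_models", "optimize", "finalize", "trial_log_tsv"]


@dataclass
class OptimizationSpace:
    """The candidate grid the greedy search walks over."""

    types: tuple[str, ...]
    families: tuple[str, ...] = FAMILIES
    orders: tuple[int, ...] = (1, 2, 3)
    contexts: tuple[str, ...] = CONTEXT_MODES
    ngram_sets: tuple[frozenset[int], ...] = (
        frozenset({2, 3, 4}), frozenset({2, 3}), frozenset({3, 4}),
    )
    hops: tuple[int, ...] = (2, 3)
    vertex_types: tuple[str, ...] = VERTEX_TYPES

    def validate(self) -> None:
        if not self.types or not self.families or not self.orders:
            raise ValueError("types, families and orders must be non-empty")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if not set(self.contexts) <= set(CONTEXT_MODES):
            raise ValueError("unknown context mode in space")
        if not set(self.vertex_types) <= set(VERTEX_TYPES):
            raise ValueError("unknown vertex type in space")

    @property
    def ngram_families(self) -> tuple[str, ...]:
        return tuple(f for f in self.families if f in NGRAM_FAMILIES)

    @property
    def hop_families(self) -> tuple[str, ...]:
        return tuple(f for f in self.families if f in HOP_FAMILIES)

    @property
    def vertex_families(self) -> tuple[str, ...]:
        return tuple(f for f in self.families if f in VERTEX_FAMILIES)


@dataclass
class TrialRecord:
    """One evaluated candidate configuration."""

    event_type: str
    step: str
    candidate: str
    per_order_f1: dict[int, float]
    best_order: int
    best_f1: float
    accepted: bool


def split_dataset(
    docs: list[Document], ratio: float = 0.75, seed: int = 0
) -> tuple[list[Document], list[Document]]:
    """Document-level random partition into train and development parts."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("split ratio must be in (0, 1)")
    if len(docs) < 2:
        raise ValueError("need at least 2 documents to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(docs))
    n_train = min(max(int(round(ratio * len(docs))), 1), len(docs) - 1)
    train_docs = [docs[i] for i in sorted(perm[:n_train])]
    dev_docs = [docs[i] for i in sorted(perm[n_train:])]
    return train_docs, dev_docs


def _dev_f1(model: TriggerModel, dev_docs: list[Document], matchers=()
            ) -> float:
    matrix = EvalMatrix()
    etype = model.event_type
    for doc in dev_docs:
        for sent in doc.sentences:
            pred = decode(model, sent, matchers=matchers)
            matrix.merge(match_exact(sent.triggers(etype), pred))
    return micro_prf(matrix, (etype,))[2]


def train_models(
    train_docs: list[Document],
    dev_docs: list[Document],
    config: ModelConfiguration,
    orders: tuple[int, ...],
    matchers=(),
    sigma2: float = 1.0,
    max_iter: int = 200,
) -> tuple[float, int, dict[int, float]]:
    """Train one model per order, score each on the development split, and
    return (best F1, best order, per-order F1); F1 ties go to the lowest
    order."""
    per_order: dict[int, float] = {}
    best_f1, best_order = -1.0, min(orders)
    for order in sorted(orders):
        cfg = replace(config, order=order)
        model = train(train_docs, cfg, matchers=matchers, sigma2=sigma2,
                      max_iter=max_iter)
        f1 = _dev_f1(model, dev_docs, matchers=matchers)
        per_order[order] = f1
        if f1 > best_f1:
            best_f1, best_order = f1, order
    return best_f1, best_order, per_order


def optimize(
    docs: list[Document],
    space: OptimizationSpace,
    ratio: float = 0.75,
    seed: int = 0,
    matchers=(),
    sigma2: float = 1.0,
    max_iter: int = 200,
) -> tuple[dict[str, ModelConfiguration], list[TrialRecord]]:
    """Run the greedy search for every event type in the space.

    Returns the optimized per-type configurations plus the full trial log.
    """
    space.validate()
    train_docs, dev_docs = split_dataset(docs, ratio=ratio, seed=seed)
    configs: dict[str, ModelConfiguration] = {}
    trials: list[TrialRecord] = []

    for etype in space.types:
        n_gold = sum(
            len(s.triggers(etype)) for d in train_docs for s in d.sentences
        )
        if n_gold == 0:
            logger.warning("no gold %s spans in the train split; skipped",
                           etype)
            continue
        config = ModelConfiguration(event_type=etype, order=min(space.orders))
        best_f1 = 0.0
        best_order = min(space.orders)

        def evaluate(candidate: ModelConfiguration, step: str, name: str,
                     accept_if_better: bool) -> tuple[float, int]:
            nonlocal best_f1, best_order
            f1, order, per_order = train_models(
                train_docs, dev_docs, candidate, space.orders,
                matchers=matchers, sigma2=sigma2, max_iter=max_iter,
            )
            accepted = f1 > best_f1
            trials.append(TrialRecord(etype, step, name, per_order, order,
                                      f1, accepted))
            if accepted and accept_if_better:
                best_f1, best_order = f1, order
            return f1, order

        # (a) greedy forward pass over the feature families
        for family in space.families:
            candidate = config.copy()
            candidate.active_features.add(family)
            f1, order = evaluate(candidate, "feature", family, True)
            if f1 > 0 and trials[-1].accepted:
                config = candidate
        if not config.active_features:
            logger.warning("no feature family improved F1 for %s", etype)
            configs[etype] = config
            continue

        # (b) best local-context mode (default none)
        for mode in space.contexts:
            if mode == config.context_mode:
                continue
            candidate = config.copy()
            candidate.context_mode = mode
            f1, order = evaluate(candidate, "context", mode, True)
            if trials[-1].accepted:
                config = candidate

        # (c) n-gram sizes per retained n-gram-bearing family
        for family in space.ngram_families:
            if family not in config.active_features:
                continue
            for sizes in space.ngram_sets:
                if sizes == config.ngram_sizes.get(family):
                    continue
                candidate = config.copy()
                candidate.ngram_sizes[family] = frozenset(sizes)
                name = f"{family}:{{{','.join(map(str, sorted(sizes)))}}}"
                evaluate(candidate, "ngrams", name, True)
                if trials[-1].accepted:
                    config = candidate

        # (d) hop limits per retained hop-bearing family
        for family in space.hop_families:
            if family not in config.active_features:
                continue
            for hops in space.hops:
                if hops == config.hop_limits.get(family):
                    continue
                candidate = config.copy()
                candidate.hop_limits[family] = hops
                evaluate(candidate, "hops", f"{family}:{hops}", True)
                if trials[-1].accepted:
                    config = candidate

        # (e) vertex information per retained vertex-bearing family
        for family in space.vertex_families:
            if family not in config.active_features:
                continue
            for vtype in space.vertex_types:
                if vtype == config.vertex_feature.get(family):
                    continue
                candidate = config.copy()
                candidate.vertex_feature[family] = vtype
                evaluate(candidate, "vertex", f"{family}:{vtype}", True)
                if trials[-1].accepted:
                    config = candidate

        config.order = best_order
        configs[etype] = config
    return configs, trials


def finalize(
    docs: list[Document],
    configs: dict[str, ModelConfiguration],
    matchers=(),
    sigma2: float = 1.0,
    max_iter: int = 200,
) -> dict[str, TriggerModel]:
    """Retrain each type's model on the complete corpus with its optimized
    configuration."""
    models = {}
    for etype, config in configs.items():
        models[etype] = train(docs, config, matchers=matchers, sigma2=sigma2,
                              max_iter=max_iter)
    return models


def trial_log_tsv(trials: list[TrialRecord]) -> str:
    lines = ["type\tstep\tcandidate\tper_order_f1\tbest_order\tbest_f1\taccepted"]
    for t in trials:
        per_order = ",".join(
            f"{o}:{f1:.3f}" for o, f1 in sorted(t.per_order_f1.items())
        )
        lines.append(
            f"{t.event_type}\t{t.step}\t{t.candidate}\t{per_order}"
            f"\t{t.best_order}\t{t.best_f1:.3f}\t{int(t.accepted)}"
        )
    return "\n".join(lines) + "\n"
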
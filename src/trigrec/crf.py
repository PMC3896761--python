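"""Per-event-type linear-chain CRF training and decoding.

Trigger spans are BIO-encoded per event type and modeled with a first-order
linear-chain conditional random field

    p(y | x, lambda) = 1/Z(x) * exp( sum_j lambda_j F_j(y, x) ),

where each global feature function F_j sums a state function s(y_i, x, i)
(one per observed attribute/label pair) or a transition function
t(y_{i-1}, y_i) over the sequence.  Weights are estimated by maximizing the
L2-regularized conditional log-likelihood with L-BFGS; decoding is exact
Viterbi dynamic programming.

Higher model orders are realized by composing each label with its previous
o-1 labels (:func:`raise_order`), which reduces an order-o chain to a
first-order-equivalent one over composite labels; invalid composite
transitions are masked out of both training and decoding, so the reduction
is behavior-equivalent to a native order-o chain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import Annotation, Sentence
from .features import ModelConfiguration, extract, filter_instance, \
    union_configuration
from .io_standoff import Document
from .matching import filter_no_concept, filter_parentheses

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "LinearChainCRF",
    "TriggerModel",
    "encode_bio",
    "decode_spans",
    "raise_order",
    "lower_order",
    "train",
    "decode",
    "annotate_corpus",
]

NEG_INF = -1e30  # large finite stand-in keeps arithmetic NaN-free


class AlignmentError(ValueError):
    """A gold trigger span does not align with token boundaries."""


# --------------------------------------------------------------------------
# BIO encoding and the composite-label order reduction
# --------------------------------------------------------------------------

def encode_bio(sentence: Sentence, event_type: str) -> list[str]:
    """Per-token B/I/O labels for one event type's gold triggers.

    Overlapping same-type spans are resolved toward the longest span.
    """
    triggers = sorted(
        sentence.triggers(event_type),
        key=lambda a: (-(a.end - a.start), a.start),
    )
    kept: list[Annotation] = []
    for ann in triggers:
        if not any(k.start < ann.end and ann.start < k.end for k in kept):
            kept.append(ann)
    labels = ["O"] * len(sentence.tokens)
    for ann in kept:
        toks = sentence.tokens_in_span(ann.start, ann.end)
        if not toks or toks[0].start != ann.start or toks[-1].end != ann.end:
            raise AlignmentError(
                f"trigger {ann.id} [{ann.start},{ann.end}) not aligned to "
                f"token boundaries"
            )
        labels[toks[0].index] = "B"
        for tok in toks[1:]:
            labels[tok.index] = "I"
    return labels


def decode_spans(
    labels: list[str], sentence: Sentence, event_type: str
) -> list[Annotation]:
    """Convert maximal B/I runs back into character-offset annotations."""
    spans: list[tuple[int, int]] = []
    run_start = None
    for i, label in enumerate(labels + ["O"]):
        if label == "B" or (label == "I" and run_start is None):
            if run_start is not None:
                spans.append((run_start, i - 1))
            run_start = i
        elif label != "I" and run_start is not None:
            spans.append((run_start, i - 1))
            run_start = None
    out = []
    base = sentence.start
    for n, (first, last) in enumerate(spans):
        start = sentence.tokens[first].start
        end = sentence.tokens[last].end
        out.append(
            Annotation(
                id=f"TP{n + 1}",
                type=event_type,
                start=start,
                end=end,
                text=sentence.text[start - base:end - base],
                kind="trigger",
            )
        )
    return out


def raise_order(labels: list[str], order: int) -> list[str]:
    """Compose each label with its previous ``order - 1`` labels, producing
    a first-order-equivalent chain; ``order == 1`` is the identity."""
    if order < 1:
        raise ValueError("model order must be >= 1")
    if order == 1:
        return list(labels)
    return [
        "|".join(labels[max(0, i - order + 1):i + 1])
        for i in range(len(labels))
    ]


def lower_order(labels: list[str]) -> list[str]:
    """Inverse of :func:`raise_order`: keep each composite's last component."""
    return [label.rsplit("|", 1)[-1] for label in labels]


# --------------------------------------------------------------------------
# the CRF estimator
# --------------------------------------------------------------------------

class LinearChainCRF:
    """Linear-chain CRF with a scikit-learn-style estimator interface.

    Parameters
    ----------
    sigma2 : float
        Variance of the Gaussian (L2) prior on the weights; the penalty is
        ``||w||^2 / (2 * sigma2)``.
    max_iter : int
        L-BFGS iteration cap.
    tol : float
        Convergence tolerance passed to the optimizer.

    Fitted attributes (trailing underscore): ``labels_``, ``attributes_``,
    ``state_weights_`` (n_attributes x n_labels), ``trans_weights_``
    (n_labels x n_labels).
    """

    def __init__(self, sigma2: float = 1.0, max_iter: int = 200,
                 tol: float = 1e-5) -> None:
        self.sigma2 = sigma2
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"sigma2": self.sigma2, "max_iter": self.max_iter,
                "tol": self.tol}

    def set_params(self, **params) -> "LinearChainCRF":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- model structure ----------------------------------------------------
    def _build_masks(self) -> None:
        comps = [label.split("|") for label in self.labels_]
        n_comp = np.array([len(c) for c in comps])
        order = int(n_comp.max())
        L = len(self.labels_)
        trans_ok = np.zeros((L, L), dtype=bool)
        for a in range(L):
            for b in range(L):
                need = min(n_comp[a] + 1, order)
                if n_comp[b] != need:
                    continue
                if n_comp[b] == 1:
                    trans_ok[a, b] = True
                else:
                    hist = comps[b][:-1]
                    trans_ok[a, b] = comps[a][-len(hist):] == hist
        self.order_ = order
        self._n_comp = n_comp
        self._trans_ok = trans_ok

    def _position_mask(self, length: int) -> np.ndarray:
        """(T, L) additive mask: a composite of k components is only valid
        at positions where exactly k labels of history are available."""
        need = np.minimum(np.arange(length) + 1, self.order_)
        mask = np.where(self._n_comp[None, :] == need[:, None], 0.0, NEG_INF)
        return mask

    # -- training -----------------------------------------------------------
    def fit(self, X: list[list[list[str]]], y: list[list[str]]
            ) -> "LinearChainCRF":
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        for xs, ys in zip(X, y):
            if len(xs) != len(ys):
                raise ValueError("sequence length mismatch")
        self.labels_ = sorted({label for seq in y for label in seq})
        self.attributes_ = sorted({a for seq in X for feats in seq
                                   for a in feats})
        attr_index = {a: i for i, a in enumerate(self.attributes_)}
        label_index = {l: i for i, l in enumerate(self.labels_)}
        self._build_masks()

        S = len(X)
        lengths = np.array([len(seq) for seq in X], dtype=np.int64)
        T = int(lengths.max()) if S else 0
        L = len(self.labels_)
        K = len(self.attributes_)

        fi_seq, fi_pos, fi_attr = [], [], []
        y_idx = np.zeros((S, T), dtype=np.int64)
        for s, (xs, ys) in enumerate(zip(X, y)):
            for t, (feats, label) in enumerate(zip(xs, ys)):
                y_idx[s, t] = label_index[label]
                for a in feats:
                    fi_seq.append(s)
                    fi_pos.append(t)
                    fi_attr.append(attr_index[a])
        fi_seq = np.array(fi_seq, dtype=np.int64)
        fi_pos = np.array(fi_pos, dtype=np.int64)
        fi_attr = np.array(fi_attr, dtype=np.int64)

        # empirical feature counts
        emp_state = np.zeros((K, L))
        np.add.at(emp_state, (fi_attr, y_idx[fi_seq, fi_pos]), 1.0)
        emp_trans = np.zeros((L, L))
        for s in range(S):
            for t in range(1, lengths[s]):
                emp_trans[y_idx[s, t - 1], y_idx[s, t]] += 1.0

        trans_mask = np.where(self._trans_ok, 0.0, NEG_INF)
        active = np.arange(T)[None, :] < lengths[:, None]  # (S, T)
        pos_mask = self._position_mask(T)  # (T, L)
        rev_idx = np.maximum(lengths[:, None] - 1 - np.arange(T)[None, :], 0)

        def node_potentials(Ws: np.ndarray) -> np.ndarray:
            node = np.tile(pos_mask[None, :, :], (S, 1, 1))
            np.add.at(node, (fi_seq, fi_pos), Ws[fi_attr])
            return node

        def forward(node: np.ndarray, trans: np.ndarray) -> np.ndarray:
            alpha = np.empty((S, T, L))
            alpha[:, 0] = node[:, 0]
            for t in range(1, T):
                new = logsumexp(
                    alpha[:, t - 1, :, None] + trans[None], axis=1
                ) + node[:, t]
                alpha[:, t] = np.where(active[:, t, None], new,
                                       alpha[:, t - 1])
            return alpha

        def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
            Ws = w[:K * L].reshape(K, L)
            Wt = w[K * L:].reshape(L, L)
            node = node_potentials(Ws)
            trans = Wt + trans_mask
            alpha = forward(node, trans)
            logZ = logsumexp(alpha[:, T - 1], axis=1)

            node_rev = np.take_along_axis(
                node, rev_idx[:, :, None].repeat(L, axis=2), axis=1
            )
            alpha_rev = forward(node_rev, trans.T)
            beta = np.take_along_axis(
                alpha_rev, rev_idx[:, :, None].repeat(L, axis=2), axis=1
            ) - node

            gold = (emp_state * Ws).sum() + (emp_trans * Wt).sum()
            nll = logZ.sum() - gold + (w @ w) / (2.0 * self.sigma2)

            log_marg = alpha + beta - logZ[:, None, None]
            marg = np.where(active[:, :, None], np.exp(log_marg), 0.0)
            g_state = -emp_state
            np.add.at(g_state, fi_attr, marg[fi_seq, fi_pos])

            if T > 1:
                log_pair = (
                    alpha[:, :-1, :, None]
                    + trans[None, None]
                    + (node + beta)[:, 1:, None, :]
                    - logZ[:, None, None, None]
                )
                pair = np.where(
                    active[:, 1:, None, None], np.exp(log_pair), 0.0
                )
                g_trans = pair.sum(axis=(0, 1)) - emp_trans
            else:
                g_trans = -emp_trans
            grad = np.concatenate([g_state.ravel(), g_trans.ravel()])
            grad += w / self.sigma2
            return nll, grad

        w0 = np.zeros(K * L + L * L)
        if S == 0 or K == 0:
            self.state_weights_ = np.zeros((K, L))
            self.trans_weights_ = np.zeros((L, L))
            return self
        with np.errstate(over="ignore", under="ignore"):
            result = minimize(
                objective, w0, jac=True, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol,
                         "gtol": 1e-6},
            )
        w = result.x
        self.state_weights_ = w[:K * L].reshape(K, L)
        self.trans_weights_ = w[K * L:].reshape(L, L)
        self._attr_index = attr_index
        return self

    # -- inference ----------------------------------------------------------
    def _node_scores(self, xseq: list[list[str]], count_unseen: bool = False
                     ) -> tuple[np.ndarray, int, int]:
        T, L = len(xseq), len(self.labels_)
        node = self._position_mask(T).copy()
        attr_index = getattr(self, "_attr_index", None)
        if attr_index is None:
            attr_index = {a: i for i, a in enumerate(self.attributes_)}
            self._attr_index = attr_index
        seen = unseen = 0
        for t, feats in enumerate(xseq):
            for a in feats:
                idx = attr_index.get(a)
                if idx is None:
                    unseen += 1
                else:
                    seen += 1
                    node[t] += self.state_weights_[idx]
        return node, seen, unseen

    def predict_single(self, xseq: list[list[str]]) -> list[str]:
        if not xseq:
            return []
        node, _, _ = self._node_scores(xseq)
        trans = self.trans_weights_ + np.where(self._trans_ok, 0.0, NEG_INF)
        T, L = node.shape
        delta = np.empty((T, L))
        back = np.zeros((T, L), dtype=np.int64)
        delta[0] = node[0]
        for t in range(1, T):
            scores = delta[t - 1][:, None] + trans
            back[t] = scores.argmax(axis=0)
            delta[t] = scores.max(axis=0) + node[t]
        path = [int(delta[T - 1].argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels_[i] for i in path]

    def predict(self, X: list[list[list[str]]]) -> list[list[str]]:
        return [self.predict_single(xs) for xs in X]

    def sequence_score(self, xseq: list[list[str]], yseq: list[str]) -> float:
        """Unnormalized log-score of a label sequence (state + transition
        weights; no validity masks — caller supplies valid sequences)."""
        label_index = {l: i for i, l in enumerate(self.labels_)}
        node, _, _ = self._node_scores(xseq)
        node -= self._position_mask(len(xseq))  # raw weights only
        score = 0.0
        prev = None
        for t, label in enumerate(yseq):
            li = label_index[label]
            score += node[t, li]
            if prev is not None:
                score += self.trans_weights_[prev, li]
            prev = li
        return float(score)

    def log_partition(self, xseq: list[list[str]]) -> float:
        """log Z(x) over valid label sequences."""
        node, _, _ = self._node_scores(xseq)
        trans = self.trans_weights_ + np.where(self._trans_ok, 0.0, NEG_INF)
        alpha = node[0]
        for t in range(1, len(xseq)):
            alpha = logsumexp(alpha[:, None] + trans, axis=0) + node[t]
        return float(logsumexp(alpha))

    def unseen_rate(self, xseq: list[list[str]]) -> float:
        _, seen, unseen = self._node_scores(xseq)
        total = seen + unseen
        return unseen / total if total else 0.0


# --------------------------------------------------------------------------
# trigger-model wrapper over corpora
# --------------------------------------------------------------------------

@dataclass
class TriggerModel:
    """A trained per-event-type model bundle: the CRF plus the feature
    configuration it was trained with."""

    event_type: str
    config: ModelConfiguration
    crf: LinearChainCRF
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        crf = self.crf
        payload = {
            "event_type": self.event_type,
            "config": self.config.to_dict(),
            "params": crf.get_params(),
            "labels": crf.labels_,
            "attributes": crf.attributes_,
            "state_weights": crf.state_weights_.tolist(),
            "trans_weights": crf.trans_weights_.tolist(),
            "meta": self.meta,
        }
        path.write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TriggerModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        crf = LinearChainCRF(**payload["params"])
        crf.labels_ = payload["labels"]
        crf.attributes_ = payload["attributes"]
        crf.state_weights_ = np.array(payload["state_weights"]).reshape(
            len(crf.attributes_), len(crf.labels_)
        )
        crf.trans_weights_ = np.array(payload["trans_weights"]).reshape(
            len(crf.labels_), len(crf.labels_)
        )
        crf._build_masks()
        return cls(
            event_type=payload["event_type"],
            config=ModelConfiguration.from_dict(payload["config"]),
            crf=crf,
            meta=payload.get("meta", {}),
        )


def train(
    docs: list[Document],
    config: ModelConfiguration,
    matchers=(),
    sigma2: float = 1.0,
    max_iter: int = 200,
) -> TriggerModel:
    """Train one event type's CRF over a corpus featurized with ``config``."""
    X, y = [], []
    positives = 0
    for doc in docs:
        for sent in doc.sentences:
            X.append(extract(sent, config, matchers))
            labels = encode_bio(sent, config.event_type)
            positives += sum(1 for l in labels if l != "O")
            y.append(raise_order(labels, config.order))
    if positives == 0:
        logger.warning(
            "no positive %s spans in training corpus; model is degenerate",
            config.event_type,
        )
    crf = LinearChainCRF(sigma2=sigma2, max_iter=max_iter)
    crf.fit(X, y)
    return TriggerModel(event_type=config.event_type, config=config, crf=crf)


def decode(
    model: TriggerModel,
    sentence: Sentence,
    instance: list[list[str]] | None = None,
    matchers=(),
) -> list[Annotation]:
    """Viterbi-decode one sentence into typed trigger annotations."""
    if instance is None:
        instance = extract(sentence, model.config, matchers)
    if instance and model.crf.unseen_rate(instance) > 0.5:
        logger.warning(
            "more than 50%% of features unseen by the %s model; was the "
            "instance extracted with a mismatched configuration?",
            model.event_type,
        )
    labels = lower_order(model.crf.predict_single(instance))
    return decode_spans(labels, sentence, model.event_type)


def annotate_corpus(
    models: list[TriggerModel],
    docs: list[Document],
    matchers=(),
    postprocess: bool = True,
) -> list[Document]:
    """Annotate a corpus with several per-event-type models.

    Features are extracted once per sentence with the union of all model
    configurations and filtered per model, so every model sees exactly the
    strings its own configuration would have produced.  Predicted triggers
    from all models are inserted into the sentence's annotation tree
    (overlapping types are all retained), then the post-processing filters
    run unless disabled.
    """
    if not models:
        return docs
    union = union_configuration([m.config for m in models])
    for doc in docs:
        for sent in doc.sentences:
            superset = extract(sent, union, matchers)
            predicted: list[Annotation] = []
            for model in models:
                instance = filter_instance(superset, sent, model.config)
                predicted.extend(decode(model, sent, instance=instance))
            if postprocess:
                predicted = filter_parentheses(predicted)
                predicted = filter_no_concept(predicted, sent)
            for ann in predicted:
                sent.annotations.insert(ann)
    return docs
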
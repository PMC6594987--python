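"""Per-entity-type linear-chain CRF tagging with N-best decoding.

One model is trained per entity type over a three-label space
{B-T, I-T, O}.  Token features follow the token-per-line schema (word,
lemma, POS, chunk, dictionary BIO) with a configurable context window.
Decoding exposes the exact conditional distribution: ``nbest`` returns the
top-N label sequences with true probabilities P(y|x) = exp(score(y))/Z,
where Z sums over all 3^len sequences — the quantity the active-learning
entropy criterion is defined on.

The model is globally normalized:

    score(y | x) = sum_t node(t, y_t) + sum_{t>0} trans(y_{t-1}, y_t)

with node potentials linear in binary indicator features.  Training
maximizes L2-penalized conditional log-likelihood with L-BFGS, which is
deterministic given the data order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus_io import Token, spans_to_bio
from .linguistics import analyse
from .rules_engine import EntityDictionary, dict_match

#: label order; ties in decoding resolve lexicographically (B < I < O),
#: which coincides with index order.
LABEL_KINDS = ("B", "I", "O")


@dataclass(frozen=True)
class FeatureRow:
    """One token's feature tuple: offsets, surface, lemma, POS tag, chunk
    BIO, and dictionary BIO for the active entity type."""
    begin: int
    end: int
    word: str
    lemma: str
    pos: str
    chunk: str
    dict_label: str


@dataclass(frozen=True)
class LabelHypothesis:
    labels: tuple[str, ...]
    probability: float
    score: float


@dataclass
class CRFConfig:
    window: int = 2          # feature context window (+/- tokens)
    use_dict: bool = True    # include the dictionary BIO column
    c2: float = 1.0          # L2 regularization strength
    max_iterations: int = 200


def labels_for(entity_type: str) -> tuple[str, str, str]:
    return (f"B-{entity_type}", f"I-{entity_type}", "O")


def build_features(
    tokens: list[Token],
    entity_dictionary: EntityDictionary | None = None,
    text: str | None = None,
) -> list[FeatureRow]:
    """Featurize one sentence: lemma/POS/chunk from the bundled linguistic
    backend, dictionary BIO from the active entity type's dictionary (all O
    when no dictionary is given, as for experimental values)."""
    lemmas, pos, chunks = analyse(tokens)
    if entity_dictionary is not None:
        spans = dict_match(tokens, entity_dictionary, text)
        dict_bio = spans_to_bio(tokens, spans, entity_dictionary.entity_type)
    else:
        dict_bio = ["O"] * len(tokens)
    return [
        FeatureRow(t.begin, t.end, t.surface, lemmas[i], pos[i], chunks[i],
                   dict_bio[i])
        for i, t in enumerate(tokens)
    ]


def _token_features(rows: list[FeatureRow], t: int, config: CRFConfig) -> list[str]:
    columns = [("w", "word"), ("l", "lemma"), ("p", "pos"), ("c", "chunk")]
    if config.use_dict:
        columns.append(("d", "dict_label"))
    feats = ["bias"]
    for d in range(-config.window, config.window + 1):
        i = t + d
        if 0 <= i < len(rows):
            for tag, attr in columns:
                feats.append(f"{tag}[{d}]={getattr(rows[i], attr)}")
        else:
            feats.append(f"pad[{d}]")
    return feats


@dataclass
class TaggerModel:
    """A trained per-entity CRF: feature vocabulary, emission weights
    (n_features x 3) and transition weights (3 x 3), plus training
    metadata so a persisted model is self-describing."""
    entity_type: str
    feature_index: dict[str, int]
    weights: np.ndarray
    transitions: np.ndarray
    config: CRFConfig
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> tuple[str, str, str]:
        return labels_for(self.entity_type)

    # -- potentials -------------------------------------------------------
    def potentials(self, rows: list[FeatureRow]) -> tuple[np.ndarray, np.ndarray]:
        """(node scores (T,3), transition scores (3,3)) for one sentence."""
        idx = self._indices(rows)
        node = np.zeros((len(rows), 3))
        for t, ids in enumerate(idx):
            if ids:
                node[t] = self.weights[ids].sum(axis=0)
        return node, self.transitions

    def _indices(self, rows: list[FeatureRow]) -> list[list[int]]:
        out = []
        for t in range(len(rows)):
            out.append([
                self.feature_index[f]
                for f in _token_features(rows, t, self.config)
                if f in self.feature_index
            ])
        return out

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "curatext-crf",
            "version": 1,
            "entity_type": self.entity_type,
            "seed": self.seed,
            "config": asdict(self.config),
            "meta": self.meta,
            "features": sorted(self.feature_index, key=self.feature_index.get),
            "weights": self.weights.tolist(),
            "transitions": self.transitions.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "curatext-crf":
            raise ValueError(f"{path}: not a CRF model file")
        return cls(
            entity_type=payload["entity_type"],
            feature_index={f: i for i, f in enumerate(payload["features"])},
            weights=np.asarray(payload["weights"]),
            transitions=np.asarray(payload["transitions"]),
            config=CRFConfig(**payload["config"]),
            seed=payload["seed"],
            meta=payload.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    labelled_sentences: list[tuple[list[FeatureRow], list[str]]],
    entity_type: str,
    config: CRFConfig | None = None,
    seed: int = 0,
) -> TaggerModel:
    """Fit a CRF by L2-penalized maximum conditional likelihood (L-BFGS).

    ``labelled_sentences`` pairs feature rows with BIO label strings.
    Raises on a degenerate label space (no sentence carries a non-O label).
    """
    config = config or CRFConfig()
    labels = labels_for(entity_type)
    lab_idx = {lab: k for k, lab in enumerate(labels)}

    ys: list[np.ndarray] = []
    for rows, labs in labelled_sentences:
        if len(rows) != len(labs):
            raise ValueError("feature rows and labels differ in length")
        ys.append(np.array([lab_idx[l] for l in labs], dtype=np.intp))
    if not any((y != 2).any() for y in ys):
        raise ValueError(
            f"degenerate training data for {entity_type}: all labels are O"
        )

    feature_index: dict[str, int] = {}
    sent_feats: list[list[list[int]]] = []
    for rows, _ in labelled_sentences:
        per_tok = []
        for t in range(len(rows)):
            ids = []
            for f in _token_features(rows, t, config):
                if f not in feature_index:
                    feature_index[f] = len(feature_index)
                ids.append(feature_index[f])
            per_tok.append(ids)
        sent_feats.append(per_tok)

    n_feat = len(feature_index)
    n_w = n_feat * 3

    def unpack(theta):
        return theta[:n_w].reshape(n_feat, 3), theta[n_w:].reshape(3, 3)

    def objective(theta):
        W, T = unpack(theta)
        gW = np.zeros_like(W)
        gT = np.zeros_like(T)
        nll = 0.0
        for feats, y in zip(sent_feats, ys):
            if len(y) == 0:
                continue
            node = np.array([W[ids].sum(axis=0) for ids in feats])
            nll_s, m_node, m_trans = _fb_marginals(node, T)
            gold = node[np.arange(len(y)), y].sum() + T[y[:-1], y[1:]].sum()
            nll += nll_s - gold
            m_node[np.arange(len(y)), y] -= 1.0
            if len(y) > 1:
                np.add.at(m_trans, (y[:-1], y[1:]), -1.0)
            gT += m_trans
            for t, ids in enumerate(feats):
                gW[ids] += m_node[t]
        nll += config.c2 * (W ** 2).sum() + config.c2 * (T ** 2).sum()
        gW += 2.0 * config.c2 * W
        gT += 2.0 * config.c2 * T
        return nll, np.concatenate([gW.ravel(), gT.ravel()])

    theta0 = np.zeros(n_w + 9)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": config.max_iterations})
    W, T = unpack(res.x)
    return TaggerModel(
        entity_type=entity_type,
        feature_index=feature_index,
        weights=W,
        transitions=T,
        config=config,
        seed=seed,
        meta={"n_sentences": len(ys), "converged": bool(res.success),
              "final_nll": float(res.fun)},
    )


def _fb_marginals(node: np.ndarray, T: np.ndarray):
    """Forward-backward: (logZ, node marginals (n,3), pairwise marginal
    sums (3,3)) in log space."""
    n = node.shape[0]
    alpha = np.zeros((n, 3))
    alpha[0] = node[0]
    for t in range(1, n):
        alpha[t] = node[t] + logsumexp(alpha[t - 1][:, None] + T, axis=0)
    logZ = logsumexp(alpha[-1])
    beta = np.zeros((n, 3))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(T + (node[t + 1] + beta[t + 1])[None, :], axis=1)
    m_node = np.exp(alpha + beta - logZ)
    m_trans = np.zeros((3, 3))
    for t in range(n - 1):
        lp = (alpha[t][:, None] + T + (node[t + 1] + beta[t + 1])[None, :]) - logZ
        m_trans += np.exp(lp)
    return logZ, m_node, m_trans


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def predict(model: TaggerModel, rows: list[FeatureRow]) -> list[str]:
    """Viterbi argmax labels (equals ``nbest(..., 1)``)."""
    if not rows:
        return []
    hyp = nbest(rows, model, 1)[0]
    return list(hyp.labels)


def log_partition(model: TaggerModel, rows: list[FeatureRow]) -> float:
    node, T = model.potentials(rows)
    alpha = node[0]
    for t in range(1, len(rows)):
        alpha = node[t] + logsumexp(alpha[:, None] + T, axis=0)
    return float(logsumexp(alpha))


def nbest(rows: list[FeatureRow], model: TaggerModel, N: int) -> list[LabelHypothesis]:
    """Top-N label sequences with exact conditional probabilities.

    k-best Viterbi over the chain; ties are broken by the lexicographically
    smaller label sequence (B < I < O).  Probabilities are normalized by the
    full partition function, so summing over all 3^len hypotheses gives 1.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not rows:
        return []
    node, T = model.potentials(rows)
    labels = model.labels
    # beam[y] = list of (score, path) sorted best-first
    beam = [[(node[0, y], (y,))] for y in range(3)]
    for t in range(1, len(rows)):
        new_beam = []
        for y in range(3):
            cands = [
                (score + T[prev_y, y] + node[t, y], path + (y,))
                for prev_y in range(3)
                for score, path in beam[prev_y]
            ]
            cands.sort(key=lambda sp: (-sp[0], sp[1]))
            new_beam.append(cands[:N])
        beam = new_beam
    final = [sp for per_state in beam for sp in per_state]
    final.sort(key=lambda sp: (-sp[0], sp[1]))
    logZ = log_partition(model, rows)
    return [
        LabelHypothesis(
            labels=tuple(labels[y] for y in path),
            probability=float(np.exp(score - logZ)),
            score=float(score),
        )
        for score, path in final[:N]
    ]
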
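"""BiLSTM-CRF named entity tagger with character-level word encodings.

Architecture (per sentence):

1. **Embedding layer** — each word maps to a trainable word vector
   (optionally initialized from pretrained word2vec-binary embeddings) and a
   matrix of character vectors.
2. **Character BiLSTM** — a forward and a backward LSTM run over the word's
   characters; their final hidden states are concatenated into a
   character-based word embedding capturing orthography.
3. **Word BiLSTM** — the concatenated word + character representation,
   regularised by dropout, feeds a bidirectional LSTM over the sentence;
   forward and backward outputs are concatenated per token.
4. **CRF layer** — a linear projection gives per-token label scores; a
   linear-chain CRF with learned transitions decodes the globally best BIO
   sequence, and training minimizes the CRF negative log-likelihood.

Everything is NumPy with hand-written backpropagation (verified against
finite differences in the test suite) and Adam updates with weight decay.
Mini-batches are processed by accumulating per-sentence gradients — no
padding is involved, so batch composition never changes a sentence's loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .crf_tagger import _fb_marginals, labels_for


@dataclass
class NetConfig:
    """Training hyperparameters.  Defaults follow the reference recipe:
    20 epochs, batches of 10, 25-dim character embeddings, 200-dim word
    embeddings, a 250-dim character-based word embedding (125 per
    direction), dropout 0.5, Adam at learning rate 0.013 with weight decay
    1e-4.  The word-level BiLSTM hidden size defaults to 100 per direction.
    """
    epochs: int = 20
    batch_size: int = 10
    char_embed_dim: int = 25
    word_embed_dim: int = 200
    char_word_dim: int = 250      # concatenated char representation (2 dirs)
    word_hidden_dim: int = 100    # word BiLSTM hidden units per direction
    dropout: float = 0.5
    learning_rate: float = 0.013
    weight_decay: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.char_word_dim % 2:
            raise ValueError("char_word_dim must be even (two directions)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("epochs", "batch_size", "char_embed_dim",
                     "word_embed_dim", "char_word_dim", "word_hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


UNK = "<unk>"


@dataclass
class Vocab:
    word2id: dict[str, int]
    char2id: dict[str, int]

    @classmethod
    def build(cls, sentences: list[list[str]]) -> "Vocab":
        word2id = {UNK: 0}
        char2id = {UNK: 0}
        for words in sentences:
            for w in words:
                if w not in word2id:
                    word2id[w] = len(word2id)
                for c in w:
                    if c not in char2id:
                        char2id[c] = len(char2id)
        return cls(word2id, char2id)

    def word_id(self, word: str) -> int:
        """Case-sensitive lookup first, lowercased second, else unknown —
        biomedical casing (mV, CaV3.1) is meaningful."""
        if word in self.word2id:
            return self.word2id[word]
        return self.word2id.get(word.lower(), 0)

    def char_ids(self, word: str) -> list[int]:
        return [self.char2id.get(c, 0) for c in word]


# ---------------------------------------------------------------------------
# LSTM building block (manual forward/backward)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _LSTM:
    """A single-direction LSTM over a (T, d_in) sequence.

    Parameters live in the model's parameter dict under ``prefix``:
    ``Wx`` (d_in, 4h), ``Wh`` (h, 4h), ``b`` (4h,) with gate order
    input/forget/output/candidate and forget bias initialized to 1.
    """

    def __init__(self, params: dict, prefix: str):
        self.Wx = params[prefix + "_Wx"]
        self.Wh = params[prefix + "_Wh"]
        self.b = params[prefix + "_b"]
        self.prefix = prefix
        self.h_dim = self.Wh.shape[0]

    def forward(self, X: np.ndarray):
        T = X.shape[0]
        H = np.zeros((T, self.h_dim))
        h = np.zeros(self.h_dim)
        c = np.zeros(self.h_dim)
        caches = []
        d = self.h_dim
        for t in range(T):
            z = X[t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:d])
            f = _sigmoid(z[d:2 * d])
            o = _sigmoid(z[2 * d:3 * d])
            g = np.tanh(z[3 * d:])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            caches.append((X[t], h, c, i, f, o, g, hc))
            h, c = h_new, c_new
            H[t] = h
        return H, caches

    def backward(self, dH: np.ndarray, caches, grads: dict) -> np.ndarray:
        T = dH.shape[0]
        dX = np.zeros((T, self.Wx.shape[0]))
        dWx = grads[self.prefix + "_Wx"]
        dWh = grads[self.prefix + "_Wh"]
        db = grads[self.prefix + "_b"]
        dh_next = np.zeros(self.h_dim)
        dc_next = np.zeros(self.h_dim)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, o, g, hc = caches[t]
            dh = dH[t] + dh_next
            do = dh * hc
            dc = dh * o * (1.0 - hc ** 2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                do * o * (1 - o), dg * (1 - g ** 2),
            ])
            dWx += np.outer(x, dz)
            dWh += np.outer(h_prev, dz)
            db += dz
            dX[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dX


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _glorot(rng, n_in, n_out):
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


def _init_lstm(params, prefix, d_in, h, rng):
    params[prefix + "_Wx"] = _glorot(rng, d_in, 4 * h)
    params[prefix + "_Wh"] = _glorot(rng, h, 4 * h)
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0  # forget-gate bias
    params[prefix + "_b"] = b


@dataclass
class NeuralModel:
    entity_type: str
    config: NetConfig
    vocab: Vocab
    params: dict[str, np.ndarray]
    history: list[float] = field(default_factory=list)

    @property
    def labels(self):
        return labels_for(self.entity_type)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "curatext-bilstm-crf",
            "version": 1,
            "entity_type": self.entity_type,
            "config": asdict(self.config),
            "word2id": self.vocab.word2id,
            "char2id": self.vocab.char2id,
            "history": self.history,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NeuralModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "curatext-bilstm-crf":
            raise ValueError(f"{path}: not a BiLSTM-CRF model file")
        return cls(
            entity_type=payload["entity_type"],
            config=NetConfig(**payload["config"]),
            vocab=Vocab(payload["word2id"], payload["char2id"]),
            params={k: np.asarray(v) for k, v in payload["params"].items()},
            history=payload.get("history", []),
        )


def init_model(
    entity_type: str,
    vocab: Vocab,
    config: NetConfig,
    pretrained: dict[str, np.ndarray] | None = None,
) -> NeuralModel:
    rng = np.random.default_rng(config.seed)
    h_c = config.char_word_dim // 2
    params: dict[str, np.ndarray] = {}
    params["Ec"] = rng.normal(0, 0.1, (len(vocab.char2id), config.char_embed_dim))
    params["Ew"] = rng.normal(0, 0.1, (len(vocab.word2id), config.word_embed_dim))
    if pretrained is not None:
        for w, i in vocab.word2id.items():
            vec = pretrained.get(w)
            if vec is None:
                vec = pretrained.get(w.lower())
            if vec is not None:
                if len(vec) != config.word_embed_dim:
                    raise ValueError(
                        f"pretrained dimension {len(vec)} != "
                        f"word_embed_dim {config.word_embed_dim}"
                    )
                params["Ew"][i] = vec
    _init_lstm(params, "cf", config.char_embed_dim, h_c, rng)
    _init_lstm(params, "cb", config.char_embed_dim, h_c, rng)
    d_word_in = config.word_embed_dim + config.char_word_dim
    _init_lstm(params, "wf", d_word_in, config.word_hidden_dim, rng)
    _init_lstm(params, "wb", d_word_in, config.word_hidden_dim, rng)
    params["Wout"] = _glorot(rng, 2 * config.word_hidden_dim, 3)
    params["bout"] = np.zeros(3)
    params["trans"] = np.zeros((3, 3))
    return NeuralModel(entity_type, config, vocab, params)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------

def encode_word(word: str, model: NeuralModel) -> np.ndarray:
    """Concatenation of the word embedding with the final forward and
    backward character LSTM states; length word_embed_dim + char_word_dim."""
    if not word:
        raise ValueError("cannot encode an empty word")
    vec, _ = _encode_word_cached(word, model)
    return vec


def _encode_word_cached(word: str, model: NeuralModel):
    p = model.params
    cids = model.vocab.char_ids(word)
    X = p["Ec"][cids]
    fwd = _LSTM(p, "cf")
    bwd = _LSTM(p, "cb")
    Hf, cf_cache = fwd.forward(X)
    Hb, cb_cache = bwd.forward(X[::-1])
    wvec = p["Ew"][model.vocab.word_id(word)]
    rep = np.concatenate([wvec, Hf[-1], Hb[-1]])
    return rep, (cids, X, cf_cache, cb_cache, fwd, bwd)


def _sentence_forward(words: list[str], model: NeuralModel,
                      drop_mask: np.ndarray | None = None):
    """Scores (T,3) for a sentence plus the caches needed for backward."""
    p = model.params
    reps, word_caches = [], []
    for w in words:
        rep, cache = _encode_word_cached(w, model)
        reps.append(rep)
        word_caches.append(cache)
    X = np.stack(reps)
    if drop_mask is not None:
        X = X * drop_mask
    wf, wb = _LSTM(p, "wf"), _LSTM(p, "wb")
    Hf, wf_cache = wf.forward(X)
    Hb_rev, wb_cache = wb.forward(X[::-1])
    Hb = Hb_rev[::-1]
    Hcat = np.concatenate([Hf, Hb], axis=1)
    scores = Hcat @ p["Wout"] + p["bout"]
    cache = (words, word_caches, drop_mask, wf, wb, wf_cache, wb_cache, Hcat)
    return scores, cache


def _sentence_backward(dscores: np.ndarray, cache, model: NeuralModel,
                       grads: dict) -> None:
    p = model.params
    words, word_caches, drop_mask, wf, wb, wf_cache, wb_cache, Hcat = cache
    grads["Wout"] += Hcat.T @ dscores
    grads["bout"] += dscores.sum(axis=0)
    dHcat = dscores @ p["Wout"].T
    h_w = model.config.word_hidden_dim
    dX = wf.backward(dHcat[:, :h_w], wf_cache, grads)
    dX += wb.backward(dHcat[::-1, h_w:], wb_cache, grads)[::-1]
    if drop_mask is not None:
        dX = dX * drop_mask
    d_w = model.config.word_embed_dim
    h_c = model.config.char_word_dim // 2
    for t, w in enumerate(words):
        cids, Xc, cf_cache, cb_cache, cf, cb = word_caches[t]
        grads["Ew"][model.vocab.word_id(w)] += dX[t, :d_w]
        n = len(cids)
        dHf = np.zeros((n, h_c))
        dHf[-1] = dX[t, d_w:d_w + h_c]
        dHb = np.zeros((n, h_c))
        dHb[-1] = dX[t, d_w + h_c:]
        dXc = cf.backward(dHf, cf_cache, grads)
        dXc += cb.backward(dHb, cb_cache, grads)[::-1]
        np.add.at(grads["Ec"], cids, dXc)


def sentence_potentials(words: list[str], model: NeuralModel):
    """(node scores (T,3), transitions (3,3)) with dropout disabled —
    the quantities the CRF layer decodes."""
    scores, _ = _sentence_forward(words, model)
    return scores, model.params["trans"]


def tag_sentence(words: list[str], model: NeuralModel) -> list[str]:
    """Viterbi-decode the globally best BIO sequence (dropout disabled).
    An empty sentence yields an empty sequence."""
    if not words:
        return []
    node, T = sentence_potentials(words, model)
    n = len(words)
    back = np.zeros((n, 3), dtype=np.intp)
    alpha = node[0].copy()
    for t in range(1, n):
        cand = alpha[:, None] + T
        back[t] = cand.argmax(axis=0)
        alpha = node[t] + cand.max(axis=0)
    path = [int(alpha.argmax())]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    labels = model.labels
    return [labels[k] for k in path]


def sentence_loss(words: list[str], labels: list[str], model: NeuralModel,
                  drop_mask: np.ndarray | None = None,
                  grads: dict | None = None) -> float:
    """CRF negative log-likelihood of the gold labels; accumulates gradients
    into ``grads`` when given."""
    lab_idx = {lab: k for k, lab in enumerate(model.labels)}
    y = np.array([lab_idx[l] for l in labels], dtype=np.intp)
    scores, cache = _sentence_forward(words, model, drop_mask)
    T = model.params["trans"]
    logZ, m_node, m_trans = _fb_marginals(scores, T)
    gold = scores[np.arange(len(y)), y].sum() + T[y[:-1], y[1:]].sum()
    loss = float(logZ - gold)
    if grads is not None:
        dscores = m_node
        dscores[np.arange(len(y)), y] -= 1.0
        dT = m_trans
        if len(y) > 1:
            np.add.at(dT, (y[:-1], y[1:]), -1.0)
        grads["trans"] += dT
        _sentence_backward(dscores, cache, model, grads)
    return loss


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def read_word2vec_binary(path) -> dict[str, np.ndarray]:
    """Minimal reader for the word2vec C binary format: an ASCII header
    "vocab_size dim\\n" followed by ``word<space><dim float32s>`` records,
    optionally newline-separated."""
    table: dict[str, np.ndarray] = {}
    with open(path, "rb") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec binary header")
        vocab_size, dim = int(header[0]), int(header[1])
        for _ in range(vocab_size):
            chars = []
            while True:
                c = fh.read(1)
                if c in (b" ", b""):
                    break
                if c != b"\n":
                    chars.append(c)
            word = b"".join(chars).decode("utf-8", errors="replace")
            vec = np.frombuffer(fh.read(4 * dim), dtype=np.float32).astype(float)
            if vec.size != dim:
                raise ValueError(f"{path}: truncated vector for {word!r}")
            table[word] = vec
    return table


def train(
    labelled_sentences: list[tuple[list[str], list[str]]],
    entity_type: str,
    config: NetConfig | None = None,
    pretrained_embeddings=None,
) -> NeuralModel:
    """Train a BiLSTM-CRF on (words, BIO labels) pairs.

    ``pretrained_embeddings`` may be a path to a word2vec binary file or a
    word->vector mapping; a named file that does not exist raises
    immediately (never a silent random fallback).  Seeding (from
    ``config.seed``) covers parameter initialization, dropout masks and
    per-epoch shuffling.  ``model.history`` records the mean per-sentence
    loss of each epoch.
    """
    config = config or NetConfig()
    if isinstance(pretrained_embeddings, (str, bytes)) or hasattr(
            pretrained_embeddings, "__fspath__"):
        pretrained_embeddings = read_word2vec_binary(pretrained_embeddings)
    sentences = [(w, l) for w, l in labelled_sentences if w]
    vocab = Vocab.build([w for w, _ in sentences])
    model = init_model(entity_type, vocab, config, pretrained_embeddings)
    rng = np.random.default_rng(config.seed + 1)

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    d_in = config.word_embed_dim + config.char_word_dim

    for _ in range(config.epochs):
        order = rng.permutation(len(sentences))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            for si in batch:
                words, labels = sentences[si]
                if config.dropout > 0.0:
                    keep = 1.0 - config.dropout
                    mask = (rng.random((len(words), d_in)) < keep) / keep
                else:
                    mask = None
                epoch_loss += sentence_loss(words, labels, model, mask, grads)
            step += 1
            scale = 1.0 / len(batch)
            for k, p in model.params.items():
                g = grads[k] * scale + config.weight_decay * p
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                mhat = adam_m[k] / (1 - beta1 ** step)
                vhat = adam_v[k] / (1 - beta2 ** step)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.history.append(epoch_loss / max(len(sentences), 1))
    return model
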
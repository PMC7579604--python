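"""Narrative vectorization: word2vec embeddings weighted by TF-IDF.

A word2vec model (CBOW by default, skip-gram available) is trained on the
normalized narrative corpus with negative sampling; every retained token
gets a dense vector (300 components by default). A narrative's vector is
the TF-IDF-weighted average of its word vectors:

    v = ( sum_t tfidf(t, doc) * vec(t) ) / #{tokens of doc with a vector}

with TF = term count / narrative length and IDF = ln(n_docs / doc_freq).
No IDF smoothing is applied, so a term present in every narrative carries
weight zero. Tokens without a vector are skipped and excluded from the
divisor.

The trainer is a compact numpy implementation (single-threaded, seeded,
mini-batched), so identical parameters and seed reproduce identical
vectors exactly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class EmbeddingParams:
    """word2vec training configuration."""

    architecture: str = "cbow"  # or "skipgram"
    dimension: int = 300
    window: int = 5
    epochs: int = 20
    min_count: int = 1
    negative: int = 5
    learning_rate: float = 0.025
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("cbow", "skipgram"):
            raise ValueError("architecture must be 'cbow' or 'skipgram'")
        if self.dimension < 1 or self.window < 1 or self.epochs < 1 or self.min_count < 1:
            raise ValueError("dimension, window, epochs and min_count must be >= 1")


@dataclass
class EmbeddingModel:
    """Token -> dense vector map plus the parameters that produced it."""

    dimension: int
    tokens: list[str]
    matrix: np.ndarray  # (n_tokens, dimension), float32
    params: EmbeddingParams

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.index[token]]

    @property
    def vectors(self) -> dict[str, np.ndarray]:
        return {t: self.matrix[i] for t, i in self.index.items()}

    def save_word2vec_text(self, path) -> None:
        """Standard word2vec text format: header 'n d', then token + floats."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.tokens)} {self.dimension}\n")
            for t, row in zip(self.tokens, self.matrix):
                fh.write(t + " " + " ".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def load_word2vec_text(cls, path, params: EmbeddingParams | None = None) -> "EmbeddingModel":
        with open(path) as fh:
            n, d = (int(x) for x in fh.readline().split())
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append(np.array(parts[1:], dtype=np.float32))
        mat = np.vstack(rows) if rows else np.zeros((0, d), np.float32)
        return cls(d, tokens, mat, params or EmbeddingParams(dimension=d))


def _build_vocab(corpus: Sequence[Sequence[str]], min_count: int) -> list[str]:
    freq = Counter(t for doc in corpus for t in doc)
    kept = [(t, c) for t, c in freq.items() if c >= min_count]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))  # frequency order, ties lexicographic
    return [t for t, _ in kept]


def train_embedding(
    corpus: Sequence[Sequence[str]], params: EmbeddingParams = EmbeddingParams()
) -> EmbeddingModel:
    """Train word vectors with negative sampling on a tokenized corpus."""
    corpus = [list(doc) for doc in corpus if len(doc) > 0]
    if not corpus:
        raise ValueError("cannot train an embedding on an empty corpus")
    tokens = _build_vocab(corpus, params.min_count)
    if not tokens:
        raise ValueError("no token reaches min_count; nothing to train")
    index = {t: i for i, t in enumerate(tokens)}
    v = len(tokens)
    d = params.dimension
    rng = np.random.default_rng(params.seed)

    docs = [[index[t] for t in doc if t in index] for doc in corpus]
    docs = [doc for doc in docs if doc]

    w = params.window
    if params.architecture == "cbow":
        centers, ctx_rows, masks = [], [], []
        for doc in docs:
            n = len(doc)
            if n < 2:
                continue
            arr = np.asarray(doc, dtype=np.int64)
            for i in range(n):
                lo, hi = max(0, i - w), min(n, i + w + 1)
                ctx = np.concatenate([arr[lo:i], arr[i + 1 : hi]])
                row = np.zeros(2 * w, np.int64)
                msk = np.zeros(2 * w, np.float32)
                row[: len(ctx)] = ctx
                msk[: len(ctx)] = 1.0
                centers.append(doc[i])
                ctx_rows.append(row)
                masks.append(msk)
        centers = np.asarray(centers, np.int64)
        ctx = np.vstack(ctx_rows) if ctx_rows else np.zeros((0, 2 * w), np.int64)
        mask = np.vstack(masks) if masks else np.zeros((0, 2 * w), np.float32)
    else:  # skipgram: one (input=center, output=context) pair per context slot
        ins, outs = [], []
        for doc in docs:
            n = len(doc)
            for i in range(n):
                for jj in range(max(0, i - w), min(n, i + w + 1)):
                    if jj != i:
                        ins.append(doc[i])
                        outs.append(doc[jj])
        centers = np.asarray(outs, np.int64)  # predicted word
        ctx = np.asarray(ins, np.int64)[:, None]  # input word
        mask = np.ones_like(ctx, np.float32)

    n_examples = len(centers)
    if n_examples == 0:
        # degenerate corpus of one-token docs: return random unit-scale vectors
        mat = ((rng.random((v, d)).astype(np.float32) - 0.5) / d)
        return EmbeddingModel(d, tokens, mat, params)

    # unigram^0.75 negative-sampling distribution
    freq = np.zeros(v)
    for doc in docs:
        np.add.at(freq, doc, 1.0)
    neg_p = freq**0.75
    neg_p /= neg_p.sum()

    w_in = ((rng.random((v, d)).astype(np.float32) - 0.5) / d)
    w_out = np.zeros((v, d), np.float32)
    k = params.negative
    lr = np.float32(params.learning_rate)
    bs = params.batch_size

    for _epoch in range(params.epochs):
        order = rng.permutation(n_examples)
        negs = rng.choice(v, size=(n_examples, k), p=neg_p)
        for start in range(0, n_examples, bs):
            sel = order[start : start + bs]
            cb, mb = ctx[sel], mask[sel]
            counts = mb.sum(axis=1, keepdims=True)
            h = (w_in[cb] * mb[:, :, None]).sum(axis=1) / counts
            targets = np.concatenate([centers[sel, None], negs[sel]], axis=1)  # (B, 1+k)
            wo = w_out[targets]  # (B, 1+k, d)
            scores = np.clip(np.einsum("bd,bkd->bk", h, wo), -30.0, 30.0)
            p = 1.0 / (1.0 + np.exp(-scores))
            g = -p
            g[:, 0] += 1.0
            g = (g * lr).astype(np.float32)
            grad_h = np.einsum("bk,bkd->bd", g, wo)
            np.add.at(w_out, targets, g[:, :, None] * h[:, None, :])
            gh = (grad_h / counts).astype(np.float32)
            np.add.at(w_in, cb, gh[:, None, :] * mb[:, :, None])

    return EmbeddingModel(d, tokens, w_in, params)


def nearest_neighbors(model: EmbeddingModel, token: str, k: int) -> list[str]:
    """Top-k cosine neighbours of ``token``, excluding the token itself.

    Ties are broken by lexicographic token order so results are stable.
    """
    if token not in model:
        raise KeyError(f"token {token!r} not in embedding vocabulary")
    q = model.vector(token).astype(np.float64)
    mat = model.matrix.astype(np.float64)
    norms = np.linalg.norm(mat, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = mat @ q / np.where(norms * qn > 0, norms * qn, np.inf)
    sims = np.nan_to_num(sims, nan=-np.inf)
    order = sorted(
        (i for i in range(len(model.tokens)) if i != model.index[token]),
        key=lambda i: (-sims[i], model.tokens[i]),
    )
    return [model.tokens[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------


@dataclass
class TfidfStats:
    """Document frequencies of a narrative corpus."""

    n_docs: int
    doc_freq: dict[str, int]

    def idf(self, token: str) -> float:
        df = self.doc_freq.get(token, self.n_docs)  # unseen -> idf 0
        return math.log(self.n_docs / df)


def compute_tfidf(corpus: Iterable[Sequence[str]]) -> TfidfStats:
    """Count, for every token, the number of narratives containing it."""
    df: Counter[str] = Counter()
    n = 0
    for doc in corpus:
        n += 1
        df.update(set(doc))
    return TfidfStats(n_docs=n, doc_freq=dict(df))


def score(stats: TfidfStats, token: str, narrative: Sequence[str]) -> float:
    """TF-IDF of ``token`` within one narrative (token sequence)."""
    if len(narrative) == 0:
        raise ValueError("narrative must be non-empty to score a token")
    tf = sum(1 for t in narrative if t == token) / len(narrative)
    return tf * stats.idf(token)


# ---------------------------------------------------------------------------
# narrative vectors
# ---------------------------------------------------------------------------


def vectorize_narrative(
    tokens: Sequence[str], embedding: EmbeddingModel, stats: TfidfStats
) -> np.ndarray:
    """TF-IDF-weighted average of the word vectors of one narrative.

    Returns the zero vector when no token has a vector (including the
    empty narrative); use :func:`vectorize_corpus` to obtain the
    out-of-vocabulary flags alongside the matrix.
    """
    out = np.zeros(embedding.dimension, dtype=np.float64)
    n_used = 0
    counts = Counter(tokens)
    length = len(tokens)
    for tok, cnt in counts.items():
        if tok not in embedding:
            continue
        n_used += cnt
        weight = (cnt / length) * stats.idf(tok)
        out += weight * embedding.vector(tok).astype(np.float64)
    if n_used == 0:
        return np.zeros(embedding.dimension, dtype=np.float64)
    return out / n_used


def vectorize_corpus(
    corpus: Sequence[Sequence[str]], embedding: EmbeddingModel, stats: TfidfStats
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize every narrative; also flag those with no in-vocabulary token."""
    mat = np.zeros((len(corpus), embedding.dimension), dtype=np.float64)
    empty = np.zeros(len(corpus), dtype=bool)
    for i, doc in enumerate(corpus):
        mat[i] = vectorize_narrative(doc, embedding, stats)
        empty[i] = not any(t in embedding for t in doc)
    return mat, empty
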
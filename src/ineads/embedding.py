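"""Corpus language model and embedding-driven synonym expansion.

A skip-gram word-embedding model with negative sampling is trained on the
preprocessed note corpus (after collocation detection merges frequent
adjacent token pairs into underscore-joined phrase items, so that multiword
expressions such as ``palliative_care`` get their own vector). Synonym
candidates for a subcategory are the vocabulary items closest — by cosine
similarity — to any of the subcategory's current terms; a reviewer accepts
or rejects each candidate, accepted candidates enter the lexicon with
``accepted_synonym`` provenance, and the suggest/review loop repeats until
an iteration accepts nothing new.

The trainer is implemented directly in numpy: mini-batch stochastic gradient
descent on the negative-sampling objective, one worker, all randomness from
one seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import csv
import datetime
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .lexicon import Lexicon, LexiconEntry, SUBCATEGORIES

__all__ = [
    "EmbeddingModel",
    "SynonymSuggestion",
    "TrainingParams",
    "detect_phrases",
    "train_embedding",
    "suggest_synonyms",
    "review_suggestions",
    "ExpansionSession",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingParams:
    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 10
    negative: int = 5
    alpha: float = 0.05
    subsample: float = 1e-3
    batch_size: int = 256
    seed: int = 0


#: Number of leading principal components removed from the similarity space.
COMMON_COMPONENTS_REMOVED = 2


@dataclass
class EmbeddingModel:
    """Vocabulary plus one fixed-length vector per item.

    Similarities are computed in a common-component-corrected space: the
    vocabulary mean and the top principal components are removed before
    unit-normalisation. Skip-gram spaces trained on small corpora are
    strongly anisotropic — every vector shares a large common direction, so
    raw cosines saturate near 1 and carry no ranking signal; removing the
    common components restores contrast. Raw trained vectors stay available
    in ``vectors``.
    """

    vocabulary: list[str]
    vectors: np.ndarray  # (V, dim)
    params: TrainingParams
    counts: np.ndarray | None = None  # training-corpus frequency per item
    _index: dict[str, int] = field(init=False, repr=False)
    _unit: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(set(self.vocabulary)):
            raise ValueError("vocabulary items must be unique")
        if self.vectors.shape != (len(self.vocabulary), self.params.dim):
            raise ValueError("vectors must be (len(vocabulary), dim)")
        if self.counts is None:
            self.counts = np.ones(len(self.vocabulary))
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        corrected = self.vectors - self.vectors.mean(axis=0)
        n_remove = min(COMMON_COMPONENTS_REMOVED, max(0, len(self.vocabulary) - 2))
        if n_remove:
            _, _, vt = np.linalg.svd(corrected, full_matrices=False)
            top = vt[:n_remove]
            corrected = corrected - (corrected @ top.T) @ top
        norms = np.linalg.norm(corrected, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = corrected / norms

    @property
    def dim(self) -> int:
        return self.params.dim

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def vector(self, item: str) -> np.ndarray:
        return self.vectors[self._index[item]]

    def similarity(self, a: str, b: str) -> float:
        """Cosine similarity between two vocabulary items."""
        return float(self._unit[self._index[a]] @ self._unit[self._index[b]])

    def term_vector(self, term: str) -> np.ndarray | None:
        """Unit vector for a (possibly multiword) term.

        Uses the merged phrase item when present, otherwise an
        inverse-frequency-weighted mean of the in-vocabulary component
        tokens (the rare components of a phrase carry its meaning; frequent
        function-like tokens would drown them in a plain mean). None if
        nothing is in vocabulary.
        """
        key = term.replace(" ", "_")
        if key in self._index:
            return self._unit[self._index[key]]
        idx = [self._index[t] for t in term.split() if t in self._index]
        if not idx:
            return None
        weights = 1.0 / np.asarray(self.counts)[idx]
        mean = (weights[:, None] * self._unit[idx]).sum(axis=0) / weights.sum()
        norm = np.linalg.norm(mean)
        return mean / norm if norm else None


def detect_phrases(
    sentences: Sequence[Sequence[str]],
    max_n: int = 3,
    min_count: int = 5,
    threshold: float = 0.2,
) -> list[list[str]]:
    """Merge exclusive collocations into underscore-joined items.

    An adjacent pair (a, b) is scored by its exclusivity bond
    ``count(ab)^2 / (count(a) * count(b))`` — the product of the two
    conditional probabilities P(b follows a) and P(a precedes b), in
    [0, 1] — and merged when the bond reaches ``threshold`` and the pair
    occurs at least ``min_count`` times. This favours pairs whose components
    rarely occur apart ("palliative care") over merely frequent neighbours
    ("pt reports"). Passes repeat so that up to ``max_n``-gram items can
    form.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    current = [list(s) for s in sentences]
    for _ in range(max_n - 1):
        unigrams: Counter[str] = Counter()
        bigrams: Counter[tuple[str, str]] = Counter()
        for sent in current:
            unigrams.update(sent)
            bigrams.update(zip(sent, sent[1:]))
        if not unigrams:
            break

        def score(pair: tuple[str, str]) -> float:
            ab = bigrams[pair]
            if ab < min_count:
                return float("-inf")
            return ab * ab / (unigrams[pair[0]] * unigrams[pair[1]])

        merged_any = False
        merged_sentences: list[list[str]] = []
        for sent in current:
            out: list[str] = []
            i = 0
            while i < len(sent):
                if i + 1 < len(sent) and score((sent[i], sent[i + 1])) >= threshold:
                    out.append(sent[i] + "_" + sent[i + 1])
                    merged_any = True
                    i += 2
                else:
                    out.append(sent[i])
                    i += 1
            merged_sentences.append(out)
        current = merged_sentences
        if not merged_any:
            break
    return current


def train_embedding(
    sentences: Sequence[Sequence[str]],
    params: TrainingParams | None = None,
    **overrides,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling vectors on tokenized sentences.

    Deterministic for a fixed seed (single worker, seeded numpy generator).
    Items occurring fewer than ``min_count`` times are dropped; an empty
    effective vocabulary raises ``ValueError``.
    """
    params = replace(params or TrainingParams(), **overrides)
    counts: Counter[str] = Counter()
    for sent in sentences:
        counts.update(sent)
    vocab = sorted(
        (w for w, c in counts.items() if c >= params.min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab:
        raise ValueError(
            "no vocabulary item reaches min_count="
            f"{params.min_count}; lower min_count or supply more text"
        )
    index = {w: i for i, w in enumerate(vocab)}
    vocab_size = len(vocab)
    rng = np.random.default_rng(params.seed)

    freq = np.array([counts[w] for w in vocab], dtype=np.float64)
    total_tokens = freq.sum()
    # frequent-word subsampling: keep probability (sqrt(f/t)+1) * t/f
    if params.subsample > 0:
        rel = freq / total_tokens
        keep_p = np.minimum(1.0, (np.sqrt(rel / params.subsample) + 1) * params.subsample / rel)
    else:
        keep_p = np.ones(vocab_size)

    centers_list: list[np.ndarray] = []
    contexts_list: list[np.ndarray] = []
    for sent in sentences:
        ids = np.array([index[w] for w in sent if w in index], dtype=np.int64)
        if len(ids):
            ids = ids[rng.random(len(ids)) < keep_p[ids]]
        n = len(ids)
        if n < 2:
            continue
        for offset in range(1, params.window + 1):
            if offset >= n:
                break
            centers_list.append(ids[:-offset])
            contexts_list.append(ids[offset:])
            centers_list.append(ids[offset:])
            contexts_list.append(ids[:-offset])
    if not centers_list:
        raise ValueError("corpus has no co-occurrence pairs after min_count filtering")
    centers = np.concatenate(centers_list)
    contexts = np.concatenate(contexts_list)
    n_pairs = len(centers)

    noise = freq**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    w_in = (rng.random((vocab_size, params.dim)) - 0.5) / params.dim
    w_out = np.zeros((vocab_size, params.dim))

    batch_size = params.batch_size
    total_updates = params.epochs * n_pairs
    done = 0
    min_alpha = params.alpha * 1e-4
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            batch = order[lo : lo + batch_size]
            c_idx = centers[batch]
            o_idx = contexts[batch]
            neg = np.searchsorted(
                noise_cdf, rng.random((len(batch), params.negative))
            ).astype(np.int64)

            lr = params.alpha + (min_alpha - params.alpha) * (done / total_updates)
            v = w_in[c_idx]  # (B, d)
            u_pos = w_out[o_idx]  # (B, d)
            u_neg = w_out[neg]  # (B, k, d)

            g_pos = 1.0 - _sigmoid(np.einsum("bd,bd->b", v, u_pos))  # (B,)
            g_neg = -_sigmoid(np.einsum("bd,bkd->bk", v, u_neg))  # (B, k)

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            _averaged_update(w_in, c_idx, grad_v, lr)
            out_idx = np.concatenate([o_idx, neg.ravel()])
            out_grad = np.concatenate(
                [g_pos[:, None] * v, (g_neg[..., None] * v[:, None, :]).reshape(-1, params.dim)]
            )
            _averaged_update(w_out, out_idx, out_grad, lr)
            done += len(batch)

    return EmbeddingModel(vocabulary=vocab, vectors=w_in, params=params, counts=freq)


def _averaged_update(
    weights: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float
) -> None:
    """Apply ``lr`` times the per-row *mean* gradient.

    Rows shared by many examples in a batch receive one averaged step
    instead of the sum of all their steps, which keeps mini-batching stable
    for high-frequency vocabulary items.
    """
    uniq, inverse, cnt = np.unique(idx, return_inverse=True, return_counts=True)
    acc = np.zeros((len(uniq), weights.shape[1]))
    np.add.at(acc, inverse, grads)
    weights[uniq] += lr * acc / cnt[:, None]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Persist as ``.npz``: float64 ``vectors``, newline-joined ``vocabulary``
    and a JSON ``params`` string."""
    np.savez(
        path,
        vectors=model.vectors,
        counts=np.asarray(model.counts),
        vocabulary=np.array("\n".join(model.vocabulary)),
        params=np.array(json.dumps(vars(model.params))),
    )


def load_model(path: str | Path) -> EmbeddingModel:
    data = np.load(path, allow_pickle=False)
    params = TrainingParams(**json.loads(str(data["params"])))
    vocab = str(data["vocabulary"]).split("\n")
    counts = data["counts"] if "counts" in data.files else None
    return EmbeddingModel(
        vocabulary=vocab, vectors=data["vectors"], params=params, counts=counts
    )


@dataclass(frozen=True)
class SynonymSuggestion:
    query_term: str
    candidate_term: str
    similarity: float
    decision: str = "pending"  # pending | accepted | rejected


def suggest_synonyms(
    model: EmbeddingModel,
    lexicon: Lexicon,
    subcategory: str,
    k: int = 10,
    rejected: frozenset[str] = frozenset(),
) -> list[SynonymSuggestion]:
    """Top-k nearest vocabulary items to a subcategory's current terms.

    Each candidate is scored by its maximum cosine similarity to any seed
    term (per-term pooling rather than a centroid, because a subcategory's
    terms can be semantically heterogeneous). Terms already in the
    subcategory, previously rejected candidates, and the seed terms
    themselves are excluded. Ties break lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if subcategory not in SUBCATEGORIES:
        raise KeyError(f"unknown subcategory {subcategory!r}")
    terms = lexicon.terms_for(subcategory)
    seed_vecs = []
    seed_terms = []
    for term in terms:
        vec = model.term_vector(term)
        if vec is not None:
            seed_vecs.append(vec)
            seed_terms.append(term)
    if not seed_vecs:
        import warnings

        warnings.warn(
            f"no term of subcategory {subcategory!r} is in the model vocabulary"
        )
        return []

    seed_matrix = np.stack(seed_vecs)  # (S, d)
    sims = model._unit @ seed_matrix.T  # (V, S)
    best = sims.max(axis=1)
    best_seed = sims.argmax(axis=1)

    existing = set(terms)
    term_token_seqs = [tuple(t.split()) for t in terms]

    def _subphrase_of_existing(candidate_tokens: tuple[str, ...]) -> bool:
        n = len(candidate_tokens)
        for seq in term_token_seqs:
            if any(seq[i : i + n] == candidate_tokens for i in range(len(seq) - n + 1)):
                return True
        return False

    suggestions: list[SynonymSuggestion] = []
    for idx in np.argsort(-best, kind="stable"):
        candidate = model.vocabulary[idx].replace("_", " ")
        if candidate in existing or candidate in rejected:
            continue
        # fragments of current terms carry no new vocabulary
        if _subphrase_of_existing(tuple(candidate.split())):
            continue
        suggestions.append(
            SynonymSuggestion(
                query_term=seed_terms[best_seed[idx]],
                candidate_term=candidate,
                similarity=float(best[idx]),
            )
        )
    suggestions.sort(key=lambda s: (-s.similarity, s.candidate_term))
    return suggestions[:k]


def review_suggestions(
    lexicon: Lexicon,
    suggestions: Sequence[SynonymSuggestion],
    decisions: Mapping[str, str],
    subcategory: str,
    log_path: str | Path | None = None,
) -> list[SynonymSuggestion]:
    """Apply accept/reject decisions to pending suggestions.

    Accepted candidates are appended to ``lexicon`` (in place) with
    ``accepted_synonym`` provenance. Every decision must reference a pending
    suggested candidate. Returns the resolved suggestions; optionally appends
    them to a TSV decision log.
    """
    pending = {s.candidate_term: s for s in suggestions if s.decision == "pending"}
    unknown = set(decisions) - set(pending)
    if unknown:
        raise KeyError(f"decisions reference unknown candidates: {sorted(unknown)}")
    resolved: list[SynonymSuggestion] = []
    for candidate, decision in decisions.items():
        if decision not in ("accept", "reject"):
            raise ValueError(f"decision for {candidate!r} must be accept/reject")
        suggestion = replace(
            pending[candidate],
            decision="accepted" if decision == "accept" else "rejected",
        )
        if decision == "accept":
            lexicon.add(LexiconEntry(candidate, subcategory, "accepted_synonym"))
        resolved.append(suggestion)
    if log_path is not None:
        _append_log(log_path, subcategory, resolved)
    return resolved


def _append_log(
    path: str | Path, subcategory: str, resolved: Sequence[SynonymSuggestion]
) -> None:
    path = Path(path)
    new = not path.exists()
    with open(path, "a", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        if new:
            writer.writerow(
                ["subcategory", "query", "candidate", "similarity", "decision",
                 "timestamp"]
            )
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        for s in resolved:
            writer.writerow(
                [subcategory, s.query_term, s.candidate_term,
                 f"{s.similarity:.4f}", s.decision, stamp]
            )


class ExpansionSession:
    """Iterative suggest-review loop over one or more subcategories.

    Rejected candidates are remembered and never re-suggested, so with a
    finite vocabulary the loop always terminates: each round either accepts
    a new term (the lexicon grows monotonically) or ends the loop.
    """

    def __init__(
        self,
        model: EmbeddingModel,
        lexicon: Lexicon,
        log_path: str | Path | None = None,
    ) -> None:
        self.model = model
        self.lexicon = lexicon
        self.log_path = log_path
        self.rejected: dict[str, set[str]] = {}

    def suggest(self, subcategory: str, k: int = 10) -> list[SynonymSuggestion]:
        return suggest_synonyms(
            self.model,
            self.lexicon,
            subcategory,
            k=k,
            rejected=frozenset(self.rejected.get(subcategory, ())),
        )

    def review(
        self, subcategory: str, suggestions: Sequence[SynonymSuggestion],
        decisions: Mapping[str, str],
    ) -> list[SynonymSuggestion]:
        resolved = review_suggestions(
            self.lexicon, suggestions, decisions, subcategory, self.log_path
        )
        rejected = self.rejected.setdefault(subcategory, set())
        rejected.update(
            s.candidate_term for s in resolved if s.decision == "rejected"
        )
        return resolved

    def expand(
        self,
        subcategory: str,
        decide: Callable[[SynonymSuggestion], bool],
        k: int = 10,
        max_rounds: int = 20,
    ) -> int:
        """Run suggest→decide→review until a round accepts nothing.

        ``decide`` returns True to accept a candidate. Returns the number of
        accepted terms.
        """
        total_accepted = 0
        for _ in range(max_rounds):
            suggestions = self.suggest(subcategory, k=k)
            if not suggestions:
                break
            decisions = {
                s.candidate_term: ("accept" if decide(s) else "reject")
                for s in suggestions
            }
            resolved = self.review(subcategory, suggestions, decisions)
            accepted = sum(1 for s in resolved if s.decision == "accepted")
            total_accepted += accepted
            if accepted == 0:
                break
        return total_accepted

    def expand_all(
        self,
        decide: Callable[[SynonymSuggestion], bool],
        k: int = 10,
        subcategories: Iterable[str] | None = None,
    ) -> dict[str, int]:
        return {
            subcat: self.expand(subcat, decide, k=k)
            for subcat in (subcategories or sorted(SUBCATEGORIES))
        }
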
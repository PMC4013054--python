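"""Naive Bayes k-mer taxonomic classifier (word-presence model).

The model follows the RDP-classifier scheme: a query sequence S containing
words (k-mers) v_i is assigned to the taxon D maximising
P(D|S) = P(S|D) P(D) / P(S) with P(S|D) = prod_i P(v_i|D), treating the
priors P(D) and P(S) as constant so the argmax is over the word-conditional
product alone.  Word counting is presence/absence per training sequence, and
conditionals are smoothed with the word prior:

    P_v     = (n(v) + 0.5) / (N + 1)
    P(v|D)  = (m(v, D) + P_v) / (M_D + 1)

where n(v) counts training sequences containing v, N the total training
sequences, m(v, D) the taxon-D training sequences containing v, and M_D the
taxon-D training count.  Smoothing keeps every score finite.  Queries are
scored in both orientations and the better one retained, so classification
is invariant to reverse complementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seq_io import SequenceRecord, revcomp

__all__ = ["WordModel", "extract_words", "train", "classify", "Classification"]

_CONCRETE = frozenset("ACGT")


def extract_words(residues: str, k: int = 8) -> frozenset[str]:
    """The set (presence, not multiplicity) of concrete-base k-mers.

    Gaps are removed first; windows containing a degenerate code are skipped.
    Sequences shorter than k yield an empty set.
    """
    s = residues.upper().replace("U", "T").replace("-", "")
    words = set()
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if set(w) <= _CONCRETE:
            words.add(w)
    return frozenset(words)


@dataclass(frozen=True)
class WordModel:
    """Trained word-containment counts for one taxonomic rank."""

    k: int
    taxa: tuple[str, ...]
    #: training-sequence count per taxon
    m_d: dict[str, int]
    #: per word: taxon -> number of that taxon's training sequences containing it
    counts: dict[str, dict[str, int]]

    @property
    def n_total(self) -> int:
        return sum(self.m_d.values())

    def word_prior(self, word: str) -> float:
        n_v = sum(self.counts.get(word, {}).values())
        return (n_v + 0.5) / (self.n_total + 1)

    def conditional(self, word: str, taxon: str) -> float:
        p_v = self.word_prior(word)
        m = self.counts.get(word, {}).get(taxon, 0)
        return (m + p_v) / (self.m_d[taxon] + 1)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "taxa": list(self.taxa), "m_d": self.m_d, "counts": self.counts}
        )

    @classmethod
    def from_json(cls, text: str) -> "WordModel":
        obj = json.loads(text)
        return cls(
            k=obj["k"], taxa=tuple(obj["taxa"]), m_d=obj["m_d"], counts=obj["counts"]
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "WordModel":
        return cls.from_json(Path(path).read_text())


def _label_at_rank(record: SequenceRecord, rank: str) -> str | None:
    if rank == "phylum":
        return record.phylum
    if rank == "subgroup":
        return record.taxon_label if record.subgroup else None
    raise ValueError(f"unknown rank {rank!r}")


def train(
    corpus: Iterable[SequenceRecord], k: int = 8, rank: str = "phylum"
) -> WordModel:
    """Train a word model at one rank; hierarchical labels are trained flat
    at each rank independently (unlabelled-at-rank records are skipped)."""
    m_d: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    for rec in corpus:
        taxon = _label_at_rank(rec, rank)
        if taxon is None:
            continue
        m_d[taxon] = m_d.get(taxon, 0) + 1
        for w in extract_words(rec.residues, k):
            d = counts.setdefault(w, {})
            d[taxon] = d.get(taxon, 0) + 1
    if len(m_d) < 2:
        raise ValueError(f"training corpus must contain >= 2 taxa at rank {rank!r}")
    return WordModel(k=k, taxa=tuple(sorted(m_d)), m_d=m_d, counts=counts)


@dataclass(frozen=True)
class Classification:
    label: str | None
    scores: dict[str, float]
    orientation: str  # '+' or '-'

    @property
    def classified(self) -> bool:
        return self.label is not None


def _score(model: WordModel, words: frozenset[str]) -> dict[str, float]:
    import math

    return {
        t: sum(math.log(model.conditional(w, t)) for w in sorted(words))
        for t in model.taxa
    }


def classify(model: WordModel, query: str) -> Classification:
    """Best taxon for a query sequence (log-score argmax; ties resolved to the
    lexicographically smallest label).  Returns an unclassifiable result when
    the query yields no words."""
    fwd = extract_words(query, model.k)
    rev = extract_words(revcomp(query.replace("-", "")), model.k)
    if not fwd and not rev:
        return Classification(label=None, scores={}, orientation="+")
    best: tuple[float, str, dict[str, float]] | None = None
    for orient, words in (("+", fwd), ("-", rev)):
        if not words:
            continue
        scores = _score(model, words)
        top = max(scores.values())
        if best is None or top > best[0]:
            best = (top, orient, scores)
    assert best is not None
    top, orient, scores = best
    winners = sorted(t for t, s in scores.items() if s == top)
    return Classification(label=winners[0], scores=scores, orientation=orient)


def classify_records(
    model: WordModel, records: Sequence[SequenceRecord]
) -> dict[str, Classification]:
    return {r.id: classify(model, r.residues) for r in records}
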
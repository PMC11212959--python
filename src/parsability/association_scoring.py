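"""Sliding-window positive PMI (PPMI) scoring with Laplace smoothing.

A four-word sliding window over a string yields exactly the word pairs at
distance 1-3 (bigrams, 1-skip-grams, 2-skip-grams).  Each pair's pointwise
mutual information is computed from smoothed unigram and pair probabilities,
clipped at zero, and averaged to a per-string combinability score.  Because
the pair set {|i-j| <= 3} is invariant under string reversal, a reversed
string scores identically to the original — the computational content of the
claim that backward presentation preserves local combinability.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

WINDOW = 4  # sliding window size; pairs at distance <= WINDOW - 1


class UndefinedScoreError(ValueError):
    """PPMI of a string with fewer than two tokens is undefined."""


def extract_window_pairs(tokens: Sequence[str]) -> list[tuple[int, int]]:
    """Index pairs (i, j) with 1 <= j - i <= 3, in lexicographic order.

    For n >= 4 this yields 3n - 6 pairs; shorter strings yield fewer, and
    strings below two tokens yield the empty list.
    """
    n = len(tokens)
    return [(i, j) for i in range(n) for j in range(i + 1, min(i + WINDOW, n))]


@dataclass
class NgramCountTable:
    """Unigram and unordered within-window pair counts with Laplace smoothing.

    Smoothed estimates (the event-space sizes are a documented choice):

        P(w)       = (c(w) + alpha) / (N_uni + alpha * V)
        P(w1, w2)  = (c({w1, w2}) + alpha) / (N_pair + alpha * V**2)

    ``alpha`` defaults to 0.1.  Pair counts are stored under a sorted
    (unordered) key; an ordered variant backs directional PMI.
    """

    unigram: Counter = field(default_factory=Counter)
    pair: Counter = field(default_factory=Counter)
    alpha: float = 0.1
    vocabulary: set = field(default_factory=set)
    ordered_pairs: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if any(c < 0 for c in self.unigram.values()) or any(c < 0 for c in self.pair.values()):
            raise ValueError("counts must be non-negative")
        self.vocabulary = set(self.vocabulary) | set(self.unigram)

    @property
    def n_uni(self) -> int:
        return sum(self.unigram.values())

    @property
    def n_pair(self) -> int:
        return sum(self.pair.values())

    @property
    def v(self) -> int:
        return len(self.vocabulary)

    def _pair_key(self, w1: str, w2: str) -> tuple[str, str]:
        return (w1, w2) if self.ordered_pairs else tuple(sorted((w1, w2)))

    def add_string(self, tokens: Sequence[str]) -> None:
        """Tally a string's unigrams and within-window pairs."""
        self.unigram.update(tokens)
        self.vocabulary.update(tokens)
        for i, j in extract_window_pairs(tokens):
            self.pair[self._pair_key(tokens[i], tokens[j])] += 1

    def p_word(self, w: str) -> float:
        return (self.unigram[w] + self.alpha) / (self.n_uni + self.alpha * self.v)

    def p_pair(self, w1: str, w2: str) -> float:
        c = self.pair[self._pair_key(w1, w2)]
        return (c + self.alpha) / (self.n_pair + self.alpha * self.v**2)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# V={self.v}\talpha={self.alpha}\tordered={int(self.ordered_pairs)}\n")
            for w in sorted(self.vocabulary):
                fh.write(f"UNI\t{w}\t{self.unigram[w]}\n")
            for key in sorted(self.pair):
                fh.write(f"PAIR\t{key[0]}\t{key[1]}\t{self.pair[key]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NgramCountTable":
        unigram: Counter = Counter()
        pair: Counter = Counter()
        vocab: set = set()
        alpha, ordered = 0.1, False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for part in line.lstrip("# ").split("\t"):
                        k, _, v = part.partition("=")
                        if k == "alpha":
                            alpha = float(v)
                        elif k == "ordered":
                            ordered = bool(int(v))
                    continue
                fields = line.split("\t")
                if fields[0] == "UNI":
                    unigram[fields[1]] += int(fields[2])
                    vocab.add(fields[1])
                elif fields[0] == "PAIR":
                    pair[(fields[1], fields[2])] += int(fields[3])
                else:
                    raise ValueError(f"unrecognised row tag {fields[0]!r}")
        return cls(unigram=unigram, pair=pair, alpha=alpha, vocabulary=vocab, ordered_pairs=ordered)


def pmi(w1: str, w2: str, table: NgramCountTable, log_base: float | None = None) -> float:
    """Signed pointwise mutual information log[P(w1,w2) / (P(w1) P(w2))].

    Natural log by default; pass ``log_base=2`` for bits.  Smoothing keeps
    every probability positive, so the value is always finite.
    """
    val = math.log(table.p_pair(w1, w2) / (table.p_word(w1) * table.p_word(w2)))
    if log_base is not None:
        val /= math.log(log_base)
    return val


@dataclass
class PpmiResult:
    """Per-pair clipped PMI scores and their per-string mean."""

    sentence_id: str
    pair_scores: list[tuple[int, int, float]]
    mean_score: float
    n_pairs: int
    normalization: str


def ppmi_string(
    tokens: Sequence[str],
    table: NgramCountTable,
    sentence_id: str = "",
    normalization: str = "actual_pairs",
    log_base: float | None = None,
) -> PpmiResult:
    """Per-string PPMI: mean of max(0, PMI) over all window pairs.

    ``normalization="actual_pairs"`` divides by the true pair count
    (3n - 6 for n >= 4); ``"printed_constant"`` divides by 3n - 2, the
    constant printed in the source formula, kept for literal replication.
    """
    pairs = extract_window_pairs(tokens)
    if not pairs:
        raise UndefinedScoreError("PPMI undefined for strings shorter than 2 tokens")
    scores = [(i, j, max(0.0, pmi(tokens[i], tokens[j], table, log_base))) for i, j in pairs]
    # fsum: correctly rounded, so reversal (which permutes the addends)
    # yields a bit-identical mean
    total = math.fsum(s for _, _, s in scores)
    if normalization == "actual_pairs":
        denom = len(pairs)
    elif normalization == "printed_constant":
        denom = 3 * len(tokens) - 2
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return PpmiResult(
        sentence_id=sentence_id,
        pair_scores=scores,
        mean_score=total / denom,
        n_pairs=len(pairs),
        normalization=normalization,
    )


def build_table_from_corpus(
    corpora: Iterable[Sequence[str]], alpha: float = 0.1, ordered_pairs: bool = False
) -> NgramCountTable:
    """Tally a table from an iterable of token sequences."""
    t = NgramCountTable(alpha=alpha, ordered_pairs=ordered_pairs)
    for tokens in corpora:
        t.add_string(list(tokens))
    return t
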
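"""Stimulus-condition generators.

Every condition used in the word-order experiments is derived from a base
annotated sentence:

* ``Backward`` — full reversal (preserves local combinability exactly).
* ``Scrambled{k}`` — k iterative adjacent swaps of randomly chosen words.
* ``Scrambled_LowPMI`` — a permutation that separates originally proximal
  content words, destroying local combinability.
* ``Nonsense`` — content words replaced by feature-matched real words.
* ``Jabberwocky`` — content words replaced by structure-preserving nonwords.
* ``WordList`` / ``NonwordList`` — pooled tokens recombined into sequences
  by sampling without replacement.

All stochastic generators take an explicit ``numpy.random.Generator`` (or
integer seed); fixed seed implies bit-identical output.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_model import (
    AnnotatedSentence,
    Lexicon,
    NoReplacementCandidateError,
    ReplacementDictionary,
    onset_class,
)

CONDITIONS = (
    "Intact",
    "Scrambled1",
    "Scrambled3",
    "Scrambled5",
    "Scrambled7",
    "Scrambled_LowPMI",
    "Backward",
    "Nonsense",
    "Jabberwocky",
    "WordList",
    "NonwordList",
)

#: window within which content-word pairs count as "proximal"
PROXIMITY = 3


class DegradedInputError(ValueError):
    pass


class GenerationFailureError(RuntimeError):
    pass


@dataclass
class StimulusVariant:
    """One generated stimulus: surfaces plus a provenance record mapping
    output positions back to source positions or replacement records."""

    item_id: str
    condition: str
    tokens: list[str]
    provenance: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def intact(s: AnnotatedSentence) -> StimulusVariant:
    return StimulusVariant(
        item_id=s.item_id,
        condition="Intact",
        tokens=list(s.surfaces),
        provenance={"mapping": list(range(len(s)))},
    )


def backward(s: AnnotatedSentence) -> StimulusVariant:
    """Reverse the word order; an involution on token sequences."""
    n = len(s)
    return StimulusVariant(
        item_id=s.item_id,
        condition="Backward",
        tokens=list(reversed(s.surfaces)),
        provenance={"mapping": list(range(n - 1, -1, -1))},
    )


def scramble_local(
    s: AnnotatedSentence, k: int, rng: np.random.Generator | int | None = None
) -> StimulusVariant:
    """k iterative local swaps: choose k word positions without replacement,
    then, in sampled order, swap each chosen word (tracked as it moves) with
    a uniformly chosen immediate neighbour on the evolving string.

    Swaps can cancel; the output may equal the input.  Each swap is logged
    in provenance as (position, direction).
    """
    n = len(s)
    if n < 2 or k >= n:
        raise ValueError(f"need k < length and length >= 2 (got k={k}, n={n})")
    gen = _rng(rng)
    order = list(np.arange(n))  # order[i] = source position shown at slot i
    chosen = gen.choice(n, size=k, replace=False)
    swaps = []
    for src in chosen:
        pos = order.index(src)  # follow the chosen word as it moves
        if pos == 0:
            direction = +1
        elif pos == n - 1:
            direction = -1
        else:
            direction = int(gen.choice([-1, +1]))
        swaps.append((int(pos), direction))
        order[pos], order[pos + direction] = order[pos + direction], order[pos]
    return StimulusVariant(
        item_id=s.item_id,
        condition=f"Scrambled{k}",
        tokens=[s.surfaces[i] for i in order],
        provenance={"mapping": [int(i) for i in order], "swaps": swaps},
    )


def low_pmi_objective(perm: Sequence[int], content_positions: Sequence[int]) -> int:
    """Number of content-word pairs proximal (distance <= 3) in BOTH the
    original and the permuted string.  perm[i] = source position at slot i."""
    where = {src: i for i, src in enumerate(perm)}
    count = 0
    for a, b in itertools.combinations(sorted(content_positions), 2):
        if abs(a - b) <= PROXIMITY and abs(where[a] - where[b]) <= PROXIMITY:
            count += 1
    return count


def scramble_low_pmi(
    s: AnnotatedSentence,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = 8,
    n_steps: int = 400,
) -> StimulusVariant:
    """Permutation minimising surviving proximal content pairs.

    Exhaustive search for length <= 8; otherwise seeded random-restart
    hill-climbing over whole-string permutations (function words move too),
    with pairwise-swap moves.  The returned permutation's objective never
    exceeds the identity permutation's.
    """
    n = len(s)
    content = s.content_indices()
    if len(content) < 2:
        raise DegradedInputError("low-PMI scrambling needs at least 2 content words")
    gen = _rng(rng)

    def obj(p):
        return low_pmi_objective(p, content)

    best = list(range(n))
    best_obj = obj(best)
    if n <= 8:
        for perm in itertools.permutations(range(n)):
            o = obj(perm)
            if o < best_obj:
                best, best_obj = list(perm), o
                if o == 0:
                    break
    else:
        for _ in range(n_restarts):
            cur = list(gen.permutation(n))
            cur_obj = obj(cur)
            for _ in range(n_steps):
                if cur_obj == 0:
                    break
                i, j = gen.choice(n, size=2, replace=False)
                cur[i], cur[j] = cur[j], cur[i]
                new_obj = obj(cur)
                if new_obj <= cur_obj:
                    cur_obj = new_obj
                else:
                    cur[i], cur[j] = cur[j], cur[i]
            if cur_obj < best_obj:
                best, best_obj = list(cur), cur_obj
            if best_obj == 0:
                break
    return StimulusVariant(
        item_id=s.item_id,
        condition="Scrambled_LowPMI",
        tokens=[s.surfaces[i] for i in best],
        provenance={"mapping": [int(i) for i in best], "objective": int(best_obj)},
    )


def make_nonsense(
    s: AnnotatedSentence,
    dictionary: ReplacementDictionary,
    rng: np.random.Generator | int | None = None,
) -> StimulusVariant:
    """Replace each content word with a random feature-matched word from the
    replacement dictionary; function words stay in place.

    If a feature key has no candidates the match is relaxed in a fixed order
    (drop dependency label, then onset, then morphology); exhaustion raises
    :class:`~parsability.corpus_model.NoReplacementCandidateError`.
    Self-replacement is permitted.
    """
    gen = _rng(rng)
    tokens = list(s.surfaces)
    records = []
    for i, tok in enumerate(s.tokens):
        if not tok.is_content:
            continue
        key = tok.feature_key()
        cands = dictionary.candidates(key)
        if not cands:
            raise NoReplacementCandidateError(
                f"no replacement candidate at position {i} for key {key}"
            )
        repl = cands[int(gen.integers(len(cands)))]
        tokens[i] = repl
        records.append({"position": i, "original": tok.surface, "replacement": repl})
    return StimulusVariant(
        item_id=s.item_id,
        condition="Nonsense",
        tokens=tokens,
        provenance={"replacements": records},
    )


# ---------------------------------------------------------------------------
# nonword generation (structure-preserving; deliberately simpler than
# syllable-transition-matched pseudoword tools)

_SUFFIXES = ("ing", "est", "ed", "er", "s")
_CONSONANTS = "bdfgklmnprstvz"
_NW_VOWELS = "aeiou"


def _cv_skeleton(word: str) -> str:
    return "".join("V" if ch in _NW_VOWELS else "C" for ch in word.lower())


def generate_nonword(
    word: str,
    blocklist: Iterable[str],
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 200,
) -> str:
    """A pronounceable nonword matching ``word`` in length and
    consonant/vowel skeleton, preserving a detected inflectional suffix
    (-s, -ed, -ing, -er, -est), and absent from the blocklist."""
    gen = _rng(rng)
    block = set(blocklist)
    suffix = ""
    stem = word
    for suf in _SUFFIXES:
        if word.endswith(suf) and len(word) > len(suf) + 1:
            suffix, stem = suf, word[: -len(suf)]
            break
    skel = _cv_skeleton(stem)
    for _ in range(max_attempts):
        cand = "".join(
            str(gen.choice(list(_NW_VOWELS if c == "V" else _CONSONANTS))) for c in skel
        )
        cand += suffix
        if cand not in block and cand != word:
            return cand
    raise GenerationFailureError(f"could not generate a nonword for {word!r}")


def make_jabberwocky(
    s: AnnotatedSentence,
    lexicon: Lexicon,
    rng: np.random.Generator | int | None = None,
) -> StimulusVariant:
    """Replace content words with skeleton- and suffix-preserving nonwords;
    the lexicon serves as the real-word blocklist."""
    gen = _rng(rng)
    block = set(lexicon.surfaces())
    tokens = list(s.surfaces)
    records = []
    for i, tok in enumerate(s.tokens):
        if not tok.is_content:
            continue
        nw = generate_nonword(tok.surface, block, gen)
        tokens[i] = nw
        records.append({"position": i, "original": tok.surface, "replacement": nw})
    return StimulusVariant(
        item_id=s.item_id,
        condition="Jabberwocky",
        tokens=tokens,
        provenance={"replacements": records},
    )


def recombine_lists(
    pool: Sequence[StimulusVariant | AnnotatedSentence],
    n_seqs: int,
    seq_len: int,
    rng: np.random.Generator | int | None = None,
    condition: str = "WordList",
) -> list[StimulusVariant]:
    """Pool all tokens and recombine them into ``n_seqs`` sequences of
    ``seq_len`` tokens by sampling without replacement; the output token
    multiset equals the pooled input multiset exactly."""
    tokens: list[str] = []
    for item in pool:
        tokens.extend(item.tokens if isinstance(item, StimulusVariant) else item.surfaces)
    if len(tokens) != n_seqs * seq_len:
        raise ValueError(
            f"pool size mismatch: expected {n_seqs * seq_len} tokens, got {len(tokens)}"
        )
    gen = _rng(rng)
    order = gen.permutation(len(tokens))
    out = []
    for q in range(n_seqs):
        idx = order[q * seq_len : (q + 1) * seq_len]
        out.append(
            StimulusVariant(
                item_id=f"{condition.lower()}_{q:03d}",
                condition=condition,
                tokens=[tokens[i] for i in idx],
                provenance={"source_token_indices": [int(i) for i in idx]},
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV I/O


def variants_to_tsv(variants: Iterable[StimulusVariant], path) -> None:
    import pandas as pd

    rows = [
        {
            "item_id": v.item_id,
            "condition": v.condition,
            "seed": v.seed if v.seed is not None else "",
            "tokens": v.text,
            "provenance": json.dumps(v.provenance),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def variants_from_tsv(path) -> list[StimulusVariant]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"item_id": str, "tokens": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StimulusVariant(
                item_id=row.item_id,
                condition=row.condition,
                tokens=str(row.tokens).split(),
                provenance=json.loads(row.provenance) if isinstance(row.provenance, str) else {},
            )
        )
    return out
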
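"""Shared text data model: tokens, annotated sentences, lexica, and the
feature-keyed replacement dictionary that backs nonsense-sentence generation.

Annotation here is lexicon-driven and deterministic: a surface form maps to a
fixed bundle of (POS, dependency label, morphological features, verb valence,
noun onset class).  That is a deliberate simplification — in real corpora the
dependency label is positional — but it keeps every downstream generator
reproducible offline and is sufficient for feature-matched word replacement.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: POS tags whose tokens count as content words.
CONTENT_POS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})

#: Verb argument-valence classes recognised by the toy lexicon.
VALENCE_CLASSES = frozenset({"intransitive", "transitive", "ditransitive", "copular"})

VOWELS = frozenset("aeiou")


class UnresolvableTokenError(KeyError):
    """A word has no entry in the annotation lexicon."""


class EmptySentenceError(ValueError):
    """Input contained no tokens after whitespace tokenization."""


class NoReplacementCandidateError(LookupError):
    """No dictionary candidate matches a content word's feature key."""


def onset_class(surface: str) -> str:
    """Coarse phonological onset from orthography: first letter in
    a/e/i/o/u counts as a vowel onset (an orthographic proxy)."""
    return "vowel" if surface[:1].lower() in VOWELS else "consonant"


@dataclass(frozen=True)
class Token:
    """One annotated word.

    ``is_content`` is derived from POS; ``valence`` is present only for
    verbs and ``onset`` only for nouns (class invariants, checked at
    construction).
    """

    surface: str
    pos: str
    dep: str = "dep"
    morph: frozenset = frozenset()  # of "Feature=Value" strings
    valence: str | None = None
    onset: str | None = None

    def __post_init__(self):
        if self.valence is not None and self.pos != "VERB":
            raise ValueError(f"valence set on non-verb {self.surface!r} ({self.pos})")
        if self.onset is not None and self.pos not in ("NOUN", "PROPN"):
            raise ValueError(f"onset set on non-noun {self.surface!r} ({self.pos})")

    @property
    def is_content(self) -> bool:
        return self.pos in CONTENT_POS

    def feature_key(self) -> "FeatureKey":
        return FeatureKey(
            pos=self.pos,
            dep=self.dep,
            morph=self.morph,
            valence=self.valence,
            onset=self.onset,
        )


@dataclass(frozen=True)
class FeatureKey:
    """Canonical hashable annotation bundle used for replacement matching.

    Normalised so that two tokens with identical annotation fields compare
    equal regardless of morphological-feature ordering (``morph`` is a
    frozenset).
    """

    pos: str
    dep: str | None = None
    morph: frozenset = frozenset()
    valence: str | None = None
    onset: str | None = None

    def relax(self, level: int) -> "FeatureKey":
        """Progressively coarser keys for fallback matching.

        level 0: full key; 1: drop dep label; 2: also drop onset;
        3: also drop morph (keep POS + valence).
        """
        if level <= 0:
            return self
        dep = None
        onset = self.onset if level < 2 else None
        morph = self.morph if level < 3 else frozenset()
        return FeatureKey(pos=self.pos, dep=dep, morph=morph, valence=self.valence, onset=onset)


@dataclass
class AnnotatedSentence:
    """An ordered sequence of annotated tokens with an item identifier."""

    tokens: list[Token]
    item_id: str = ""

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise EmptySentenceError("a sentence needs at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def content_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if t.is_content]


class Lexicon:
    """Deterministic surface -> Token annotation source.

    Entries are added with :meth:`add` or read from a TSV
    (columns: surface, upos, deprel, feats, valence, onset; ``_`` = absent).
    """

    def __init__(self):
        self._entries: dict[str, Token] = {}

    def add(
        self,
        surface: str,
        pos: str,
        dep: str = "dep",
        morph: Iterable[str] = (),
        valence: str | None = None,
    ) -> None:
        if valence is not None and valence not in VALENCE_CLASSES:
            raise ValueError(f"unknown valence class {valence!r}")
        onset = onset_class(surface) if pos in ("NOUN", "PROPN") else None
        self._entries[surface] = Token(
            surface=surface,
            pos=pos,
            dep=dep,
            morph=frozenset(morph),
            valence=valence if pos == "VERB" else None,
            onset=onset,
        )

    def __contains__(self, surface: str) -> bool:
        return surface in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, surface: str) -> Token:
        try:
            return self._entries[surface]
        except KeyError:
            raise UnresolvableTokenError(f"no lexicon entry for word {surface!r}") from None

    def surfaces(self) -> list[str]:
        return sorted(self._entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s, t in sorted(self._entries.items()):
            rows.append(
                {
                    "surface": s,
                    "upos": t.pos,
                    "deprel": t.dep,
                    "feats": "|".join(sorted(t.morph)) or "_",
                    "valence": t.valence or "_",
                    "onset": t.onset or "_",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("_")
        lex = cls()
        for row in df.itertuples(index=False):
            morph = () if row.feats == "_" else tuple(row.feats.split("|"))
            lex.add(
                row.surface,
                row.upos,
                dep=row.deprel,
                morph=morph,
                valence=None if row.valence == "_" else row.valence,
            )
        return lex


def annotate(raw_sentence: str, lexicon: Lexicon, item_id: str = "") -> AnnotatedSentence:
    """Annotate a whitespace-tokenized sentence against a lexicon.

    Raises :class:`EmptySentenceError` for empty input and
    :class:`UnresolvableTokenError` naming the first unknown word.
    """
    words = raw_sentence.split()
    if not words:
        raise EmptySentenceError("empty sentence")
    return AnnotatedSentence(tokens=[lexicon[w] for w in words], item_id=item_id)


@dataclass
class ReplacementDictionary:
    """FeatureKey -> multiset of content-word surfaces, duplicates retained.

    Multiplicity of a surface under a key equals that (surface, key) pair's
    corpus token frequency, so sampling from a key's candidate list
    reproduces the corpus-frequency distribution.
    """

    entries: dict[FeatureKey, Counter] = field(default_factory=dict)

    @property
    def total_entries(self) -> int:
        return sum(sum(c.values()) for c in self.entries.values())

    def candidates(self, key: FeatureKey, max_relax: int = 3) -> list[str]:
        """Candidate surfaces for a key, relaxing the key in the fixed
        fallback order (drop dep -> drop onset -> drop morph) until some
        candidate exists.  Returns the expanded multiset as a sorted list."""
        for level in range(max_relax + 1):
            relaxed = key.relax(level)
            pool: Counter = Counter()
            for k, counter in self.entries.items():
                if k.relax(level) == relaxed:
                    pool.update(counter)
            if pool:
                return sorted(pool.elements())
        return []


def build_replacement_dictionary(corpus: Iterable[AnnotatedSentence]) -> ReplacementDictionary:
    """Collect every content token of the corpus into a feature-keyed
    dictionary, retaining duplicates (a word occurring twice under the same
    key is stored twice)."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be non-empty")
    d = ReplacementDictionary()
    for sent in corpus:
        for tok in sent.tokens:
            if tok.is_content:
                d.entries.setdefault(tok.feature_key(), Counter())[tok.surface] += 1
    if d.total_entries == 0:
        warnings.warn("corpus contains no content tokens; replacement dictionary is empty")
    return d


# ---------------------------------------------------------------------------
# CoNLL-like TSV I/O for annotated corpora

_CONLL_COLUMNS = ["item_id", "id", "form", "upos", "deprel", "feats", "valence", "onset"]


def corpus_to_tsv(sentences: Iterable[AnnotatedSentence], path: str | Path) -> None:
    rows = []
    for sent in sentences:
        for i, t in enumerate(sent.tokens, start=1):
            rows.append(
                {
                    "item_id": sent.item_id,
                    "id": i,
                    "form": t.surface,
                    "upos": t.pos,
                    "deprel": t.dep,
                    "feats": "|".join(sorted(t.morph)) or "_",
                    "valence": t.valence or "_",
                    "onset": t.onset or "_",
                }
            )
    pd.DataFrame(rows, columns=_CONLL_COLUMNS).to_csv(path, sep="\t", index=False)


def corpus_from_tsv(path: str | Path) -> list[AnnotatedSentence]:
    df = pd.read_csv(path, sep="\t", dtype={"item_id": str, "form": str}).fillna("_")
    sentences = []
    for item_id, group in df.groupby("item_id", sort=False):
        toks = []
        for row in group.sort_values("id").itertuples(index=False):
            morph = frozenset() if row.feats == "_" else frozenset(str(row.feats).split("|"))
            toks.append(
                Token(
                    surface=row.form,
                    pos=row.upos,
                    dep=row.deprel,
                    morph=morph,
                    valence=None if row.valence == "_" else row.valence,
                    onset=None if row.onset == "_" else row.onset,
                )
            )
        sentences.append(AnnotatedSentence(tokens=toks, item_id=str(item_id)))
    return sentences
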
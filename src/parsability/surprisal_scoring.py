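"""Per-word surprisal from probabilistic context-free grammars.

The grammaticality measure used throughout this package is incremental
surprisal: for a string w_1..w_n, the surprisal of w_i is

    s(w_i) = log P(w_1..w_{i-1}) - log P(w_1..w_i)

where P(prefix) is the *prefix probability* — the total probability mass of
all complete sentences of the grammar that begin with that prefix.  Prefix
probabilities are computed exactly by a CKY-style chart over the prefix
combined with, at each start position, a linear system that accounts for
constituents spilling past the prefix end (this handles unit and
left-recursive rule chains in closed form via matrix inversion).

A broad-coverage parser is out of scope; the :class:`ToyPCFG` is the
desk-scale stand-in, with exhaustive derivation enumeration available as an
independent oracle (:func:`enumerate_language`).  For scoring arbitrary word
orders — which a crisp grammar assigns zero probability — the
:class:`GrammarScorer` optionally interpolates the grammar's conditional
with a unigram distribution, mirroring the smoothing any practical parser
applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

PROB_TOL = 1e-9


class GrammarError(ValueError):
    pass


class OutOfVocabularyError(KeyError):
    """A token is not a terminal of the grammar."""


class UndefinedConditionalError(ValueError):
    """Surprisal conditioned on a zero-probability prefix."""


@dataclass(frozen=True)
class Rule:
    lhs: str
    rhs: tuple[str, ...]
    prob: float


class ToyPCFG:
    """A small probabilistic context-free grammar.

    Symbols appearing on any left-hand side are nonterminals; all other
    right-hand-side symbols are terminals.  Rule probabilities must sum to
    one per left-hand side (checked to 1e-9).  Empty right-hand sides are
    not supported.
    """

    def __init__(self, rules: Iterable[tuple[str, Sequence[str], float]], start: str = "S"):
        self.rules = [Rule(lhs, tuple(rhs), float(p)) for lhs, rhs, p in rules]
        if not self.rules:
            raise GrammarError("grammar has no rules")
        self.start = start
        self.nonterminals = {r.lhs for r in self.rules}
        if start not in self.nonterminals:
            raise GrammarError(f"start symbol {start!r} has no rules")
        self.terminals = {
            sym for r in self.rules for sym in r.rhs if sym not in self.nonterminals
        }
        for r in self.rules:
            if len(r.rhs) == 0:
                raise GrammarError(f"empty right-hand side for {r.lhs}")
            if r.prob < 0:
                raise GrammarError(f"negative probability on {r}")
        sums: dict[str, float] = {}
        for r in self.rules:
            sums[r.lhs] = sums.get(r.lhs, 0.0) + r.prob
        bad = {lhs: s for lhs, s in sums.items() if abs(s - 1.0) > PROB_TOL}
        if bad:
            raise GrammarError(f"rule probabilities do not sum to 1 for {sorted(bad)}")
        self._chart: _BinarizedGrammar | None = None

    # ------------------------------------------------------------- sampling

    def sample(self, rng: np.random.Generator, max_expansions: int = 10_000) -> list[str]:
        """Sample one sentence by stochastic leftmost expansion."""
        by_lhs: dict[str, list[Rule]] = {}
        for r in self.rules:
            by_lhs.setdefault(r.lhs, []).append(r)
        form: list[str] = [self.start]
        out: list[str] = []
        expansions = 0
        while form:
            sym = form.pop(0)
            if sym not in self.nonterminals:
                out.append(sym)
                continue
            expansions += 1
            if expansions > max_expansions:
                raise GrammarError("sampling exceeded the expansion bound (runaway recursion?)")
            rules = by_lhs[sym]
            probs = np.array([r.prob for r in rules])
            choice = rules[rng.choice(len(rules), p=probs / probs.sum())]
            form = list(choice.rhs) + form
        return out

    # -------------------------------------------------------- chart backend

    def _binarized(self) -> "_BinarizedGrammar":
        if self._chart is None:
            self._chart = _BinarizedGrammar(self)
        return self._chart

    def inside_chart(self, tokens: Sequence[str]) -> dict[tuple[int, int], np.ndarray]:
        return self._binarized().inside_chart(tokens)

    # --------------------------------------------------------------- file IO

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# start: {self.start}\n")
            for r in self.rules:
                fh.write(f"{r.lhs} -> {' '.join(r.rhs)} : {r.prob!r}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ToyPCFG":
        rules = []
        start = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("# start:"):
                        start = line.split(":", 1)[1].strip()
                    continue
                head, _, prob = line.rpartition(":")
                lhs, _, rhs = head.partition("->")
                rules.append((lhs.strip(), tuple(rhs.split()), float(prob)))
        return cls(rules, start=start or rules[0][0])


class _BinarizedGrammar:
    """Internal chart form: lexical, unit and binary rules over an index
    space of nonterminals, with the unit-closure and prefix-spill matrices
    precomputed."""

    def __init__(self, g: ToyPCFG):
        self.terminals = g.terminals
        lexical: dict[str, dict[str, float]] = {}
        units: list[tuple[str, str, float]] = []
        binaries: list[tuple[str, str, str, float]] = []
        fresh = 0
        extra_nts: set[str] = set()

        def wrap_terminal(w: str) -> str:
            name = f"_T[{w}]"
            if name not in extra_nts:
                extra_nts.add(name)
                lexical.setdefault(w, {})[name] = 1.0
            return name

        for r in g.rules:
            rhs = list(r.rhs)
            if len(rhs) == 1:
                if rhs[0] in g.nonterminals:
                    units.append((r.lhs, rhs[0], r.prob))
                else:
                    lexical.setdefault(rhs[0], {})[r.lhs] = (
                        lexical.setdefault(rhs[0], {}).get(r.lhs, 0.0) + r.prob
                    )
                continue
            syms = [s if s in g.nonterminals else wrap_terminal(s) for s in rhs]
            # left-to-right binarization; probability carried on the first rule
            prev, prob = r.lhs, r.prob
            for k in range(len(syms) - 2):
                mid = f"_B{fresh}"
                fresh += 1
                extra_nts.add(mid)
                binaries.append((prev, syms[k], mid, prob))
                prev, prob = mid, 1.0
            binaries.append((prev, syms[-2], syms[-1], prob))

        nts = sorted(g.nonterminals | extra_nts)
        self.index = {nt: i for i, nt in enumerate(nts)}
        self.n = len(nts)
        self.start = self.index[g.start]

        self.lexical = {
            w: self._vector(d) for w, d in lexical.items()
        }  # word -> raw production vector
        self.binaries = [
            (self.index[a], self.index[b], self.index[c], p) for a, b, c, p in binaries
        ]
        p_unit = np.zeros((self.n, self.n))
        for a, b, p in units:
            p_unit[self.index[a], self.index[b]] += p
        # unit closure: inside = U @ raw sums over arbitrary unit chains
        self.u_closure = np.linalg.inv(np.eye(self.n) - p_unit)
        # prefix spill: pre[A] picks up p * pre[B] for A -> B C (C unseen)
        # and p * pre[B] for unit rules A -> B
        spill = p_unit.copy()
        for a, b, _c, p in self.binaries:
            spill[a, b] += p
        self.m_spill = np.linalg.inv(np.eye(self.n) - spill)

    def _vector(self, d: Mapping[str, float]) -> np.ndarray:
        v = np.zeros(self.n)
        for nt, p in d.items():
            v[self.index[nt]] = p
        return v

    def inside_chart(self, tokens: Sequence[str]) -> dict[tuple[int, int], np.ndarray]:
        """inside[(i, k)][A] = P(A derives tokens[i:k]) for all spans."""
        for w in tokens:
            if w not in self.terminals:
                raise OutOfVocabularyError(f"token {w!r} is not a terminal of the grammar")
        n = len(tokens)
        chart: dict[tuple[int, int], np.ndarray] = {}
        for i, w in enumerate(tokens):
            chart[(i, i + 1)] = self.u_closure @ self.lexical[w]
        for width in range(2, n + 1):
            for i in range(n - width + 1):
                k = i + width
                raw = np.zeros(self.n)
                for a, b, c, p in self.binaries:
                    acc = 0.0
                    for j in range(i + 1, k):
                        acc += chart[(i, j)][b] * chart[(j, k)][c]
                    raw[a] += p * acc
                chart[(i, k)] = self.u_closure @ raw
        return chart

    def prefix_vectors(
        self, chart: dict[tuple[int, int], np.ndarray], tokens: Sequence[str], l: int
    ) -> np.ndarray:
        """pre[i][A] = P(A derives a string beginning with tokens[i:l]),
        assuming a consistent grammar (each nonterminal's total string mass
        is one).  Returns an (l+1, n) array; row l is all ones."""
        pre = np.ones((l + 1, self.n))
        for i in range(l - 1, -1, -1):
            c = np.zeros(self.n)
            # raw (un-closed) lexical vector: unit chains above it are
            # accounted for by m_spill, which embeds the unit matrix
            if tokens[i] in self.lexical and i == l - 1:
                c += self.lexical[tokens[i]]
            for a, b, cc, p in self.binaries:
                acc = 0.0
                for k in range(i + 1, l + 1):
                    if (i, k) in chart:
                        acc += chart[(i, k)][b] * pre[k][cc]
                # subtract the exact-cover part of the spill term to avoid
                # double counting B deriving tokens[i:l] exactly
                exact = chart[(i, l)][b] if (i, l) in chart else 0.0
                c[a] += p * (acc - exact)
            pre[i] = self.m_spill @ c
        return pre


# ---------------------------------------------------------------------------
# public scoring API


def prefix_probability(g: ToyPCFG, prefix: Sequence[str]) -> float:
    """Total probability of all complete sentences extending ``prefix``
    (including the sentence equal to the prefix itself)."""
    prefix = list(prefix)
    if not prefix:
        return 1.0
    bg = g._binarized()
    chart = bg.inside_chart(prefix)
    pre = bg.prefix_vectors(chart, prefix, len(prefix))
    return float(max(0.0, pre[0][bg.start]))


def string_prefix_probabilities(g: ToyPCFG, tokens: Sequence[str]) -> np.ndarray:
    """Prefix probabilities P(w_1..w_l) for l = 0..n in one chart pass."""
    tokens = list(tokens)
    bg = g._binarized()
    chart = bg.inside_chart(tokens)
    out = np.empty(len(tokens) + 1)
    out[0] = 1.0
    for l in range(1, len(tokens) + 1):
        pre = bg.prefix_vectors(chart, tokens, l)
        out[l] = max(0.0, pre[0][bg.start])
    return out


def word_surprisal(
    g: ToyPCFG, tokens: Sequence[str], position: int, log_base: float | None = None
) -> float:
    """Surprisal of tokens[position] given the preceding words."""
    probs = string_prefix_probabilities(g, tokens[: position + 1])
    if probs[position] <= 0:
        raise UndefinedConditionalError(
            f"prefix up to position {position} has zero probability"
        )
    val = math.log(probs[position]) - (
        math.log(probs[position + 1]) if probs[position + 1] > 0 else -math.inf
    )
    if log_base is not None:
        val /= math.log(log_base)
    return val


@dataclass
class SurprisalResult:
    """Per-word surprisals (possibly +inf) and their mean for one string."""

    sentence_id: str
    per_word: list[float]
    mean: float
    backend: str


def mean_surprisal(per_word: Sequence[float], sentence_id: str = "", backend: str = "external_file") -> SurprisalResult:
    vals = [float(v) for v in per_word]
    m = sum(vals) / len(vals) if vals else float("nan")
    return SurprisalResult(sentence_id=sentence_id, per_word=vals, mean=m, backend=backend)


class GrammarScorer:
    """Surprisal scorer over a :class:`ToyPCFG`, optionally smoothed.

    With ``smoothing_lambda == 0`` the scorer is the pure grammar: the
    conditional of each word is the ratio of consecutive prefix
    probabilities, and an impossible continuation yields infinite surprisal.
    With ``smoothing_lambda > 0`` the conditional is interpolated with a
    unigram distribution over the grammar's terminals,

        P(w | prefix) = (1 - lam) * P_g(w | prefix) + lam * P_uni(w),

    so every word order receives a finite score.  Once a prefix has zero
    grammar probability the grammar component stays at zero for the rest of
    the string (no re-entry).  Results are cached per token tuple.
    """

    backend = "toy_pcfg"

    def __init__(
        self,
        grammar: ToyPCFG,
        smoothing_lambda: float = 0.0,
        unigram: Mapping[str, float] | None = None,
        log_base: float | None = None,
    ):
        if not 0.0 <= smoothing_lambda < 1.0:
            raise ValueError("smoothing_lambda must be in [0, 1)")
        self.grammar = grammar
        self.lam = smoothing_lambda
        self.log_base = log_base
        if unigram is None:
            terms = sorted(grammar.terminals)
            unigram = {w: 1.0 / len(terms) for w in terms}
        z = sum(unigram.values())
        self.unigram = {w: p / z for w, p in unigram.items()}
        self._cache: dict[tuple[str, ...], list[float]] = {}

    def _p_uni(self, w: str) -> float:
        p = self.unigram.get(w, 0.0)
        if p <= 0:
            raise OutOfVocabularyError(f"{w!r} has no unigram mass in the scorer")
        return p

    def per_word(self, tokens: Sequence[str]) -> list[float]:
        key = tuple(tokens)
        if key in self._cache:
            return list(self._cache[key])
        prefix_p = string_prefix_probabilities(self.grammar, tokens)
        out: list[float] = []
        scale = math.log(self.log_base) if self.log_base else 1.0
        for i, w in enumerate(tokens):
            cond_g = prefix_p[i + 1] / prefix_p[i] if prefix_p[i] > 0 else 0.0
            if self.lam > 0:
                cond = (1 - self.lam) * cond_g + self.lam * self._p_uni(w)
            else:
                cond = cond_g
            if cond <= 0:
                if prefix_p[i] <= 0:
                    raise UndefinedConditionalError(
                        f"zero-probability prefix before position {i}; "
                        "use smoothing_lambda > 0 to score arbitrary orders"
                    )
                out.append(math.inf)
            else:
                out.append(-math.log(cond) / scale)
        self._cache[key] = out
        return list(out)

    def score(self, tokens: Sequence[str], sentence_id: str = "") -> SurprisalResult:
        pw = self.per_word(tokens)
        return SurprisalResult(
            sentence_id=sentence_id,
            per_word=pw,
            mean=sum(pw) / len(pw),
            backend=self.backend,
        )


class ExternalFileScorer:
    """Scorer backed by a TSV of externally computed per-word surprisals
    (columns: sentence_id, position, word, surprisal).  This is the seam
    through which broad-coverage parser or neural-LM estimates enter the
    analyses; the module only validates alignment."""

    backend = "external_file"

    def __init__(self, path: str | Path):
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"sentence_id": str, "word": str})
        self._table: dict[str, list[tuple[str, float]]] = {}
        for sid, group in df.groupby("sentence_id", sort=False):
            g = group.sort_values("position")
            self._table[str(sid)] = list(zip(g["word"], g["surprisal"].astype(float)))

    def score(self, tokens: Sequence[str], sentence_id: str) -> SurprisalResult:
        if sentence_id not in self._table:
            raise KeyError(f"no external surprisals for sentence {sentence_id!r}")
        rows = self._table[sentence_id]
        words = [w for w, _ in rows]
        if list(tokens) != words:
            raise ValueError(
                f"alignment error for {sentence_id!r}: tokens {list(tokens)} vs file {words}"
            )
        return mean_surprisal([v for _, v in rows], sentence_id, backend=self.backend)


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle


def enumerate_language(
    g: ToyPCFG, max_len: int = 20, max_expansions: int = 200_000
) -> dict[tuple[str, ...], float]:
    """Enumerate all sentences of the grammar up to ``max_len`` tokens by
    exhaustive leftmost derivation, returning sentence -> total probability.

    Independent of the chart backend; used as the surprisal oracle in tests
    and validation.  Raises :class:`GrammarError` if the expansion budget is
    exhausted (infinite or too-large language).
    """
    by_lhs: dict[str, list[Rule]] = {}
    for r in g.rules:
        by_lhs.setdefault(r.lhs, []).append(r)
    out: dict[tuple[str, ...], float] = {}
    stack: list[tuple[tuple[str, ...], float]] = [((g.start,), 1.0)]
    expansions = 0
    while stack:
        form, prob = stack.pop()
        idx = next((i for i, s in enumerate(form) if s in g.nonterminals), None)
        if idx is None:
            out[form] = out.get(form, 0.0) + prob
            continue
        for r in by_lhs[form[idx]]:
            expansions += 1
            if expansions > max_expansions:
                raise GrammarError("enumeration budget exhausted")
            new_form = form[:idx] + r.rhs + form[idx + 1 :]
            # every symbol yields >= 1 terminal (no epsilon rules), so any
            # form longer than max_len can only derive over-long sentences
            if len(new_form) > max_len:
                continue
            stack.append((new_form, prob * r.prob))
    return out


def prefix_probability_by_enumeration(
    language: Mapping[tuple[str, ...], float], prefix: Sequence[str]
) -> float:
    """Oracle prefix probability: sum over enumerated sentences that start
    with ``prefix``."""
    prefix = tuple(prefix)
    return sum(p for s, p in language.items() if s[: len(prefix)] == prefix)
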
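"""Synthetic study worlds: a no-download test surface with the statistical
structure the analyses assume.

A :class:`SyntheticWorld` bundles, all derived deterministically from one
seed: a toy lexicon and probabilistic grammar standing in for a natural
corpus; grammar-generated 12-word annotated base sentences; an n-gram count
table tallied from a large grammar sample (standing in for web-scale count
corpora); a minimal participant model for the incremental-reordering task
(per-condition per-word repair probability); and voxel maps with planted
condition effects plus Gaussian noise (standing in for scanner data).

The generator emulates the *structure* of the real inputs — sentence length,
content/function-word mix, co-occurrence statistics induced by a generative
grammar, skill-dependent reconstruction, signal-carrying voxels — not their
surface statistics (no natural-corpus lexical frequencies, no neural-LM
surprisal distributions, no spatial voxel correlation).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .association_scoring import NgramCountTable, build_table_from_corpus
from .corpus_model import AnnotatedSentence, Lexicon, annotate
from .froi_stats import VoxelMap
from .stimulus_engine import StimulusVariant
from .surprisal_scoring import ToyPCFG
from .synreco import ParticipantLog, SynRecoTrial, run_trial

#: per-condition per-word repair probability of the simulated participant
#: pool: locally scrambled strings are repairable in real time, severely
#: scrambled and reversed strings mostly are not
DEFAULT_SKILL = {
    "Intact": 1.0,
    "Scrambled1": 0.85,
    "Scrambled3": 0.85,
    "Scrambled5": 0.85,
    "Scrambled7": 0.85,
    "Scrambled_LowPMI": 0.25,
    "Backward": 0.25,
}

#: planted per-condition percent-signal-change effects; the ordering mirrors
#: the qualitative response profile of language-selective cortex (structured
#: and structure-recoverable stimuli high, reversed and unstructured low)
DEFAULT_VOXEL_EFFECTS = {
    "Sentence": 1.5,
    "Nonsense": 1.45,
    "Backward": 0.9,
    "WordList": 0.7,
    "Jabberwocky": 0.7,
    "NonwordList": 0.4,
}


def default_lexicon() -> Lexicon:
    """Hand-built deterministic annotation lexicon for the toy grammar."""
    lex = Lexicon()
    det = ["the", "a"]
    nouns = [
        "dog", "cat", "owl", "otter", "apple", "farmer", "letter", "garden",
        "table", "engine", "idea", "violin", "teacher", "island", "basket", "mirror",
    ]
    adjs = ["old", "red", "quiet", "eager", "tiny", "warm"]
    advs = ["quietly", "soon", "gladly", "twice"]
    preps = ["near", "behind", "above", "beside"]
    v_intr = ["slept", "smiled", "vanished", "wandered"]
    v_tr = ["chased", "found", "admired", "carried"]
    v_cop = ["seemed", "looked"]
    for w in det:
        lex.add(w, "DET", dep="det")
    for w in nouns:
        lex.add(w, "NOUN", dep="nmod", morph=("Number=Sing",))
    for w in adjs:
        lex.add(w, "ADJ", dep="amod", morph=("Degree=Pos",))
    for w in advs:
        lex.add(w, "ADV", dep="advmod")
    for w in preps:
        lex.add(w, "ADP", dep="case")
    for w in v_intr:
        lex.add(w, "VERB", dep="root", morph=("Tense=Past",), valence="intransitive")
    for w in v_tr:
        lex.add(w, "VERB", dep="root", morph=("Tense=Past",), valence="transitive")
    for w in v_cop:
        lex.add(w, "VERB", dep="root", morph=("Tense=Past",), valence="copular")
    return lex


def default_grammar() -> ToyPCFG:
    """Small phrase-structure grammar over the default lexicon, recursive
    through prepositional phrases so that 12-token sentences are common."""
    lex = default_lexicon()
    by_pos: dict[str, list[str]] = {}
    for w in lex.surfaces():
        by_pos.setdefault(lex[w].pos, []).append(w)
    by_val: dict[str, list[str]] = {}
    for w in by_pos["VERB"]:
        by_val.setdefault(lex[w].valence, []).append(w)

    rules: list[tuple[str, tuple[str, ...], float]] = [
        ("S", ("NP", "VP"), 1.0),
        ("NP", ("Det", "N"), 0.45),
        ("NP", ("Det", "Adj", "N"), 0.30),
        ("NP", ("Det", "N", "PP"), 0.25),
        ("PP", ("P", "NP"), 1.0),
        ("VP", ("Vi",), 0.15),
        ("VP", ("Vi", "Adv"), 0.10),
        ("VP", ("Vt", "NP"), 0.45),
        ("VP", ("Vt", "NP", "PP"), 0.20),
        ("VP", ("Vc", "Adj"), 0.10),
    ]

    def lexical(nt: str, words: list[str]):
        p = 1.0 / len(words)
        # exact unit mass: assign the residual to the last word
        for w in words[:-1]:
            rules.append((nt, (w,), p))
        rules.append((nt, (words[-1],), 1.0 - p * (len(words) - 1)))

    lexical("Det", by_pos["DET"])
    lexical("N", by_pos["NOUN"])
    lexical("Adj", by_pos["ADJ"])
    lexical("Adv", by_pos["ADV"])
    lexical("P", by_pos["ADP"])
    lexical("Vi", by_val["intransitive"])
    lexical("Vt", by_val["transitive"])
    lexical("Vc", by_val["copular"])
    return ToyPCFG(rules)


class GenerationFailureError(RuntimeError):
    pass


@dataclass
class SyntheticWorld:
    """Seeded bundle of toy lexicon, grammar, and simulation parameters.

    All generators draw from child streams of the world seed, so the same
    seed and configuration reproduce every artifact bit-identically.
    """

    seed: int
    lexicon: Lexicon = field(default_factory=default_lexicon)
    grammar: ToyPCFG = field(default_factory=default_grammar)
    skill: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SKILL))
    voxel_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VOXEL_EFFECTS))

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 rather than hash(): stable across interpreter sessions
        key = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    # ----------------------------------------------------------- sentences

    def gen_base_sentences(
        self, n: int, length: int = 12, max_attempts_per_sentence: int = 2000
    ) -> list[AnnotatedSentence]:
        """Rejection-sample ``n`` grammar sentences of exactly ``length``
        tokens, annotated via the world lexicon."""
        gen = self.rng("sentences")
        out: list[AnnotatedSentence] = []
        attempts = 0
        budget = n * max_attempts_per_sentence
        while len(out) < n:
            attempts += 1
            if attempts > budget:
                raise GenerationFailureError(
                    f"rejection bound exceeded generating {length}-token sentences"
                )
            toks = self.grammar.sample(gen)
            if len(toks) == length:
                out.append(annotate(" ".join(toks), self.lexicon, item_id=f"item_{len(out):03d}"))
        return out

    # -------------------------------------------------------- n-gram table

    def gen_ngram_table(self, sample_size: int, alpha: float = 0.1) -> NgramCountTable:
        """Tally unigram and within-window pair counts from
        ``sample_size`` freely sampled grammar sentences."""
        if sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        gen = self.rng("ngrams")
        return build_table_from_corpus(
            (self.grammar.sample(gen) for _ in range(sample_size)), alpha=alpha
        )

    # -------------------------------------------------- participant model

    def _repair_policy(self, skill: float, orig_of: Mapping[int, int], rng: np.random.Generator):
        """Insertion-style repair: after each reveal, walk the target ranks
        (original relative order) of the visible words; each word not at its
        target slot is moved there with probability ``skill``.  A word whose
        repair attempt fails is given up for the rest of the trial — the
        simulated participant commits to the misparse — so the chance of a
        verbatim reconstruction decays with the number of displaced words."""
        given_up: set[int] = set()

        def policy(trial: SynRecoTrial):
            cur = list(trial.current_order)
            target = sorted(cur, key=lambda i: orig_of[i])
            for tid in target:
                pos = cur.index(tid)
                r = target.index(tid)
                if pos == r or tid in given_up:
                    continue
                if rng.random() < skill:
                    cur.pop(pos)
                    cur.insert(r, tid)
                else:
                    given_up.add(tid)
            return [trial.full_sequence[i] for i in cur]

        return policy

    def simulate_synreco_logs(
        self,
        stimuli: Sequence[StimulusVariant],
        n_participants: int = 72,
        skill: Mapping[str, float] | None = None,
        p_attention_pass: float = 0.95,
        p_filler_pass: float = 0.85,
    ) -> list[ParticipantLog]:
        """Simulate the reordering experiment.

        Stimuli are grouped by item; each participant receives one
        condition version of each item, rotated Latin-square style across
        participants.  At each reveal the simulated participant repairs the
        display toward the original word order with the per-condition
        per-word probability given by ``skill``.  Attention-check and
        filler outcomes are Bernoulli bookkeeping.
        """
        skill = dict(DEFAULT_SKILL if skill is None else skill)
        for cond, v in skill.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"skill for {cond!r} must be in [0, 1]")
        rng = self.rng("participants")
        by_item: dict[str, dict[str, StimulusVariant]] = {}
        for v in stimuli:
            by_item.setdefault(v.item_id, {})[v.condition] = v
        items = sorted(by_item)
        conditions = sorted({v.condition for v in stimuli})
        logs = []
        for p in range(n_participants):
            log = ParticipantLog(participant_id=f"p{p:03d}")
            for i, item in enumerate(items):
                cond = conditions[(i + p) % len(conditions)]
                var = by_item[item].get(cond)
                if var is None:
                    continue
                mapping = var.provenance.get("mapping", list(range(len(var.tokens))))
                orig_of = {pos: src for pos, src in enumerate(mapping)}
                policy = self._repair_policy(skill.get(cond, 0.5), orig_of, rng)
                log.trials.append(
                    run_trial(var.tokens, item_id=item, condition=cond, policy=policy)
                )
            log.attention_results = list(rng.random(7) < p_attention_pass)
            log.filler_results = list(rng.random(12) < p_filler_pass)
            logs.append(log)
        return logs

    # ------------------------------------------------------------ voxels

    def simulate_voxel_data(
        self,
        n_voxels: int = 200,
        effects: Mapping[str, float] | None = None,
        noise_sd: float = 1.0,
        signal_fraction: float = 0.10,
        localizer_effect: float = 4.0,
        n_participants: int = 1,
        mask_label: str = "LH_synthetic",
    ) -> list[VoxelMap]:
        """Voxel maps with a planted signal subpopulation.

        ``signal_fraction`` of voxels carry the localizer effect and the
        per-condition response effects; all voxels receive independent
        Gaussian noise of ``noise_sd`` on both the statistic and the
        responses.  ``noise_sd=0`` reproduces the effects exactly.
        """
        if not 0 < signal_fraction <= 1:
            raise ValueError("signal_fraction must be in (0, 1]")
        effects = dict(DEFAULT_VOXEL_EFFECTS if effects is None else effects)
        rng = self.rng("voxels")
        n_signal = max(1, round(signal_fraction * n_voxels))
        maps = []
        for p in range(n_participants):
            is_signal = np.zeros(n_voxels, dtype=bool)
            is_signal[rng.choice(n_voxels, size=n_signal, replace=False)] = True
            stat = rng.normal(0.0, 1.0, n_voxels) + localizer_effect * is_signal
            responses = {
                cond: eff * is_signal + rng.normal(0.0, noise_sd, n_voxels) if noise_sd > 0
                else eff * is_signal + 0.0
                for cond, eff in effects.items()
            }
            maps.append(
                VoxelMap(
                    voxel_ids=np.arange(n_voxels),
                    localizer_stat=stat,
                    condition_responses=responses,
                    mask_label=f"{mask_label}_p{p:02d}",
                )
            )
        return maps

    # ----------------------------------------------------------- artifacts

    def write_world(self, out_dir: str | Path, n_sentences: int = 35, ngram_sample: int = 2000) -> dict:
        """Materialise the world's artifacts (corpus TSV, grammar file,
        n-gram table TSV, lexicon TSV) under ``out_dir``."""
        from .corpus_model import corpus_to_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sentences = self.gen_base_sentences(n_sentences)
        corpus_to_tsv(sentences, out / "corpus.tsv")
        self.grammar.to_file(out / "grammar.txt")
        self.gen_ngram_table(ngram_sample).to_tsv(out / "ngrams.tsv")
        self.lexicon.to_tsv(out / "lexicon.tsv")
        return {
            "corpus": out / "corpus.tsv",
            "grammar": out / "grammar.txt",
            "ngrams": out / "ngrams.tsv",
            "lexicon": out / "lexicon.tsv",
        }
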
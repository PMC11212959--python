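"""Incremental sentence-reordering (SynReco) paradigm and its analyses.

A trial reveals a stimulus one word at a time; after each reveal the
participant may reorder the currently visible words, and each newly revealed
word is appended to the last submitted order.  Analyses consume only the
final submitted orders plus pass/fail bookkeeping: verbatim reconstruction
accuracy, reconstruction grammaticality (mean surprisal of final orders,
with the unreconstructed stimuli as a baseline), participant inclusion
filters, and rating-study quality control.

Duplicate words are distinguished internally by their reveal index, so
"permutation of the visible multiset" is well-defined.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

N_ATTENTION_CHECKS = 7
N_OTHER_FILLERS = 12
ATTENTION_PASS_MIN = 4
FILLER_PASS_MIN = 6


class TrialCompleteError(RuntimeError):
    pass


class IllegalOrderError(ValueError):
    pass


class NotCheckableError(LookupError):
    pass


class IncompleteTrialError(ValueError):
    pass


class MalformedLogError(ValueError):
    pass


@dataclass
class SynRecoTrial:
    """Evolving state of one trial.

    ``current_order`` holds reveal indices (0-based position in
    ``full_sequence``), so duplicates are unambiguous; ``current_words``
    gives the corresponding surfaces.
    """

    item_id: str
    condition: str
    full_sequence: list[str]
    n_revealed: int = 0
    current_order: list[int] = field(default_factory=list)
    submissions: list[tuple[int, list[int]]] = field(default_factory=list)
    allowed_orders: dict[int, set[tuple[str, ...]]] | None = None

    @property
    def current_words(self) -> list[str]:
        return [self.full_sequence[i] for i in self.current_order]

    @property
    def is_complete(self) -> bool:
        return self.n_revealed == len(self.full_sequence)

    def reveal_next(self) -> "SynRecoTrial":
        """Reveal the next word, appending it to the last submitted order."""
        if self.is_complete:
            raise TrialCompleteError(f"all words of {self.item_id!r} already revealed")
        self.current_order.append(self.n_revealed)
        self.n_revealed += 1
        return self

    def apply_reorder(self, new_words: Sequence[str]) -> "SynRecoTrial":
        """Submit a reordering of the visible words (given as surfaces).

        The submission must be a permutation of the visible multiset; it is
        recorded with step = number of revealed words.
        """
        if sorted(new_words) != sorted(self.current_words):
            raise IllegalOrderError(
                f"submitted order {list(new_words)} is not a permutation of "
                f"the visible words {self.current_words}"
            )
        # greedy left-to-right matching of surfaces to reveal indices keeps
        # duplicate words in their current relative order
        remaining = list(self.current_order)
        new_order = []
        for w in new_words:
            for idx in remaining:
                if self.full_sequence[idx] == w:
                    new_order.append(idx)
                    remaining.remove(idx)
                    break
        self.current_order = new_order
        self.submissions.append((self.n_revealed, list(new_order)))
        return self

    def check_order(self) -> bool:
        """Feedback check against the authored permissible-order sets
        (practice and filler items only)."""
        if self.allowed_orders is None or self.n_revealed not in self.allowed_orders:
            raise NotCheckableError(
                f"no permissible orders recorded for step {self.n_revealed}"
            )
        return tuple(self.current_words) in self.allowed_orders[self.n_revealed]

    @property
    def final_words(self) -> list[str]:
        if not self.is_complete:
            raise IncompleteTrialError(f"trial {self.item_id!r} is not complete")
        return self.current_words


def run_trial(
    stimulus_tokens: Sequence[str],
    item_id: str,
    condition: str,
    policy: Callable[[SynRecoTrial], Sequence[str] | None],
    allowed_orders: dict[int, set[tuple[str, ...]]] | None = None,
) -> SynRecoTrial:
    """Drive one trial to completion: reveal, then let ``policy`` propose a
    reorder (or None to leave the display untouched) until every word is
    revealed."""
    t = SynRecoTrial(
        item_id=item_id,
        condition=condition,
        full_sequence=list(stimulus_tokens),
        allowed_orders=allowed_orders,
    )
    while not t.is_complete:
        t.reveal_next()
        proposal = policy(t)
        if proposal is not None:
            t.apply_reorder(proposal)
        else:
            t.submissions.append((t.n_revealed, list(t.current_order)))
    return t


@dataclass
class ParticipantLog:
    """One participant's completed trials plus filler bookkeeping."""

    participant_id: str
    trials: list[SynRecoTrial] = field(default_factory=list)
    attention_results: list[bool] = field(default_factory=list)
    filler_results: list[bool] = field(default_factory=list)


def include_participant(
    p: ParticipantLog,
    attention_min: int = ATTENTION_PASS_MIN,
    filler_min: int = FILLER_PASS_MIN,
) -> bool:
    """Inclusion filter: at least 4 of 7 attention checks passed AND at
    least 6 of the 12 remaining fillers passed."""
    if len(p.attention_results) != N_ATTENTION_CHECKS or len(p.filler_results) != N_OTHER_FILLERS:
        raise MalformedLogError(
            f"expected {N_ATTENTION_CHECKS} attention and {N_OTHER_FILLERS} filler "
            f"results, got {len(p.attention_results)}/{len(p.filler_results)}"
        )
    return sum(p.attention_results) >= attention_min and sum(p.filler_results) >= filler_min


def verbatim_accuracy(
    trials: Iterable[SynRecoTrial], originals: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Per-condition rate of exact recovery of the original word order."""
    hits: dict[str, list[int]] = defaultdict(list)
    for t in trials:
        final = t.final_words  # raises on incomplete trials
        hits[t.condition].append(int(final == list(originals[t.item_id])))
    return {cond: sum(v) / len(v) for cond, v in hits.items()}


def reconstruction_grammaticality(
    trials: Iterable[SynRecoTrial], scorer
) -> dict[str, dict[str, float]]:
    """Per-condition mean surprisal of final submitted orders, alongside the
    stimulus baseline (the unreconstructed inputs) for the
    reconstruction-vs-stimulus comparison.

    ``scorer`` is any object with ``score(tokens, sentence_id) ->
    SurprisalResult`` (grammar-backed or external-file)."""
    recon: dict[str, list[float]] = defaultdict(list)
    base: dict[str, list[float]] = defaultdict(list)
    for t in trials:
        final = t.final_words
        recon[t.condition].append(scorer.score(final, t.item_id).mean)
        base[t.condition].append(scorer.score(t.full_sequence, t.item_id).mean)
    return {
        cond: {
            "reconstruction": sum(recon[cond]) / len(recon[cond]),
            "stimulus_baseline": sum(base[cond]) / len(base[cond]),
            "n_trials": len(recon[cond]),
        }
        for cond in recon
    }


# ---------------------------------------------------------------------------
# rating-study quality control


@dataclass
class RatingRecord:
    """Likert ratings (1-5) for grammaticality and semantic acceptability,
    one row per rated stimulus."""

    participant_id: str
    ratings: list[tuple[str, int, int]]  # (condition, grammaticality, semantic)

    def __post_init__(self):
        for cond, g, s in self.ratings:
            if g not in (1, 2, 3, 4, 5) or s not in (1, 2, 3, 4, 5):
                raise ValueError(f"ratings must be in 1..5 (got {g}, {s} for {cond})")


def include_rater(
    r: RatingRecord,
    sentence_condition: str = "Intact",
    wordlist_condition: str = "WordList",
) -> bool:
    """Rater QC: the full 1-5 scale was used at least once across the
    record, mean grammaticality of sentences >= 3, and mean grammaticality
    of word lists <= 3."""
    used = {g for _, g, _ in r.ratings} | {s for _, _, s in r.ratings}
    by_cond: dict[str, list[int]] = defaultdict(list)
    for cond, g, _ in r.ratings:
        by_cond[cond].append(g)
    for needed in (sentence_condition, wordlist_condition):
        if needed not in by_cond:
            raise MalformedLogError(f"rating record lacks condition {needed!r}")
    sent_mean = sum(by_cond[sentence_condition]) / len(by_cond[sentence_condition])
    wl_mean = sum(by_cond[wordlist_condition]) / len(by_cond[wordlist_condition])
    return used == {1, 2, 3, 4, 5} and sent_mean >= 3 and wl_mean <= 3


# ---------------------------------------------------------------------------
# JSON-lines event-log I/O (replayable)


def write_logs(logs: Iterable[ParticipantLog], path: str | Path) -> None:
    """Serialize participant logs as one event per line:
    {participant, item, condition, step, action, order}."""
    with open(path, "w") as fh:
        for log in logs:
            for t in log.trials:
                for step, order in t.submissions:
                    fh.write(
                        json.dumps(
                            {
                                "participant": log.participant_id,
                                "item": t.item_id,
                                "condition": t.condition,
                                "step": step,
                                "action": "submit",
                                "order": [t.full_sequence[i] for i in order],
                                "sequence": t.full_sequence,
                            }
                        )
                        + "\n"
                    )
            fh.write(
                json.dumps(
                    {
                        "participant": log.participant_id,
                        "action": "bookkeeping",
                        "attention": [bool(x) for x in log.attention_results],
                        "fillers": [bool(x) for x in log.filler_results],
                    }
                )
                + "\n"
            )


def read_logs(path: str | Path) -> list[ParticipantLog]:
    """Rebuild participant logs from the JSON-lines event stream (final
    submitted orders and bookkeeping; intermediate submissions retained)."""
    by_participant: dict[str, ParticipantLog] = {}
    trials: dict[tuple[str, str], SynRecoTrial] = {}
    with open(path) as fh:
        for line in fh:
            ev = json.loads(line)
            pid = ev["participant"]
            log = by_participant.setdefault(pid, ParticipantLog(participant_id=pid))
            if ev["action"] == "bookkeeping":
                log.attention_results = [bool(x) for x in ev["attention"]]
                log.filler_results = [bool(x) for x in ev["fillers"]]
                continue
            key = (pid, ev["item"])
            if key not in trials:
                t = SynRecoTrial(
                    item_id=ev["item"],
                    condition=ev["condition"],
                    full_sequence=list(ev["sequence"]),
                )
                trials[key] = t
                log.trials.append(t)
            t = trials[key]
            order_words = list(ev["order"])
            step = int(ev["step"])
            # replay: advance reveals to the event's step, then submit
            while t.n_revealed < step:
                t.reveal_next()
            t.apply_reorder(order_words)
    return list(by_participant.values())
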
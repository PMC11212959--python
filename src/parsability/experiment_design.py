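"""Counterbalanced list, run, block, trial-timeline and memory-probe
construction for the blocked reading experiments.

Layout of the full-scale imaging design: each list holds 48 stimuli per
condition; a list is divided into 8 runs of 48 stimuli (6 per condition);
each run contains 16 experimental blocks (2 per condition, 3 same-condition
trials each) plus 5 fixation blocks.  A trial presents 12 words at 350 ms
each, then a 300 ms blank, a 1000 ms memory probe, and a 500 ms blank
(6 s total; blocks 18 s; runs 16*18 + 5*12 = 348 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class LayoutError(ValueError):
    pass


class AssignmentError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Timing and layout parameters (durations in ms unless suffixed)."""

    words_per_trial: int = 12
    trials_per_block: int = 3
    blocks_per_condition_per_run: int = 2
    fixation_blocks_per_run: int = 5
    word_ms: int = 350
    isi_blank_ms: int = 300
    probe_ms: int = 1000
    end_blank_ms: int = 500
    fixation_block_s: float = 12.0

    def __post_init__(self):
        for name in ("word_ms", "isi_blank_ms", "probe_ms", "end_blank_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixation_block_s <= 0:
            raise ValueError("fixation_block_s must be positive")

    @property
    def trial_ms(self) -> int:
        return self.words_per_trial * self.word_ms + self.isi_blank_ms + self.probe_ms + self.end_blank_ms

    @property
    def block_s(self) -> float:
        return self.trials_per_block * self.trial_ms / 1000.0


def schedule_trial(spec: DesignSpec) -> list[dict]:
    """Within-trial event timeline (onset/duration in ms)."""
    events = []
    t = 0
    for w in range(spec.words_per_trial):
        events.append({"event": f"word_{w + 1}", "onset_ms": t, "duration_ms": spec.word_ms})
        t += spec.word_ms
    events.append({"event": "isi_blank", "onset_ms": t, "duration_ms": spec.isi_blank_ms})
    t += spec.isi_blank_ms
    events.append({"event": "probe", "onset_ms": t, "duration_ms": spec.probe_ms})
    t += spec.probe_ms
    events.append({"event": "end_blank", "onset_ms": t, "duration_ms": spec.end_blank_ms})
    return events


def build_latin_square_lists(
    item_ids: Sequence[str], conditions: Sequence[str], n_lists: int | None = None
) -> list[list[tuple[str, str]]]:
    """Latin-square list assignment: each list contains every item exactly
    once; across lists each item appears once per condition; within a list
    the condition counts are equal.

    ``n_lists`` defaults to (and must equal) the number of conditions being
    rotated; the item count must be divisible by it.
    """
    conditions = list(conditions)
    if n_lists is None:
        n_lists = len(conditions)
    if n_lists != len(conditions):
        raise LayoutError("n_lists must equal the number of rotated condition versions")
    if len(item_ids) % n_lists != 0:
        raise LayoutError(
            f"item count {len(item_ids)} not divisible by {n_lists} lists"
        )
    lists: list[list[tuple[str, str]]] = []
    for l in range(n_lists):
        assignment = [
            (item, conditions[(i + l) % len(conditions)])
            for i, item in enumerate(item_ids)
        ]
        lists.append(assignment)
    return lists


@dataclass
class Block:
    condition: str
    trials: list[str]  # stimulus ids
    onset_s: float = 0.0
    duration_s: float = 0.0
    kind: str = "experimental"  # or "fixation"


@dataclass
class RunSchedule:
    run_index: int
    blocks: list[Block] = field(default_factory=list)

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.blocks)

    def experimental_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.kind == "experimental"]


def _order_blocks(blocks: list[Block], rng: np.random.Generator, max_tries: int = 2000) -> list[Block]:
    """Seeded permutation with the two same-condition blocks non-adjacent."""
    for _ in range(max_tries):
        perm = [blocks[i] for i in rng.permutation(len(blocks))]
        if all(perm[i].condition != perm[i + 1].condition for i in range(len(perm) - 1)):
            return perm
    raise LayoutError("could not order blocks without adjacent same-condition pairs")


def build_runs(
    assigned: Sequence[tuple[str, str]],
    spec: DesignSpec,
    n_runs: int,
    rng: np.random.Generator | int | None = None,
) -> list[RunSchedule]:
    """Divide a list's stimuli into runs of blocked same-condition trials.

    Every stimulus is used exactly once.  Each run receives an equal share
    of each condition, grouped into blocks of ``trials_per_block`` trials,
    ordered by a seeded permutation with same-condition blocks non-adjacent,
    and interleaved with fixation blocks (one at run start, then one after
    every 4 experimental blocks).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    by_cond: dict[str, list[str]] = {}
    for stim, cond in assigned:
        by_cond.setdefault(cond, []).append(stim)
    per_run: dict[str, int] = {}
    for cond, stims in by_cond.items():
        if len(stims) % n_runs != 0:
            raise LayoutError(f"{len(stims)} {cond!r} stimuli not divisible by {n_runs} runs")
        per_run[cond] = len(stims) // n_runs
        if per_run[cond] % spec.trials_per_block != 0:
            raise LayoutError(
                f"{per_run[cond]} {cond!r} stimuli per run not divisible by "
                f"block size {spec.trials_per_block}"
            )
    runs = []
    for r in range(n_runs):
        blocks: list[Block] = []
        for cond, stims in by_cond.items():
            share = stims[r * per_run[cond] : (r + 1) * per_run[cond]]
            for b in range(0, len(share), spec.trials_per_block):
                blocks.append(Block(condition=cond, trials=share[b : b + spec.trials_per_block]))
        blocks = _order_blocks(blocks, gen)
        # interleave fixation: run start, then after every 4 experimental blocks
        final: list[Block] = [Block(condition="fixation", trials=[], kind="fixation")]
        for i, blk in enumerate(blocks, start=1):
            final.append(blk)
            if i % 4 == 0:
                final.append(Block(condition="fixation", trials=[], kind="fixation"))
        t = 0.0
        for blk in final:
            blk.onset_s = t
            blk.duration_s = spec.fixation_block_s if blk.kind == "fixation" else spec.block_s
            t += blk.duration_s
        runs.append(RunSchedule(run_index=r, blocks=final))
    return runs


def assign_probes(
    run: RunSchedule,
    final_tokens: dict[str, str],
    rng: np.random.Generator | int | None = None,
) -> dict[str, tuple[str, bool]]:
    """Memory-probe assignment for one run: per condition, exactly half the
    trials get a matching probe (the stimulus's last token); each remaining
    trial gets the final token of a same-condition stimulus from a
    *different* block of the same run.

    Returns stimulus id -> (probe token, is_match).
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    by_cond: dict[str, list[tuple[str, int]]] = {}
    for bi, block in enumerate(run.experimental_blocks()):
        for stim in block.trials:
            by_cond.setdefault(block.condition, []).append((stim, bi))
    out: dict[str, tuple[str, bool]] = {}
    for cond, trials in by_cond.items():
        n = len(trials)
        if n % 2 != 0:
            raise AssignmentError(f"odd trial count ({n}) for condition {cond!r}")
        if len({bi for _, bi in trials}) < 2:
            raise AssignmentError(f"condition {cond!r} occupies a single block")
        match_idx = set(gen.choice(n, size=n // 2, replace=False))
        for i, (stim, bi) in enumerate(trials):
            if i in match_idx:
                out[stim] = (final_tokens[stim], True)
            else:
                donors = [s for s, bj in trials if bj != bi and s != stim]
                donor = donors[int(gen.integers(len(donors)))]
                out[stim] = (final_tokens[donor], False)
    return out


def runs_to_events_tsv(
    runs: Sequence[RunSchedule],
    spec: DesignSpec,
    out_dir: str | Path,
    probes: Sequence[dict[str, tuple[str, bool]]] | None = None,
) -> list[Path]:
    """Write one BIDS-style events table per run (onset, duration,
    trial_type, stimulus, probe, probe_match)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, run in enumerate(runs):
        rows = []
        probe_map = probes[i] if probes is not None else {}
        for block in run.blocks:
            if block.kind == "fixation":
                rows.append(
                    {
                        "onset": block.onset_s,
                        "duration": block.duration_s,
                        "trial_type": "fixation",
                        "stimulus": "",
                        "probe": "",
                        "probe_match": "",
                    }
                )
                continue
            for k, stim in enumerate(block.trials):
                probe, match = probe_map.get(stim, ("", ""))
                rows.append(
                    {
                        "onset": block.onset_s + k * spec.trial_ms / 1000.0,
                        "duration": spec.trial_ms / 1000.0,
                        "trial_type": block.condition,
                        "stimulus": stim,
                        "probe": probe,
                        "probe_match": match,
                    }
                )
        path = out_dir / f"run-{i + 1:02d}_events.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
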
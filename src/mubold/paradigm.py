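"""Block/trial paradigm generation for the motor execution / imagery task.

Each task block lasts 22 s: a 2 s text instruction followed by four 3 s
trials, each trailed by a 2 s inter-trial interval.  Task blocks alternate
with 16 s rest blocks.  Within a run the block sequence is randomized and
balanced across the four task conditions, under the constraint that the
i-th execution (ME) block of a hand precedes the i-th imagery (MI) block
of the same hand.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    INSTRUCTION_S,
    ITI_S,
    REST,
    REST_BLOCK_S,
    TASK_BLOCK_S,
    TASK_CONDITIONS,
    TRIALS_PER_BLOCK,
    TRIAL_S,
    Interval,
    Paradigm,
    Run,
)


def _condition_sequence(blocks_per_condition: int, rng: np.random.Generator) -> list[str]:
    """Randomized balanced sequence with ME-before-MI pairing per hand.

    Random position keys are drawn for every block; within each hand the
    sorted positions are filled alternately ME, MI, ME, MI, ..., which
    guarantees the i-th ME block of that hand precedes its i-th MI block.
    """
    n = 4 * blocks_per_condition
    seq: list[str | None] = [None] * n
    # split the n slots into two random halves, one per hand
    all_slots = list(rng.permutation(n))
    slots = {
        "LH": sorted(all_slots[: 2 * blocks_per_condition]),
        "RH": sorted(all_slots[2 * blocks_per_condition:]),
    }
    for hand, hand_slots in slots.items():
        for i, s in enumerate(hand_slots):
            seq[s] = ("ME_" if i % 2 == 0 else "MI_") + hand
    assert all(c is not None for c in seq)
    return seq  # type: ignore[return-value]


def _build_task_block(condition: str, onset: float) -> tuple[Interval, Interval, list[Interval]]:
    block = Interval(onset, TASK_BLOCK_S, condition)
    instruction = Interval(onset, INSTRUCTION_S, condition)
    trials = []
    t = onset + INSTRUCTION_S
    for _ in range(TRIALS_PER_BLOCK):
        trials.append(Interval(t, TRIAL_S, condition))
        t += TRIAL_S + ITI_S
    return block, instruction, trials


def generate_paradigm(
    n_runs: int,
    blocks_per_condition: int,
    seed: int,
    tr_s: float = 2.0,
    min_run_length_s: float | None = None,
) -> Paradigm:
    """Generate a randomized, balanced block/trial paradigm.

    Parameters
    ----------
    n_runs, blocks_per_condition
        Number of runs and, per run, how often each of the four task
        conditions occurs.  Must be >= 1.
    seed
        Seed for the block-order randomization.
    tr_s
        fMRI repetition time; the run length is padded with trailing rest
        to an integer multiple of it.
    min_run_length_s
        If given, trailing rest additionally pads every run to at least
        this length (useful to hit a fixed volume count).
    """
    if n_runs < 1 or blocks_per_condition < 1:
        raise ValueError("n_runs and blocks_per_condition must be >= 1")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        seq = _condition_sequence(blocks_per_condition, rng)
        blocks: list[Interval] = []
        trials: list[Interval] = []
        instructions: list[Interval] = []
        t = 0.0
        for cond in seq:
            block, instr, blk_trials = _build_task_block(cond, t)
            blocks.append(block)
            instructions.append(instr)
            trials.extend(blk_trials)
            t += TASK_BLOCK_S
            blocks.append(Interval(t, REST_BLOCK_S, REST))
            t += REST_BLOCK_S
        length = t
        if min_run_length_s is not None:
            length = max(length, float(min_run_length_s))
        length = math.ceil(length / tr_s) * tr_s
        if length > t:
            # extend the trailing rest block rather than appending a new one
            last = blocks[-1]
            blocks[-1] = Interval(last.onset, last.duration + (length - t), REST)
        runs.append(Run(blocks, trials, instructions, run_length_s=length))
    return Paradigm(runs=runs, tr_s=tr_s)


def check_paradigm(p: Paradigm) -> None:
    """Raise AssertionError if structural invariants are violated."""
    for run in p.runs:
        t = 0.0
        for b in run.blocks:
            assert abs(b.onset - t) < 1e-9, "blocks must tile the run"
            t = b.end
            if b.label != REST:
                assert abs(b.duration - TASK_BLOCK_S) < 1e-9
        assert abs(t - run.run_length_s) < 1e-9
        n = run.run_length_s / p.tr_s
        assert abs(n - round(n)) < 1e-9, "run length must be a TR multiple"
        for tr in run.trials:
            host = [b for b in run.blocks if b.onset <= tr.onset and tr.end <= b.end + 1e-9]
            assert host and host[0].label == tr.label, "trials must lie inside their block"


def events_frame(p: Paradigm, run: int = 0) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type) for one run.

    Rows: one per rest block (trial_type REST), one per instruction
    (instr_<cond>) and one per trial (<cond>), in chronological order.
    """
    rows = []
    r = p.runs[run]
    for b in r.blocks:
        if b.label == REST:
            rows.append((b.onset, b.duration, REST))
    for i in r.instructions:
        rows.append((i.onset, i.duration, f"instr_{i.label}"))
    for t in r.trials:
        rows.append((t.onset, t.duration, t.label))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def paradigm_from_events(
    events: pd.DataFrame, tr_s: float = 2.0, run_length_s: float | None = None
) -> Paradigm:
    """Rebuild a single-run Paradigm from an events table written by
    :func:`events_frame` (real-data mode entry point)."""
    trials, instructions, blocks = [], [], []
    for _, row in events.iterrows():
        iv = Interval(float(row.onset), float(row.duration), str(row.trial_type))
        if iv.label == REST:
            blocks.append(iv)
        elif iv.label.startswith("instr_"):
            cond = iv.label[len("instr_"):]
            instructions.append(Interval(iv.onset, iv.duration, cond))
            blocks.append(Interval(iv.onset, TASK_BLOCK_S, cond))
        elif iv.label in TASK_CONDITIONS:
            trials.append(iv)
    blocks.sort(key=lambda b: b.onset)
    end = max(b.end for b in blocks)
    length = run_length_s if run_length_s is not None else math.ceil(end / tr_s) * tr_s
    run = Run(blocks, sorted(trials, key=lambda t: t.onset),
              sorted(instructions, key=lambda t: t.onset), run_length_s=float(length))
    return Paradigm(runs=[run], tr_s=tr_s)
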
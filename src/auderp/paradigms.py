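"""Stimulus schedule builders for the two auditory paradigms.

The own-name (SON) paradigm presents the subject's own first name among
six other unfamiliar first names, all equiprobable (1/7 each), in 12
sequences of 42 names.  The semantic/lexical priming (SLP) paradigm
presents 320 word pairs — 80 semantically related (RW), 80 unrelated
(UW) and 160 word–pseudoword (PW) — in one pseudo-random block with no
more than three successive pairs of the same category.

Word tokens are represented by integer ids only; the acoustic/lexical
content of the stimuli is irrelevant to the signal chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EventSchedule


@dataclass
class SonParams:
    """Design constants of the own-name oddball sequence."""

    n_sequences: int = 12
    names_per_sequence: int = 7      # 1 SON + 6 OFN
    reps_per_name: int = 6
    isi_range_ms: tuple[int, int] = (400, 500)
    inter_sequence_gap_s: float = 4.0
    n_voices: int = 3
    stimulus_duration_ms: int = 1000

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.names_per_sequence < 1 or self.reps_per_name < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.isi_range_ms
        if lo > hi or lo < 0:
            raise ValueError("isi_range_ms must satisfy 0 <= lo <= hi")
        if self.n_voices < 1:
            raise ValueError("need at least one voice")

    @property
    def events_per_sequence(self) -> int:
        return self.names_per_sequence * self.reps_per_name


@dataclass
class SlpParams:
    """Design constants of the priming block."""

    n_rw_pairs: int = 80
    n_uw_pairs: int = 80
    n_pw_pairs: int = 160
    within_pair_isi_ms: int = 400
    between_pair_isi_ms: tuple[int, int, int] = (1500, 2000, 100)  # lo, hi, step
    max_category_run: int = 3
    mid_block_pause_s: float = 60.0
    word_duration_ms: int = 600

    def __post_init__(self) -> None:
        if min(self.n_rw_pairs, self.n_uw_pairs, self.n_pw_pairs) < 0:
            raise ValueError("pair counts must be nonnegative")
        if self.max_category_run < 1:
            raise ValueError("max_category_run must be >= 1")

    @property
    def n_pairs(self) -> int:
        return self.n_rw_pairs + self.n_uw_pairs + self.n_pw_pairs


def _shuffle_no_immediate_repeat(items: np.ndarray, rng: np.random.Generator,
                                 max_tries: int = 10_000) -> np.ndarray:
    """Uniform shuffle rejected until no two equal items are adjacent."""
    for _ in range(max_tries):
        perm = rng.permutation(items)
        if perm.size < 2 or not np.any(perm[1:] == perm[:-1]):
            return perm
    raise RuntimeError("could not satisfy the no-immediate-repeat constraint")


def build_son_schedule(params: SonParams | None = None, seed: int = 0) -> EventSchedule:
    """Build the own-name oddball schedule.

    Within each sequence every one of the 7 names occurs exactly
    ``reps_per_name`` times in shuffled order (no immediate repetition of
    the same name).  Consecutive onsets are separated by the stimulus
    duration plus an ISI drawn uniformly in 1 ms steps from
    ``isi_range_ms`` (offset-to-onset); sequences are separated by
    ``inter_sequence_gap_s`` and each is spoken by one of ``n_voices``
    voices drawn uniformly.  Name id 0 is the subject's own name.
    """
    p = params or SonParams()
    rng = np.random.default_rng(seed)
    stim_s = p.stimulus_duration_ms / 1000.0
    lo, hi = p.isi_range_ms

    onsets: list[float] = []
    labels: list[str] = []
    blocks: list[int] = []
    name_ids: list[int] = []
    voices: list[int] = []

    t = 0.0
    base = np.repeat(np.arange(p.names_per_sequence), p.reps_per_name)
    for block in range(p.n_sequences):
        order = _shuffle_no_immediate_repeat(base, rng)
        voice = int(rng.integers(p.n_voices))
        for k, name in enumerate(order):
            onsets.append(t)
            labels.append("SON" if name == 0 else "OFN")
            blocks.append(block)
            name_ids.append(int(name))
            voices.append(voice)
            isi_ms = int(rng.integers(lo, hi + 1))
            t += stim_s + isi_ms / 1000.0
        # replace the trailing within-sequence ISI by the inter-sequence gap
        t = onsets[-1] + stim_s + p.inter_sequence_gap_s

    return EventSchedule(np.array(onsets), labels, np.array(blocks),
                         {"name_id": np.array(name_ids), "voice": np.array(voices),
                          "paradigm": "SON"})


def _pair_order(p: SlpParams, rng: np.random.Generator,
                max_tries: int = 10_000) -> np.ndarray:
    """Pseudo-random pair category order with bounded same-category runs.

    Sequential constrained sampling: at each position a category is
    drawn with probability proportional to its remaining count, skipping
    any category already repeated ``max_category_run`` times; dead ends
    (only the forbidden category remains) trigger a restart.  With half
    the pairs in one category, plain shuffle-and-reject essentially
    never satisfies the constraint, whereas this construction succeeds
    in a handful of restarts.
    """
    counts0 = np.array([p.n_rw_pairs, p.n_uw_pairs, p.n_pw_pairs])
    n = int(counts0.sum())
    if n == 0:
        return np.empty(0, dtype=int)
    if np.max(counts0) > (n - np.max(counts0) + 1) * p.max_category_run:
        raise RuntimeError("pair counts incompatible with max_category_run")
    for _ in range(max_tries):
        counts = counts0.astype(float).copy()
        out = np.empty(n, dtype=int)
        run_cat, run_len = -1, 0
        for i in range(n):
            w = counts.copy()
            if run_len >= p.max_category_run:
                w[run_cat] = 0.0
            total = w.sum()
            if total <= 0:
                break
            cat = int(rng.choice(3, p=w / total))
            out[i] = cat
            counts[cat] -= 1
            run_len = run_len + 1 if cat == run_cat else 1
            run_cat = cat
        else:
            return out
    raise RuntimeError("could not satisfy max_category_run constraint")


_CAT_NAMES = ("RW", "UW", "PW")


def build_slp_schedule(params: SlpParams | None = None, seed: int = 0) -> EventSchedule:
    """Build the priming schedule: 320 pairs = 640 word events in one block.

    Each pair contributes a prime (position 1) and a target (position 2)
    with a fixed 400 ms offset-to-onset ISI.  The inter-pair ISI is drawn
    uniformly from {1500, 1600, ..., 2000} ms and a pause is inserted
    after half the pairs.  Labels are category plus word position, e.g.
    "RW1", "RW2".
    """
    p = params or SlpParams()
    rng = np.random.default_rng(seed)
    order = _pair_order(p, rng)
    word_s = p.word_duration_ms / 1000.0
    within_s = p.within_pair_isi_ms / 1000.0
    lo, hi, step = p.between_pair_isi_ms
    isi_choices = np.arange(lo, hi + 1, step) / 1000.0
    half = order.size // 2

    onsets: list[float] = []
    labels: list[str] = []
    pair_ids: list[int] = []

    t = 0.0
    for k, cat in enumerate(order):
        name = _CAT_NAMES[cat]
        onsets.extend([t, t + word_s + within_s])
        labels.extend([name + "1", name + "2"])
        pair_ids.extend([k, k])
        t = onsets[-1] + word_s + float(rng.choice(isi_choices))
        if half and k + 1 == half:
            t += p.mid_block_pause_s

    return EventSchedule(np.array(onsets), labels,
                         np.zeros(len(onsets), dtype=int),
                         {"pair_id": np.array(pair_ids), "paradigm": "SLP"})
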
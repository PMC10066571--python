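#!/usr/bin/env python
"""Build the two stimulus schedules and check their design numbers.

Writes the schedules as JSON under results/paradigms/ and prints the
design summary: event counts, per-name probability, pair-category
counts, run-length statistics and timing.
"""

import collections
from pathlib import Path

import numpy as np

from auderp import build_slp_schedule, build_son_schedule, schedule_to_json

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "paradigms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    son = build_son_schedule(seed=SEED)
    schedule_to_json(son, OUT / "son_schedule.json")
    per_name = collections.Counter(son.metadata["name_id"].tolist())
    seq0 = son.onsets[son.block_index == 0]
    print("== own-name (SON) paradigm ==")
    print(f"events: {len(son)} in {son.block_index.max() + 1} sequences "
          f"of {np.sum(son.block_index == 0)}")
    print(f"own-name events: {son.labels.count('SON')} "
          f"({100 * son.labels.count('SON') / len(son):.2f} % = 1/7 per name)")
    print(f"all name counts equal: {len(set(per_name.values())) == 1}")
    print(f"first sequence spans {seq0[-1] - seq0[0] + 1.0:.1f} s (~60 s by design)")
    print(f"total duration: {son.onsets[-1] / 60:.1f} min")

    slp = build_slp_schedule(seed=SEED)
    schedule_to_json(slp, OUT / "slp_schedule.json")
    pairs = [lb[:2] for lb in slp.labels[::2]]
    counts = collections.Counter(pairs)
    run, longest = 1, 1
    for a, b in zip(pairs, pairs[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    print("\n== semantic/lexical priming (SLP) paradigm ==")
    print(f"word events: {len(slp)} ({len(pairs)} pairs: "
          f"{counts['RW']} RW / {counts['UW']} UW / {counts['PW']} PW)")
    print(f"longest same-category run: {longest} (constraint: <= 3)")
    print(f"total duration: {slp.onsets[-1] / 60:.1f} min (incl. 60 s pause)")
    print(f"\nschedules written to {OUT}")


if __name__ == "__main__":
    main()
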
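#!/usr/bin/env python
"""Simulate one control subject and export the recording.

Generates a desk-scale own-name session (32 channels, 4 sequences) for a
control-profile subject, prints basic signal statistics, and writes the
continuous recording as EDF plus the schedule JSON under
results/example_subject/.
"""

from pathlib import Path

import numpy as np

from auderp import (build_son_schedule, export_edf, fibonacci_montage,
                    schedule_to_json, simulate_subject)
from auderp.paradigms import SonParams
from auderp.simulate import default_profiles

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results" / "example_subject"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = fibonacci_montage(32)
    schedule = build_son_schedule(SonParams(n_sequences=4), seed=SEED)
    profile = default_profiles()["CONTROL"]
    rec = simulate_subject(profile, schedule, layout, srate=500.0, seed=SEED)

    print(f"simulated {rec.data.shape[0]} channels x {rec.data.shape[1]} samples "
          f"({rec.duration / 60:.1f} min at {rec.srate:.0f} Hz)")
    print(f"events: {len(rec.events)} "
          f"({rec.events.labels.count('SON')} own-name targets)")
    print(f"signal SD: {rec.data.std():.1f} uV "
          f"(background 10 uV + line + blinks + ERPs)")

    export_edf(rec, OUT / "control_son.edf")
    schedule_to_json(schedule, OUT / "control_son_events.json")
    size_kb = (OUT / "control_son.edf").stat().st_size / 1024
    print(f"wrote EDF ({size_kb:.0f} KiB) and schedule JSON to {OUT}")


if __name__ == "__main__":
    main()
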
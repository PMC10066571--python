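#!/usr/bin/env python
"""Calibration and power of the cluster permutation test on synthetic cohorts.

Two experiments at the statistics scale (32 channels, full trial and
subject counts, subject-level ERP generator):

1. type-I error — 200 noise-only cohorts (n = 14): fraction with any
   cluster p <= 0.05 should sit at or just below 0.05;
2. effect-pattern recovery — 50 replicate cohorts per group: controls
   show the own-name effect, the no-delirium group the lexical but not
   the semantic priming effect, the delirium group nothing.

Writes results/statistics_validation.json.
"""

import json
from pathlib import Path

from auderp.study import group_pattern_rates, type_one_error_rate

SEED = 2024
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    t1 = type_one_error_rate(n_cohorts=200, n_subjects=14, n_channels=32,
                             n_permutations=1000, alpha=0.05, seed=SEED)
    print(f"type-I error over {t1['n_cohorts']} noise-only cohorts: "
          f"{100 * t1['rate']:.1f} % (nominal 5 %)")

    rates = group_pattern_rates(n_replicates=50, n_channels=32,
                                n_permutations=1000, alpha=0.05, seed=SEED)
    print(f"\nover {rates['n_replicates']} replicate cohorts per group:")
    print(f"  CONTROL  own-name effect detected: {100 * rates['control_son']:.0f} % "
          f"(centro-parietal in {100 * rates['control_son_centroparietal']:.0f} %)")
    print(f"  DEL-     lexical effect: {100 * rates['delminus_lexical']:.0f} %, "
          f"semantic effect: {100 * rates['delminus_semantic']:.0f} %, "
          f"lexical-without-semantic: {100 * rates['delminus_lexical_only']:.0f} %")
    print(f"  DEL+     no significant cluster in any contrast: "
          f"{100 * rates['delplus_clean']:.0f} %")
    print("\n(the DEL+ clean rate is bounded near ~87 % in expectation: three "
          "exactly calibrated 5 %-level tests are run per cohort)")

    doc = {"type_one_error": t1, "pattern_rates": rates}
    (OUT / "statistics_validation.json").write_text(json.dumps(doc, indent=1))
    print(f"\nwritten to {OUT / 'statistics_validation.json'}")


if __name__ == "__main__":
    main()
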
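"""Study-level replication helpers.

Bundles the design constants of the two paradigms (trial counts per
condition), the three group profiles, and replicate-level experiments —
simulate a cohort's condition-average ERPs, run the within-group
contrasts, repeat — used to validate type-I error control and the
qualitative three-group result pattern on synthetic data.

Statistics-scale runs use the reduced subject-level generator
(:func:`auderp.simulate.simulate_condition_erp`, exact in distribution
for the additive model) and a 32-channel montage; trial counts and
subject counts stay at the full study design.
"""

from __future__ import annotations

import numpy as np

from .cluster import AdjacencyGraph, ClusterResult, build_adjacency, permutation_test
from .containers import Erp
from .layout import SensorLayout, fibonacci_montage
from .simulate import GroupProfile, default_profiles, simulate_condition_erp, DEFAULT_GROUP_SIZES

#: targets per condition implied by the paradigm designs: the own-name
#: sequence presents each of 7 names 72 times (12 x 42 events, 1 SON +
#: 6 OFN names); the priming block has 80 RW, 80 UW and 160 PW target words.
DESIGN_TRIALS = {"SON": 72, "OFN": 432, "RW2": 80, "UW2": 80, "PW2": 160}

#: the contrasts the study tests per group (A minus B, one-sided A > B)
PRIMARY_CONTRASTS = (("SON-OFN", "SON", "OFN"),
                     ("RW-UW", "RW2", "UW2"),
                     ("RW-PW", "RW2", "PW2"))


def suggested_max_arc(layout: SensorLayout, z_min: float = -0.35,
                      factor: float = 1.3) -> float:
    """Adjacency arc scaled to the montage density.

    The quasi-uniform cap montage has nearest-neighbour spacing of about
    sqrt(cap solid angle / n * 2/sqrt(3)); ``factor`` times that links
    first neighbours only.  For the 128-channel montage this lands at
    the 0.35 rad default.
    """
    cap = 2 * np.pi * (1.0 - z_min)
    spacing = np.sqrt(cap / layout.n_channels * 2 / np.sqrt(3))
    return factor * spacing


def cohort_condition_erps(profile: GroupProfile, layout: SensorLayout,
                          n_subjects: int, conditions: dict[str, int],
                          rng: np.random.Generator,
                          srate: float = 500.0) -> list[dict[str, Erp]]:
    """Per-subject condition-average ERPs drawn from the reduced generator."""
    out = []
    for s in range(n_subjects):
        subject = f"{profile.group.lower()}-{s:02d}"
        erps: dict[str, Erp] = {}
        for cond, n_trials in conditions.items():
            data = simulate_condition_erp(profile, layout, cond, n_trials,
                                          srate=srate, rng=rng)
            erps[cond] = Erp(data, -0.2, srate, n_trials, cond, layout,
                             subject_id=subject,
                             provenance={"group": profile.group,
                                         "generator": "reduced"})
        out.append(erps)
    return out


def run_replicate(profile: GroupProfile, layout: SensorLayout,
                  adjacency: AdjacencyGraph, contrasts,
                  n_subjects: int, rng: np.random.Generator,
                  n_permutations: int = 1000, threshold_p: float = 0.05,
                  srate: float = 500.0) -> dict[str, ClusterResult]:
    """Simulate one cohort and run the requested contrasts on it."""
    needed = sorted({c for _, a, b in contrasts for c in (a, b)})
    conditions = {c: DESIGN_TRIALS[c] for c in needed}
    subjects = cohort_condition_erps(profile, layout, n_subjects, conditions,
                                     rng, srate)
    results = {}
    for name, cond_a, cond_b in contrasts:
        erps_a = [s[cond_a] for s in subjects]
        erps_b = [s[cond_b] for s in subjects]
        results[name] = permutation_test(
            erps_a, erps_b, n_permutations=n_permutations,
            threshold_p=threshold_p,
            seed=int(rng.integers(2 ** 31)), adjacency=adjacency)
    return results


def _stats_layout(n_channels: int = 32) -> tuple[SensorLayout, AdjacencyGraph]:
    layout = fibonacci_montage(n_channels)
    adjacency = build_adjacency(layout, suggested_max_arc(layout))
    return layout, adjacency


def type_one_error_rate(n_cohorts: int = 200, n_subjects: int = 14,
                        n_channels: int = 32, n_permutations: int = 1000,
                        alpha: float = 0.05, seed: int = 0,
                        srate: float = 500.0) -> dict:
    """Fraction of noise-only cohorts with any cluster p <= alpha.

    Uses the own-name design's trial counts but a component-free profile,
    so every positive is false.  With family-wise error controlled by the
    max-statistic null, the rate should sit at or just below ``alpha``.
    """
    layout, adjacency = _stats_layout(n_channels)
    null_profile = GroupProfile("NULL", [], default_profiles()["CONTROL"].noise)
    rng = np.random.default_rng(seed)
    contrasts = (("SON-OFN", "SON", "OFN"),)
    hits = 0
    for _ in range(n_cohorts):
        res = run_replicate(null_profile, layout, adjacency, contrasts,
                            n_subjects, rng, n_permutations, srate=srate)
        if res["SON-OFN"].min_p <= alpha:
            hits += 1
    return {"rate": hits / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha, "n_subjects": n_subjects,
            "n_channels": n_channels}


def group_pattern_rates(n_replicates: int = 50, n_channels: int = 32,
                        n_permutations: int = 1000, alpha: float = 0.05,
                        seed: int = 0, srate: float = 500.0,
                        group_sizes: dict[str, int] | None = None) -> dict:
    """Replicate-level rates of the three-group effect pattern.

    For each replicate cohort: controls should show a significant
    own-name (SON vs OFN) cluster; the no-delirium group should show the
    lexical (RW vs PW) but not the semantic (RW vs UW) effect; the
    delirium group should show no significant cluster in any of the
    three tested contrasts.  For the control own-name effect the
    centro-parietal concentration of the cluster is also checked (the
    significant cluster's channels lie nearer the centro-parietal focus
    than the average channel).
    """
    sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    layout, adjacency = _stats_layout(n_channels)
    profiles = default_profiles()
    rng = np.random.default_rng(seed)
    arc_cp = layout.arc_to("centro-parietal")

    counts = {"control_son": 0, "control_son_centroparietal": 0,
              "delminus_lexical": 0, "delminus_semantic": 0,
              "delminus_lexical_only": 0, "delplus_any": 0}
    for _ in range(n_replicates):
        res = run_replicate(profiles["CONTROL"], layout, adjacency,
                            (("SON-OFN", "SON", "OFN"),), sizes["CONTROL"],
                            rng, n_permutations, srate=srate)["SON-OFN"]
        sig = res.significant(alpha)
        if sig:
            counts["control_son"] += 1
            best = sig[0]
            scalp_idx = np.array([layout.index(n) for n in res.channel_names])
            member = scalp_idx[best.channel_set]
            if arc_cp[member].mean() < arc_cp[scalp_idx].mean():
                counts["control_son_centroparietal"] += 1

        res = run_replicate(profiles["DEL_MINUS"], layout, adjacency,
                            (("RW-UW", "RW2", "UW2"), ("RW-PW", "RW2", "PW2")),
                            sizes["DEL_MINUS"], rng, n_permutations, srate=srate)
        lex = res["RW-PW"].min_p <= alpha
        sem = res["RW-UW"].min_p <= alpha
        counts["delminus_lexical"] += lex
        counts["delminus_semantic"] += sem
        counts["delminus_lexical_only"] += lex and not sem

        res = run_replicate(profiles["DEL_PLUS"], layout, adjacency,
                            PRIMARY_CONTRASTS, sizes["DEL_PLUS"], rng,
                            n_permutations, srate=srate)
        if any(r.min_p <= alpha for r in res.values()):
            counts["delplus_any"] += 1

    rates = {k: v / n_replicates for k, v in counts.items()}
    rates["delplus_clean"] = 1.0 - rates.pop("delplus_any")
    rates["n_replicates"] = n_replicates
    return rates
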
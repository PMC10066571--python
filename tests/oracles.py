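"""Independent brute-force oracles used only by the tests.

Everything here is written against the mathematical definitions, not the
package's implementation: connected components by breadth-first search
over the explicit sample-level graph, paired t via scipy, exhaustive
sign-flip enumeration by direct looping.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bfs_clusters(t_map: np.ndarray, threshold_t: float,
                 neighbor_lists: list[np.ndarray]) -> list[dict]:
    """Flood-fill clusters of supra-threshold (channel, time) samples.

    Edges: consecutive time samples on the same channel; same time
    sample on spatially adjacent channels.
    """
    n_ch, n_t = t_map.shape
    supra = t_map > threshold_t
    seen = np.zeros_like(supra, dtype=bool)
    clusters = []
    for c0 in range(n_ch):
        for s0 in range(n_t):
            if not supra[c0, s0] or seen[c0, s0]:
                continue
            members = []
            queue = [(c0, s0)]
            seen[c0, s0] = True
            while queue:
                c, s = queue.pop()
                members.append((c, s))
                for cc, ss in [(c, s - 1), (c, s + 1)]:
                    if 0 <= ss < n_t and supra[c, ss] and not seen[c, ss]:
                        seen[c, ss] = True
                        queue.append((cc, ss))
                for cc in neighbor_lists[c]:
                    if supra[cc, s] and not seen[cc, s]:
                        seen[cc, s] = True
                        queue.append((cc, s))
            mass = float(sum(t_map[c, s] for c, s in members))
            clusters.append({"members": frozenset(members), "mass": mass})
    clusters.sort(key=lambda d: -d["mass"])
    return clusters


def scipy_paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0 via scipy, zero-variance entries set to 0."""
    t = stats.ttest_1samp(diffs, 0.0, axis=0).statistic
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def exhaustive_cluster_p(diffs: np.ndarray, threshold_p: float,
                         neighbor_lists: list[np.ndarray]) -> list[dict]:
    """Exact sign-flip permutation p for every observed cluster.

    Enumerates all 2^n sign patterns (identity included), recomputes the
    t map and the maximum cluster mass for each, and reports
    p = #{max mass >= observed mass} / 2^n.
    """
    n = diffs.shape[0]
    threshold_t = float(stats.t.ppf(1 - threshold_p, n - 1))
    observed = bfs_clusters(scipy_paired_t(diffs), threshold_t, neighbor_lists)
    null = np.empty(2 ** n)
    for k in range(2 ** n):
        signs = np.array([1.0 if (k >> b) & 1 == 0 else -1.0 for b in range(n)])
        t = scipy_paired_t(signs[:, None, None] * diffs)
        cl = bfs_clusters(t, threshold_t, neighbor_lists)
        null[k] = cl[0]["mass"] if cl else 0.0
    for c in observed:
        c["p"] = float(np.sum(null >= c["mass"])) / 2 ** n
    return observed
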
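"""Spatio-temporal cluster permutation statistics, from scratch.

The paired, one-sided design: per (channel, time) sample a paired t
statistic is computed on subject condition differences; samples above
the cluster-forming threshold are joined into clusters along
consecutive time samples (same channel) and spatially adjacent channels
(same time sample); each cluster's mass is its summed t.  The null is
built by randomly sign-flipping every subject's difference wave (the
exchangeability argument for within-subject designs) and recording the
maximum cluster mass per permutation — the max-statistic correction
controlling family-wise error over space x time.

Cluster formation uses a run-merging union-find: supra-threshold
samples are first collapsed into per-channel temporal runs, and runs on
adjacent channels with overlapping time intervals are merged.  This is
equivalent to connected components on the sample-level graph and is
what makes thousand-permutation nulls cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import Erp
from .layout import SensorLayout

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyGraph:
    """Symmetric channel neighbourhood from a great-circle distance rule."""

    n_channels: int
    neighbors: list[np.ndarray]
    max_arc: float

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("self-loops are not allowed")

    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of i < j adjacent channel pairs."""
        out = [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if j > i]
        return np.array(out, dtype=int).reshape(-1, 2)

    @property
    def mean_degree(self) -> float:
        return float(np.mean([len(nb) for nb in self.neighbors]))


def build_adjacency(layout: SensorLayout, max_arc: float = 0.35,
                    channel_names: list[str] | None = None) -> AdjacencyGraph:
    """Channels are adjacent iff their great-circle arc is below ``max_arc``.

    ``channel_names`` restricts the graph (e.g. scalp channels only);
    indices in the result refer to that subset, in the given order.
    """
    if channel_names is None:
        channel_names = list(layout.channel_names)
    pos = layout.positions[[layout.index(n) for n in channel_names]]
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    arc = np.arccos(cosang)
    adj = (arc < max_arc) & ~np.eye(len(channel_names), dtype=bool)
    neighbors = [np.flatnonzero(row) for row in adj]
    if any(nb.size == 0 for nb in neighbors):
        logger.warning("adjacency at max_arc=%.3f leaves isolated channels", max_arc)
    return AdjacencyGraph(len(channel_names), neighbors, max_arc)


# ---------------------------------------------------------------------------
# t maps

def paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over the first axis: mean(d) / (sd(d)/sqrt(n)).

    Zero-variance samples yield t = 0 (logged once); ``diffs`` is
    (n_subjects, ...).
    """
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("paired t needs n >= 2 subjects")
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    bad = sd == 0
    if np.any(bad & (m != 0)):
        logger.warning("zero-variance samples with nonzero mean: t set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(bad, 0.0, m / (sd / np.sqrt(n)))
    return t


def _scalp_stack(erps: list[Erp]) -> tuple[np.ndarray, list[str]]:
    idx = erps[0].scalp_indices()
    names = [erps[0].layout.channel_names[i] for i in idx]
    return np.stack([e.data[idx] for e in erps]), names


def subject_differences(erps_a: list[Erp], erps_b: list[Erp]) -> tuple[np.ndarray, list[str]]:
    """(n_subjects, channels, time) scalp difference waves a − b."""
    if len(erps_a) != len(erps_b) or len(erps_a) == 0:
        raise ValueError("need matched, nonempty subject lists")
    for ea, eb in zip(erps_a, erps_b):
        if ea.subject_id != eb.subject_id:
            raise ValueError("subject lists must be matched pairwise")
        if ea.data.shape != eb.data.shape:
            raise ValueError("ERP shapes differ between conditions")
    a, names = _scalp_stack(erps_a)
    b, _ = _scalp_stack(erps_b)
    return a - b, names


def paired_t_map(erps_a: list[Erp], erps_b: list[Erp]) -> np.ndarray:
    """Channels x time paired t map of condition A minus condition B.

    Positive t means the hypothesised direction (A above B); scalp
    channels only.
    """
    diffs, _ = subject_differences(erps_a, erps_b)
    return paired_t(diffs)


# ---------------------------------------------------------------------------
# cluster formation (run-merging union-find)

def _find(parent: np.ndarray, x: int) -> int:
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


def _runs(supra: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel maximal runs of True: (channel, start, end-exclusive)."""
    pad = np.zeros((supra.shape[0], supra.shape[1] + 2), dtype=np.int8)
    pad[:, 1:-1] = supra
    d = np.diff(pad, axis=1)
    ch, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    return ch, starts, ends


def _cluster_runs(t_map: np.ndarray, threshold_t: float,
                  adjacency: AdjacencyGraph):
    """Cluster the supra-threshold runs; returns run table + run labels.

    Returns ``(ch, starts, ends, masses, root)`` where ``root[r]`` is the
    cluster id (union-find root) of run ``r``; empty arrays when nothing
    survives the threshold.
    """
    supra = t_map > threshold_t
    ch, starts, ends = _runs(supra)
    n_runs = ch.size
    if n_runs == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty, empty, np.empty(0), empty

    cs = np.concatenate([np.zeros((t_map.shape[0], 1)),
                         np.cumsum(t_map, axis=1)], axis=1)
    masses = cs[ch, ends] - cs[ch, starts]

    # per-channel slices into the run table (runs are channel-sorted)
    bounds = np.searchsorted(ch, np.arange(t_map.shape[0] + 1))
    parent = np.arange(n_runs)
    for i, j in adjacency.pairs():
        ai, bi = bounds[i], bounds[i + 1]
        aj, bj = bounds[j], bounds[j + 1]
        if ai == bi or aj == bj:
            continue
        p, q = ai, aj
        while p < bi and q < bj:
            # overlap in time = shares at least one sample
            if starts[p] < ends[q] and starts[q] < ends[p]:
                rp, rq = _find(parent, p), _find(parent, q)
                if rp != rq:
                    parent[rp] = rq
            if ends[p] < ends[q]:
                p += 1
            else:
                q += 1
    root = np.array([_find(parent, r) for r in range(n_runs)])
    return ch, starts, ends, masses, root


def max_cluster_mass(t_map: np.ndarray, threshold_t: float,
                     adjacency: AdjacencyGraph) -> float:
    """Largest cluster mass in the map; 0.0 if nothing is supra-threshold."""
    ch, starts, ends, masses, root = _cluster_runs(t_map, threshold_t, adjacency)
    if ch.size == 0:
        return 0.0
    total = np.zeros(root.max() + 1)
    np.add.at(total, root, masses)
    return float(total.max())


try:  # numba accelerates the permutation null; the numpy path is the reference
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

if _njit is not None:
    @_njit(cache=True)
    def _max_masses_kernel(T, thr, pairs, bounds_buf):  # pragma: no cover
        n_maps, n_ch, n_t = T.shape
        out = np.zeros(n_maps)
        max_runs = n_ch * ((n_t + 1) // 2) + 1
        run_ch = np.empty(max_runs, np.int64)
        run_s = np.empty(max_runs, np.int64)
        run_e = np.empty(max_runs, np.int64)
        run_mass = np.empty(max_runs)
        parent = np.empty(max_runs, np.int64)
        mass_acc = np.empty(max_runs)
        for m in range(n_maps):
            nr = 0
            for c in range(n_ch):
                bounds_buf[c] = nr
                t = 0
                while t < n_t:
                    if T[m, c, t] > thr:
                        s = t
                        acc = 0.0
                        while t < n_t and T[m, c, t] > thr:
                            acc += T[m, c, t]
                            t += 1
                        run_ch[nr] = c
                        run_s[nr] = s
                        run_e[nr] = t
                        run_mass[nr] = acc
                        nr += 1
                    else:
                        t += 1
            bounds_buf[n_ch] = nr
            if nr == 0:
                continue
            for r in range(nr):
                parent[r] = r
            for e in range(pairs.shape[0]):
                i = pairs[e, 0]
                j = pairs[e, 1]
                p = bounds_buf[i]
                q = bounds_buf[j]
                bi = bounds_buf[i + 1]
                bj = bounds_buf[j + 1]
                while p < bi and q < bj:
                    if run_s[p] < run_e[q] and run_s[q] < run_e[p]:
                        rp = p
                        while parent[rp] != rp:
                            parent[rp] = parent[parent[rp]]
                            rp = parent[rp]
                        rq = q
                        while parent[rq] != rq:
                            parent[rq] = parent[parent[rq]]
                            rq = parent[rq]
                        if rp != rq:
                            parent[rp] = rq
                    if run_e[p] < run_e[q]:
                        p += 1
                    else:
                        q += 1
            best = 0.0
            for r in range(nr):
                mass_acc[r] = 0.0
            for r in range(nr):
                rr = r
                while parent[rr] != rr:
                    parent[rr] = parent[parent[rr]]
                    rr = parent[rr]
                mass_acc[rr] += run_mass[r]
            for r in range(nr):
                if mass_acc[r] > best:
                    best = mass_acc[r]
            out[m] = best
        return out


def _null_max_masses(T: np.ndarray, threshold_t: float,
                     adjacency: AdjacencyGraph) -> np.ndarray:
    """Max cluster mass per map in a (n_maps, ch, time) stack."""
    if _njit is not None:
        pairs = adjacency.pairs()
        if pairs.size == 0:
            pairs = np.empty((0, 2), dtype=np.int64)
        bounds = np.empty(adjacency.n_channels + 1, np.int64)
        return _max_masses_kernel(np.ascontiguousarray(T), threshold_t,
                                  pairs.astype(np.int64), bounds)
    return np.array([max_cluster_mass(T[m], threshold_t, adjacency)
                     for m in range(T.shape[0])])


@dataclass
class Cluster:
    """One spatio-temporal cluster with its mass and permutation p."""

    channels: np.ndarray        # member channel index per sample
    times: np.ndarray           # member time index per sample
    mass: float
    p: float = np.nan

    @property
    def n_samples(self) -> int:
        return int(self.channels.size)

    @property
    def channel_set(self) -> np.ndarray:
        return np.unique(self.channels)

    @property
    def time_span(self) -> tuple[int, int]:
        return int(self.times.min()), int(self.times.max())


def form_clusters(t_map: np.ndarray, threshold_p: float, df: int,
                  adjacency: AdjacencyGraph) -> tuple[list[Cluster], float]:
    """Threshold a one-sided t map and extract connected clusters.

    The cluster-forming threshold is the upper ``threshold_p`` quantile
    of Student t with ``df`` degrees of freedom.  Returns the clusters
    (sorted by decreasing mass) and the threshold t value.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    threshold_t = float(stats.t.ppf(1.0 - threshold_p, df))
    ch, starts, ends, masses, root = _cluster_runs(t_map, threshold_t, adjacency)
    clusters: list[Cluster] = []
    for r in np.unique(root) if ch.size else []:
        member = root == r
        chans = np.concatenate([np.full(e - s, c) for c, s, e in
                                zip(ch[member], starts[member], ends[member])])
        times = np.concatenate([np.arange(s, e) for s, e in
                                zip(starts[member], ends[member])])
        clusters.append(Cluster(chans, times, float(masses[member].sum())))
    clusters.sort(key=lambda c: -c.mass)
    return clusters, threshold_t


# ---------------------------------------------------------------------------
# permutation test

REPORTING_THRESHOLDS = (0.05, 0.1)


@dataclass
class ClusterResult:
    """Observed clusters, their permutation p-values and test parameters."""

    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_t: float
    threshold_p: float
    n_permutations: int
    cluster_alpha: float
    seed: int | None
    df: int
    channel_names: list[str]
    tmin: float
    srate: float
    exhaustive: bool = False
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        alpha = self.cluster_alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p <= alpha]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def to_dict(self) -> dict:
        return {
            "params": {"threshold_p": self.threshold_p,
                       "threshold_t": self.threshold_t,
                       "n_permutations": self.n_permutations,
                       "cluster_alpha": self.cluster_alpha,
                       "seed": self.seed, "df": self.df,
                       "exhaustive": self.exhaustive},
            "clusters": [{
                "mass": c.mass, "p": c.p, "n_samples": c.n_samples,
                "channels": [self.channel_names[i] for i in c.channel_set],
                "time_span_ms": [1000 * (self.tmin + c.time_span[0] / self.srate),
                                 1000 * (self.tmin + c.time_span[1] / self.srate)],
                "significant": {f"p<={a}": bool(c.p <= a)
                                for a in (self.cluster_alpha, *REPORTING_THRESHOLDS)},
            } for c in self.clusters],
        }


def _sign_matrix(n: int, n_permutations: int, rng: np.random.Generator,
                 exhaustive: bool) -> np.ndarray:
    if exhaustive:
        if n > 16:
            raise ValueError("exhaustive enumeration limited to n <= 16 subjects")
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        return 1.0 - 2.0 * bits
    return rng.choice([-1.0, 1.0], size=(n_permutations, n))


def permutation_test(erps_a: list[Erp], erps_b: list[Erp],
                     n_permutations: int = 1000, threshold_p: float = 0.05,
                     cluster_alpha: float = 0.01, seed: int | None = 0,
                     adjacency: AdjacencyGraph | None = None,
                     max_arc: float = 0.35, exhaustive: bool = False,
                     _chunk: int = 256) -> ClusterResult:
    """Paired one-sided spatio-temporal cluster permutation test (A > B).

    Monte-Carlo mode draws ``n_permutations`` random sign-flip patterns
    and uses the (1 + count)/(n + 1) rule, which counts the observed data
    as one permutation and guarantees valid p-values; ``exhaustive=True``
    enumerates all 2^n patterns (identity included) and reports the
    exact p = #{null >= observed}/2^n.  Deterministic per seed.
    """
    diffs, names = subject_differences(erps_a, erps_b)
    n, n_ch, n_t = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if adjacency is None:
        adjacency = build_adjacency(erps_a[0].layout, max_arc,
                                    channel_names=names)
    df = n - 1

    t_obs = paired_t(diffs)
    clusters, threshold_t = form_clusters(t_obs, threshold_p, df, adjacency)

    rng = np.random.default_rng(seed)
    signs = _sign_matrix(n, n_permutations, rng, exhaustive)
    n_eff = signs.shape[0]

    D = diffs.reshape(n, -1)
    sumsq = np.einsum("ij,ij->j", D, D)
    null_max = np.empty(n_eff)
    fac = n / (n - 1)
    for lo in range(0, n_eff, _chunk):
        S = signs[lo:lo + _chunk]
        M = (S @ D) / n
        var = (sumsq[None, :] / n - M * M) * fac
        with np.errstate(divide="ignore", invalid="ignore"):
            T = M / np.sqrt(var / n)
        T[~np.isfinite(T)] = 0.0
        null_max[lo:lo + S.shape[0]] = _null_max_masses(
            T.reshape(-1, n_ch, n_t), threshold_t, adjacency)

    for c in clusters:
        exceed = int(np.sum(null_max >= c.mass))
        c.p = exceed / n_eff if exhaustive else (1 + exceed) / (n_eff + 1)

    return ClusterResult(clusters, t_obs, threshold_t, threshold_p, n_eff,
                         cluster_alpha, seed, df, names,
                         erps_a[0].tmin, erps_a[0].srate, exhaustive, null_max)


# ---------------------------------------------------------------------------
# the study's four within-group contrasts

#: (name, condition A, condition B) with one-sided direction A > B:
#: the own-name P300 makes SON more positive than OFN, and the N400 makes
#: unrelated/pseudoword targets more negative than related ones.
CONTRASTS = (
    ("SON-OFN", "SON", "OFN"),
    ("RW-UW", "RW2", "UW2"),
    ("RW-PW", "RW2", "PW2"),
    ("UW-PW", "UW2", "PW2"),
)


def run_group_contrasts(subject_erps: list[dict[str, Erp]],
                        n_permutations: int = 1000, threshold_p: float = 0.05,
                        cluster_alpha: float = 0.01, seed: int | None = 0,
                        adjacency: AdjacencyGraph | None = None,
                        contrasts=CONTRASTS) -> dict[str, ClusterResult]:
    """Run the four stimulus contrasts for one group.

    ``subject_erps`` maps condition label to :class:`Erp` per subject;
    subjects missing either condition of a contrast are skipped with a
    log message.  Word-pair contrasts are computed on target (second)
    words.
    """
    results: dict[str, ClusterResult] = {}
    for name, cond_a, cond_b in contrasts:
        pairs = [(s[cond_a], s[cond_b]) for s in subject_erps
                 if cond_a in s and cond_b in s]
        skipped = len(subject_erps) - len(pairs)
        if skipped:
            logger.info("%s: skipped %d subjects missing a condition", name, skipped)
        if len(pairs) < 2:
            raise ValueError(f"contrast {name}: fewer than 2 complete subjects")
        erps_a, erps_b = [p[0] for p in pairs], [p[1] for p in pairs]
        results[name] = permutation_test(erps_a, erps_b, n_permutations,
                                         threshold_p, cluster_alpha, seed,
                                         adjacency)
    return results
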
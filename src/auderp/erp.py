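"""Condition averages, contrasts and global field power."""

from __future__ import annotations

import numpy as np

from .containers import EpochSet, Erp, GfpTrace


def average_condition(epochs: EpochSet, label: str) -> Erp:
    """Arithmetic mean over retained trials of one condition."""
    idx = epochs.retained(label)
    if idx.size == 0:
        raise ValueError(f"no retained trials with label {label!r}")
    return Erp(epochs.data[idx].mean(axis=0), epochs.tmin, epochs.srate,
               int(idx.size), label, epochs.layout, epochs.subject_id,
               list(epochs.non_scalp), dict(epochs.provenance))


def gfp(erp: Erp, mode: str = "rss") -> GfpTrace:
    """Global field power: per-sample root summed square over scalp channels.

    ``mode="rss"`` (the default) is sqrt(sum v^2); ``mode="rms"`` divides
    by the channel count inside the root, the common normalised variant.
    The two differ by a constant sqrt(N) factor, so peak latencies and
    all shape-based comparisons are identical.  The virtual EOG channel
    never enters.
    """
    v = erp.data[erp.scalp_indices()]
    ss = np.sum(v * v, axis=0)
    if mode == "rms":
        ss = ss / v.shape[0]
    elif mode != "rss":
        raise ValueError("mode must be 'rss' or 'rms'")
    return GfpTrace(np.sqrt(ss), erp.tmin, erp.srate)


def group_gfp(subject_gfps: list[GfpTrace]) -> GfpTrace:
    """Pointwise mean of individual GFP traces (the group-level summary)."""
    if not subject_gfps:
        raise ValueError("need at least one GFP trace")
    first = subject_gfps[0]
    for g in subject_gfps[1:]:
        if g.values.size != first.values.size or abs(g.tmin - first.tmin) > 1e-12 \
                or abs(g.srate - first.srate) > 1e-12:
            raise ValueError("GFP traces must share one time axis")
    stack = np.stack([g.values for g in subject_gfps])
    return GfpTrace(stack.mean(axis=0), first.tmin, first.srate)


def difference_wave(erp_a: Erp, erp_b: Erp) -> Erp:
    """Channelwise condition difference a − b (same subject, same axes)."""
    if erp_a.data.shape != erp_b.data.shape:
        raise ValueError("ERPs must have matching shapes")
    return Erp(erp_a.data - erp_b.data, erp_a.tmin, erp_a.srate,
               min(erp_a.n_trials, erp_b.n_trials),
               f"{erp_a.condition}-{erp_b.condition}", erp_a.layout,
               erp_a.subject_id, list(erp_a.non_scalp),
               {**erp_a.provenance, "contrast": [erp_a.condition, erp_b.condition]})
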
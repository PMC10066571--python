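"""Synthetic multi-channel EEG with embedded ERP components.

The generator emulates the three study groups of an auditory ERP battery
in critically ill COVID-19 patients: healthy controls (own-name P300
effect plus semantic and lexical N400 effects), patients without
delirium (P300 preserved, lexical N400 only, with a more posterior
topography) and patients with delirium (early N100/P200 preserved, no
higher-order effect).  Each component is a Gaussian-in-time deflection
with a Gaussian spatial falloff around a named scalp focus; background
activity is 1/f-shaped noise plus 50 Hz line contamination, Poisson
blink artifacts with a frontal dipolar pattern, and occasional
high-amplitude bad-trial bursts.

Continuous recordings are additive: components + noise terms sum, so a
noise-free run recovers the embedded templates exactly.  Voltages are
"absolute" (ideal reference); the average-reference step of the
preprocessing chain removes the spatial mean as it would for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EventSchedule, Recording
from .layout import SensorLayout, topography

#: lognormal sigma giving ~±20% multiplicative per-trial amplitude jitter
JITTER_SIGMA = 0.2
#: mean of the per-trial lognormal jitter (exp(sigma^2 / 2))
JITTER_MEAN = float(np.exp(JITTER_SIGMA ** 2 / 2))


@dataclass
class ComponentSpec:
    """One ERP component: when, where and on which conditions it appears."""

    name: str
    latency_s: float
    width_s: float
    amplitude_uV: float
    focus: str = "vertex"
    spatial_sd_rad: float = 0.7
    conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width_s must be positive")
        self.conditions = frozenset(self.conditions)

    def temporal(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak Gaussian deflection at ``latency_s``."""
        return np.exp(-0.5 * ((t - self.latency_s) / self.width_s) ** 2)

    def template(self, layout: SensorLayout, t: np.ndarray) -> np.ndarray:
        """channels x time spatio-temporal template (includes amplitude)."""
        topo = topography(layout, self.focus, self.spatial_sd_rad)
        return self.amplitude_uV * topo[:, None] * self.temporal(t)[None, :]


@dataclass
class NoiseSpec:
    """Additive nuisance terms of the continuous recording."""

    background_sd_uV: float = 10.0
    line_amp_uV: float = 2.0
    blink_rate_hz: float = 0.2
    blink_amp_uV: float = 80.0
    bad_trial_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("background_sd_uV", "line_amp_uV", "blink_rate_hz",
                     "blink_amp_uV", "bad_trial_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def silent(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class GroupProfile:
    """Study-group recipe: which components ride on which conditions."""

    group: str
    components: list[ComponentSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)


_SON_LABELS = frozenset({"SON", "OFN"})
_SLP_LABELS = frozenset({"RW1", "RW2", "UW1", "UW2", "PW1", "PW2"})
_ALL_LABELS = _SON_LABELS | _SLP_LABELS


def _early_components() -> list[ComponentSpec]:
    """N100/P200 on every auditory event — preserved in all three groups."""
    return [
        ComponentSpec("N100", 0.100, 0.030, -4.0, "vertex", conditions=_ALL_LABELS),
        ComponentSpec("P200", 0.200, 0.050, +3.0, "vertex", conditions=_ALL_LABELS),
    ]


def default_profiles() -> dict[str, GroupProfile]:
    """The three group profiles with the default component parameters.

    Controls carry the own-name P300 effect (centro-parietal) and N400
    effects on both unrelated-word and pseudoword targets
    (fronto-central); the no-delirium group keeps the P300 and only the
    lexical (pseudoword) N400, shifted parieto-occipitally; the delirium
    group keeps only the obligatory N100/P200.
    """
    p300 = ComponentSpec("P300", 0.450, 0.120, +4.0, "centro-parietal",
                         conditions={"SON"})
    n400_ctrl = ComponentSpec("N400", 0.450, 0.080, -3.0, "fronto-central",
                              conditions={"UW2", "PW2"})
    n400_lex = ComponentSpec("N400", 0.450, 0.080, -3.0, "parieto-occipital",
                             conditions={"PW2"})
    return {
        "CONTROL": GroupProfile("CONTROL", _early_components() + [p300, n400_ctrl]),
        "DEL_MINUS": GroupProfile("DEL_MINUS", _early_components() + [p300, n400_lex]),
        "DEL_PLUS": GroupProfile("DEL_PLUS", _early_components()),
    }


DEFAULT_GROUP_SIZES = {"CONTROL": 14, "DEL_MINUS": 22, "DEL_PLUS": 19}


# ---------------------------------------------------------------------------
# noise terms

def one_over_f_noise(shape: tuple[int, ...], srate: float,
                     rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f.

    White noise is shaped in the frequency domain by 1/sqrt(f) (the DC
    bin reuses the first nonzero frequency) and rescaled to standard
    deviation ``sd`` per sample.
    """
    if sd == 0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / srate)
    f[0] = f[1] if n > 1 else 1.0
    spec *= 1.0 / np.sqrt(f)
    x = np.fft.irfft(spec, n=n, axis=-1)
    x *= sd / np.std(x)
    return x


def blink_template(srate: float, duration_s: float = 0.35) -> np.ndarray:
    """Biphasic ocular deflection (~300 ms), unit positive peak."""
    t = np.arange(int(round(duration_s * srate))) / srate
    b = np.exp(-0.5 * ((t - 0.09) / 0.035) ** 2) - 0.4 * np.exp(-0.5 * ((t - 0.21) / 0.05) ** 2)
    return b / np.max(np.abs(b))


def blink_topography(layout: SensorLayout) -> np.ndarray:
    """Dipolar periocular pattern: positive above, negative below the eye."""
    above = topography(layout, "above-eye", 0.55)
    below = topography(layout, "below-eye", 0.40)
    w = above - 0.8 * below
    return w / np.max(np.abs(w))


# ---------------------------------------------------------------------------
# subject and cohort simulation

def simulate_subject(profile: GroupProfile, schedule: EventSchedule,
                     layout: SensorLayout, srate: float = 500.0,
                     seed: int | np.random.SeedSequence = 0,
                     tail_s: float = 1.5,
                     jitter_sigma: float = JITTER_SIGMA) -> Recording:
    """Simulate one continuous recording for one subject.

    Additive model: 1/f background + 50 Hz line + Poisson blinks + the
    spatio-temporal template of every component whose ``conditions``
    contain the event label, scaled by an independent lognormal per-trial
    amplitude jitter — plus rare high-amplitude bursts ("bad trials").
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_ch = layout.n_channels
    duration = (schedule.duration_hint if len(schedule) else 0.0) + tail_s
    n_samp = int(round(duration * srate))
    noise = profile.noise

    data = one_over_f_noise((n_ch, n_samp), srate, rng, noise.background_sd_uV)

    if noise.line_amp_uV > 0:
        t = np.arange(n_samp) / srate
        phase = rng.uniform(0, 2 * np.pi)
        data += noise.line_amp_uV * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]

    if noise.blink_rate_hz > 0 and noise.blink_amp_uV > 0:
        n_blinks = rng.poisson(noise.blink_rate_hz * duration)
        tmpl = blink_template(srate)
        w = blink_topography(layout) * noise.blink_amp_uV
        for onset in np.sort(rng.uniform(0, duration - len(tmpl) / srate,
                                         size=n_blinks)):
            i0 = int(round(onset * srate))
            amp = rng.lognormal(0.0, 0.25)
            data[:, i0:i0 + len(tmpl)] += amp * w[:, None] * tmpl[None, :]

    # event-locked components
    half_span = 8.0  # evaluate templates out to ±8 temporal SDs (<1e-13 tails)
    for onset, label in zip(schedule.onsets, schedule.labels):
        for comp in profile.components:
            if label not in comp.conditions:
                continue
            t0 = onset + comp.latency_s - half_span * comp.width_s
            t1 = onset + comp.latency_s + half_span * comp.width_s
            i0, i1 = max(0, int(t0 * srate)), min(n_samp, int(np.ceil(t1 * srate)))
            if i1 <= i0:
                continue
            t = np.arange(i0, i1) / srate - onset
            jitter = rng.lognormal(0.0, jitter_sigma) if jitter_sigma > 0 else 1.0
            topo = topography(layout, comp.focus, comp.spatial_sd_rad)
            data[:, i0:i1] += (comp.amplitude_uV * jitter
                               * topo[:, None] * comp.temporal(t)[None, :])

    # bad trials: broadband burst on a random channel subset
    if noise.bad_trial_rate > 0:
        for onset in schedule.onsets:
            if rng.uniform() >= noise.bad_trial_rate:
                continue
            i0 = int(round(onset * srate))
            i1 = min(n_samp, i0 + int(0.8 * srate))
            n_bad = max(1, int(rng.uniform(0.15, 0.4) * n_ch))
            bad = rng.choice(n_ch, size=n_bad, replace=False)
            data[bad, i0:i1] += rng.normal(0, 150.0, size=(n_bad, i1 - i0))

    return Recording(data, srate, layout, schedule,
                     provenance={"group": profile.group,
                                 "simulated": True})


def subject_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent per-subject seed streams derived from one master seed."""
    return list(np.random.SeedSequence(master_seed).spawn(n))


def simulate_cohort(group_sizes: dict[str, int] | None = None,
                    schedules: dict[str, EventSchedule] | None = None,
                    layout: SensorLayout | None = None,
                    profiles: dict[str, GroupProfile] | None = None,
                    srate: float = 500.0, seed: int = 0):
    """Simulate recordings for every subject of every group and paradigm.

    Returns ``(recordings, manifest)`` where ``recordings`` maps
    ``(group, subject_index, paradigm)`` to a :class:`Recording` and the
    manifest records the embedded ground truth (components per group,
    per-subject seed entropy) for downstream validation.
    """
    from .paradigms import build_son_schedule, build_slp_schedule
    from .layout import fibonacci_montage

    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    profiles = profiles or default_profiles()
    layout = layout or fibonacci_montage()
    if any(n < 1 for n in group_sizes.values()):
        raise ValueError("group sizes must be >= 1")

    n_total = sum(group_sizes.values())
    seeds = subject_seeds(seed, n_total)
    recordings: dict[tuple[str, int, str], Recording] = {}
    manifest = {"master_seed": seed, "srate": srate, "groups": {}}

    k = 0
    for group, n in group_sizes.items():
        prof = profiles[group]
        manifest["groups"][group] = {
            "n_subjects": n,
            "components": [{"name": c.name, "latency_s": c.latency_s,
                            "width_s": c.width_s, "amplitude_uV": c.amplitude_uV,
                            "focus": c.focus, "conditions": sorted(c.conditions)}
                           for c in prof.components],
        }
        for subj in range(n):
            child = seeds[k].spawn(3)
            if schedules is None:
                subj_schedules = {
                    "SON": build_son_schedule(seed=int(child[0].generate_state(1)[0] % 2**31)),
                    "SLP": build_slp_schedule(seed=int(child[1].generate_state(1)[0] % 2**31)),
                }
            else:
                subj_schedules = schedules
            for paradigm, sched in subj_schedules.items():
                rec = simulate_subject(prof, sched, layout, srate, child[2])
                rec.provenance.update(subject=f"{group.lower()}-{subj:02d}",
                                      paradigm=paradigm)
                recordings[(group, subj, paradigm)] = rec
            k += 1
    return recordings, manifest


# ---------------------------------------------------------------------------
# reduced generator: condition-average ERPs directly

def simulate_condition_erp(profile: GroupProfile, layout: SensorLayout,
                           condition: str, n_trials: int,
                           srate: float = 500.0, tmin: float = -0.2,
                           tmax: float = 1.0,
                           rng: np.random.Generator | None = None,
                           seed: int | None = 0,
                           jitter_sigma: float = JITTER_SIGMA) -> np.ndarray:
    """Draw one subject's condition-average ERP (channels x time) directly.

    Exploits two exact reductions of the additive trial model: the
    average of ``n`` independent Gaussian 1/f noise epochs is one 1/f
    noise draw scaled by 1/sqrt(n), and per-trial lognormal amplitude
    jitter enters the average through its sampled n-trial mean.  The
    result is distributed exactly as the trial-averaged, baseline-
    corrected ERP of the continuous model without artifact terms (which
    the preprocessing chain removes).  Used for statistics-scale
    validation where materialising every trial would be wasteful.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_t = int(round((tmax - tmin) * srate)) + 1
    t = tmin + np.arange(n_t) / srate

    erp = one_over_f_noise((layout.n_channels, n_t), srate, rng,
                           profile.noise.background_sd_uV / np.sqrt(n_trials))
    for comp in profile.components:
        if condition not in comp.conditions:
            continue
        mean_jitter = (float(np.mean(rng.lognormal(0.0, jitter_sigma, n_trials)))
                       if jitter_sigma > 0 else 1.0)
        erp += mean_jitter * comp.template(layout, t)

    baseline = t <= 0
    erp -= erp[:, baseline].mean(axis=1, keepdims=True)
    return erp
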
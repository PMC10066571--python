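"""End-to-end driver: simulate -> preprocess -> ERP/GFP -> contrasts -> report.

One YAML (or dict) config plus one seed reproduces the full chain; every
stage's parameters and derived seeds are archived in the output
manifest.  Rendering is side-effect free with respect to the numeric
results: figures and the markdown summary are generated from the result
bundle after the JSONs are written.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cluster import build_adjacency, run_group_contrasts
from .containers import Erp
from .erp import average_condition, gfp, group_gfp
from .io import _jsonable
from .layout import eog_pair, fibonacci_montage
from .paradigms import SlpParams, SonParams, build_slp_schedule, build_son_schedule
from .preprocess import preprocess_recording
from .simulate import NoiseSpec, default_profiles, simulate_subject, subject_seeds

PARADIGM_CONDITIONS = {"SON": ["SON", "OFN"], "SLP": ["RW2", "UW2", "PW2"]}

DEFAULT_CONFIG: dict = {
    "cohort": {
        "group_sizes": {"CONTROL": 14, "DEL_MINUS": 22, "DEL_PLUS": 19},
        "srate": 500.0,
        "n_channels": 128,
    },
    "paradigms": {"son": {}, "slp": {}},
    "noise": {},
    "preprocessing": {"low": 0.5, "high": 25.0, "notch": 50.0,
                      "tmin": -0.2, "tmax": 1.0, "k": 6.0, "rho": 0.1},
    "statistics": {"n_permutations": 1000, "threshold_p": 0.05,
                   "cluster_alpha": 0.01},
}


# sections whose keys are validated downstream by their own constructors
_OPEN_SECTIONS = {"paradigms.son", "paradigms.slp", "noise",
                  "cohort.group_sizes"}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        here = f"{path}.{key}" if path else key
        if key not in base and path not in _OPEN_SECTIONS:
            raise ValueError(f"unknown config field: {here}")
        if here == "cohort.group_sizes":
            if not isinstance(val, dict):
                raise ValueError(f"config field {here} must be a mapping")
            out[key] = dict(val)  # replaces the default cohort wholesale
        elif isinstance(base.get(key), dict) or here in _OPEN_SECTIONS:
            if not isinstance(val, dict):
                raise ValueError(f"config field {here} must be a mapping")
            out[key] = _merge(base.get(key, {}), val, here)
        else:
            out[key] = val
    return out


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a user config (YAML path or dict) over the defaults and validate."""
    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        override = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, override)
    stats = cfg["statistics"]
    if stats["n_permutations"] < 1:
        raise ValueError("statistics.n_permutations must be >= 1")
    if not (0 < stats["threshold_p"] < 1):
        raise ValueError("statistics.threshold_p must lie in (0, 1)")
    if any(n < 1 for n in cfg["cohort"]["group_sizes"].values()):
        raise ValueError("cohort.group_sizes entries must be >= 1")
    if cfg["cohort"]["n_channels"] < 8:
        raise ValueError("cohort.n_channels must be >= 8")
    return cfg


def run_pipeline(config: str | Path | dict | None, seed: int,
                 out_dir: str | Path | None = None) -> dict:
    """Run the whole chain under one config and seed; returns the bundle.

    The bundle holds, per group: group-average Cz ERPs and group GFP per
    condition, and the cluster permutation results of the within-group
    contrasts.  When ``out_dir`` is given, result JSONs and a manifest
    are written there (``render_report`` adds figures).
    """
    cfg = load_config(config)
    rng_master = np.random.default_rng(seed)
    srate = float(cfg["cohort"]["srate"])
    layout = fibonacci_montage(int(cfg["cohort"]["n_channels"]))
    above, below = eog_pair(layout)
    noise = NoiseSpec(**{k: float(v) for k, v in cfg["noise"].items()}) \
        if cfg["noise"] else NoiseSpec()
    profiles = default_profiles()
    for p in profiles.values():
        p.noise = noise
    pre = cfg["preprocessing"]
    stats = cfg["statistics"]
    son_params = SonParams(**cfg["paradigms"]["son"])
    slp_params = SlpParams(**cfg["paradigms"]["slp"])

    group_sizes = cfg["cohort"]["group_sizes"]
    seeds = subject_seeds(int(rng_master.integers(2 ** 31)),
                          sum(group_sizes.values()))
    times = None
    bundle: dict = {"config": cfg, "seed": seed, "version": __version__,
                    "groups": {}}

    k = 0
    for group, n_subj in group_sizes.items():
        profile = profiles[group]
        subject_erps: list[dict[str, Erp]] = []
        gfps: dict[str, list] = {c: [] for cs in PARADIGM_CONDITIONS.values()
                                 for c in cs}
        for s in range(n_subj):
            child = seeds[k].spawn(3)
            k += 1
            sid = f"{group.lower()}-{s:02d}"
            erps: dict[str, Erp] = {}
            for paradigm, sched_seed, rec_seed in (("SON", child[0], child[2].spawn(2)[0]),
                                                   ("SLP", child[1], child[2].spawn(2)[1])):
                if paradigm == "SON":
                    sched = build_son_schedule(son_params,
                                               int(sched_seed.generate_state(1)[0] % 2**31))
                else:
                    sched = build_slp_schedule(slp_params,
                                               int(sched_seed.generate_state(1)[0] % 2**31))
                rec = simulate_subject(profile, sched, layout, srate, rec_seed)
                epochs = preprocess_recording(
                    rec, above, below, low=pre["low"], high=pre["high"],
                    notch_freq=pre["notch"], tmin=pre["tmin"], tmax=pre["tmax"],
                    k=pre["k"], rho=pre["rho"], subject_id=sid)
                for cond in PARADIGM_CONDITIONS[paradigm]:
                    e = average_condition(epochs, cond)
                    erps[cond] = e
                    gfps[cond].append(gfp(e))
                    times = e.times
            subject_erps.append(erps)

        # adjacency over scalp channels, arc scaled to montage density
        from .study import suggested_max_arc
        scalp_names = [n for n in subject_erps[0]["SON"].layout.channel_names
                       if n not in subject_erps[0]["SON"].non_scalp]
        adjacency = build_adjacency(subject_erps[0]["SON"].layout,
                                    suggested_max_arc(layout),
                                    channel_names=scalp_names)
        contrasts = run_group_contrasts(
            subject_erps, adjacency=adjacency,
            n_permutations=int(stats["n_permutations"]),
            threshold_p=float(stats["threshold_p"]),
            cluster_alpha=float(stats["cluster_alpha"]),
            seed=int(rng_master.integers(2 ** 31)))

        icz = layout.index(layout.reference_name)
        bundle["groups"][group] = {
            "n_subjects": n_subj,
            "erp_cz": {c: np.mean([s[c].data[icz] for s in subject_erps], axis=0)
                       for c in gfps},
            "group_gfp": {c: group_gfp(v).values for c, v in gfps.items()},
            "contrasts": contrasts,
        }

    bundle["times"] = times
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"seed": bundle["seed"], "version": bundle["version"],
           "config": bundle["config"],
           "times_s": np.asarray(bundle["times"]).tolist(), "groups": {}}
    for g, res in bundle["groups"].items():
        doc["groups"][g] = {
            "n_subjects": res["n_subjects"],
            "erp_cz": {c: np.asarray(v).tolist() for c, v in res["erp_cz"].items()},
            "group_gfp": {c: np.asarray(v).tolist() for c, v in res["group_gfp"].items()},
            "contrasts": {name: r.to_dict() for name, r in res["contrasts"].items()},
        }
    (out_dir / "results.json").write_text(json.dumps(_jsonable(doc)))
    manifest = {"seed": bundle["seed"], "version": bundle["version"],
                "config": bundle["config"]}
    (out_dir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))


_CONDITION_COLORS = {"SON": "tab:blue", "OFN": "m", "RW2": "tab:blue",
                     "UW2": "m", "PW2": "g"}


def render_report(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Figures + markdown summary from a result bundle.

    Per group and paradigm: Cz ERP overlay per condition and the group
    GFP overlay, with horizontal bars under the traces marking time
    samples inside clusters significant at the reporting thresholds.
    Purely a view of the bundle — numeric results are not touched.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = np.asarray(bundle["times"])
    written: list[Path] = []
    lines = ["# Auditory ERP analysis report", "",
             f"seed {bundle['seed']}, package version {bundle['version']}", ""]

    contrast_paradigm = {"SON-OFN": "SON", "RW-UW": "SLP", "RW-PW": "SLP",
                         "UW-PW": "SLP"}
    for g, res in bundle["groups"].items():
        fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True)
        for col, paradigm in enumerate(("SON", "SLP")):
            conds = [c for c in res["erp_cz"] if c in PARADIGM_CONDITIONS[paradigm]]
            for c in conds:
                axes[0, col].plot(times, res["erp_cz"][c],
                                  color=_CONDITION_COLORS.get(c), label=c)
                axes[1, col].plot(times, res["group_gfp"][c],
                                  color=_CONDITION_COLORS.get(c), label=c)
            y0 = min((np.min(res["erp_cz"][c]) for c in conds), default=0) - 0.5
            for name, r in res["contrasts"].items():
                if contrast_paradigm.get(name) != paradigm:
                    continue
                for alpha, lw in ((0.05, 3), (0.1, 1)):
                    for c in r.significant(alpha):
                        t0, t1 = c.time_span
                        axes[0, col].plot(times[[t0, t1]], [y0, y0], lw=lw,
                                          color="k", solid_capstyle="butt")
            axes[0, col].set_title(f"{g} — {paradigm}: Cz ERP")
            axes[1, col].set_title(f"{g} — {paradigm}: group GFP")
            axes[1, col].set_xlabel("time (s)")
            axes[0, col].legend(fontsize=8)
        axes[0, 0].set_ylabel("µV")
        axes[1, 0].set_ylabel("GFP (µV)")
        fig.tight_layout()
        fpath = out_dir / f"group_{g}.png"
        fig.savefig(fpath, dpi=110)
        plt.close(fig)
        written.append(fpath)

        lines.append(f"## {g} (n = {res['n_subjects']})\n")
        for name, r in res["contrasts"].items():
            sig = r.significant(0.05)
            lines.append(f"- **{name}**: {len(r.clusters)} cluster(s); "
                         + (f"min p = {r.min_p:.4g}; "
                            f"{len(sig)} significant at p ≤ 0.05"
                            if r.clusters else "none supra-threshold"))
            for c in sig:
                t0, t1 = c.time_span
                lines.append(f"  - mass {c.mass:.1f}, p = {c.p:.4g}, "
                             f"{1000*times[t0]:.0f}–{1000*times[t1]:.0f} ms, "
                             f"{c.channel_set.size} channels")
        lines.append("")

    report = out_dir / "report.md"
    report.write_text("\n".join(lines))
    written.append(report)
    return written
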
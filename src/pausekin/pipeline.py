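"""End-to-end orchestration: simulate or load, select, segment, fit, report.

`run_pipeline` executes the full analysis on a multi-condition experiment
(one NTP concentration per condition) and returns a JSON-serialisable
report; identical config + seed give identical outputs. `make_fixtures`
writes small deterministic trace bundles with ground-truth sidecars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .branching import (
    classify_trajectories,
    first_attempt_probability,
    fit_isotherm,
    transition_histogram,
)
from .dwells import bootstrap_sd, extract_dwells, fit_exp_mixture, pause_exit_rate
from .fret import (
    SelectionPolicy,
    compute_fret,
    detect_active,
    fit_fret_levels,
    select_traces,
)
from .schemes import build_default_scheme, build_withdrawal_scheme
from .segment import (
    _trace_window,
    allan_deviation,
    filter_steps,
    map_states,
    segment_hmm,
    segment_mean_levels,
)
from .simulate import (
    EmissionParams,
    render_trace,
    simulate_experiment,
    write_paths_csv,
    write_traces_csv,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """Serialisable configuration of one pipeline run."""

    seed: int = 0
    conditions: list[dict] = field(
        default_factory=lambda: [{"ntp": 80.0, "n_traces": 150}]
    )
    scheme: dict = field(
        default_factory=lambda: dict(
            k_itc6=0.11, K_ntp=28.0, P_max=0.79, k1=0.15, k2=0.02, P_k1=0.6
        )
    )
    duration: float = 600.0
    t_injection: float = 20.0
    frame_time: float = 0.2
    emission: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    max_states: int = 4
    hmm_fit_subset: int | None = 60
    min_len_frames: int = 2
    allan_block: int = 5
    tol_sd: float = 3.0
    min_pause_frames: int = 2
    m_max: int = 2
    restarts: int = 10
    bootstrap_B: int = 200
    min_level_samples: int = 30
    dwell_t_min: float | None = None  # None -> (min_len_frames + 1) * frame_time
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where outputs land is not part of the science
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _condition_seed(base: int, i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base, spawn_key=(i,))


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> select -> FRET -> segment -> filter -> map -> dwell
    fits -> classification -> isotherm on every condition of ``config``.

    Returns the run report (dict); when ``config.out_dir`` is set, also
    writes per-trace class tables, dwell tables, the transition matrix and
    the report JSON there. Fully deterministic for fixed config + seed.
    """
    em = EmissionParams(frame_time=config.frame_time, **config.emission)
    t_min = config.dwell_t_min
    if t_min is None:
        t_min = (config.min_len_frames + 1) * config.frame_time
    policy = SelectionPolicy(**config.selection)
    inj_frame = int(round(config.t_injection / config.frame_time))

    report: dict = {
        "provenance": {
            "package": "pausekin",
            "version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
        },
        "conditions": [],
    }
    per_cond: list[dict] = []
    iso_points = []
    class_rows = []
    dwell_rows = []
    all_paths = []
    selection_rows = []
    segment_rows = []

    for i, cond in enumerate(config.conditions):
        ntp = float(cond["ntp"])
        n_traces = int(cond["n_traces"])
        scheme = build_default_scheme(ntp=ntp, **config.scheme)
        ss = _condition_seed(config.seed, i)
        traces, truth = simulate_experiment(
            scheme,
            n_traces,
            config.duration,
            em,
            seed=ss,
            t_injection=config.t_injection,
            trace_prefix=f"c{i}_",
        )

        kept, sel_report = select_traces(traces, policy)
        frets = [compute_fret(tr) for tr in kept]
        try:
            frac_active, active_ci, _ = detect_active(frets, inj_frame)
        except ValueError:
            frac_active, active_ci = None, None
        segs = segment_hmm(
            frets,
            max_states=config.max_states,
            shared=True,
            seed=config.seed,
            fit_subset=config.hmm_fit_subset,
        )

        filtered = []
        for ft, sg in zip(frets, segs):
            base = ft.E[:inj_frame][ft.mask[:inj_frame]]
            try:
                sig = allan_deviation(base, block=config.allan_block)
            except ValueError:
                usable = ft.E[ft.mask]
                sig = allan_deviation(usable, block=config.allan_block)
            filtered.append(filter_steps(sg, sig, min_len=config.min_len_frames))

        # centers from pooled segment means (unweighted: one vote per
        # visit, so a long-lived level cannot swamp the others); per-frame
        # widths for the 3-sigma assignment tolerance in map_states
        seg_levels = [segment_mean_levels(ft, sg)[0] for ft, sg in zip(frets, filtered)]
        all_e = np.concatenate([_trace_window(ft) for ft in frets])
        levels = fit_fret_levels(
            np.concatenate(seg_levels),
            frame_values=all_e,
            min_samples_per_peak=config.min_level_samples,
        )

        paths = [map_states(sg, levels, tol_sd=config.tol_sd) for sg in filtered]
        all_paths.extend(paths)
        for tid, kept_flag, reason in sel_report.rows:
            selection_rows.append((ntp, tid, kept_flag, reason))
        for sg, lp in zip(filtered, paths):
            for (lvl, start, n_fr), lseg in zip(sg.segments, lp.segments):
                segment_rows.append((ntp, sg.trace_id, start, n_fr, lvl, lseg.label))
        classes = classify_trajectories(
            paths,
            min_pause_frames=config.min_pause_frames,
            frame_time=config.frame_time,
            t_injection=config.t_injection,
        )
        for c in classes:
            class_rows.append((ntp, c.trace_id, c.cls or "withheld", c.n_attempts,
                               c.paused, c.reason))

        entry: dict = {
            "ntp_uM": ntp,
            "n_traces": n_traces,
            "n_kept": len(kept),
            "fraction_active": frac_active,
            "fraction_active_ci": list(active_ci) if active_ci else None,
            "levels": {lab: levels.center(lab) for lab in levels.labels},
            "classes": {
                cls: sum(1 for c in classes if c.cls == cls)
                for cls in set(c.cls or "withheld" for c in classes)
            },
        }
        try:
            p, ci, n = first_attempt_probability(classes)
            entry["first_attempt"] = {"p": p, "ci": list(ci), "n": n}
            iso_points.append((ntp, p, ci))
        except ValueError:
            entry["first_attempt"] = None

        # pause-exit rate from single-scrunch trajectories
        ss_ids = {c.trace_id for c in classes
                  if c.cls == "single_scrunch_with_pause"}
        ss_paths = [p_ for p_ in paths if p_.trace_id in ss_ids]
        try:
            fit = pause_exit_rate(ss_paths, B=config.bootstrap_B,
                                  seed=config.seed + i, t_min=t_min)
            entry["k_itc6"] = {"k": float(fit.k[0]), "sd": float(fit.k_sd[0]),
                               "n_dwells": fit.n}
        except ValueError:
            entry["k_itc6"] = None

        # cycling kinetics: two-exponential US / PS dwell fits
        cyc_ids = {c.trace_id for c in classes
                   if c.cls in ("cycling_then_FS", "cycling_only")}
        cyc_paths = [p_ for p_ in paths if p_.trace_id in cyc_ids]
        entry["cycling"] = {}
        for state in ("US", "PS"):
            try:
                ds = extract_dwells(cyc_paths, state,
                                    skip_first_visit=(state == "PS"))
            except ValueError:
                continue
            for t_, tid in zip(ds.tau, ds.trace_ids):
                dwell_rows.append((ntp, state, tid, t_))
            if ds.N >= 5 * (2 * config.m_max - 1):
                f2 = fit_exp_mixture(ds, 2, restarts=config.restarts,
                                     seed=config.seed + i, t_min=t_min)
                entry["cycling"][state] = {
                    "k1": float(f2.k[0]), "k2": float(f2.k[1]),
                    "P_k1": float(f2.p[0]), "n_dwells": f2.n,
                }
        per_cond.append(entry)

    report["conditions"] = per_cond

    # isotherm across conditions
    try:
        iso = fit_isotherm(iso_points)
        report["isotherm"] = {
            "K_ntp_uM": iso.K_ntp, "P_max": iso.P_max,
            "K_sd": iso.K_sd, "P_sd": iso.P_sd,
        }
    except ValueError as err:
        report["isotherm"] = {"error": str(err)}

    # across-condition averages (weighted by dwell count)
    def _avg(key: str) -> dict | None:
        vals = {"k1": [], "k2": [], "P_k1": [], "w": []}
        for entry in per_cond:
            for state in ("US", "PS"):
                c = entry["cycling"].get(state)
                if c:
                    for q in ("k1", "k2", "P_k1"):
                        vals[q].append(c[q])
                    vals["w"].append(c["n_dwells"])
        if not vals["w"]:
            return None
        w = np.array(vals["w"], dtype=float)
        return {q: float(np.average(vals[q], weights=w)) for q in ("k1", "k2", "P_k1")}

    report["cycling_summary"] = _avg("cycling")
    ks = [e["k_itc6"]["k"] for e in per_cond if e["k_itc6"]]
    report["k_itc6_mean"] = float(np.mean(ks)) if ks else None
    trans = transition_histogram(all_paths)
    report["transitions"] = {
        "labels": list(trans.labels),
        "counts": trans.counts.tolist(),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            class_rows,
            columns=["ntp_uM", "trace_id", "class", "n_attempts", "paused", "reason"],
        ).to_csv(out / "classes.csv", index=False)
        pd.DataFrame(
            dwell_rows, columns=["ntp_uM", "state", "trace_id", "tau_s"]
        ).to_csv(out / "dwells.csv", index=False, float_format="%.6f")
        pd.DataFrame(trans.counts, index=trans.labels, columns=trans.labels).to_csv(
            out / "transitions.csv"
        )
        pd.DataFrame(
            selection_rows, columns=["ntp_uM", "trace_id", "kept", "reason"]
        ).to_csv(out / "selection.csv", index=False)
        pd.DataFrame(
            segment_rows,
            columns=["ntp_uM", "trace_id", "start_frame", "n_frames", "level", "label"],
        ).to_csv(out / "segments.csv", index=False, float_format="%.4f")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "config.json").write_text(config.to_json())
        (out / "summary.txt").write_text(_summary_text(report))
    return report


def _summary_text(report: dict) -> str:
    lines = [
        f"pausekin {report['provenance']['version']}  "
        f"config {report['provenance']['config_hash']}  "
        f"seed {report['provenance']['seed']}",
        "",
    ]
    for c in report["conditions"]:
        fa = c.get("first_attempt")
        line = f"[{c['ntp_uM']:g} uM] kept {c['n_kept']}/{c['n_traces']}"
        if c.get("fraction_active") is not None:
            line += f", active {c['fraction_active']:.2f}"
        if fa:
            line += f", first-attempt p={fa['p']:.3f} (n={fa['n']})"
        if c.get("k_itc6"):
            line += f", k_ITC6={c['k_itc6']['k']:.3f}/s"
        lines.append(line)
    iso = report.get("isotherm") or {}
    if "K_ntp_uM" in iso:
        lines.append(
            f"isotherm: K_NTP={iso['K_ntp_uM']:.1f} uM, P_max={iso['P_max']:.3f}"
        )
    cyc = report.get("cycling_summary")
    if cyc:
        lines.append(
            f"cycling: k1={cyc['k1']:.3f}/s k2={cyc['k2']:.3f}/s P(k1)={cyc['P_k1']:.2f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write small deterministic trace bundles with ground-truth sidecars.

    Bundles: ``productive`` (saturating NTP, mostly single-scrunch),
    ``cycling`` (low NTP, cycling-heavy), ``withdrawal`` (no-NTP mix of
    US/PS and US/PS/FS cyclers), ``doped`` (clean traces plus summed
    double-dye artifacts, flagged in the sidecar). Returns a manifest with
    per-file SHA-256 checksums; stable under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    em = EmissionParams()
    manifest: dict = {"seed": seed, "bundles": {}}

    def write(name: str, traces, paths, extra: dict | None = None) -> None:
        tpath = out / f"{name}_traces.csv"
        ppath = out / f"{name}_truth.csv"
        write_traces_csv(traces, tpath)
        write_paths_csv(paths, ppath)
        entry = {
            "n_traces": len(traces),
            "traces_file": tpath.name,
            "truth_file": ppath.name,
            "sha256": {
                tpath.name: hashlib.sha256(tpath.read_bytes()).hexdigest(),
                ppath.name: hashlib.sha256(ppath.read_bytes()).hexdigest(),
            },
        }
        entry.update(extra or {})
        manifest["bundles"][name] = entry

    sch_hi = build_default_scheme(ntp=500.0)
    tr, pa = simulate_experiment(sch_hi, 20, 240.0, em, seed=seed, trace_prefix="prod")
    write("productive", tr, pa)

    sch_lo = build_default_scheme(ntp=5.0)
    tr, pa = simulate_experiment(sch_lo, 20, 400.0, em,
                                 seed=np.random.SeedSequence(entropy=seed, spawn_key=(1,)),
                                 trace_prefix="cyc")
    write("cycling", tr, pa)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    wtr, wpa = [], []
    for j in range(10):
        sub = "US/PS" if j % 2 == 0 else "US/PS/FS"
        sch = build_withdrawal_scheme(sub)
        from .simulate import gillespie_simulate

        p = gillespie_simulate(sch, 200.0, 1, rng, trace_prefix=f"wd{j}_")[0]
        wpa.append(p)
        wtr.append(render_trace(p, em, rng))
    write("withdrawal", wtr, wpa)

    tr, pa = simulate_experiment(sch_hi, 18, 240.0, em,
                                 seed=np.random.SeedSequence(entropy=seed, spawn_key=(3,)),
                                 trace_prefix="dope")
    doped_ids = []
    rng2 = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    for j in range(2):
        a, b = tr[2 * j], tr[2 * j + 1]
        n = min(len(a), len(b))
        from .fret import IntensityTrace

        mix = IntensityTrace(
            f"doped{j:02d}", a.frame_time,
            a.I_DD[:n] + b.I_DD[:n], a.I_DA[:n] + b.I_DA[:n], a.I_AA[:n] + b.I_AA[:n],
        )
        tr.append(mix)
        doped_ids.append(mix.trace_id)
    write("doped", tr, pa, {"doped_trace_ids": doped_ids})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
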
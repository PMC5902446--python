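"""Stochastic simulation of kinetic schemes and synthetic trace rendering.

`gillespie_simulate` draws continuous-time Markov-chain paths from a
:class:`~pausekin.schemes.KineticScheme`; `render_trace` turns a hidden path
into a three-channel ALEX intensity trace with Gaussian channel noise and
single-step photobleaching; `simulate_experiment` wires both together with a
pre-injection open-complex baseline, giving downstream stages ground truth
to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import IntensityTrace
from .schemes import KineticScheme

__all__ = [
    "Segment",
    "StatePath",
    "EmissionParams",
    "gillespie_simulate",
    "render_trace",
    "simulate_experiment",
    "noise_sd_for_e_sd",
    "write_traces_csv",
    "read_traces_csv",
    "write_paths_csv",
    "read_paths_csv",
]


@dataclass(frozen=True)
class Segment:
    """One dwell of a hidden-state path."""

    state: str
    tag: str
    fret: float
    start_s: float
    duration_s: float


@dataclass
class StatePath:
    """Piecewise-constant hidden-state trajectory for one molecule."""

    trace_id: str
    segments: list[Segment]
    truncation: str = "end-of-record"  # end-of-record | bleach | escape

    def __post_init__(self) -> None:
        t = None
        for seg in self.segments:
            if seg.duration_s <= 0:
                raise ValueError(f"segment duration must be > 0, got {seg.duration_s}")
            if t is not None:
                if abs(seg.start_s - t) > 1e-9:
                    raise ValueError("segments must be contiguous")
            t = seg.start_s + seg.duration_s

    @property
    def duration(self) -> float:
        if not self.segments:
            return 0.0
        last = self.segments[-1]
        return last.start_s + last.duration_s - self.segments[0].start_s

    def observable_segments(self) -> list[Segment]:
        """Merge consecutive segments sharing the same observable tag.

        Hidden fast/slow substates of one observable level are invisible;
        the merged segments are what a perfect detector would report.
        """
        out: list[Segment] = []
        for seg in self.segments:
            if out and out[-1].tag == seg.tag:
                prev = out[-1]
                out[-1] = Segment(
                    prev.tag, prev.tag, prev.fret, prev.start_s,
                    prev.duration_s + seg.duration_s,
                )
            else:
                out.append(Segment(seg.tag, seg.tag, seg.fret, seg.start_s, seg.duration_s))
        return out


@dataclass
class EmissionParams:
    """Photophysical parameters of the rendered traces.

    total : expected summed donor-excitation intensity per frame (a.u.)
    noise_sd : additive Gaussian SD per channel (a.u.)
    donor_bleach_rate, acceptor_bleach_rate : single-step bleaching rates (1/s)
    frame_time : ALEX frame time (s); default 0.2 s (100 ms per excitation)
    alex_duty : fraction of the frame spent on each excitation
    """

    total: float = 200.0
    noise_sd: float = 14.0
    donor_bleach_rate: float = 0.002
    acceptor_bleach_rate: float = 0.002
    frame_time: float = 0.2
    alex_duty: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleaching rates must be >= 0")
        if self.frame_time <= 0:
            raise ValueError(f"frame_time must be > 0, got {self.frame_time}")


def noise_sd_for_e_sd(e_sd: float, total: float, e_level: float = 0.5) -> float:
    """Channel noise SD giving a target per-frame FRET-efficiency SD.

    First-order error propagation of E = A/(A+D) with independent channel
    noise of SD sigma: SD(E) ~= sigma * sqrt((1-E)^2 + E^2) / total.
    """
    return e_sd * total / np.sqrt((1.0 - e_level) ** 2 + e_level**2)


# ---------------------------------------------------------------------------
# Gillespie simulation


def _compile(scheme: KineticScheme):
    names = scheme.state_names
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    rates = np.zeros((n, n))
    for f, t, r in scheme.transitions:
        rates[idx[f], idx[t]] += r
    total = rates.sum(axis=1)
    probs = np.zeros_like(rates)
    nz = total > 0
    probs[nz] = rates[nz] / total[nz, None]
    init_p = np.zeros(n)
    for name, p in scheme.initial.items():
        init_p[idx[name]] = p
    states = [scheme.state(nm) for nm in names]
    return states, total, probs, init_p


def gillespie_simulate(
    scheme: KineticScheme,
    duration: float,
    n_traces: int,
    seed: int | np.random.Generator,
    t_start: float = 0.0,
    trace_prefix: str = "sim",
) -> list[StatePath]:
    """Draw exact stochastic paths from a kinetic scheme.

    Dwell times in each hidden state are exponential with the state's total
    exit rate; the successor is drawn proportionally to outgoing rates.
    Paths start at ``t_start`` and are truncated at ``t_start + duration``
    with truncation cause ``end-of-record`` (or ``escape`` if an absorbing
    state tagged ``absorbing`` was reached earlier). Fixed seeds reproduce
    paths exactly.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if n_traces < 1:
        raise ValueError(f"n_traces must be >= 1, got {n_traces}")
    states, total_rate, probs, init_p = _compile(scheme)
    if np.all(total_rate[init_p > 0] == 0):
        raise ValueError("no dynamics: every initial state is absorbing")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_states = len(states)
    paths: list[StatePath] = []
    t_end = t_start + duration
    for i in range(n_traces):
        s = int(rng.choice(n_states, p=init_p))
        t = t_start
        segs: list[Segment] = []
        cause = "end-of-record"
        while t < t_end:
            st = states[s]
            if total_rate[s] == 0:
                # absorbing: occupy to end of record
                if st.tag == "absorbing":
                    cause = "escape"
                    break
                segs.append(Segment(st.name, st.tag, st.fret, t, t_end - t))
                t = t_end
                break
            dt = rng.exponential(1.0 / total_rate[s])
            if t + dt >= t_end:
                segs.append(Segment(st.name, st.tag, st.fret, t, t_end - t))
                t = t_end
                break
            segs.append(Segment(st.name, st.tag, st.fret, t, dt))
            t += dt
            s = int(rng.choice(n_states, p=probs[s]))
        paths.append(StatePath(f"{trace_prefix}{i:04d}", segs, cause))
    return paths


# ---------------------------------------------------------------------------
# trace rendering


def render_trace(
    path: StatePath,
    em: EmissionParams,
    seed: int | np.random.Generator,
    n_frames: int | None = None,
) -> IntensityTrace:
    """Render a hidden path into a noisy three-channel intensity trace.

    Frames are aligned to the frame-time grid; each frame displays the FRET
    level of the state occupying the majority of the frame (events shorter
    than half a frame are therefore invisible by construction). Expected
    intensities per frame are I_DA = total*E, I_DD = total*(1-E) and
    I_AA = total while the acceptor is present; donor and acceptor bleach
    times are drawn exponentially. After acceptor bleach the FRET channel
    drops to noise and all donor-excitation light appears in I_DD; after
    donor bleach both donor-excitation channels drop to noise. Independent
    zero-mean Gaussian noise is added to every channel.

    Bleach times are recorded in ``metadata['donor_bleach_s']`` /
    ``['acceptor_bleach_s']`` (NaN if beyond the record).
    """
    if em.frame_time <= 0:
        raise ValueError(f"frame_time must be > 0, got {em.frame_time}")
    dt = em.frame_time
    t0 = path.segments[0].start_s if path.segments else 0.0
    dur = path.duration
    if dur < dt:
        raise ValueError("path must span at least one frame")
    if n_frames is None:
        n_frames = int(np.floor(dur / dt + 1e-9))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # majority-occupancy level per frame
    obs = path.observable_segments()
    levels = sorted({seg.fret for seg in obs})
    lvl_idx = {v: i for i, v in enumerate(levels)}
    occ = np.zeros((n_frames, len(levels) + 1))  # last column: absorbed/no signal
    for seg in obs:
        a = seg.start_s - t0
        b = a + seg.duration_s
        f0 = max(int(np.floor(a / dt)), 0)
        f1 = min(int(np.ceil(b / dt)), n_frames)
        if f1 <= f0:
            continue
        fr = np.arange(f0, f1)
        overlap = np.minimum(b, (fr + 1) * dt) - np.maximum(a, fr * dt)
        occ[fr, lvl_idx[seg.fret]] += np.clip(overlap, 0.0, None)
    covered = occ[:, :-1].sum(axis=1)
    occ[:, -1] = dt - covered  # time not covered by any observable segment
    which = occ.argmax(axis=1)
    E = np.where(which < len(levels), np.array(levels + [0.0])[which], 0.0)
    signal = which < len(levels)

    # single-step bleaching
    t_d = rng.exponential(1.0 / em.donor_bleach_rate) if em.donor_bleach_rate > 0 else np.inf
    t_a = rng.exponential(1.0 / em.acceptor_bleach_rate) if em.acceptor_bleach_rate > 0 else np.inf
    frames = np.arange(n_frames)
    # the frame containing the bleach time already shows the drop
    donor_on = (frames + 1) * dt <= t_d
    acceptor_on = (frames + 1) * dt <= t_a

    I_DA = np.where(signal & donor_on & acceptor_on, em.total * E, 0.0)
    I_DD = np.where(signal & donor_on, em.total * np.where(acceptor_on, 1.0 - E, 1.0), 0.0)
    I_AA = np.where(signal & acceptor_on, em.total, 0.0)
    if em.noise_sd > 0:
        I_DA = I_DA + rng.normal(0.0, em.noise_sd, n_frames)
        I_DD = I_DD + rng.normal(0.0, em.noise_sd, n_frames)
        I_AA = I_AA + rng.normal(0.0, em.noise_sd, n_frames)

    meta = {
        "donor_bleach_s": float(t_d) if t_d < n_frames * dt else float("nan"),
        "acceptor_bleach_s": float(t_a) if t_a < n_frames * dt else float("nan"),
        "t0_s": t0,
    }
    return IntensityTrace(path.trace_id, dt, I_DD, I_DA, I_AA, meta)


# ---------------------------------------------------------------------------
# experiment-level wrapper


def simulate_experiment(
    scheme: KineticScheme,
    n_traces: int,
    duration: float,
    em: EmissionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    t_injection: float = 20.0,
    inactive_fraction: float = 0.0,
    baseline_tag: str = "US",
    trace_prefix: str = "sim",
    metadata: dict | None = None,
) -> tuple[list[IntensityTrace], list[StatePath]]:
    """Simulate a full imaging run: baseline, NTP injection, kinetics, noise.

    Each molecule shows the unscrunched open-complex level for
    ``t_injection`` seconds (the pre-NTP baseline), then evolves under
    ``scheme`` until ``duration``. A fraction ``inactive_fraction`` of
    molecules never leaves the baseline level (transcriptionally inactive).
    Returns rendered traces together with the ground-truth hidden paths.
    """
    em = em or EmissionParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    rng_path = np.random.default_rng(seeds[0])
    rng_mix = np.random.default_rng(seeds[1])
    rng_render = np.random.default_rng(seeds[2])

    lv = scheme.level_map()
    base_fret = lv.get(baseline_tag, 0.49)

    kinetic = duration - t_injection
    if kinetic <= 0:
        raise ValueError("duration must exceed t_injection")
    raw = gillespie_simulate(
        scheme, kinetic, n_traces, rng_path, t_start=t_injection, trace_prefix=trace_prefix
    )

    paths: list[StatePath] = []
    for p in raw:
        if inactive_fraction > 0 and rng_mix.uniform() < inactive_fraction:
            segs = [Segment("baseline", baseline_tag, base_fret, 0.0, duration)]
            paths.append(StatePath(p.trace_id, segs, "end-of-record"))
            continue
        segs = []
        if t_injection > 0:
            segs.append(Segment("baseline", baseline_tag, base_fret, 0.0, t_injection))
        segs += list(p.segments)
        # pad absorbed tail so the rendered record always spans `duration`
        end = segs[-1].start_s + segs[-1].duration_s if segs else 0.0
        if end < duration and p.truncation == "escape":
            last = p.segments[-1] if p.segments else None
            # molecule escaped: hold the FS level to end of record
            fs = lv.get("FS", 0.80)
            segs.append(Segment("escaped", "FS", fs, end, duration - end))
        paths.append(StatePath(p.trace_id, segs, p.truncation))

    base_meta = dict(metadata or {})
    base_meta.setdefault("t_injection_s", t_injection)
    if scheme.ntp is not None:
        base_meta.setdefault("ntp_uM", scheme.ntp)
    traces = []
    for p in paths:
        tr = render_trace(p, em, rng_render)
        tr.metadata.update(base_meta)
        traces.append(tr)
    return traces, paths


# ---------------------------------------------------------------------------
# tabular I/O


def write_traces_csv(traces: list[IntensityTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tr.trace_id,
                    "frame": np.arange(len(tr)),
                    "I_DD": tr.I_DD,
                    "I_DA": tr.I_DA,
                    "I_AA": tr.I_AA,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def read_traces_csv(path, frame_time: float = 0.2) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        out.append(
            IntensityTrace(str(tid), frame_time, g["I_DD"].values, g["I_DA"].values, g["I_AA"].values)
        )
    return out


def write_paths_csv(paths: list[StatePath], path) -> None:
    rows = []
    for p in paths:
        for seg in p.segments:
            rows.append(
                (p.trace_id, seg.state, seg.tag, seg.fret, seg.start_s, seg.duration_s, p.truncation)
            )
    # full float precision: contiguity must survive the round trip
    pd.DataFrame(
        rows,
        columns=["trace_id", "state", "tag", "fret", "start_s", "duration_s", "truncation"],
    ).to_csv(path, index=False)


def read_paths_csv(path) -> list[StatePath]:
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("trace_id", sort=False):
        segs = [
            Segment(r.state, r.tag, r.fret, r.start_s, r.duration_s)
            for r in g.itertuples(index=False)
        ]
        out.append(StatePath(str(tid), segs, g["truncation"].iloc[0]))
    return out
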
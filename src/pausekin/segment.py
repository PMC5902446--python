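"""Piecewise-constant FRET level inference and the dwell step filter.

A Gaussian-emission hidden Markov model (fit by EM, state count chosen by
BIC) yields a Viterbi level path per trace. The raw path is then cleaned by
a step filter: steps lasting no more than ``min_len`` frames are merged into
the neighbouring level closest in E, and adjacent steps separated by less
than twice the Allan deviation (estimated at five-frame blocks) are fused.
Finally the fitted levels are mapped onto the calibrated US/PS/FS states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fret import FretTrace, LevelTable

__all__ = [
    "SegmentedTrace",
    "LabeledSegment",
    "LabeledPath",
    "segment_hmm",
    "allan_deviation",
    "filter_steps",
    "map_states",
    "labeled_from_statepath",
]


@dataclass
class SegmentedTrace:
    """Fitted piecewise-constant levels: (level, start_frame, n_frames)."""

    trace_id: str
    frame_time: float
    segments: list[tuple[float, int, int]]
    confidence: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = None
        for lvl, start, length in self.segments:
            if length < 1:
                raise ValueError("segment length must be >= 1 frame")
            if prev_end is not None and start != prev_end:
                raise ValueError("segments must be contiguous and non-overlapping")
            prev_end = start + length

    @property
    def n_frames(self) -> int:
        if not self.segments:
            return 0
        lvl, start, length = self.segments[-1]
        return start + length - self.segments[0][1]

    def frame_levels(self) -> np.ndarray:
        out = np.empty(self.n_frames)
        off = self.segments[0][1]
        for lvl, start, length in self.segments:
            out[start - off : start - off + length] = lvl
        return out


@dataclass(frozen=True)
class LabeledSegment:
    label: str  # US | PS | FS | unassigned
    start_s: float
    duration_s: float
    level: float = float("nan")


@dataclass
class LabeledPath:
    """Observable state sequence in seconds, ready for dwell pooling."""

    trace_id: str
    segments: list[LabeledSegment]
    truncation: str = "end-of-record"
    flagged: bool = False
    metadata: dict = field(default_factory=dict)

    def labels(self, drop_unassigned: bool = True) -> list[str]:
        labs = [s.label for s in self.segments]
        if drop_unassigned:
            labs = [l for l in labs if l != "unassigned"]
        return labs


# ---------------------------------------------------------------------------
# HMM segmentation


def _trace_window(ft: FretTrace) -> np.ndarray:
    """Usable E series of a trace: analysis window, masked frames filled."""
    end = int(ft.metadata.get("analysis_end_frame", len(ft)))
    e = np.array(ft.E[:end], dtype=float)
    bad = ~ft.mask[:end] | ~np.isfinite(e)
    if bad.all():
        return np.empty(0)
    if bad.any():
        idx = np.arange(len(e))
        e[bad] = np.interp(idx[bad], idx[~bad], e[~bad])
    return e


def segment_hmm(
    fret_traces: list[FretTrace],
    max_states: int = 4,
    shared: bool = True,
    min_states: int = 2,
    seed: int = 0,
    n_iter: int = 150,
    tol: float = 1e-2,
    fit_subset: int | None = None,
) -> list[SegmentedTrace]:
    """Segment FRET traces with a Gaussian-emission HMM (EM + BIC + Viterbi).

    With ``shared=True`` (ensemble mode) one model with pooled emission
    parameters is fitted to all traces; otherwise each trace gets its own
    model. All states share one emission variance (the camera noise does
    not depend on the FRET level), which keeps EM from splitting a heavily
    occupied level instead of resolving close-lying ones. The state count
    is chosen by BIC between ``min_states`` and ``max_states``.
    Initialisation is deterministic for a fixed ``seed`` (means spread over
    the observed E range, variance from frame-to-frame differences, sticky
    transitions), so repeated runs give identical segmentations.
    ``fit_subset`` limits EM fitting to the first that many traces
    (decoding still covers all traces), which keeps large ensembles
    tractable without changing the estimator.

    Raises ``RuntimeError`` with the log-likelihood trajectory if EM fails
    to converge for every candidate state count.
    """
    from hmmlearn.hmm import GaussianHMM

    if len(fret_traces) == 0:
        raise ValueError("segment_hmm requires at least one trace")
    if not 2 <= max_states <= 6:
        raise ValueError(f"max_states must lie in [2, 6], got {max_states}")
    if not shared:
        return [
            seg
            for ft in fret_traces
            for seg in segment_hmm([ft], max_states, True, min_states, seed, n_iter, tol)
        ]

    series = [_trace_window(ft) for ft in fret_traces]
    keep = [i for i, e in enumerate(series) if len(e) >= 3]
    fit_idx = keep if fit_subset is None else keep[:fit_subset]
    X_fit = np.concatenate([series[i] for i in fit_idx])[:, None]
    lengths = [len(series[i]) for i in fit_idx]

    lo, hi = np.quantile(X_fit[:, 0], [0.01, 0.99])
    noise_var = max(0.5 * float(np.var(np.diff(X_fit[:, 0]))), 1e-5)
    best = None
    histories = []
    for n in range(min_states, max_states + 1):
        model = GaussianHMM(
            n_components=n,
            covariance_type="tied",
            n_iter=n_iter,
            tol=tol,
            init_params="",
            params="stmc",
            random_state=seed,
        )
        model.means_ = np.linspace(lo, hi, n)[:, None]
        model.covars_ = np.array([[noise_var]])
        model.startprob_ = np.full(n, 1.0 / n)
        A = np.full((n, n), 0.05 / max(n - 1, 1))
        np.fill_diagonal(A, 0.95)
        model.transmat_ = A
        model.fit(X_fit, lengths)
        histories.append((n, list(model.monitor_.history)))
        ll = float(model.score(X_fit, lengths))
        n_params = n + 1 + (n - 1) + n * (n - 1)  # means, tied var, start, transitions
        bic = -2.0 * ll + n_params * np.log(len(X_fit))
        if model.monitor_.converged and (best is None or bic < best[0]):
            best = (bic, model)
    if best is None:
        raise RuntimeError(f"HMM EM did not converge; log-likelihood histories: {histories}")
    model = best[1]

    out: list[SegmentedTrace] = []
    means = model.means_[:, 0]
    for ft, e in zip(fret_traces, series):
        if len(e) < 1:
            out.append(SegmentedTrace(ft.trace_id, ft.frame_time, [], metadata=dict(ft.metadata)))
            continue
        if len(e) < 3:
            lvl = float(means[np.argmin(np.abs(means - e.mean()))])
            out.append(
                SegmentedTrace(ft.trace_id, ft.frame_time, [(lvl, 0, len(e))], [1.0],
                               metadata=dict(ft.metadata))
            )
            continue
        states = model.predict(e[:, None])
        post = model.predict_proba(e[:, None])
        segs: list[tuple[float, int, int]] = []
        confs: list[float] = []
        start = 0
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[start]:
                s = states[start]
                segs.append((float(means[s]), start, i - start))
                confs.append(float(post[start:i, s].mean()))
                start = i
        out.append(SegmentedTrace(ft.trace_id, ft.frame_time, segs, confs, dict(ft.metadata)))
    return out


# ---------------------------------------------------------------------------
# Allan deviation and the step filter


def allan_deviation(series: np.ndarray, block: int = 5) -> float:
    """Two-sample (Allan) deviation of consecutive non-overlapping block means.

    sigma_A = sqrt( 0.5 * mean_i (ybar_{i+1} - ybar_i)^2 ), where ybar are
    means over consecutive non-overlapping blocks of ``block`` frames. For
    white noise of SD sigma this converges to sigma/sqrt(block); correlated
    drift inflates it, which is why it serves as the noise floor for
    accepting FRET steps.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2 * block:
        raise ValueError(f"need >= {2 * block} frames for block size {block}, got {len(series)}")
    m = len(series) // block
    means = series[: m * block].reshape(m, block).mean(axis=1)
    d = np.diff(means)
    return float(np.sqrt(0.5 * np.mean(d * d)))


def filter_steps(
    seg: SegmentedTrace, sigma_A: float, min_len: int = 2
) -> SegmentedTrace:
    """Apply the dwell step filter to a segmented trace.

    Two merge rules, applied iteratively to a fixed point: (i) segments of
    ``min_len`` frames or fewer are absorbed into the neighbour whose level
    is nearest in E (shortest segment first, earliest on ties); (ii)
    adjacent segments whose level difference is at most ``2 * sigma_A`` are
    fused into one segment at the duration-weighted mean level (closest pair
    first). Total duration is conserved exactly.
    """
    if sigma_A < 0:
        raise ValueError(f"sigma_A must be >= 0, got {sigma_A}")
    segs = [list(s) for s in seg.segments]  # [level, start, length]
    if not segs:
        return SegmentedTrace(seg.trace_id, seg.frame_time, [], metadata=dict(seg.metadata))

    def fuse(i: int) -> None:
        """Fuse segment i+1 into segment i at the duration-weighted level."""
        l0, s0, n0 = segs[i]
        l1, _, n1 = segs[i + 1]
        level = l0 if l0 == l1 else (l0 * n0 + l1 * n1) / (n0 + n1)
        segs[i] = [level, s0, n0 + n1]
        del segs[i + 1]

    changed = True
    while changed and len(segs) > 1:
        changed = False
        # rule (i): short segments, shortest first (tie -> earliest)
        short = [(n, i) for i, (_, _, n) in enumerate(segs) if n <= min_len]
        if short:
            _, i = min(short)
            if i == 0:
                j = 1
            elif i == len(segs) - 1:
                j = i - 1
            else:
                j = i - 1 if abs(segs[i - 1][0] - segs[i][0]) <= abs(
                    segs[i + 1][0] - segs[i][0]) else i + 1
            # absorb the short segment into neighbour j, keeping j's level
            keep_level = segs[j][0]
            lo = min(i, j)
            fuse(lo)
            segs[lo][0] = keep_level
            changed = True
            continue
        # rule (ii): level-close neighbours, closest pair first
        diffs = [abs(segs[i + 1][0] - segs[i][0]) for i in range(len(segs) - 1)]
        i = int(np.argmin(diffs))
        if diffs[i] <= 2.0 * sigma_A:
            fuse(i)
            changed = True
    # collapse exact-duplicate neighbours left over
    i = 0
    while i < len(segs) - 1:
        if segs[i][0] == segs[i + 1][0]:
            fuse(i)
        else:
            i += 1
    return SegmentedTrace(
        seg.trace_id, seg.frame_time, [tuple(s) for s in segs], metadata=dict(seg.metadata)
    )


# ---------------------------------------------------------------------------
# level -> state mapping


def map_states(
    seg: SegmentedTrace, levels: LevelTable, tol_sd: float = 3.0
) -> LabeledPath:
    """Label each fitted segment with its nearest calibrated FRET state.

    Segments farther than ``tol_sd`` peak SDs from every calibrated center
    become ``unassigned`` (excluded from dwell pooling). Exact ties between
    two centers break deterministically to the lower level and flag the
    path. A path with more than half of its frames unassigned is flagged.
    """
    if len(levels.levels) != 3:
        raise ValueError("map_states expects a three-level table (PS/US/FS)")
    entries = sorted(levels.levels, key=lambda r: r[1])  # ascending center
    out: list[LabeledSegment] = []
    dt = seg.frame_time
    flagged = False
    unassigned_frames = 0
    total_frames = 0
    for lvl, start, length in seg.segments:
        dists = [(abs(lvl - c), c, lab, sd) for lab, c, sd, _ in entries]
        dmin = min(d for d, _, _, _ in dists)
        nearest = [e for e in dists if e[0] - dmin <= 1e-12]
        if len(nearest) > 1:  # equidistant: tie-break to the lower level
            nearest.sort(key=lambda e: e[1])
            flagged = True
        d, c, lab, sd = nearest[0]
        if d > tol_sd * sd:
            lab = "unassigned"
            unassigned_frames += length
        total_frames += length
        out.append(LabeledSegment(lab, start * dt, length * dt, lvl))
    if total_frames and unassigned_frames / total_frames > 0.5:
        flagged = True
    return LabeledPath(
        seg.trace_id,
        out,
        truncation=seg.metadata.get("truncation", "end-of-record"),
        flagged=flagged,
        metadata=dict(seg.metadata),
    )


def segment_mean_levels(
    ft: FretTrace, seg: SegmentedTrace
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment mean of the raw E series, with segment lengths as weights.

    These means (rather than the fitted HMM levels, which collapse onto the
    model's state means) carry the spread needed for Gaussian peak
    calibration of the FRET levels.
    """
    e = _trace_window(ft)
    vals, wts = [], []
    for _, start, length in seg.segments:
        chunk = e[start : start + length]
        if len(chunk):
            vals.append(float(np.mean(chunk)))
            wts.append(length)
    return np.array(vals), np.array(wts, dtype=float)


def labeled_from_statepath(path, frame_time: float | None = None) -> LabeledPath:
    """Ground-truth LabeledPath from a simulated hidden path (oracle view)."""
    segs = [
        LabeledSegment(s.tag, s.start_s, s.duration_s, s.fret)
        for s in path.observable_segments()
    ]
    return LabeledPath(path.trace_id, segs, truncation=path.truncation)
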
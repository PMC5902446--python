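"""FRET efficiency computation, trace selection and level calibration.

Input traces carry three ALEX channels per frame: donor emission under donor
excitation (I_DD), acceptor emission under donor excitation (I_DA), and
acceptor emission under direct acceptor excitation (I_AA, which reports
acceptor presence independently of FRET). The apparent FRET efficiency is

    E = I_DA / (I_DA + I_DD).

Selection emulates the manual curation applied to camera-extracted traces:
keep only traces consistent with a single donor / single acceptor pair
(single terminal acceptor bleach step, at most one donor bleach step,
bounded blinking), with an automated change-point implementation so the
filter is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "IntensityTrace",
    "FretTrace",
    "LevelTable",
    "SelectionPolicy",
    "compute_fret",
    "select_traces",
    "detect_active",
    "fit_fret_levels",
    "find_intensity_steps",
]


@dataclass
class IntensityTrace:
    """Per-frame three-channel intensities for one molecule."""

    trace_id: str
    frame_time: float
    I_DD: np.ndarray
    I_DA: np.ndarray
    I_AA: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I_DD = np.asarray(self.I_DD, dtype=float)
        self.I_DA = np.asarray(self.I_DA, dtype=float)
        self.I_AA = np.asarray(self.I_AA, dtype=float)
        n = len(self.I_DD)
        if not (len(self.I_DA) == n == len(self.I_AA)):
            raise ValueError("channel arrays must have equal length")
        if n < 1:
            raise ValueError("trace must contain at least one frame")
        if self.frame_time <= 0:
            raise ValueError(f"frame_time must be > 0, got {self.frame_time}")

    def __len__(self) -> int:
        return len(self.I_DD)


@dataclass
class FretTrace:
    """Per-frame apparent FRET efficiency with a validity mask."""

    trace_id: str
    frame_time: float
    E: np.ndarray
    mask: np.ndarray  # True = frame usable
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.E) != len(self.mask):
            raise ValueError("mask length must equal trace length")
        if not np.all(np.isfinite(self.E[self.mask])):
            raise ValueError("masked-in frames must have finite E")

    def __len__(self) -> int:
        return len(self.E)


@dataclass
class LevelTable:
    """Calibrated FRET levels: (label, peak center, peak SD, SE of center)."""

    levels: list[tuple[str, float, float, float]]
    merged_flag: bool = False

    def __post_init__(self) -> None:
        centers = {label: c for label, c, _, _ in self.levels}
        for label, c, sd, _ in self.levels:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"center for {label} outside [0, 1]: {c}")
            if sd <= 0:
                raise ValueError(f"SD for {label} must be > 0: {sd}")
        if {"US", "PS", "FS"} <= set(centers):
            if not centers["PS"] < centers["US"] < centers["FS"]:
                raise ValueError(
                    "level centers must be ordered PS < US < FS, got "
                    f"PS={centers['PS']}, US={centers['US']}, FS={centers['FS']}"
                )

    def center(self, label: str) -> float:
        for lab, c, _, _ in self.levels:
            if lab == label:
                return c
        raise KeyError(label)

    def sd(self, label: str) -> float:
        for lab, _, sd, _ in self.levels:
            if lab == label:
                return sd
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _, _, _ in self.levels]


def compute_fret(trace: IntensityTrace) -> FretTrace:
    """Apparent FRET efficiency E = I_DA / (I_DA + I_DD) per frame.

    Frames with non-positive total donor-excitation intensity are masked out
    (no signal to form a ratio). Raises ``ValueError`` if no frame is usable.
    """
    total = trace.I_DA + trace.I_DD
    mask = total > 0
    if not mask.any():
        raise ValueError(f"trace {trace.trace_id}: no usable frames")
    E = np.full(len(trace), np.nan)
    E[mask] = trace.I_DA[mask] / total[mask]
    return FretTrace(trace.trace_id, trace.frame_time, E, mask, dict(trace.metadata))


# ---------------------------------------------------------------------------
# step detection and selection


def find_intensity_steps(
    y: np.ndarray, min_len: int = 5, n_sigma: float = 4.0
) -> list[tuple[int, float]]:
    """Detect mean-shift change points in an intensity series.

    Recursive binary segmentation with a two-segment mean-shift likelihood:
    at each stage the split minimising the residual sum of squares is
    accepted if the mean shift exceeds ``n_sigma`` times the local noise SD
    (estimated from first differences). Returns ``(index, shift)`` pairs,
    sorted by index; ``shift`` is (mean after) - (mean before).
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * min_len:
        return []
    sigma = np.std(np.diff(y)) / np.sqrt(2.0)
    if sigma == 0:
        sigma = 1e-12
    steps: list[tuple[int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_len:
            return
        seg = y[lo:hi]
        csum = np.cumsum(seg)
        tot = csum[-1]
        k = np.arange(min_len, n - min_len + 1)
        mean_l = csum[k - 1] / k
        mean_r = (tot - csum[k - 1]) / (n - k)
        # RSS reduction of a two-segment fit is k*(n-k)/n * (dmean)^2
        gain = k * (n - k) / n * (mean_r - mean_l) ** 2
        i = int(np.argmax(gain))
        shift = mean_r[i] - mean_l[i]
        se = sigma * np.sqrt(1.0 / k[i] + 1.0 / (n - k[i]))
        if abs(shift) < n_sigma * se or abs(shift) < n_sigma * sigma * 0.25:
            return
        cut = lo + int(k[i])
        recurse(lo, cut)
        steps.append((cut, float(shift)))
        recurse(cut, hi)

    recurse(0, len(y))
    steps.sort(key=lambda s: s[0])
    return steps


@dataclass
class SelectionPolicy:
    """Thresholds for single-pair trace selection.

    ``presence_frac``: I_AA above this fraction of its initial level counts
    as acceptor present. ``max_blinks``: tolerated below-threshold runs that
    recover. ``step_frac``: a detected intensity drop larger than this
    fraction of the initial level counts as a photobleaching step.
    """

    min_frames: int = 20
    presence_frac: float = 0.5
    max_blinks: int = 2
    step_frac: float = 0.35
    step_min_len: int = 5
    step_n_sigma: float = 4.0
    #: reject traces whose initial intensity exceeds this multiple of the
    #: population median (trace-level surrogate for image-plane spot
    #: filters against multi-dye spots); None disables
    max_intensity_ratio: float | None = 1.5


def _terminal_drop_frame(present: np.ndarray) -> int | None:
    """First frame of the terminal absent-run, or None if present at end."""
    if present[-1]:
        return None
    idx = np.nonzero(present)[0]
    if len(idx) == 0:
        return 0
    return int(idx[-1]) + 1


def select_traces(
    traces: list[IntensityTrace], policy: SelectionPolicy | None = None
) -> tuple[list[IntensityTrace], "object"]:
    """Keep traces consistent with a single donor/acceptor FRET pair.

    Rejection reasons: ``too_short``, ``no_acceptor``, ``blinking`` (more
    than ``max_blinks`` I_AA dropouts that recover), ``multistep_acceptor``
    and ``multistep_donor`` (two or more discrete photobleaching steps in
    I_AA or in the donor-excitation total, indicating multiple dyes), and
    ``intensity_outlier`` (initial brightness far above the population
    median, indicating a multi-dye spot that never shows a bleach step).

    Returns the kept traces (each with ``metadata['analysis_end_frame']``
    set to the first bleach event, or the trace length) and a report object
    with a ``rows`` list of (trace_id, kept, reason).
    """
    if policy is None:
        policy = SelectionPolicy()
    if len(traces) == 0:
        raise ValueError("select_traces requires at least one trace")

    ref_aa = ref_tot = None
    if policy.max_intensity_ratio is not None and len(traces) >= 5:
        aa0s, tot0s = [], []
        for tr in traces:
            head = max(5, min(25, len(tr) // 10))
            aa0s.append(float(np.median(tr.I_AA[:head])))
            tot0s.append(float(np.median(tr.I_DD[:head] + tr.I_DA[:head])))
        ref_aa = float(np.median(aa0s))
        ref_tot = float(np.median(tot0s))

    kept: list[IntensityTrace] = []
    rows: list[tuple[str, bool, str]] = []
    for tr in traces:
        reason = _screen_trace(tr, policy, ref_aa, ref_tot)
        if reason is None:
            kept.append(tr)
            rows.append((tr.trace_id, True, ""))
        else:
            rows.append((tr.trace_id, False, reason))
    report = SelectionReport(rows)
    return kept, report


@dataclass
class SelectionReport:
    rows: list[tuple[str, bool, str]]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["trace_id", "kept", "reason"])


def _screen_trace(
    tr: IntensityTrace,
    policy: SelectionPolicy,
    ref_aa: float | None = None,
    ref_tot: float | None = None,
) -> str | None:
    n = len(tr)
    if n < policy.min_frames:
        return "too_short"

    head = max(5, min(25, n // 10))
    aa0 = float(np.median(tr.I_AA[:head]))
    if aa0 <= 0:
        return "no_acceptor"
    if policy.max_intensity_ratio is not None:
        tot0 = float(np.median(tr.I_DD[:head] + tr.I_DA[:head]))
        if ref_aa and aa0 > policy.max_intensity_ratio * ref_aa:
            return "intensity_outlier"
        if ref_tot and tot0 > policy.max_intensity_ratio * ref_tot:
            return "intensity_outlier"
    thr = policy.presence_frac * aa0
    present = tr.I_AA > thr

    # below-threshold runs: the terminal one (if any) is the bleach; interior
    # ones that recover are blinks
    below = ~present
    runs = _runs(below)
    acceptor_end = _terminal_drop_frame(present)
    blinks = sum(1 for (s, e) in runs if not (acceptor_end is not None and s >= acceptor_end))
    if blinks > policy.max_blinks:
        return "blinking"

    # multi-dye check on I_AA: >= 2 large discrete downward steps
    aa_steps = find_intensity_steps(tr.I_AA, policy.step_min_len, policy.step_n_sigma)
    big_down_aa = [s for s in aa_steps if s[1] < -policy.step_frac * aa0]
    if len(big_down_aa) >= 2:
        return "multistep_acceptor"

    # donor-excitation total is FRET-independent; check it up to acceptor bleach
    stop = acceptor_end if acceptor_end is not None else n
    tot = tr.I_DD[:stop] + tr.I_DA[:stop]
    donor_end = None
    if len(tot) >= 2 * policy.step_min_len:
        t0 = float(np.median(tot[:head]))
        d_steps = find_intensity_steps(tot, policy.step_min_len, policy.step_n_sigma)
        big_down = [s for s in d_steps if s[1] < -policy.step_frac * t0]
        if len(big_down) >= 2:
            return "multistep_donor"
        if len(big_down) == 1:
            donor_end = big_down[0][0]

    ends = [e for e in (acceptor_end, donor_end) if e is not None]
    tr.metadata["analysis_end_frame"] = int(min(ends)) if ends else n
    return None


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    out = []
    in_run = False
    start = 0
    for i, f in enumerate(flags):
        if f and not in_run:
            in_run, start = True, i
        elif not f and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(flags)))
    return out


# ---------------------------------------------------------------------------
# activity detection


def detect_active(
    fret_traces: list[FretTrace],
    injection_frame: int,
    sigma: float | None = None,
    min_len: int = 3,
) -> tuple[float, tuple[float, float], list[bool]]:
    """Fraction of traces showing >= 1 accepted FRET level change after injection.

    A trace is active when change-point detection on its post-injection E
    series finds at least one mean shift exceeding twice the per-trace noise
    floor (Allan deviation at five frames, unless ``sigma`` is given). The
    search window starts a few frames before injection so a level change at
    the injection boundary itself still counts.
    Returns (fraction, Wilson 95% CI, per-trace activity flags).
    """
    from .segment import allan_deviation

    if len(fret_traces) == 0:
        raise ValueError("detect_active requires at least one trace")
    flags: list[bool] = []
    for ft in fret_traces:
        if injection_frame >= len(ft):
            raise ValueError(
                f"injection frame {injection_frame} outside record of "
                f"{ft.trace_id} (length {len(ft)})"
            )
        end = int(ft.metadata.get("analysis_end_frame", len(ft)))
        e = ft.E[:end][ft.mask[:end]]
        w0 = max(0, injection_frame - 2 * min_len)
        post = ft.E[w0:end][ft.mask[w0:end]]
        if len(post) < 2 * min_len:
            flags.append(False)
            continue
        s = sigma
        if s is None:
            base = e[: max(10, injection_frame)] if injection_frame >= 10 else e
            s = allan_deviation(base, block=5) if len(base) >= 10 else np.std(post)
        steps = find_intensity_steps(post, min_len=min_len, n_sigma=3.0)
        flags.append(any(abs(sh) > 2.0 * s for _, sh in steps))
    k = int(sum(flags))
    n = len(flags)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi)), flags


# ---------------------------------------------------------------------------
# level calibration


def _em_gmm1d(
    x: np.ndarray, w: np.ndarray, n: int, n_iter: int = 300, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted EM for a 1-D Gaussian mixture; deterministic linspace init.

    Returns (means, SDs, weights) sorted by mean. Variances are floored at
    1e-6 to keep components from collapsing onto single samples.
    """
    lo, hi = np.quantile(x, [0.005, 0.995])
    mu = np.linspace(lo, hi, n)
    var = np.full(n, max(((hi - lo) / (2 * n)) ** 2, 1e-6))
    pi = np.full(n, 1.0 / n)
    wn = w / w.sum()
    prev = -np.inf
    for _ in range(n_iter):
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(np.sum(wn * lse))
        r = np.exp(logp - lse[:, None]) * wn[:, None]
        nk = r.sum(axis=0)
        nk = np.clip(nk, 1e-12, None)
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = np.clip((r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, 1e-6, None)
        pi = nk
        if abs(ll - prev) < tol:
            break
        prev = ll
    order = np.argsort(mu)
    return mu[order], np.sqrt(var[order]), pi[order]


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i : i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_fret_levels(
    segment_levels: np.ndarray,
    weights: np.ndarray | None = None,
    frame_values: np.ndarray | None = None,
    n_levels: int = 3,
    labels: tuple[str, ...] = ("PS", "US", "FS"),
    bins: int = 80,
    min_samples_per_peak: int = 50,
    overlap_sd: float = 1.0,
) -> LevelTable:
    """Calibrate FRET levels from pooled segment mean-E values.

    Peak centers come from a sum-of-Gaussians least-squares fit to the
    histogram of ``segment_levels`` (per-segment mean E pooled over traces,
    optionally weighted by segment length), initialised by a deterministic
    EM mixture. Segment means average the camera noise down, so the level
    clusters stay separated even when one level dominates the occupancy —
    which is what makes this calibration robust where a per-frame histogram
    is not.

    Each level's reported SD is the Gaussian width of the *per-frame* E
    distribution around its center (estimated from ``frame_values`` when
    given, otherwise from the segment-mean fit): this is the noise scale
    that downstream assignment tolerances are measured in. The SE of each
    center is reported from the fit covariance. Peaks closer than
    ``overlap_sd`` combined widths set the ``merged_flag``.
    """
    x = np.asarray(segment_levels, dtype=float)
    if weights is None:
        weights = np.ones_like(x)
    weights = np.asarray(weights, dtype=float)
    if len(x) < n_levels * min_samples_per_peak:
        raise ValueError(
            f"need >= {n_levels * min_samples_per_peak} pooled level samples, got {len(x)}"
        )

    if np.ptp(x) < 1e-9 * max(1.0, abs(float(x[0]))):
        raise ValueError("level samples are constant; no peaks to resolve")

    uniq = np.unique(x)
    if len(uniq) == n_levels:
        # noiseless data: the levels are the unique sample values, exactly
        return _finish_level_table(uniq, [np.nan] * n_levels, frame_values,
                                   n_levels, labels, overlap_sd)
    hist, edges = np.histogram(x, bins=bins, weights=weights, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initial centers: the n_levels most prominent modes of the smoothed
    # histogram (robust to small spurious clusters from over-segmented
    # noise tails); EM fallback when fewer modes are resolved
    from scipy.ndimage import gaussian_filter1d
    from scipy.signal import find_peaks

    smooth = gaussian_filter1d(hist, sigma=1.5)
    pk_idx, props = find_peaks(smooth, prominence=1e-6)
    order = np.argsort(props["prominences"])[::-1][:n_levels]
    mu0 = sorted(float(centers[i]) for i in pk_idx[order])
    if len(mu0) < n_levels:
        mu_em, _, _ = _em_gmm1d(x, weights, n_levels)
        for m_ in mu_em:
            if all(abs(m_ - m) > 0.02 for m in mu0):
                mu0.append(float(m_))
        mu0 = sorted(mu0)[:n_levels]
        while len(mu0) < n_levels:
            mu0.append(mu0[-1] + 0.05)
    gap = min(np.diff(mu0)) if n_levels > 1 else np.ptp(x)
    sd0_val = max(float(gap) / 4.0, 2e-3)
    p0 = []
    for mu in mu0:
        amp = float(smooth[np.argmin(np.abs(centers - mu))])
        p0 += [max(amp, 1e-3), mu, sd0_val]
    lo = [0.0, float(x.min() - 1e-6), 1e-5] * n_levels
    hi = [np.inf, float(x.max() + 1e-6), float(np.ptp(x) + 1e-3)] * n_levels
    p0 = np.clip(p0, lo, hi)
    try:
        popt, pcov = curve_fit(
            _gauss_sum, centers, hist, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        # degenerate histograms (e.g. noiseless spikes): keep the EM solution
        popt = np.asarray(p0, dtype=float)
        perr = np.full(len(p0), np.nan)

    peaks = sorted(
        [(popt[i + 1], popt[i + 2], perr[i + 1]) for i in range(0, 3 * n_levels, 3)]
    )
    mus = np.array([pk[0] for pk in peaks])
    return _finish_level_table(
        mus, [float(pk[2]) for pk in peaks], frame_values, n_levels, labels,
        overlap_sd, fallback_sds=[float(pk[1]) for pk in peaks],
    )


def _finish_level_table(
    mus, ses, frame_values, n_levels, labels, overlap_sd, fallback_sds=None
) -> LevelTable:
    mus = np.asarray(mus, dtype=float)
    if fallback_sds is None:
        fallback_sds = [1e-4] * n_levels
    # per-frame Gaussian width around each center
    if frame_values is not None:
        fv = np.asarray(frame_values, dtype=float)
        fv = fv[np.isfinite(fv)]
        assign = np.argmin(np.abs(fv[:, None] - mus[None, :]), axis=1)
        sds = []
        for i in range(n_levels):
            sel = fv[assign == i]
            if len(sel) >= 10:
                # MAD-based width resists tail frames claimed from neighbours
                sds.append(float(1.4826 * np.median(np.abs(sel - np.median(sel)))))
            else:
                sds.append(float(fallback_sds[i]))
    else:
        sds = list(fallback_sds)
    sds = [max(s, 1e-4) for s in sds]

    merged = any(
        (mus[i + 1] - mus[i]) < overlap_sd * (sds[i] + sds[i + 1])
        for i in range(n_levels - 1)
    )
    if merged:
        import warnings

        warnings.warn("FRET level peaks overlap; merged-level flag set", stacklevel=2)
    rows = [
        (labels[i], float(np.clip(mus[i], 0.0, 1.0)), sds[i], float(ses[i]))
        for i in range(n_levels)
    ]
    return LevelTable(rows, merged_flag=merged)
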
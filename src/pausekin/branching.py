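"""Pathway classification and branching statistics of initial transcription.

After the ITC6 pause a complex either escapes productively to the fully
scrunched state on its first attempt, or enters cyclic unscrunching /
scrunching between US and PS. This module classifies labelled trajectories
into those pathways, estimates the NTP dependence of the first-attempt
escape probability with a hyperbolic isotherm fit, counts state-to-state
transitions, tests dwell-time memory-lessness, and splits NTP-withdrawal
runs into US/PS and US/PS/FS cycler subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

from .dwells import ExpMixtureFit, extract_dwells, fit_exp_mixture
from .segment import LabeledPath

__all__ = [
    "TrajectoryClass",
    "IsothermFit",
    "TransitionCounts",
    "MemoryTestResult",
    "WithdrawalResult",
    "classify_trajectories",
    "first_attempt_probability",
    "fit_isotherm",
    "transition_histogram",
    "dwell_memory_test",
    "withdrawal_subpopulations",
    "pretranslocated_slowdown",
]

CLASSES = (
    "single_scrunch_with_pause",
    "single_scrunch_no_pause",
    "cycling_then_FS",
    "cycling_only",
    "inactive",
)


@dataclass
class TrajectoryClass:
    """Pathway assignment for one trajectory.

    ``cls`` is one of :data:`CLASSES`, or ``None`` when classification was
    withheld (``reason`` says why). ``n_attempts`` counts PS -> US returns
    before the fully scrunched level is first reached; ``paused`` records
    whether a detectable ITC6 pause (PS dwell of at least the minimum
    length) preceded the first FS arrival.
    """

    trace_id: str
    cls: str | None
    n_attempts: int = 0
    paused: bool = False
    reason: str = ""
    subpopulation: str | None = None


def _merged_labels(path: LabeledPath) -> list[tuple[str, float]]:
    """(label, duration) sequence, unassigned dropped, same-label runs merged."""
    out: list[list] = []
    for s in path.segments:
        if s.label == "unassigned":
            continue
        if out and out[-1][0] == s.label:
            out[-1][1] += s.duration_s
        else:
            out.append([s.label, s.duration_s])
    return [(lab, dur) for lab, dur in out]


def _clip_after(path: LabeledPath, t: float) -> list[tuple[str, float]]:
    """Merged label sequence restricted to times >= t.

    The state occupied just before ``t`` is kept as a zero-duration leading
    marker, so a level change happening exactly at ``t`` still counts as a
    post-injection transition.
    """
    out: list[list] = []
    pre_label = None
    for s in path.segments:
        if s.label == "unassigned":
            continue
        end = s.start_s + s.duration_s
        if end <= t:
            pre_label = s.label
            continue
        if not out and pre_label is not None and pre_label != s.label:
            out.append([pre_label, 0.0])
        dur = end - max(s.start_s, t)
        if out and out[-1][0] == s.label:
            out[-1][1] += dur
        else:
            out.append([s.label, dur])
    return [(lab, dur) for lab, dur in out]


def classify_trajectories(
    paths: list[LabeledPath],
    min_pause_frames: int = 2,
    frame_time: float = 0.2,
    t_injection: float | None = None,
) -> list[TrajectoryClass]:
    """Deterministic pathway classification of labelled trajectories.

    Rules on the post-injection label sequence: reaching FS with zero
    PS -> US returns is a single-scrunch trajectory (with or without a
    detectable pause, depending on whether a PS dwell of at least
    ``min_pause_frames`` frames preceded FS); one or more returns followed
    by FS is ``cycling_then_FS``; returns without ever reaching FS is
    ``cycling_only`` (bleach-truncated cyclers included); no post-injection
    transitions is ``inactive``. Unassigned-dominated paths, and paths
    truncated inside their first pause before either outcome, have their
    class withheld with a reason.
    """
    min_pause_s = min_pause_frames * frame_time
    out: list[TrajectoryClass] = []
    for path in paths:
        if path.flagged:
            out.append(TrajectoryClass(path.trace_id, None, reason="unassigned-dominated"))
            continue
        t0 = t_injection
        if t0 is None:
            t0 = float(path.metadata.get("t_injection_s", 0.0))
        seq = _clip_after(path, t0) if t0 > 0 else _merged_labels(path)
        labels = [lab for lab, _ in seq]
        if len(set(labels)) <= 1:
            out.append(TrajectoryClass(path.trace_id, "inactive"))
            continue

        first_fs = labels.index("FS") if "FS" in labels else None
        upto = labels if first_fs is None else labels[: first_fs + 1]
        returns = sum(
            1 for a, b in zip(upto[:-1], upto[1:]) if a == "PS" and b == "US"
        )
        paused = any(
            lab == "PS" and dur >= min_pause_s
            for (lab, dur) in (seq if first_fs is None else seq[: first_fs + 1])
        )

        if first_fs is not None:
            if returns == 0:
                cls = "single_scrunch_with_pause" if paused else "single_scrunch_no_pause"
            else:
                cls = "cycling_then_FS"
            out.append(TrajectoryClass(path.trace_id, cls, returns, paused))
        elif returns >= 1:
            out.append(TrajectoryClass(path.trace_id, "cycling_only", returns, paused))
        else:
            # entered the pause but truncated before escape or return
            out.append(
                TrajectoryClass(path.trace_id, None, 0, paused, reason="unresolved")
            )
    return out


def first_attempt_probability(
    classes: list[TrajectoryClass],
) -> tuple[float, tuple[float, float], int]:
    """Probability of reaching FS in a single attempt, with Wilson 95% CI.

    p = #single-scrunch / (#single-scrunch + #cycling); inactive and
    withheld trajectories do not enter the denominator.
    """
    single = sum(1 for c in classes if c.cls in
                 ("single_scrunch_with_pause", "single_scrunch_no_pause"))
    cycling = sum(1 for c in classes if c.cls in ("cycling_then_FS", "cycling_only"))
    n = single + cycling
    if n == 0:
        raise ValueError("no pause-resolving trajectories to form a probability")
    lo, hi = proportion_confint(single, n, alpha=0.05, method="wilson")
    return single / n, (float(lo), float(hi)), n


# ---------------------------------------------------------------------------
# escape isotherm


@dataclass
class IsothermFit:
    """Hyperbolic fit p(NTP) = P_max * NTP / (NTP + K_NTP)."""

    K_ntp: float
    P_max: float
    K_sd: float
    P_sd: float
    residuals: np.ndarray
    ntp: np.ndarray

    def __post_init__(self) -> None:
        if self.K_ntp <= 0:
            raise ValueError(f"K_NTP must be > 0, got {self.K_ntp}")
        if not 0.0 <= self.P_max <= 1.0:
            raise ValueError(f"P_max must lie in [0, 1], got {self.P_max}")

    def predict(self, ntp) -> np.ndarray:
        ntp = np.asarray(ntp, dtype=float)
        return self.P_max * ntp / (ntp + self.K_ntp)


def _isotherm(ntp, p_max, k):
    return p_max * ntp / (ntp + k)


def fit_isotherm(
    points: list[tuple[float, float, tuple[float, float] | None]],
    weighted: bool = True,
) -> IsothermFit:
    """Fit the first-attempt escape probabilities to a binding isotherm.

    ``points`` are ``(ntp_uM, p, ci)`` with ``ci`` the 95% interval (or
    None). Weighted least squares uses the inverse squared CI half-width;
    parameter SDs come from the fit covariance. Requires at least four
    distinct concentrations and identifiable curvature (errors out when all
    points sit on the saturated plateau).
    """
    ntp = np.array([pt[0] for pt in points], dtype=float)
    p = np.array([pt[1] for pt in points], dtype=float)
    if len(np.unique(ntp)) < 4:
        raise ValueError("need >= 4 distinct NTP concentrations")
    sigma = None
    if weighted and all(pt[2] is not None for pt in points):
        hw = np.array([(pt[2][1] - pt[2][0]) / 2.0 for pt in points])
        sigma = np.clip(hw, 1e-3, None)
    if p.max() - p.min() < 0.05 * max(p.max(), 1e-9):
        raise ValueError("K not constrained: all points saturated")
    p0 = (min(max(p.max(), 0.05), 1.0), float(np.median(ntp)))
    popt, pcov = curve_fit(
        _isotherm, ntp, p, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        bounds=([0.0, 1e-6], [1.0, 1e6]), maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)):
        raise ValueError("K not constrained: singular fit covariance")
    resid = p - _isotherm(ntp, *popt)
    return IsothermFit(float(popt[1]), float(popt[0]), float(perr[1]), float(perr[0]),
                       resid, ntp)


# ---------------------------------------------------------------------------
# transition counting


@dataclass
class TransitionCounts:
    """Ordered-pair counts of consecutive dwell transitions between levels."""

    labels: tuple[str, ...]
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over the labels")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero: adjacent dwells differ")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    def frequency(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot else self.counts.astype(float)

    def count(self, frm: str, to: str) -> int:
        return int(self.counts[self.labels.index(frm), self.labels.index(to)])


def transition_histogram(
    paths: list[LabeledPath], labels: tuple[str, ...] = ("US", "PS", "FS")
) -> TransitionCounts:
    """Count consecutive dwell-to-dwell transitions over all paths."""
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for path in paths:
        seq = [lab for lab, _ in _merged_labels(path) if lab in idx]
        for a, b in zip(seq[:-1], seq[1:]):
            if a != b:
                counts[idx[a], idx[b]] += 1
    return TransitionCounts(tuple(labels), counts)


# ---------------------------------------------------------------------------
# dwell-time memory test


@dataclass
class MemoryTestResult:
    rho: float
    p_value: float
    n_pairs: int
    reason: str | None = None


def dwell_memory_test(
    paths: list[LabeledPath],
    state: str,
    n_perm: int = 10_000,
    seed: int = 0,
    min_pairs: int = 50,
) -> MemoryTestResult:
    """Rank correlation between successive visits to ``state``.

    Pools pairs (dt_n, dt_{n+1}) of consecutive dwells in ``state`` within
    each trace; first and last dwells of each trace are excluded
    (incomplete). Significance is a two-sided permutation test on the
    Spearman correlation with ``n_perm`` shuffles of the successor dwells,
    seeded for reproducibility. A memory-less process gives rho near 0 (the
    fast/slow character of a visit carries no information about the next),
    while deterministic alternation gives strong negative rho. Degenerate
    (constant) dwell lists are reported as NA with a reason.
    """
    x, y = [], []
    for path in paths:
        seq = _merged_labels(path)
        visits = [dur for lab, dur in seq[1:-1] if lab == state]
        for a, b in zip(visits[:-1], visits[1:]):
            x.append(a)
            y.append(b)
    n = len(x)
    if n < min_pairs:
        raise ValueError(f"need >= {min_pairs} consecutive dwell pairs, got {n}")
    x = np.asarray(x)
    y = np.asarray(y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return MemoryTestResult(float("nan"), float("nan"), n,
                                reason="degenerate: constant dwell list")
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = (rx - rx.mean()) / rx.std()
    ryc = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rxc * ryc))
    rng = np.random.default_rng(seed)
    perm = np.array([np.mean(rxc * rng.permutation(ryc)) for _ in range(n_perm)])
    p = float((np.sum(np.abs(perm) >= abs(rho)) + 1) / (n_perm + 1))
    return MemoryTestResult(rho, p, n)


# ---------------------------------------------------------------------------
# NTP-withdrawal subpopulations


@dataclass
class WithdrawalResult:
    """Subpopulation shares and per-subpopulation dwell kinetics."""

    assignments: dict[str, str]  # trace_id -> US/PS | US/PS/FS | none
    fractions: dict[str, tuple[float, tuple[float, float]]]
    fits: dict[tuple[str, str], ExpMixtureFit]  # (subpop, state) -> fit
    n_cyclers: int


def withdrawal_subpopulations(
    paths: list[LabeledPath],
    m: int = 2,
    restarts: int = 20,
    seed: int = 0,
    min_dwells: int = 25,
) -> WithdrawalResult:
    """Split NTP-withdrawal cyclers by the set of FRET levels they visit.

    Molecules visiting only US and PS form the ``US/PS`` subpopulation
    (6-mer RNA at withdrawal); molecules additionally sampling FS form
    ``US/PS/FS`` (11-mer). Traces visiting fewer than two levels are
    excluded (``none``). Per subpopulation and state, dwells are pooled and
    fitted with an ``m``-exponential mixture where sample size permits.
    """
    assignments: dict[str, str] = {}
    groups: dict[str, list[LabeledPath]] = {"US/PS": [], "US/PS/FS": []}
    for path in paths:
        visited = {lab for lab, _ in _merged_labels(path)}
        if "FS" in visited and {"US", "PS"} <= visited:
            assignments[path.trace_id] = "US/PS/FS"
            groups["US/PS/FS"].append(path)
        elif visited == {"US", "PS"}:
            assignments[path.trace_id] = "US/PS"
            groups["US/PS"].append(path)
        else:
            assignments[path.trace_id] = "none"

    n_cyc = len(groups["US/PS"]) + len(groups["US/PS/FS"])
    fractions: dict[str, tuple[float, tuple[float, float]]] = {}
    for sub in ("US/PS", "US/PS/FS"):
        k = len(groups[sub])
        if n_cyc:
            lo, hi = proportion_confint(k, n_cyc, alpha=0.05, method="wilson")
            fractions[sub] = (k / n_cyc, (float(lo), float(hi)))
        else:
            fractions[sub] = (float("nan"), (float("nan"), float("nan")))

    fits: dict[tuple[str, str], ExpMixtureFit] = {}
    for sub, members in groups.items():
        if not members:
            continue
        states = ("US", "PS") if sub == "US/PS" else ("US", "PS", "FS")
        for st in states:
            try:
                ds = extract_dwells(members, st)
            except ValueError:
                continue
            if ds.N < max(min_dwells, 5 * (2 * m - 1)):
                continue
            fits[(sub, st)] = fit_exp_mixture(ds, m, restarts=restarts, seed=seed)
    return WithdrawalResult(assignments, fractions, fits, n_cyc)


def pretranslocated_slowdown(
    t_initiation: float = 2.3, t_elongation: float = 0.0087
) -> float:
    """Fold-change between pre-translocated lifetimes in initiation vs elongation.

    The ITC6 pre-translocated state lives ~2.3 s (1/0.43 of the fastest
    observed pause exit) against ~8.7 ms during elongation — a ~265-fold
    slowdown imposed by the sigma3.2 translocation barrier.
    """
    if t_initiation <= 0 or t_elongation <= 0:
        raise ValueError("lifetimes must be positive")
    return t_initiation / t_elongation
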
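"""Exponential-mixture maximum likelihood for pooled dwell times.

State dwell times pooled over molecules are modelled by a mixture of ``m``
exponentials,

    p_t(tau) = sum_{n=1..m} p_n * k_n * exp(-k_n * tau),

with rates ``k_n`` and mixture probabilities ``p_n`` (sum 1). Parameters
are the maximisers of the log-likelihood L = sum_i ln p_t(tau_i); the
number of components is chosen by the Bayes–Schwarz information criterion
BIC = -2 L + (2m - 1) ln N, and parameter uncertainties are one standard
deviation over nonparametric bootstrap refits.

The first dwell of every trace (preceding NTP addition) and the last
(truncated by photobleaching or by the transition out of the observation
window) are excluded from pooling, so the fitted dwells are complete
observations; Eq. fitting therefore carries no censoring term by default
(a survival-term option exists for right-censored dwells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .segment import LabeledPath

__all__ = [
    "DwellSet",
    "ExpMixtureFit",
    "exp_mixture_pdf",
    "exp_mixture_logpdf",
    "exp_mixture_sf",
    "extract_dwells",
    "fit_exp_mixture",
    "select_m_bic",
    "bootstrap_sd",
    "pause_exit_rate",
]

#: Rate floor/ceiling (1/s). Frame time and record length bound what is
#: observable; the box keeps the optimizer off divergent boundaries.
K_MIN, K_MAX = 1e-4, 1e3


@dataclass
class DwellSet:
    """Pooled dwell times for one observable state."""

    state: str
    tau: np.ndarray
    censored: np.ndarray | None = None
    trace_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(len(self.tau), dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.tau <= 0):
            raise ValueError("dwell times must be strictly positive")
        if len(self.censored) != len(self.tau):
            raise ValueError("censoring flags must match dwell count")

    @property
    def N(self) -> int:
        return len(self.tau)


@dataclass
class ExpMixtureFit:
    """MLE of an m-exponential dwell-time mixture.

    Rates are sorted descending (fast component first); ``k_sd`` / ``p_sd``
    are filled by :func:`bootstrap_sd`.
    """

    m: int
    k: np.ndarray
    p: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool = True
    n_restarts: int = 1
    k_sd: np.ndarray | None = None
    p_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.k) != self.m or len(self.p) != self.m:
            raise ValueError("k and p must have length m")
        if np.any(self.k <= 0):
            raise ValueError("rates must be positive")
        if self.m > 1 and np.any(np.diff(self.k) >= 0):
            raise ValueError("rates must be strictly descending")
        if abs(self.p.sum() - 1.0) > 1e-10 or np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("weights must lie in (0, 1] and sum to 1")
        if not np.isfinite(self.bic):
            raise ValueError("BIC must be finite")

    @property
    def mean_dwell(self) -> float:
        return float(np.sum(self.p / self.k))


def exp_mixture_logpdf(tau, k, p) -> np.ndarray:
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    return logsumexp(
        np.log(p)[None, :] + np.log(k)[None, :] - k[None, :] * tau[:, None], axis=1
    )


def exp_mixture_pdf(tau, k, p) -> np.ndarray:
    return np.exp(exp_mixture_logpdf(tau, k, p))


def exp_mixture_sf(tau, k, p) -> np.ndarray:
    """Survival function sum_n p_n exp(-k_n tau)."""
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    return np.exp(logsumexp(np.log(p)[None, :] - k[None, :] * tau[:, None], axis=1))


# ---------------------------------------------------------------------------
# dwell pooling


def extract_dwells(
    paths: list[LabeledPath], state: str, skip_first_visit: bool = False
) -> DwellSet:
    """Pool interior dwells of ``state`` over labelled paths.

    The first and last dwell of every trace are dropped: the first precedes
    NTP addition and the last is truncated by photobleaching or by leaving
    the observation window, so neither is a complete, unbiased dwell.
    ``unassigned`` segments never contribute. ``skip_first_visit``
    additionally drops the first interior visit to ``state`` in each trace
    (used to keep the initial ITC6 pause out of cycling-dwell pools, whose
    exit law differs from the cycling kinetics). Raises if no interior
    dwell of the requested state exists.
    """
    if len(paths) == 0:
        raise ValueError("extract_dwells requires at least one path")
    taus: list[float] = []
    ids: list[str] = []
    for path in paths:
        segs = [s for s in path.segments if s.label != "unassigned"]
        # merge adjacent same-label survivors so one visit is one dwell
        merged: list[list] = []
        for s in segs:
            if merged and merged[-1][0] == s.label:
                merged[-1][1] += s.duration_s
            else:
                merged.append([s.label, s.duration_s])
        skipped = not skip_first_visit
        for lab, dur in merged[1:-1]:
            if lab == state:
                if not skipped:
                    skipped = True
                    continue
                taus.append(dur)
                ids.append(path.trace_id)
    if not taus:
        raise ValueError(f"no interior dwells for state {state!r}")
    return DwellSet(state, np.array(taus), trace_ids=ids)


# ---------------------------------------------------------------------------
# mixture MLE


def _neg_loglik(theta: np.ndarray, tau: np.ndarray, m: int, t_min: float = 0.0) -> float:
    logk = theta[:m]
    a = theta[m:]
    logp = np.concatenate([a, [0.0]])
    logp = logp - logsumexp(logp)
    k = np.exp(logk)
    ll = logsumexp(logp[None, :] + logk[None, :] - k[None, :] * tau[:, None], axis=1)
    if t_min > 0:
        # left truncation at the detection floor: density renormalised by
        # the mixture survival at t_min
        ll = ll - logsumexp(logp - k * t_min)
    return -float(np.sum(ll))


def _censored_neg_loglik(theta, tau, cens, m):
    logk = theta[:m]
    a = theta[m:]
    logp = np.concatenate([a, [0.0]])
    logp = logp - logsumexp(logp)
    k = np.exp(logk)
    obs = logsumexp(logp[None, :] + logk[None, :] - k[None, :] * tau[:, None], axis=1)
    surv = logsumexp(logp[None, :] - k[None, :] * tau[:, None], axis=1)
    return -float(np.sum(np.where(cens, surv, obs)))


def fit_exp_mixture(
    dwells: DwellSet,
    m: int,
    restarts: int = 20,
    seed: int | np.random.Generator = 0,
    include_censored: bool = False,
    t_min: float = 0.0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> ExpMixtureFit:
    """Maximum-likelihood fit of an m-exponential mixture.

    The optimisation runs in log-rate / logit-weight space (rates boxed to
    [1e-4, 1e3] 1/s) with ``restarts`` random initialisations whose rates
    are spread over the dwell quantiles around 1/mean; the best restart is
    returned with rates sorted descending. For ``m = 1`` the closed form
    k = 1/mean(tau) is exact and is used directly.

    ``t_min > 0`` fits a left-truncated mixture: dwells shorter than the
    detection floor (steps below the minimum segment length are invisible
    by construction) never enter the pool, so the density is renormalised
    by the survival at ``t_min``. Without it the fast rate is biased low.
    ``include_censored=True`` adds survival terms ln S(tau) for dwells
    flagged right-censored; by default censored dwells are excluded.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    tau = dwells.tau if include_censored else dwells.tau[~dwells.censored]
    cens = dwells.censored if include_censored else np.zeros(len(tau), dtype=bool)
    if t_min > 0:
        keep = tau > t_min
        tau, cens = tau[keep], cens[keep]
    N = len(tau)
    if N < 5 * (2 * m - 1):
        raise ValueError(f"need N >= {5 * (2 * m - 1)} dwells for m={m}, got {N}")

    if m == 1 and not include_censored:
        # truncated-exponential MLE: k = 1 / (mean - t_min)
        k = float(np.clip(1.0 / max(np.mean(tau) - t_min, 1e-12), K_MIN, K_MAX))
        ll = float(np.sum(np.log(k) - k * (tau - t_min)))
        bic = -2.0 * ll + 1.0 * np.log(N)
        return ExpMixtureFit(1, [k], [1.0], ll, bic, N)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = [(np.log(K_MIN), np.log(K_MAX))] * m + [(-12.0, 12.0)] * (m - 1)
    fun = (
        (lambda th: _censored_neg_loglik(th, tau, cens, m))
        if include_censored
        else (lambda th: _neg_loglik(th, tau, m, t_min))
    )

    inits = []
    if init is not None:
        k0, p0 = np.asarray(init[0], float), np.asarray(init[1], float)
        a0 = np.log(p0[:-1] / p0[-1])
        inits.append(np.concatenate([np.log(k0), a0]))
    base = 1.0 / np.mean(tau)
    for r in range(restarts):
        if r == 0:
            # deterministic spread: rates at 1/quantiles of the data
            qs = np.quantile(tau, (np.arange(m) + 0.5) / m)[::-1]
            k0 = np.clip(1.0 / qs, K_MIN, K_MAX)
            a0 = np.zeros(m - 1)
        else:
            k0 = np.clip(base * np.exp(rng.normal(0.0, 2.0, m)), K_MIN, K_MAX)
            a0 = rng.normal(0.0, 1.0, m - 1)
        inits.append(np.concatenate([np.log(np.sort(k0)[::-1]), a0]))

    best = None
    n_ok = 0
    for th0 in inits:
        res = minimize(fun, th0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"exponential-mixture MLE failed to converge in {len(inits)} restarts (m={m})"
        )

    logk = best.x[:m]
    a = np.concatenate([best.x[m:], [0.0]])
    p = np.exp(a - logsumexp(a))
    k = np.exp(logk)
    order = np.argsort(-k)
    k, p = k[order], p[order]
    # collapse numerically duplicate rates so ordering stays strict
    k = _break_rate_ties(k)
    ll = -float(best.fun)
    bic = -2.0 * ll + (2 * m - 1) * np.log(N)
    return ExpMixtureFit(m, k, p / p.sum(), ll, bic, N, converged=bool(best.success),
                         n_restarts=n_ok)


def _break_rate_ties(k: np.ndarray) -> np.ndarray:
    k = k.copy()
    for i in range(1, len(k)):
        if k[i] >= k[i - 1]:
            k[i] = k[i - 1] * (1.0 - 1e-9)
    return k


def select_m_bic(
    dwells: DwellSet,
    m_max: int,
    restarts: int = 20,
    seed: int = 0,
    t_min: float = 0.0,
) -> tuple[int, dict[int, ExpMixtureFit], list[str]]:
    """Choose the number of exponentials by BIC.

    Returns ``(m_star, fits, notices)``: the BIC-minimising component count
    (ties break to the smaller m), all candidate fits, and notices for
    skipped candidates (m whose parameter count exceeds N/5).
    """
    if m_max < 1:
        raise ValueError(f"m_max must be >= 1, got {m_max}")
    fits: dict[int, ExpMixtureFit] = {}
    notices: list[str] = []
    for m in range(1, m_max + 1):
        if dwells.N < 5 * (2 * m - 1):
            notices.append(f"m={m} skipped: N={dwells.N} < {5 * (2 * m - 1)}")
            continue
        fits[m] = fit_exp_mixture(dwells, m, restarts=restarts, seed=seed + m,
                                  t_min=t_min)
    if not fits:
        raise ValueError("no candidate model satisfies the sample-size guard")
    m_star = min(fits, key=lambda m: (round(fits[m].bic, 12), m))
    return m_star, fits, notices


def bootstrap_sd(
    dwells: DwellSet,
    m: int,
    B: int = 1000,
    seed: int = 0,
    restarts: int = 3,
    t_min: float = 0.0,
    fit: ExpMixtureFit | None = None,
) -> ExpMixtureFit:
    """Nonparametric bootstrap SDs for the mixture parameters.

    ``B`` resamples with replacement of size N are refit (initialised at the
    point estimate plus a few random restarts); per-parameter SDs are taken
    over the resample estimates after matching components by descending
    rate. Returns the point fit with ``k_sd`` and ``p_sd`` attached;
    reproducible for a fixed seed. Warns if more than 5% of refits fail.
    """
    if fit is None:
        fit = fit_exp_mixture(dwells, m, seed=seed, t_min=t_min)
    rng = np.random.default_rng(seed)
    ks, ps = [], []
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, dwells.N, dwells.N)
        resample = DwellSet(dwells.state, dwells.tau[idx])
        try:
            f = fit_exp_mixture(
                resample, m, restarts=restarts, seed=rng, t_min=t_min,
                init=(fit.k, fit.p)
            )
            ks.append(f.k)
            ps.append(f.p)
        except (RuntimeError, ValueError):
            failures += 1
    if failures > 0.05 * B:
        warnings.warn(f"{failures}/{B} bootstrap refits failed", stacklevel=2)
    fit.k_sd = np.std(np.array(ks), axis=0)
    fit.p_sd = np.std(np.array(ps), axis=0)
    return fit


def pause_exit_rate(
    single_scrunch_paths: list[LabeledPath],
    B: int = 1000,
    seed: int = 0,
    min_dwells: int = 30,
    t_min: float = 0.0,
) -> ExpMixtureFit:
    """Single-exponential exit rate of the initial pause (k_ITC6).

    Input paths must already be restricted to single-scrunch trajectories
    (US -> PS -> FS without returns); their PS dwell is the pause duration.
    Fits m = 1 by MLE and attaches bootstrap SDs.
    """
    if len(single_scrunch_paths) == 0:
        raise ValueError("no single-scrunch trajectories supplied")
    ds = extract_dwells(single_scrunch_paths, "PS")
    if ds.N < min_dwells:
        raise ValueError(f"need >= {min_dwells} pause dwells, got {ds.N}")
    fit = fit_exp_mixture(ds, 1, seed=seed, t_min=t_min)
    return bootstrap_sd(ds, 1, B=B, seed=seed, t_min=t_min, fit=fit)
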
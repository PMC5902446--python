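"""Branching kinetic schemes for initial transcription.

The central object is :class:`KineticScheme`, a continuous-time Markov chain
over hidden kinetic states, each of which displays one of three observable
FRET levels: US (unscrunched open complex RP_O), PS (partly scrunched paused
complex ITC6), FS (fully scrunched ITC11, pause cleared).

The default scheme implements a branching model of initial transcription:
after NTP addition the complex synthesises a 6-mer and pauses (PS level).
Pause exit is a single-exponential process with rate ``k_itc6``; on exit the
complex either escapes productively to FS, with NTP-dependent probability

    p(NTP) = P_max * [NTP] / ([NTP] + K_NTP),

or enters a futile unscrunching/scrunching cycle between US and PS levels.
Each cycling observable is backed by two hidden substates with exit rates
``k1`` (fast) and ``k2`` (slow), entered with probabilities ``p_k1`` and
``1 - p_k1`` and re-sampled independently at each visit, which makes the
observable dwell times two-exponential and memory-less.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "State",
    "KineticScheme",
    "SchemeValidationError",
    "FRET_LEVELS",
    "escape_probability",
    "build_default_scheme",
    "build_cycler_scheme",
    "build_withdrawal_scheme",
]

#: Calibrated observable FRET levels (apparent FRET efficiency).
FRET_LEVELS = {"US": 0.49, "PS": 0.37, "FS": 0.80}


class SchemeValidationError(ValueError):
    """Raised when a kinetic scheme violates a structural invariant."""


@dataclass(frozen=True)
class State:
    """One hidden kinetic state.

    Parameters
    ----------
    name : str
        Unique identifier of the hidden state (e.g. ``"US_fast"``).
    tag : str
        Observable level tag: ``US``, ``PS``, ``FS`` or ``absorbing``
        (no signal; molecule departed).
    fret : float
        Apparent FRET efficiency displayed while in this state.
    absorbing : bool
        True if the state has no outgoing transitions by design.
    """

    name: str
    tag: str
    fret: float
    absorbing: bool = False


@dataclass
class KineticScheme:
    """A continuous-time Markov chain with observable FRET levels.

    Attributes
    ----------
    states : list of State
    transitions : list of (from_name, to_name, rate_per_s)
    initial : dict
        Initial-state distribution ``{state name: probability}``.
    ntp_branching : tuple or None
        ``(K_NTP in µM, P_max)`` of the escape isotherm used to build the
        scheme, kept as metadata; the branching is already baked into the
        transition rates.
    ntp : float or None
        NTP concentration (µM) the rates were built for.
    """

    states: list[State]
    transitions: list[tuple[str, str, float]]
    initial: dict[str, float]
    ntp_branching: tuple[float, float] | None = None
    ntp: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def state(self, name: str) -> State:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def exit_rate(self, name: str) -> float:
        return float(sum(r for f, _, r in self.transitions if f == name))

    def level_map(self) -> dict[str, float]:
        """Map each observable tag to its (unique) FRET level."""
        levels: dict[str, float] = {}
        for s in self.states:
            if s.tag == "absorbing":
                continue
            if s.tag in levels and levels[s.tag] != s.fret:
                raise SchemeValidationError(
                    f"tag {s.tag!r} maps to two FRET levels "
                    f"({levels[s.tag]} and {s.fret})"
                )
            levels[s.tag] = s.fret
        return levels

    def validate(self) -> None:
        names = self.state_names
        if len(set(names)) != len(names):
            raise SchemeValidationError("states: duplicate state names")
        for f, t, r in self.transitions:
            if f not in names or t not in names:
                raise SchemeValidationError(
                    f"transitions: unknown state in ({f!r}, {t!r})"
                )
            if not np.isfinite(r) or r < 0:
                raise SchemeValidationError(
                    f"transitions: rate {f}->{t} must be >= 0, got {r}"
                )
        for name, p in self.initial.items():
            if name not in names:
                raise SchemeValidationError(f"initial: unknown state {name!r}")
            if p < 0:
                raise SchemeValidationError(f"initial: negative weight for {name!r}")
        tot = sum(self.initial.values())
        if abs(tot - 1.0) > 1e-12:
            raise SchemeValidationError(f"initial: distribution sums to {tot}, not 1")
        for s in self.states:
            if not s.absorbing and self.exit_rate(s.name) <= 0:
                raise SchemeValidationError(
                    f"states: non-absorbing state {s.name!r} has zero exit rate"
                )
        if self.ntp_branching is not None:
            k_ntp, p_max = self.ntp_branching
            if k_ntp <= 0:
                raise SchemeValidationError(f"ntp_branching: K_NTP must be > 0, got {k_ntp}")
            if not 0 <= p_max <= 1:
                raise SchemeValidationError(
                    f"ntp_branching: P_max must lie in [0, 1], got {p_max}"
                )
        self.level_map()  # raises on ambiguous tag -> level mapping

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": [
                {"name": s.name, "tag": s.tag, "fret": s.fret, "absorbing": s.absorbing}
                for s in self.states
            ],
            "transitions": [[f, t, r] for f, t, r in self.transitions],
            "initial": dict(self.initial),
            "ntp_branching": list(self.ntp_branching) if self.ntp_branching else None,
            "ntp": self.ntp,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            states=[State(**s) for s in d["states"]],
            transitions=[tuple(t) for t in d["transitions"]],
            initial=dict(d["initial"]),
            ntp_branching=tuple(d["ntp_branching"]) if d.get("ntp_branching") else None,
            ntp=d.get("ntp"),
            params=d.get("params", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def escape_probability(ntp: float, k_ntp: float, p_max: float) -> float:
    """Probability that a pause exit is productive at NTP concentration ``ntp``.

    Hyperbolic binding isotherm ``p = P_max * ntp / (ntp + K_NTP)`` with
    apparent half-saturation ``K_NTP`` (µM) and asymptote ``P_max``.
    """
    if k_ntp <= 0:
        raise SchemeValidationError(f"K_ntp must be > 0, got {k_ntp}")
    if not 0 <= p_max <= 1:
        raise SchemeValidationError(f"P_max must lie in [0, 1], got {p_max}")
    if ntp < 0:
        raise SchemeValidationError(f"ntp must be >= 0, got {ntp}")
    return p_max * ntp / (ntp + k_ntp)


def _require_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise SchemeValidationError(f"{name} must be a positive rate, got {value}")


def _require_prob(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise SchemeValidationError(f"{name} must lie in [0, 1], got {value}")


def build_default_scheme(
    k_itc6: float = 0.11,
    K_ntp: float = 28.0,
    P_max: float = 0.79,
    k1: float = 0.15,
    k2: float = 0.02,
    P_k1: float = 0.6,
    ntp: float = 80.0,
    fret_levels: dict[str, float] | None = None,
) -> KineticScheme:
    """Build the branching initiation scheme at a given NTP concentration.

    The chain starts in the ITC6 pause (PS level). The pause exits with rate
    ``k_itc6``; with probability ``p(ntp)`` the exit is productive (to the
    absorbing-in-practice FS state) and otherwise the complex enters
    US/PS cycling. Each cycling observable (US and PS) is represented by a
    fast and a slow hidden substate (exit rates ``k1 > k2``), entered with
    probabilities ``P_k1`` / ``1 - P_k1``; every cycling PS exit branches to
    FS with the same isotherm probability ``p(ntp)``, so complexes eventually
    clear the pause after a variable number of attempts.

    Defaults are the wild-type promoter / ApA parameters: ``k_itc6 = 0.11``
    s⁻¹, ``K_NTP = 28`` µM, ``P_max = 0.79``, cycling rates ``k1 = 0.15``
    and ``k2 = 0.02`` s⁻¹ with ``P(k1) = 0.6``.
    """
    _require_rate("k_itc6", k_itc6)
    _require_rate("k1", k1)
    _require_rate("k2", k2)
    if not k1 > k2:
        raise SchemeValidationError(f"k1 must exceed k2, got k1={k1}, k2={k2}")
    _require_prob("P_max", P_max)
    _require_prob("P_k1", P_k1)
    if ntp < 0:
        raise SchemeValidationError(f"ntp must be >= 0, got {ntp}")

    lv = dict(FRET_LEVELS if fret_levels is None else fret_levels)
    p = escape_probability(ntp, K_ntp, P_max)

    states = [
        State("ITC6", "PS", lv["PS"]),
        State("US_fast", "US", lv["US"]),
        State("US_slow", "US", lv["US"]),
        State("PS_fast", "PS", lv["PS"]),
        State("PS_slow", "PS", lv["PS"]),
        State("FS", "FS", lv["FS"], absorbing=True),
    ]

    def cycle_entry(frm: str, k: float, weight: float) -> list[tuple[str, str, float]]:
        # enter the US cycling observable, split fast/slow
        return [
            (frm, "US_fast", k * weight * P_k1),
            (frm, "US_slow", k * weight * (1.0 - P_k1)),
        ]

    transitions: list[tuple[str, str, float]] = []
    # initial pause: productive escape vs cycling entry
    transitions.append(("ITC6", "FS", k_itc6 * p))
    transitions += cycle_entry("ITC6", k_itc6, 1.0 - p)
    # US cycling -> PS cycling
    for us, k in (("US_fast", k1), ("US_slow", k2)):
        transitions.append((us, "PS_fast", k * P_k1))
        transitions.append((us, "PS_slow", k * (1.0 - P_k1)))
    # PS cycling: renewed escape attempt vs return to US
    for ps, k in (("PS_fast", k1), ("PS_slow", k2)):
        transitions.append((ps, "FS", k * p))
        transitions += cycle_entry(ps, k, 1.0 - p)
    transitions = [(f, t, r) for f, t, r in transitions if r > 0]

    return KineticScheme(
        states=states,
        transitions=transitions,
        initial={"ITC6": 1.0},
        ntp_branching=(K_ntp, P_max),
        ntp=ntp,
        params={
            "k_itc6": k_itc6, "K_ntp": K_ntp, "P_max": P_max,
            "k1": k1, "k2": k2, "P_k1": P_k1, "ntp": ntp,
        },
    )


def build_cycler_scheme(
    tags: list[str],
    branch: dict[str, dict[str, float]],
    k1: float,
    k2: float,
    P_k1: float,
    start: str | None = None,
    fret_levels: dict[str, float] | None = None,
) -> KineticScheme:
    """Build a pure cycling scheme over observable ``tags``.

    Each observable is backed by fast/slow substates (``k1``/``k2``, entry
    probability ``P_k1`` for the fast one). ``branch[a][b]`` is the
    probability that an exit from observable ``a`` lands in observable ``b``
    (rows must sum to 1, diagonal 0). No absorbing escape: the molecule
    cycles until the record ends or a dye bleaches.
    """
    _require_rate("k1", k1)
    _require_rate("k2", k2)
    if not k1 > k2:
        raise SchemeValidationError(f"k1 must exceed k2, got k1={k1}, k2={k2}")
    _require_prob("P_k1", P_k1)
    lv = dict(FRET_LEVELS if fret_levels is None else fret_levels)
    for a, row in branch.items():
        tot = sum(row.values())
        if abs(tot - 1.0) > 1e-9:
            raise SchemeValidationError(f"branch[{a!r}] rows must sum to 1, got {tot}")
        if row.get(a, 0.0) != 0.0:
            raise SchemeValidationError(f"branch[{a!r}][{a!r}] must be 0 (no self-loop)")

    states = []
    for tag in tags:
        states.append(State(f"{tag}_fast", tag, lv[tag]))
        states.append(State(f"{tag}_slow", tag, lv[tag]))

    transitions: list[tuple[str, str, float]] = []
    for tag in tags:
        for sub, k in ((f"{tag}_fast", k1), (f"{tag}_slow", k2)):
            for to_tag, b in branch[tag].items():
                if b <= 0:
                    continue
                transitions.append((sub, f"{to_tag}_fast", k * b * P_k1))
                transitions.append((sub, f"{to_tag}_slow", k * b * (1.0 - P_k1)))
    transitions = [(f, t, r) for f, t, r in transitions if r > 0]

    start_tag = start or tags[0]
    initial = {f"{start_tag}_fast": P_k1, f"{start_tag}_slow": 1.0 - P_k1}
    return KineticScheme(
        states=states,
        transitions=transitions,
        initial=initial,
        params={"k1": k1, "k2": k2, "P_k1": P_k1, "tags": list(tags)},
    )


def build_withdrawal_scheme(
    subpopulation: str,
    k1: float | None = None,
    k2: float | None = None,
    P_k1: float | None = None,
) -> KineticScheme:
    """Scheme for a molecule observed after NTP withdrawal.

    Two subpopulations are seen after a brief NTP pulse and rinse:

    ``"US/PS"``
        cycles between US and PS only (6-mer RNA at withdrawal);
        defaults k1 = 0.16 s⁻¹, k2 = 0.02 s⁻¹, P(k1) = 0.57.
    ``"US/PS/FS"``
        samples all three scrunching states, roughly 6x faster, with
        US<->FS exchange about 4-fold more frequent than US<->PS and
        PS<->FS rare; defaults k1 = 0.96 s⁻¹, k2 = 0.07 s⁻¹, P(k1) = 0.79.
    """
    if subpopulation == "US/PS":
        k1 = 0.16 if k1 is None else k1
        k2 = 0.02 if k2 is None else k2
        P_k1 = 0.57 if P_k1 is None else P_k1
        branch = {"US": {"PS": 1.0}, "PS": {"US": 1.0}}
        return build_cycler_scheme(["US", "PS"], branch, k1, k2, P_k1, start="US")
    if subpopulation == "US/PS/FS":
        k1 = 0.96 if k1 is None else k1
        k2 = 0.07 if k2 is None else k2
        P_k1 = 0.79 if P_k1 is None else P_k1
        # dominant US<->FS exchange; US<->PS ~4-fold rarer; PS<->FS rare
        branch = {
            "US": {"FS": 0.8, "PS": 0.2},
            "FS": {"US": 0.9, "PS": 0.1},
            "PS": {"US": 0.9, "FS": 0.1},
        }
        return build_cycler_scheme(["US", "PS", "FS"], branch, k1, k2, P_k1, start="US")
    raise SchemeValidationError(
        f"subpopulation must be 'US/PS' or 'US/PS/FS', got {subpopulation!r}"
    )
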
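"""Kinetic Monte Carlo simulation of the anaphase B spindle.

The model is one-dimensional: two spindle poles slide apart at constant
speed, each anchoring the minus ends of a set of interpolar microtubules
that grow toward (and past) the opposite pole. Microtubules undergo
dynamic instability. Catastrophe is a multi-step process: the time spent
growing has CDF ``(1 - exp(-theta*t))**n``, the distribution of the
maximum of ``n`` independent exponential clocks. Shrinking microtubules
are rescued only inside the midzone, a region of fixed length ``Lm``
centred on the spindle, where a conserved budget ``R`` of rescue factor
is spread along the antiparallel overlap and shaped by a Beta(alpha,
beta) density of the reduced midzone coordinate. Microtubule positions
in the transverse plane live on a chequerboard lattice; when a
microtubule depolymerises completely, the lattice greedily reorganises
to maximise the number of antiparallel contacts. The spindle collapses
when the longest microtubules of the two poles no longer overlap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .params import SimParams

__all__ = [
    "Microtubule",
    "SpindleState",
    "EventRecord",
    "RescueContext",
    "Trajectory",
    "init_spindle",
    "sample_growth_duration",
    "mean_growth_duration",
    "midzone_coordinate",
    "rescue_rate",
    "neighbour_census",
    "reorganize_lattice",
    "advance_timestep",
    "check_collapse",
    "run_simulation",
    "pole_loss_probability",
]

GROWING = "growing"
SHRINKING = "shrinking"
LEFT = "left"
RIGHT = "right"

#: 4-connected lattice offsets
_NEIGHBOUR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(slots=True)
class Microtubule:
    """A single interpolar microtubule.

    ``length`` is measured from its own pole; the plus end of a
    left-pole microtubule sits at lab position ``length - S/2`` and that
    of a right-pole microtubule at ``S/2 - length``. ``tau_c`` is the
    remaining time to catastrophe and is only meaningful while growing.
    """

    mt_id: int
    pole: str
    site: tuple[int, int]
    length: float
    state: str = GROWING
    tau_c: float = math.inf

    def pos_signed(self, S: float) -> float:
        """Plus-end position relative to the spindle centre, signed
        positive in the microtubule's growth direction (so a tip past
        the centre is positive for either orientation)."""
        return self.length - S / 2.0


@dataclass(slots=True)
class EventRecord:
    kind: str  # rescue | catastrophe | loss | reorganization | collapse
    t: float
    mt_id: int
    pos_signed: float
    S_at_event: float


@dataclass(slots=True)
class RescueContext:
    """Diagnostic bundle returned by :func:`rescue_rate`."""

    n_neighbours: int
    N_pairs: int
    x: float | None
    p_density: float | None
    rate: float


@dataclass
class SpindleState:
    t: float
    S: float
    Lm: float
    mts: list[Microtubule]
    grid_shape: tuple[int, int] = (3, 3)
    N_pairs: int = 0
    neighbour_counts: dict[int, int] = field(default_factory=dict)

    def refresh_census(self) -> None:
        self.neighbour_counts, self.N_pairs = neighbour_census(self)

    def polymer(self) -> float:
        return sum(m.length for m in self.mts)

    def mts_of(self, pole: str) -> list[Microtubule]:
        return [m for m in self.mts if m.pole == pole]


@dataclass
class Trajectory:
    """Sampled time series and event log of one simulation run."""

    params: SimParams
    seed: int
    times: np.ndarray
    spindle_length: np.ndarray
    polymer: np.ndarray
    n_left: np.ndarray
    n_right: np.ndarray
    #: one snapshot per sampled time: list of (mt_id, pole, length, state)
    mt_snapshots: list[list[tuple[int, str, float, str]]]
    events: list[EventRecord]
    collapsed: bool
    collapse_length: float | None
    Lm: float

    @property
    def outcome(self) -> str:
        if self.collapsed:
            return f"collapsed at length {self.collapse_length:.2f} um"
        return "survived to t_max"


def sample_growth_duration(theta_cat: float, n_cat: float,
                           rng: np.random.Generator) -> float:
    """Draw one growth duration (min) by inverse-CDF sampling.

    The CDF ``F(t) = (1 - exp(-theta*t))**n`` inverts in closed form to
    ``t = -ln(1 - u**(1/n)) / theta``; degenerate uniform draws (0 or 1)
    are rejected to avoid infinities.
    """
    while True:
        u = rng.random()
        if 0.0 < u < 1.0:
            break
    return -math.log(1.0 - u ** (1.0 / n_cat)) / theta_cat


def mean_growth_duration(theta_cat: float, n_cat: float) -> float:
    """Analytic mean of the growth-duration distribution (min).

    Integrates the survival function ``1 - (1 - exp(-theta*t))**n`` by
    quadrature; used as an independent check of the sampler.
    """
    from scipy.integrate import quad

    val, _ = quad(lambda t: 1.0 - (1.0 - math.exp(-theta_cat * t)) ** n_cat,
                  0.0, np.inf, limit=200)
    return val


def _sample_midzone_length(params: SimParams, rng: np.random.Generator,
                           lower: float = 0.2) -> float:
    # the normal fit admits (unphysical) non-positive draws; resample
    while True:
        Lm = rng.normal(params.mu_mz, params.sigma_mz)
        if Lm > lower:
            return Lm


def init_spindle(params: SimParams, rng: np.random.Generator) -> SpindleState:
    """Build the initial 9-microtubule spindle.

    Microtubules occupy a full 3x3 chequerboard: corners and centre from
    one pole (5), edge centres from the other (4), so every 4-connected
    contact is antiparallel and the initial pair count is 12. All start
    growing with freshly sampled catastrophe clocks.
    """
    mts: list[Microtubule] = []
    mt_id = 0
    for row in range(3):
        for col in range(3):
            pole = LEFT if (row + col) % 2 == 0 else RIGHT
            mts.append(Microtubule(
                mt_id=mt_id, pole=pole, site=(row, col),
                length=params.L_mt0, state=GROWING,
                tau_c=sample_growth_duration(params.theta_cat, params.n_cat, rng),
            ))
            mt_id += 1
    state = SpindleState(t=0.0, S=params.S0,
                         Lm=_sample_midzone_length(params, rng), mts=mts)
    state.refresh_census()
    return state


def neighbour_census(state: SpindleState) -> tuple[dict[int, int], int]:
    """Count antiparallel 4-connected lattice neighbours.

    Returns a map ``mt_id -> neighbour count`` and the total number of
    unordered antiparallel adjacent pairs ``N_pairs`` (the sum of the
    per-microtubule counts is ``2 * N_pairs``).
    """
    occ = {m.site: m for m in state.mts}
    counts: dict[int, int] = {}
    total = 0
    for m in state.mts:
        r, c = m.site
        n = 0
        for dr, dc in _NEIGHBOUR_OFFSETS:
            other = occ.get((r + dr, c + dc))
            if other is not None and other.pole != m.pole:
                n += 1
        counts[m.mt_id] = n
        total += n
    return counts, total // 2


def midzone_coordinate(state: SpindleState, mt: Microtubule) -> float | None:
    """Reduced midzone coordinate of a plus end, or None if outside.

    Runs from 0 at the midzone edge closest to the microtubule's own
    pole to 1 at the far edge. In the signed tip coordinate ``q``
    (positive in the growth direction) both orientations reduce to
    ``x = (q + Lm/2) / Lm``.
    """
    q = mt.pos_signed(state.S)
    if abs(q) > state.Lm / 2.0:
        return None
    return (q + state.Lm / 2.0) / state.Lm


def rescue_rate(state: SpindleState, mt: Microtubule,
                params: SimParams) -> RescueContext:
    """Instantaneous rescue rate (1/min) of a microtubule's plus end.

    Midzone variant: ``r = n * R * P(x; alpha, beta) / (Lm * N)`` with
    ``n`` the antiparallel neighbour count and ``N`` the current pair
    count, zero outside the midzone or without neighbours — so the
    midzone-integrated total over all microtubules is exactly ``2R``.
    Uniform variant: ``r = R / (2 * Lt)`` with ``Lt`` the total polymer,
    anywhere on the spindle.
    """
    n = state.neighbour_counts.get(mt.mt_id, 0)
    N = state.N_pairs
    if params.variant == "uniform":
        Lt = state.polymer()
        rate = params.R / (2.0 * Lt) if Lt > 0 else 0.0
        return RescueContext(n, N, None, None, rate)
    x = midzone_coordinate(state, mt)
    if x is None or n == 0 or N == 0:
        return RescueContext(n, N, x, None, 0.0)
    p = params.beta_pdf(x)
    rate = n * params.R * p / (state.Lm * N)
    return RescueContext(n, N, x, p, rate)


def _pairs_delta(occ: dict[tuple[int, int], str], site: tuple[int, int],
                 pole: str) -> int:
    """Antiparallel contacts a microtubule of `pole` has at `site`."""
    r, c = site
    n = 0
    for dr, dc in _NEIGHBOUR_OFFSETS:
        other = occ.get((r + dr, c + dc))
        if other is not None and other != pole:
            n += 1
    return n


def reorganize_lattice(state: SpindleState) -> list[tuple[int, tuple[int, int], tuple[int, int]]]:
    """Greedily relocate microtubules to empty sites to maximise
    antiparallel contacts.

    Each accepted move relocates one microtubule (orientation unchanged)
    to an empty lattice site and strictly increases the antiparallel
    pair count; moves are applied until no improving move exists. Ties
    are broken by lowest microtubule id, then row-major target site, so
    the outcome is deterministic. Returns the list of applied moves as
    ``(mt_id, old_site, new_site)``.
    """
    rows, cols = state.grid_shape
    all_sites = [(r, c) for r in range(rows) for c in range(cols)]
    moves: list[tuple[int, tuple[int, int], tuple[int, int]]] = []
    while True:
        occ = {m.site: m.pole for m in state.mts}
        empty = [s for s in all_sites if s not in occ]
        best: tuple[int, Microtubule, tuple[int, int]] | None = None
        for m in sorted(state.mts, key=lambda m: m.mt_id):
            occ_wo = dict(occ)
            del occ_wo[m.site]
            current = _pairs_delta(occ_wo, m.site, m.pole)
            for target in empty:
                gain = _pairs_delta(occ_wo, target, m.pole) - current
                if gain > 0 and (best is None or gain > best[0]):
                    best = (gain, m, target)
        if best is None:
            break
        _, m, target = best
        moves.append((m.mt_id, m.site, target))
        m.site = target
    if moves:
        state.refresh_census()
    return moves


def check_collapse(state: SpindleState) -> bool:
    """True when the longest microtubules of the two poles no longer
    overlap (crosslinking needs strictly positive overlap), or a pole
    has no microtubules left."""
    left = [m.length for m in state.mts if m.pole == LEFT]
    right = [m.length for m in state.mts if m.pole == RIGHT]
    if not left or not right:
        return True
    return max(left) + max(right) <= state.S


def advance_timestep(state: SpindleState, params: SimParams,
                     rng: np.random.Generator,
                     step_index: int | None = None) -> list[EventRecord]:
    """Advance the spindle by one timestep ``h``.

    Update order is fixed for reproducibility: (1) poles slide outward;
    (2) growing microtubules elongate, their catastrophe clocks tick
    down, and they undergo catastrophe when the clock expires or the tip
    reaches the opposite pole (length clipped to the pole separation);
    (3) shrinking microtubules shorten, are removed at zero length
    (triggering lattice reorganisation) or tested for rescue with
    probability ``1 - exp(-r*h)``; (4) the neighbour census is
    refreshed. If ``step_index`` is given, time and pole separation are
    recomputed from it so that ``S = S0 + 2*v_s*t`` holds to machine
    precision over arbitrarily many steps.
    """
    h = params.h
    if step_index is not None:
        state.t = step_index * h
        state.S = params.S0 + 2.0 * params.v_s * state.t
    else:
        state.t += h
        state.S += 2.0 * params.v_s * h
    events: list[EventRecord] = []
    t, S = state.t, state.S

    lost: list[Microtubule] = []
    for m in state.mts:
        if m.state == GROWING:
            m.length += params.v_p * h
            m.tau_c -= h
            if m.tau_c <= 0.0 or m.length >= S:
                if m.length >= S:
                    m.length = S  # tip at the opposite pole
                m.state = SHRINKING
                events.append(EventRecord("catastrophe", t, m.mt_id,
                                          m.pos_signed(S), S))
        else:
            m.length -= params.v_d * h
            if m.length <= 0.0:
                lost.append(m)
                continue
            ctx = rescue_rate(state, m, params)
            if ctx.rate > 0.0 and rng.random() < -math.expm1(-ctx.rate * h):
                m.state = GROWING
                m.tau_c = sample_growth_duration(params.theta_cat,
                                                 params.n_cat, rng)
                events.append(EventRecord("rescue", t, m.mt_id,
                                          m.pos_signed(S), S))

    for m in lost:
        state.mts.remove(m)
        events.append(EventRecord("loss", t, m.mt_id, m.pos_signed(S), S))
        state.refresh_census()
        for mt_id, _old, _new in reorganize_lattice(state):
            moved = next(x for x in state.mts if x.mt_id == mt_id)
            events.append(EventRecord("reorganization", t, mt_id,
                                      moved.pos_signed(S), S))
    state.refresh_census()
    return events


def run_simulation(params: SimParams, seed: int,
                   record_interval: float = 0.1) -> Trajectory:
    """Run one spindle to collapse or to ``t_max``.

    Fully reproducible from ``(params, seed)``. The state is sampled
    every ``record_interval`` minutes (and at the final step).
    """
    rng = np.random.default_rng(seed)
    state = init_spindle(params, rng)
    events: list[EventRecord] = []
    n_steps = int(round(params.t_max / params.h))
    rec_every = max(1, int(round(record_interval / params.h)))

    times, S_ser, poly, n_l, n_r = [], [], [], [], []
    snaps: list[list[tuple[int, str, float, str]]] = []

    def record() -> None:
        times.append(state.t)
        S_ser.append(state.S)
        poly.append(state.polymer())
        n_l.append(sum(1 for m in state.mts if m.pole == LEFT))
        n_r.append(sum(1 for m in state.mts if m.pole == RIGHT))
        snaps.append([(m.mt_id, m.pole, m.length, m.state) for m in state.mts])

    record()
    collapsed = False
    collapse_length: float | None = None
    for i in range(1, n_steps + 1):
        events.extend(advance_timestep(state, params, rng, step_index=i))
        if check_collapse(state):
            collapsed = True
            collapse_length = state.S
            events.append(EventRecord("collapse", state.t, -1, 0.0, state.S))
            record()
            break
        if i % rec_every == 0 or i == n_steps:
            record()

    return Trajectory(
        params=params, seed=seed,
        times=np.asarray(times), spindle_length=np.asarray(S_ser),
        polymer=np.asarray(poly),
        n_left=np.asarray(n_l, dtype=int), n_right=np.asarray(n_r, dtype=int),
        mt_snapshots=snaps, events=events,
        collapsed=collapsed, collapse_length=collapse_length, Lm=state.Lm,
    )


def pole_loss_probability(n_left: int = 4, n_right: int = 5,
                          p_loss: float = 0.5) -> float:
    """Analytic spindle-failure probability under independent losses.

    Enumerates all ``2**(n_left+n_right)`` loss outcomes, each
    microtubule independently lost with probability ``p_loss``, and sums
    the probability that the left pole loses everything plus the
    probability that the right pole does — the back-of-the-envelope
    estimate ``p**n_left + p**n_right`` (for p = 1/2, 4 and 5
    microtubules: 9.375%). The tiny both-poles intersection is counted
    in both terms, as in the estimate.
    """
    n = n_left + n_right
    p_left = 0.0
    p_right = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        k = sum(outcome)
        w = p_loss ** k * (1.0 - p_loss) ** (n - k)
        if all(outcome[:n_left]):
            p_left += w
        if all(outcome[n_left:]):
            p_right += w
    return p_left + p_right
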
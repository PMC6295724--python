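"""Stochastic and mean-field dynamics of a chemical universe.

The simulation follows every reaction pair with total mass <= L - low- and
high-barrier alike, each at its own barrier height - so rare high-barrier
"innovation" events can occur at any time.  Population kinetics:

* synthesis ``i + j -> i+j``:  ``k * N_i * N_j / (S + N)`` for distinct
  reactants and ``k * N_i * (N_i - 1) / (S + N)`` for identical ones
  (proper stochastic combinatorics; indistinguishable from ``N_i * N_j`` at
  reservoir scale but correct at ``N_i = 1``),
* decomposition ``i+j -> i + j``:  ``k * N_{i+j}``,

with ``S`` the solvent count setting the encounter rate and ``N`` the total
non-solvent population.  Decompositions therefore outrun syntheses with the
same rate constant whenever ``N_j / (S + N) < 1``, i.e. always in the
dilute regime.

Selected *resource* species are clamped to a reservoir count Q: after every
event the resource is reset and the net amount consumed is accumulated in a
ledger ``F``, which keeps the mass and Gibbs-energy bookkeeping exact.

The stochastic path is the exact (event-by-event) stochastic simulation
algorithm with the standard two-uniform draw; the mean-field path integrates
``dN_i/dt = sum_r nu_ir * gamma_r(N)`` with the same rate expressions and
clamped resources.  On top of the trajectories sit growth-mode diagnostics
(bounded / linear / exponential / superexponential), the side-reaction
critical-multiplier search, and the Gibbs-energy ledger splitting the
system's standard Gibbs energy into replicating, resource and waste parts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .universe import (
    DirectedReaction,
    Universe,
    as_system,
    delta_g_standard,
    rate_constant,
)

__all__ = [
    "SimulationConfig",
    "Trace",
    "MeanFieldResult",
    "propensity",
    "gillespie_run",
    "meanfield_run",
    "growth_mode",
    "critical_eta",
    "gibbs_ledger",
    "write_trace_tsv",
]

BOUNDED = "bounded"
LINEAR = "linear"
EXPONENTIAL = "exponential"
SUPEREXPONENTIAL = "superexponential"


@dataclass
class SimulationConfig:
    """Everything one run needs.

    ``resources`` maps species mass to its clamped reservoir count Q;
    ``rate_overrides`` maps a directed reaction to a dimensionless rate
    multiplier eta (implemented as an activation-energy offset
    ``-ln(eta)/kappa``, so the rate constant becomes exactly ``eta * k``).
    ``solvent_count`` S is dimensionless like the populations.
    """

    universe: Universe
    resources: dict[int, int] = field(default_factory=dict)
    initial_counts: dict[int, int] = field(default_factory=dict)
    solvent_count: float = 1e6
    max_time: float | None = None
    max_events: int | None = None
    seed: int = 0
    rate_overrides: dict[DirectedReaction, float] = field(default_factory=dict)
    record_every: int = 1
    include_high_barrier: bool = True

    def __post_init__(self) -> None:
        if self.solvent_count <= 0:
            raise ValueError("solvent_count must be positive")
        for m, q in self.resources.items():
            if q <= 0:
                raise ValueError(f"reservoir count for {m} must be positive")
            if m > self.universe.mass_cap:
                raise ValueError(f"resource {m} exceeds mass cap")
        for m, c in self.initial_counts.items():
            if c < 0 or m > self.universe.mass_cap:
                raise ValueError(f"bad initial count {m}: {c}")
        for m in set(self.resources) & set(self.initial_counts):
            if self.initial_counts[m] != self.resources[m]:
                raise ValueError(
                    f"initial count of resource {m} conflicts with its reservoir"
                )
        if self.max_time is None and self.max_events is None:
            raise ValueError("need a stopping rule: max_time and/or max_events")
        for r, eta in self.rate_overrides.items():
            if eta < 0:
                raise ValueError(f"rate multiplier for {r} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "universe": self.universe.to_dict(),
            "resources": {int(m): int(q) for m, q in sorted(self.resources.items())},
            "initial_counts": {
                int(m): int(c) for m, c in sorted(self.initial_counts.items())
            },
            "solvent_count": self.solvent_count,
            "max_time": self.max_time,
            "max_events": self.max_events,
            "seed": self.seed,
            "rate_overrides": {
                str(r): float(eta) for r, eta in self.rate_overrides.items()
            },
            "record_every": self.record_every,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        return cls(
            universe=Universe.from_dict(data["universe"]),
            resources={int(m): int(q) for m, q in data.get("resources", {}).items()},
            initial_counts={
                int(m): int(c) for m, c in data.get("initial_counts", {}).items()
            },
            solvent_count=float(data.get("solvent_count", 1e6)),
            max_time=data.get("max_time"),
            max_events=data.get("max_events"),
            seed=int(data.get("seed", 0)),
            rate_overrides={
                DirectedReaction.parse(key): float(eta)
                for key, eta in data.get("rate_overrides", {}).items()
            },
            record_every=int(data.get("record_every", 1)),
        )

    def effective_rate_constant(self, reaction: DirectedReaction) -> float:
        k = rate_constant(reaction, self.universe)
        eta = self.rate_overrides.get(reaction)
        if eta is not None:
            k *= eta  # == beta*exp(-kappa*(dG_act - ln(eta)/kappa))
        return k


# ---------------------------------------------------------------------------
# Compiled reaction network
# ---------------------------------------------------------------------------

class _Network:
    """Vectorised view of every directed reaction in the universe."""

    def __init__(self, config: SimulationConfig):
        uni = config.universe
        self.L = uni.mass_cap
        self.reactions = uni.all_reactions()
        if not config.include_high_barrier:
            # restrict to explicitly listed (low-barrier) pairs
            self.reactions = [r for r in self.reactions if r.pair in uni.psi_table]
        R = len(self.reactions)
        self.k = np.empty(R)
        self.a_idx = np.empty(R, dtype=np.intp)   # first reactant (0-based)
        self.b_idx = np.empty(R, dtype=np.intp)   # second reactant (synthesis)
        self.ident_adj = np.zeros(R)              # 1 for i+i syntheses
        self.is_dec = np.zeros(R, dtype=bool)
        self.stoich = np.zeros((self.L, R))       # nu: species x reaction
        self.dg = np.empty(R)                     # net standard Gibbs change
        for j, r in enumerate(self.reactions):
            self.k[j] = config.effective_rate_constant(r)
            self.dg[j] = float(delta_g_standard(r, uni.g_table))
            pair = r.pair
            if r.direction == "synthesis":
                self.a_idx[j] = pair.lo - 1
                self.b_idx[j] = pair.hi - 1
                if pair.lo == pair.hi:
                    self.ident_adj[j] = 1.0
                self.stoich[pair.lo - 1, j] -= 1
                self.stoich[pair.hi - 1, j] -= 1
                self.stoich[pair.total - 1, j] += 1
            else:
                self.is_dec[j] = True
                self.a_idx[j] = pair.total - 1
                self.b_idx[j] = pair.total - 1
                self.stoich[pair.total - 1, j] -= 1
                self.stoich[pair.lo - 1, j] += 1
                self.stoich[pair.hi - 1, j] += 1
        # per-reaction sparse updates for the event loop
        self.upd = [
            (np.nonzero(self.stoich[:, j])[0], self.stoich[np.nonzero(self.stoich[:, j])[0], j])
            for j in range(R)
        ]

    def propensities(self, counts: np.ndarray, S: float) -> np.ndarray:
        n_tot = counts.sum()
        denom = S + n_tot
        ca = counts[self.a_idx]
        cb = counts[self.b_idx] - self.ident_adj
        second = np.where(self.is_dec, 1.0, cb / denom)
        return self.k * ca * np.maximum(second, 0.0)


def propensity(
    reaction: DirectedReaction,
    counts: Mapping[int, float],
    universe: Universe,
    solvent_count: float,
    rate_k: float | None = None,
) -> float:
    """Propensity (1/s) of one reaction at the given populations.

    ``counts`` maps mass -> population; ``rate_k`` overrides the rate
    constant (used for eta-scaled side reactions).
    """
    k = rate_k if rate_k is not None else rate_constant(reaction, universe)
    if reaction.direction == "synthesis":
        lo, hi = reaction.pair.lo, reaction.pair.hi
        n_tot = sum(counts.values())
        ni = counts.get(lo, 0)
        nj = counts.get(hi, 0) - (1 if lo == hi else 0)
        return k * ni * max(nj, 0) / (solvent_count + n_tot)
    return k * counts.get(reaction.pair.total, 0)


# ---------------------------------------------------------------------------
# Stochastic simulation
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Event-level output of one stochastic run.

    Population snapshots (``counts``, row per sample, column per species
    mass 1..L) are taken every ``record_every`` events plus the initial and
    final states; ``times``/``event_reactions`` cover *every* event so event
    statistics and the Gibbs ledger stay exact.  ``resource_consumed`` holds
    the net reservoir ledger F at the same sample points.
    """

    universe: Universe
    reactions: list[DirectedReaction]
    times: np.ndarray
    event_reactions: np.ndarray
    sample_events: np.ndarray
    sample_times: np.ndarray
    counts: np.ndarray
    resource_consumed: dict[int, np.ndarray]
    reaction_event_totals: dict[DirectedReaction, int]
    first_appearance: dict[int, float]
    stop_reason: str
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def species_series(self, mass: int) -> tuple[np.ndarray, np.ndarray]:
        """(sample_times, population) for one species."""
        if not 1 <= mass <= self.universe.mass_cap:
            raise ValueError(f"species {mass} outside universe")
        return self.sample_times, self.counts[:, mass - 1]

    def final_counts(self) -> dict[int, int]:
        return {
            m: int(self.counts[-1, m - 1])
            for m in range(1, self.universe.mass_cap + 1)
            if self.counts[-1, m - 1]
        }


def gillespie_run(config: SimulationConfig, stop_on_species: int | None = None) -> Trace:
    """Exact stochastic simulation of the full universe.

    Every reaction pair with total mass <= L is simulated at its own barrier
    height.  After each event, resource species are reset to their reservoir
    count with the net difference accumulated in the consumption ledger.
    Runs until ``max_time``/``max_events``, until no reaction has positive
    propensity, or (with ``stop_on_species``) as soon as that species first
    appears.  Fully reproducible from ``seed``.
    """
    net = _Network(config)
    S = float(config.solvent_count)
    L = net.L
    counts = np.zeros(L)
    for m, q in config.resources.items():
        counts[m - 1] = q
    for m, c in config.initial_counts.items():
        counts[m - 1] = c

    res_idx = np.array([m - 1 for m in sorted(config.resources)], dtype=np.intp)
    res_q = np.array([config.resources[m] for m in sorted(config.resources)], float)
    consumed = np.zeros(len(res_idx))

    rng = np.random.default_rng(config.seed)
    max_events = config.max_events if config.max_events is not None else np.inf
    max_time = config.max_time if config.max_time is not None else np.inf
    every = max(1, int(config.record_every))

    times: list[float] = []
    events: list[int] = []
    sample_events = [0]
    sample_times = [0.0]
    snapshots = [counts.copy()]
    consumed_snap = [consumed.copy()]
    appeared = counts > 0
    first_appearance = {
        m + 1: 0.0 for m in range(L) if appeared[m]
    }
    totals = np.zeros(len(net.reactions), dtype=np.int64)

    t = 0.0
    stop = "max_events"
    n_ev = 0
    while n_ev < max_events:
        prop = net.propensities(counts, S)
        a0 = prop.sum()
        if a0 <= 0.0:
            stop = "no_reactions_possible"
            break
        u1, u2 = rng.random(2)
        tau = -math.log(u1) / a0
        if t + tau > max_time:
            stop = "max_time"
            t = max_time
            break
        t += tau
        j = int(np.searchsorted(np.cumsum(prop), u2 * a0))
        j = min(j, len(prop) - 1)
        idx, delta = net.upd[j]
        counts[idx] += delta
        if len(res_idx):
            diff = counts[res_idx] - res_q
            if np.any(diff):
                consumed -= diff
                counts[res_idx] = res_q
        for m in idx:
            if counts[m] > 0 and not appeared[m]:
                appeared[m] = True
                first_appearance[m + 1] = t
        totals[j] += 1
        times.append(t)
        events.append(j)
        n_ev += 1
        if stop_on_species is not None and counts[stop_on_species - 1] > 0:
            stop = f"species_{stop_on_species}_appeared"
            n_ev = -1  # force a final snapshot below
            break
        if n_ev % every == 0:
            sample_events.append(n_ev)
            sample_times.append(t)
            snapshots.append(counts.copy())
            consumed_snap.append(consumed.copy())

    n_ev = len(times)
    if sample_events[-1] != n_ev:
        sample_events.append(n_ev)
        sample_times.append(t)
        snapshots.append(counts.copy())
        consumed_snap.append(consumed.copy())

    consumed_arr = np.array(consumed_snap)
    return Trace(
        universe=config.universe,
        reactions=net.reactions,
        times=np.array(times),
        event_reactions=np.array(events, dtype=np.int32),
        sample_events=np.array(sample_events),
        sample_times=np.array(sample_times),
        counts=np.array(snapshots),
        resource_consumed={
            m: consumed_arr[:, k] for k, m in enumerate(sorted(config.resources))
        },
        reaction_event_totals={
            net.reactions[j]: int(totals[j]) for j in np.nonzero(totals)[0]
        },
        first_appearance=first_appearance,
        stop_reason=stop,
        seed=config.seed,
        metadata={
            "solvent_count": S,
            "resources": dict(config.resources),
            "record_every": every,
        },
    )


# ---------------------------------------------------------------------------
# Mean-field ODEs
# ---------------------------------------------------------------------------

@dataclass
class MeanFieldResult:
    """Continuous mean-field trajectories, row per time point, column per
    species mass 1..L."""

    universe: Universe
    t: np.ndarray
    counts: np.ndarray
    status: int
    message: str

    def species_series(self, mass: int) -> tuple[np.ndarray, np.ndarray]:
        if not 1 <= mass <= self.universe.mass_cap:
            raise ValueError(f"species {mass} outside universe")
        return self.t, self.counts[:, mass - 1]


def meanfield_run(
    config: SimulationConfig,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    stop_at_population: float | None = None,
) -> MeanFieldResult:
    """Integrate the mean-field rate equations on ``t_grid``.

    Uses the same propensity expressions as the stochastic path, with
    resource species held constant at their reservoir counts.
    ``stop_at_population`` installs a terminal event on the total non-
    solvent population (useful when trajectories grow exponentially).
    Integrator failures raise with the solver's diagnostics.
    """
    net = _Network(config)
    S = float(config.solvent_count)
    y0 = np.zeros(net.L)
    for m, q in config.resources.items():
        y0[m - 1] = q
    for m, c in config.initial_counts.items():
        y0[m - 1] = c
    clamp = np.zeros(net.L, dtype=bool)
    for m in config.resources:
        clamp[m - 1] = True

    def rhs(_t, y):
        counts = np.maximum(y, 0.0)
        dy = net.stoich @ net.propensities(counts, S)
        dy[clamp] = 0.0
        return dy

    events = None
    if stop_at_population is not None:
        def pop_cap(_t, y):
            return stop_at_population - y.sum()
        pop_cap.terminal = True
        pop_cap.direction = -1
        events = pop_cap

    t_grid = np.asarray(t_grid, float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
        events=events,
    )
    if sol.status < 0:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return MeanFieldResult(
        universe=config.universe,
        t=sol.t,
        counts=sol.y.T,
        status=sol.status,
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# Growth diagnostics
# ---------------------------------------------------------------------------

def _r_squared(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R^2, slope) of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return r2, float(slope)


def growth_mode(
    trajectory: Trace | MeanFieldResult | tuple[np.ndarray, np.ndarray],
    species: int | None = None,
    window: float = 0.5,
) -> str:
    """Classify the late-time growth of one species.

    ``window`` is the trailing fraction of the samples used for the fits
    (at least 10 samples required).  Decision rule, in order: windowed
    log-slopes strictly increasing by > 5 % per sub-window ->
    ``superexponential``; log-linear fit with R^2 >= 0.98 and positive
    slope -> ``exponential`` (ties against a straight-line fit broken by
    the larger R^2); straight-line fit with R^2 >= 0.98 and positive slope
    -> ``linear``; series whose late-window relative range is below 5 % (or
    absolute range <= 2 counts) -> ``bounded``; anything else ``bounded``.
    """
    if isinstance(trajectory, (Trace, MeanFieldResult)):
        if species is None:
            raise ValueError("species required when passing a trace")
        t, n = trajectory.species_series(species)
    else:
        t, n = trajectory
        t = np.asarray(t, float)
        n = np.asarray(n, float)
    start = int(len(t) * (1.0 - window))
    t_w, n_w = t[start:], n[start:]
    if len(t_w) < 10:
        raise ValueError(f"need >= 10 samples in window, have {len(t_w)}")

    span = n_w.max() - n_w.min()
    if span <= 2 or (n_w.max() > 0 and span / n_w.max() < 0.05):
        return BOUNDED

    lin_r2, lin_slope = _r_squared(t_w, n_w)
    log_ok = bool(np.all(n_w > 0))
    if log_ok:
        logn = np.log(n_w)
        log_r2, log_slope = _r_squared(t_w, logn)
        # superexponential: log-slope itself accelerates across sub-windows
        thirds = np.array_split(np.arange(len(t_w)), 3)
        if all(len(ix) >= 3 for ix in thirds):
            slopes = [_r_squared(t_w[ix], logn[ix])[1] for ix in thirds]
            if all(s > 0 for s in slopes) and all(
                s2 > 1.05 * s1 for s1, s2 in zip(slopes, slopes[1:])
            ):
                return SUPEREXPONENTIAL
        if log_r2 >= 0.98 and log_slope > 0 and (lin_r2 < 0.98 or log_r2 >= lin_r2):
            return EXPONENTIAL
    if lin_r2 >= 0.98 and lin_slope > 0:
        return LINEAR
    return BOUNDED


def critical_eta(
    config: SimulationConfig,
    side_reaction: DirectedReaction | str,
    species: int,
    eta_grid: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0),
    tol: float = 0.005,
    t_end: float | None = None,
    population_cap: float = 1e8,
) -> float:
    """Smallest side-reaction rate multiplier that kills replication.

    The side reaction's rate constant is scaled by eta; for each trial the
    mean-field equations of the *listed* reaction network are integrated
    and the late-window log-slope of the target species decides growth vs
    decay (hitting ``population_cap`` counts as growth).  The grid must bracket a sign change; the bracket is
    then bisected to width ``tol`` and its midpoint returned.
    """
    side = DirectedReaction.parse(side_reaction) if isinstance(side_reaction, str) else side_reaction
    if t_end is None:
        # ~2000 characteristic times of the fastest reservoir-fed reaction
        k_max = max(
            config.effective_rate_constant(r)
            for r in config.universe.all_reactions()
            if config.universe.psi_for(r.pair) <= config.universe.psi_default
        )
        q_max = max(config.resources.values()) if config.resources else 1.0
        t_end = 2000.0 / (k_max * q_max / config.solvent_count)

    t_grid = np.linspace(0.0, t_end, 200)

    def growth_sign(eta: float) -> float:
        overrides = dict(config.rate_overrides)
        overrides[side] = eta
        cfg = SimulationConfig(
            universe=config.universe,
            resources=dict(config.resources),
            initial_counts=dict(config.initial_counts),
            solvent_count=config.solvent_count,
            max_time=t_end,
            seed=config.seed,
            rate_overrides=overrides,
            # the threshold concerns the listed network itself: rare
            # high-barrier channels (e.g. re-decomposition of the side
            # product) only add an exponentially small background that
            # blurs the asymptotic growth sign over long horizons
            include_high_barrier=False,
        )
        sol = meanfield_run(cfg, t_grid, stop_at_population=population_cap)
        t, n = sol.species_series(species)
        if sol.status == 1:  # hit the population cap: unambiguous growth
            return 1.0
        half = len(t) // 2
        _, slope = _r_squared(t[half:], np.log(np.maximum(n[half:], 1e-300)))
        # a decayed trajectory sits at the integrator's absolute-tolerance
        # floor where the fitted log-slope is noise; demand a fifth of an
        # e-fold across the window and a population clearly off the floor
        gain = slope * (t[-1] - t[half])
        if n[-1] < 1e-6 or gain <= 0.2:
            return -1.0
        return 1.0

    signs = [growth_sign(e) for e in eta_grid]
    lo = hi = None
    for (e1, s1), (e2, s2) in zip(
        zip(eta_grid, signs), list(zip(eta_grid, signs))[1:]
    ):
        if s1 > 0 >= s2:
            lo, hi = e1, e2
            break
    if lo is None:
        raise ValueError(
            f"eta grid {list(eta_grid)} does not bracket a growth/decay change"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if growth_sign(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Gibbs-energy ledger
# ---------------------------------------------------------------------------

def gibbs_ledger(
    trace: Trace,
    replicating_species: set[int],
    resource: int,
    waste: int,
) -> dict[str, np.ndarray]:
    """Split the trace's standard Gibbs energy over time (reference 0 at t=0).

    ``G_replicating = sum_i N_i(t) G_i`` over the replicating species,
    ``G_resource = -F(t) G_resource`` (F = net reservoir consumption),
    ``G_waste = N_waste(t) G_waste``; ``G_living`` is replicating plus
    resource and ``G_total`` adds the waste.  All series subtract their
    t = 0 value, so for a partition covering every reacting species
    ``G_total`` equals the cumulative net standard Gibbs change of the
    events - energy bookkeeping is exact, event by event.

    Units: kJ/mol times molecule count (per-mole energies weighted by
    dimensionless populations).
    """
    uni = trace.universe
    g = uni.g_table
    for m in set(replicating_species) | {waste}:
        if not 1 <= m <= uni.mass_cap:
            raise ValueError(f"species {m} outside universe")
    if resource not in trace.resource_consumed:
        raise ValueError(f"species {resource} is not a reservoir of this trace")

    rep = sorted(replicating_species)
    rep_idx = [m - 1 for m in rep]
    g_rep_w = np.array([g[m] for m in rep])
    n_rep = trace.counts[:, rep_idx]
    g_replicating = (n_rep - n_rep[0]) @ g_rep_w
    f = trace.resource_consumed[resource]
    g_resource = -(f - f[0]) * g[resource]
    n_w = trace.counts[:, waste - 1]
    g_waste = (n_w - n_w[0]) * g[waste]
    g_living = g_replicating + g_resource
    return {
        "t": trace.sample_times,
        "g_replicating": g_replicating,
        "g_resource": g_resource,
        "g_waste": g_waste,
        "g_living": g_living,
        "g_total": g_living + g_waste,
    }


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_trace_tsv(trace: Trace, path: str, metadata_path: str | None = None) -> None:
    """Sampled trace as TSV (time, one column per species); optional JSON
    sidecar with seed, stop reason and event totals."""
    L = trace.universe.mass_cap
    header = "time\t" + "\t".join(f"n{m}" for m in range(1, L + 1))
    rows = [header]
    for i, t in enumerate(trace.sample_times):
        rows.append(
            f"{t:.9g}\t" + "\t".join(str(int(c)) for c in trace.counts[i])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    if metadata_path:
        meta = {
            "seed": trace.seed,
            "stop_reason": trace.stop_reason,
            "n_events": trace.n_events,
            "reaction_event_totals": {
                str(r): n for r, n in trace.reaction_event_totals.items()
            },
            "first_appearance": {str(m): t for m, t in trace.first_appearance.items()},
            **trace.metadata,
        }
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=2)
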
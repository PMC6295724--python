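"""Built-in scheme library and random-universe generation.

The named fixtures are the model systems used throughout the docs and
tests: a simplified citric acid cycle (collectively catalytic), the formose
reaction (self-replicating), formose plus benign and lethal side reactions,
an entropy-ledger system, a collectively catalytic stand-in for a single
high-barrier reaction, a physically impossible cycle, and a staged cascade
in which complexity emerges innovation by innovation.  Each fixture bundles
its reaction list, standard-Gibbs-energy table, barrier heights, reservoir
and initial populations, ready to turn into a simulation config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .dynamics import SimulationConfig
from .feasibility import is_physically_possible, validate_witness
from .universe import (
    DEFAULT_PSI_HIGH,
    DEFAULT_PSI_LOW,
    DirectedReaction,
    ReactionSystem,
    Universe,
    as_system,
    enumerate_pairs,
)

__all__ = [
    "SchemeFixture",
    "load_fixture",
    "fixture_names",
    "generate_random_universe",
    "load_config",
]

log = logging.getLogger(__name__)


@dataclass
class SchemeFixture:
    """A named reaction system with its full parameter set."""

    name: str
    reactions: ReactionSystem
    g_table: dict[int, float]
    mass_cap: int
    psi_low: float = DEFAULT_PSI_LOW
    psi_high: float = DEFAULT_PSI_HIGH
    resources: dict[int, int] = field(default_factory=dict)
    initial_counts: dict[int, int] = field(default_factory=dict)
    solvent_count: float = 1e6
    feasible: bool = True
    provenance: str = ""

    def universe(self) -> Universe:
        uni, _ = Universe.from_low_barrier(
            self.mass_cap,
            self.g_table,
            self.reactions,
            psi_low=self.psi_low,
            psi_high=self.psi_high,
        )
        return uni

    def config(
        self,
        seed: int = 0,
        max_events: int | None = None,
        max_time: float | None = None,
        record_every: int = 1,
        rate_overrides: Mapping[DirectedReaction, float] | None = None,
    ) -> SimulationConfig:
        return SimulationConfig(
            universe=self.universe(),
            resources=dict(self.resources),
            initial_counts=dict(self.initial_counts),
            solvent_count=self.solvent_count,
            max_time=max_time,
            max_events=max_events,
            seed=seed,
            rate_overrides=dict(rate_overrides or {}),
            record_every=record_every,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reactions": [str(r) for r in self.reactions],
            "g_table": {int(m): float(g) for m, g in sorted(self.g_table.items())},
            "mass_cap": self.mass_cap,
            "psi_low": self.psi_low,
            "psi_high": self.psi_high,
            "resources": {int(m): int(q) for m, q in sorted(self.resources.items())},
            "initial_counts": {
                int(m): int(c) for m, c in sorted(self.initial_counts.items())
            },
            "solvent_count": self.solvent_count,
            "feasible": self.feasible,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SchemeFixture":
        return cls(
            name=data["name"],
            reactions=as_system(data["reactions"]),
            g_table={int(m): float(g) for m, g in data["g_table"].items()},
            mass_cap=int(data["mass_cap"]),
            psi_low=float(data.get("psi_low", DEFAULT_PSI_LOW)),
            psi_high=float(data.get("psi_high", DEFAULT_PSI_HIGH)),
            resources={int(m): int(q) for m, q in data.get("resources", {}).items()},
            initial_counts={
                int(m): int(c) for m, c in data.get("initial_counts", {}).items()
            },
            solvent_count=float(data.get("solvent_count", 1e6)),
            feasible=bool(data.get("feasible", True)),
            provenance=data.get("provenance", ""),
        )


def _fill(g: dict[int, float], mass_cap: int, default=lambda m: -100.0 * m):
    """Complete a G table over 1..mass_cap; unlisted masses only steer the
    spontaneous direction of high-barrier pairs."""
    return {m: g.get(m, default(m)) for m in range(1, mass_cap + 1)}


def _builders() -> dict:
    def scheme1() -> SchemeFixture:
        return SchemeFixture(
            name="scheme1",
            reactions=as_system(["5 -> 1 + 4", "6 -> 1 + 5", "2 + 4 -> 6"]),
            g_table={1: -780, 2: -500, 3: -490, 4: -190, 5: -830, 6: -900},
            mass_cap=6,
            resources={2: 1000},
            initial_counts={4: 1},
            provenance="simplified citric acid cycle; standard parameter set",
        )

    def scheme2() -> SchemeFixture:
        return SchemeFixture(
            name="scheme2",
            reactions=as_system(["1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2"]),
            g_table={1: 220, 2: -760, 3: -970, 4: -1160},
            mass_cap=4,
            resources={1: 1000},
            initial_counts={2: 1},
            provenance="simplified formose reaction; standard parameter set",
        )

    def scheme3() -> SchemeFixture:
        # formose plus a benign side reaction that loses the race for 4
        return SchemeFixture(
            name="scheme3",
            reactions=as_system(
                ["1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2", "4 + 5 -> 9"]
            ),
            g_table=_fill({1: 220, 2: -760, 3: -970, 4: -1160, 5: -150, 9: -1400}, 9),
            mass_cap=9,
            resources={1: 1000, 5: 1000},
            initial_counts={2: 1},
            provenance="formose with a 4-consuming side reaction (side-reaction "
            "energies chosen here; only the listed reactions are constrained)",
        )

    def scheme4() -> SchemeFixture:
        # formose plus a side reaction that intercepts the replicated species
        return SchemeFixture(
            name="scheme4",
            reactions=as_system(
                ["1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2", "2 + 5 -> 7"]
            ),
            g_table=_fill({1: 220, 2: -760, 3: -970, 4: -1160, 5: -150, 7: -1000}, 7),
            mass_cap=7,
            resources={1: 1000, 5: 1000},
            initial_counts={2: 1},
            provenance="formose with a 2-consuming side reaction (side-reaction "
            "energies chosen here; only the listed reactions are constrained)",
        )

    def scheme5() -> SchemeFixture:
        return SchemeFixture(
            name="scheme5",
            reactions=as_system(
                ["5 -> 1 + 4", "2 + 3 -> 5", "2 + 4 -> 6", "6 -> 3 + 3"]
            ),
            g_table={1: -800, 2: -500, 3: -400, 4: -200, 5: -950, 6: -750},
            mass_cap=6,
            resources={2: 1000},
            initial_counts={3: 1},
            provenance="self-replicating system whose replicating part climbs "
            "in Gibbs energy; standard parameter set",
        )

    def scheme6() -> SchemeFixture:
        return SchemeFixture(
            name="scheme6",
            reactions=as_system(["1 + 30 -> 31", "3 + 31 -> 34", "34 -> 4 + 30"]),
            g_table=_fill(
                {1: 220, 3: -970, 4: -1160, 30: -500, 31: -400, 34: -1400}, 34
            ),
            mass_cap=34,
            resources={1: 1000, 3: 1000},
            initial_counts={30: 1},
            provenance="collectively catalytic trio whose overall reaction is "
            "1 + 3 -> 4 (energies chosen here)",
        )

    def scheme7() -> SchemeFixture:
        return SchemeFixture(
            name="scheme7",
            reactions=as_system(
                ["2 -> 1 + 1", "1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2"]
            ),
            g_table={1: 0, 2: 0, 3: 0, 4: 0},
            mass_cap=4,
            initial_counts={2: 100},
            feasible=False,
            provenance="physically impossible cycle: the four reactions sum to "
            "complete cancellation, so no energy assignment makes all four "
            "spontaneous (g_table is a placeholder)",
        )

    def scheme_table2_synthetic() -> SchemeFixture:
        """Synthetic staged-cascade system (reconstruction).

        The original staged system is specified only as an architecture:
        the formose trio, a three-reaction collectively catalytic system
        fed by 3 and triggered by the first 5, and a 13-reaction
        self-replicating system on a mass-12 species triggered by the first
        12.  This fixture realises that architecture with concrete
        reactions and energies chosen here (hence "synthetic"): formose;
        the cycle {3+5->8, 3+8->11, 11->5+6} with overall reaction
        3 + 3 -> 6; and the chain 12+1->13, ..., 23+1->24, 24->12+12 with
        overall reaction 12 x 1 -> 12.  The barrier gap (psi_high = 45)
        keeps innovations ~1e7-fold rarer than low-barrier traffic while
        letting the full cascade complete within ~1e5-1e6 events; the stage
        ordering itself does not depend on the gap.
        """
        formose = ["1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2"]
        cc_trio = ["3 + 5 -> 8", "3 + 8 -> 11", "11 -> 5 + 6"]
        sr_chain = [f"{m} + 1 -> {m + 1}" for m in range(12, 24)] + ["24 -> 12 + 12"]
        g = {1: 220, 2: -760, 3: -970, 4: -1160, 5: -1800, 6: -2400, 8: -2900,
             11: -4000}
        for m in range(12, 25):
            g[m] = -5000.0 - 100.0 * (m - 12)
        return SchemeFixture(
            name="scheme_table2_synthetic",
            reactions=as_system(formose + cc_trio + sr_chain),
            g_table=_fill(g, 24),
            mass_cap=24,
            psi_high=40.0,
            resources={1: 1000},
            initial_counts={},
            provenance="synthetic staged cascade: formose, a collectively "
            "catalytic trio on resource 3, and a 13-reaction self-replicator "
            "on mass 12; reconstruction, all parameters chosen here",
        )

    builders = {
        "scheme1": scheme1,
        "scheme2": scheme2,
        "scheme3": scheme3,
        "scheme4": scheme4,
        "scheme5": scheme5,
        "scheme6": scheme6,
        "scheme7": scheme7,
        "scheme_table2_synthetic": scheme_table2_synthetic,
        # alias: the staged system is only available as the documented
        # synthetic reconstruction above
        "scheme_table2": scheme_table2_synthetic,
    }
    return builders


def fixture_names() -> list[str]:
    return sorted(_builders())


def load_fixture(name: str) -> SchemeFixture:
    """Fetch a named fixture (a fresh copy each call)."""
    try:
        builder = _builders()[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    fixture = builder()
    return fixture


def generate_random_universe(
    mass_cap: int,
    n_low_barrier: int,
    seed: int,
    g_range: tuple[float, float] = (-1500.0, 300.0),
    max_attempts: int = 1000,
) -> tuple[Universe, ReactionSystem]:
    """A random physically possible universe with ``n_low_barrier`` listed
    reactions.

    Pairs and directions are rejection-sampled until the listed set is
    strictly feasible; the exact witness is then scaled into ``g_range``
    (feasibility is scale-invariant, so the range is cosmetic) and unlisted
    masses get uniform energies from the same range.  Deterministic in
    ``seed``.
    """
    pairs = enumerate_pairs(mass_cap)
    if n_low_barrier > len(pairs):
        raise ValueError(
            f"n_low_barrier={n_low_barrier} exceeds {len(pairs)} pairs at L={mass_cap}"
        )
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        chosen = rng.choice(len(pairs), size=n_low_barrier, replace=False)
        system = tuple(
            pairs[i].synthesis() if rng.random() < 0.5 else pairs[i].decomposition()
            for i in sorted(chosen)
        )
        result = is_physically_possible(system)
        if result.feasible:
            break
    else:
        raise RuntimeError(
            f"no feasible assignment found in {max_attempts} attempts"
        )
    log.debug("feasible assignment found after %d attempt(s)", attempt)

    witness = {m: float(g) for m, g in result.witness.items()}
    lo, hi = g_range
    vals = np.array(list(witness.values())) if witness else np.array([0.0])
    scale = np.inf
    if vals.max() > 0:
        scale = 0.8 * hi / vals.max()
    if vals.min() < 0:
        scale = min(scale, 0.8 * lo / vals.min())
    if not np.isfinite(scale):
        scale = 1.0
    g_table = {m: scale * g for m, g in witness.items()}
    for m in range(1, mass_cap + 1):
        if m not in g_table:
            g_table[m] = float(rng.uniform(lo, hi))
    assert validate_witness(system, g_table)
    uni, system = Universe.from_low_barrier(mass_cap, g_table, system)
    return uni, system


def load_config(path: str) -> SimulationConfig:
    """Read a simulation config from YAML or JSON."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data)
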
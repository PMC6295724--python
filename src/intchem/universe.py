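"""Molecules, reaction pairs, and transition-state energetics.

The model world is a well-mixed soup of molecules identified only by a
positive integer mass ``i``.  The only elementary reactions are synthesis
(``i + j -> i+j``) and decomposition (``i+j -> i + j``), so mass conservation
holds by construction.  Each molecule type carries a standard Gibbs energy of
formation ``G_i`` (kJ/mol); each reaction pair carries a barrier height
``psi`` (kJ/mol) sitting above the higher end of its Gibbs profile.  Rate
constants follow transition-state theory::

    k = beta * exp(-kappa * dG_activation)

with ``beta = k_B T / h`` and ``kappa = 1 / (R T)``.  A pair is *low-barrier*
(small psi, fast) or *high-barrier* (large psi, rare "innovation" events); a
reaction system is written down as its list of low-barrier spontaneous
reactions only, all other pairs remaining present but slow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import math

from scipy import constants as _const

__all__ = [
    "SYNTHESIS",
    "DECOMPOSITION",
    "DEFAULT_PSI_LOW",
    "DEFAULT_PSI_HIGH",
    "MoleculeType",
    "ReactionPair",
    "DirectedReaction",
    "ReactionSystem",
    "as_system",
    "Universe",
    "enumerate_pairs",
    "delta_g_standard",
    "is_spontaneous",
    "activation_energy",
    "rate_constant",
    "constants_from_conditions",
]

SYNTHESIS = "synthesis"
DECOMPOSITION = "decomposition"

#: Barrier heights (kJ/mol) used throughout for listed / unlisted pairs.
DEFAULT_PSI_LOW = 10.0
DEFAULT_PSI_HIGH = 100.0


@dataclass(frozen=True)
class MoleculeType:
    """A molecule type: an integer mass plus its standard Gibbs energy of
    formation in kJ/mol."""

    mass: int
    g_formation: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 1:
            raise ValueError(f"mass must be >= 1, got {self.mass}")
        if not math.isfinite(self.g_formation):
            raise ValueError("g_formation must be finite")


@dataclass(frozen=True, order=True)
class ReactionPair:
    """An unordered synthesis/decomposition pair ``lo + hi <-> lo+hi``.

    The pair (i, j) is identical to (j, i); the constructor canonicalises to
    ``lo <= hi``.
    """

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo < 1 or self.hi < 1:
            raise ValueError("pair members must be positive masses")
        if self.lo > self.hi:  # canonicalise (j, i) -> (i, j)
            lo, hi = self.hi, self.lo
            object.__setattr__(self, "lo", lo)
            object.__setattr__(self, "hi", hi)

    @property
    def total(self) -> int:
        return self.lo + self.hi

    def synthesis(self) -> "DirectedReaction":
        return DirectedReaction(self, SYNTHESIS)

    def decomposition(self) -> "DirectedReaction":
        return DirectedReaction(self, DECOMPOSITION)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.lo},{self.hi})<->{self.total}"


def _pair_of(reactants: Sequence[int], products: Sequence[int]) -> tuple[ReactionPair, str]:
    """Infer (pair, direction) from explicit reactant/product multisets."""
    r = sorted(reactants)
    p = sorted(products)
    if len(r) == 2 and len(p) == 1:
        pair, direction = ReactionPair(r[0], r[1]), SYNTHESIS
        if pair.total != p[0]:
            raise ValueError(f"mass not conserved: {r} -> {p}")
    elif len(r) == 1 and len(p) == 2:
        pair, direction = ReactionPair(p[0], p[1]), DECOMPOSITION
        if pair.total != r[0]:
            raise ValueError(f"mass not conserved: {r} -> {p}")
    else:
        raise ValueError(
            f"only binary synthesis or decomposition reactions exist: {r} -> {p}"
        )
    return pair, direction


@dataclass(frozen=True)
class DirectedReaction:
    """One direction of a reaction pair.

    Synthesis has reactants ``{lo, hi}`` and product ``{lo+hi}``;
    decomposition is the reverse.  Mass is conserved by construction.
    """

    pair: ReactionPair
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (SYNTHESIS, DECOMPOSITION):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_species(
        cls, reactants: Sequence[int], products: Sequence[int]
    ) -> "DirectedReaction":
        pair, direction = _pair_of(reactants, products)
        return cls(pair, direction)

    @classmethod
    def parse(cls, text: str) -> "DirectedReaction":
        """Parse ``"1 + 2 -> 3"`` / ``"4 -> 2 + 2"`` notation."""
        lhs, _, rhs = text.partition("->")
        if not rhs:
            raise ValueError(f"no '->' in reaction {text!r}")
        reactants = [int(tok) for tok in lhs.replace("+", " ").split()]
        products = [int(tok) for tok in rhs.replace("+", " ").split()]
        return cls.from_species(reactants, products)

    @property
    def reactants(self) -> tuple[int, ...]:
        if self.direction == SYNTHESIS:
            return (self.pair.lo, self.pair.hi)
        return (self.pair.total,)

    @property
    def products(self) -> tuple[int, ...]:
        if self.direction == SYNTHESIS:
            return (self.pair.total,)
        return (self.pair.lo, self.pair.hi)

    @property
    def reverse(self) -> "DirectedReaction":
        other = DECOMPOSITION if self.direction == SYNTHESIS else SYNTHESIS
        return DirectedReaction(self.pair, other)

    def species(self) -> set[int]:
        return {self.pair.lo, self.pair.hi, self.pair.total}

    def __str__(self) -> str:
        return " + ".join(map(str, self.reactants)) + " -> " + " + ".join(
            map(str, self.products)
        )


#: A reaction system ("scheme") is simply a finite ordered list of directed
#: reactions; order matters only for reporting (certificate weights etc.).
ReactionSystem = tuple[DirectedReaction, ...]


def as_system(reactions: Iterable[DirectedReaction | str]) -> ReactionSystem:
    """Normalise an iterable of reactions / ``"a + b -> c"`` strings."""
    out = []
    for r in reactions:
        out.append(DirectedReaction.parse(r) if isinstance(r, str) else r)
    return tuple(out)


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def enumerate_pairs(mass_cap: int) -> list[ReactionPair]:
    """All unordered pairs ``{i, j}`` with ``i <= j`` and ``i + j <= mass_cap``.

    Canonical order: ascending total mass, then ascending smaller member.
    ``mass_cap < 2`` yields no pairs.  At ``mass_cap = 6`` there are 9 pairs,
    which is why a six-molecule universe admits ``3**9 = 19,683`` distinct
    artificial chemistries.
    """
    pairs = [
        ReactionPair(i, total - i)
        for total in range(2, mass_cap + 1)
        for i in range(1, total // 2 + 1)
    ]
    return pairs


# ---------------------------------------------------------------------------
# Energetics
# ---------------------------------------------------------------------------

def _lookup_g(g_table: Mapping[int, float], mass: int) -> float:
    try:
        return g_table[mass]
    except KeyError:
        raise KeyError(
            f"no standard Gibbs energy of formation for molecule {mass}"
        ) from None


def delta_g_standard(reaction: DirectedReaction, g_table: Mapping[int, float]):
    """Net standard Gibbs energy change: sum G(products) - sum G(reactants).

    Negative iff the reaction is spontaneous.  Exact (Fraction) arithmetic is
    preserved when the table holds rationals, which the feasibility module
    relies on.
    """
    return sum(_lookup_g(g_table, m) for m in reaction.products) - sum(
        _lookup_g(g_table, m) for m in reaction.reactants
    )


def is_spontaneous(reaction: DirectedReaction, g_table: Mapping[int, float]) -> bool:
    """True iff the reaction runs energetically downhill (strict).

    For a pair with nonzero net energy change exactly one direction is
    spontaneous; at exactly zero both directions count as nonspontaneous.
    """
    return delta_g_standard(reaction, g_table) < 0


def activation_energy(
    reaction: DirectedReaction,
    g_table: Mapping[int, float],
    psi_table: Mapping[ReactionPair, float] | float,
) -> float:
    """Gibbs energy of activation for one direction of a pair.

    The barrier sits ``psi`` above the higher side of the reaction's Gibbs
    profile: a spontaneous direction climbs only ``psi``; the nonspontaneous
    direction additionally climbs the uphill gap ``|delta G|``.  Consequently
    ``dG_act(synthesis) - dG_act(decomposition)`` always equals the net
    synthesis energy change, which keeps the kinetics thermodynamically
    consistent.
    """
    if isinstance(psi_table, Mapping):
        psi = psi_table[reaction.pair]
    else:
        psi = psi_table
    if psi <= 0 or not math.isfinite(psi):
        raise ValueError(f"barrier height must be positive and finite, got {psi}")
    dg = delta_g_standard(reaction, g_table)
    if dg < 0:
        return float(psi)
    return float(psi + dg)


def rate_constant(reaction: DirectedReaction, universe: "Universe") -> float:
    """First-order rate constant ``beta * exp(-kappa * dG_activation)`` in 1/s."""
    dg_act = activation_energy(reaction, universe.g_table, universe.psi_for(reaction.pair))
    return universe.beta * math.exp(-universe.kappa * float(dg_act))


def constants_from_conditions(
    temperature: float = 298.15, pressure: float = 100.0
) -> tuple[float, float]:
    """Kinetic constants (beta [1/s], kappa [mol/kJ]) at the given conditions.

    ``beta = k_B T / h`` is the transition-state-theory attempt frequency and
    ``kappa = 1 / (R T)`` the inverse thermal energy; at 298.15 K these come
    out to about 6.21e12 1/s and 0.403 mol/kJ.  Pressure is carried for
    bookkeeping (the system is ideal-gas at constant T, p) but does not enter
    either formula.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    beta = _const.Boltzmann * temperature / _const.Planck
    kappa = 1.0 / (_const.R / 1000.0 * temperature)  # R in kJ/(mol K)
    return beta, kappa


# ---------------------------------------------------------------------------
# Universe
# ---------------------------------------------------------------------------

@dataclass
class Universe:
    """A chemical universe: mass cap L, energy tables and kinetic constants.

    ``g_table`` must cover every mass ``1..mass_cap``.  Barrier heights are
    given per pair via ``psi_table`` with a default (``psi_default_high``) for
    unlisted pairs, so every pair with total mass <= L has a well-defined
    kinetics and rare high-barrier events can occur anywhere in the universe.
    """

    mass_cap: int
    g_table: dict[int, float]
    psi_table: dict[ReactionPair, float] = field(default_factory=dict)
    psi_default: float = DEFAULT_PSI_HIGH
    temperature: float = 298.15
    pressure: float = 100.0
    beta: float | None = None
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.mass_cap < 1:
            raise ValueError("mass_cap must be >= 1")
        missing = [m for m in range(1, self.mass_cap + 1) if m not in self.g_table]
        if missing:
            raise ValueError(f"g_table missing masses {missing}")
        if self.beta is None or self.kappa is None:
            beta, kappa = constants_from_conditions(self.temperature, self.pressure)
            if self.beta is None:
                self.beta = beta
            if self.kappa is None:
                self.kappa = kappa
        if self.beta <= 0 or self.kappa <= 0:
            raise ValueError("beta and kappa must be positive")
        for pair, psi in self.psi_table.items():
            if pair.total > self.mass_cap:
                raise ValueError(f"pair {pair} exceeds mass cap {self.mass_cap}")
            if psi <= 0:
                raise ValueError(f"psi for {pair} must be positive")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_low_barrier(
        cls,
        mass_cap: int,
        g_table: Mapping[int, float],
        low_barrier: Iterable[DirectedReaction | str],
        psi_low: float = DEFAULT_PSI_LOW,
        psi_high: float = DEFAULT_PSI_HIGH,
        **kwargs,
    ) -> tuple["Universe", ReactionSystem]:
        """Build a universe from a listed set of low-barrier reactions.

        Listed pairs get ``psi_low``; everything else defaults to
        ``psi_high``.  Returns the universe together with the normalised
        reaction list.
        """
        system = as_system(low_barrier)
        psi_table = {r.pair: float(psi_low) for r in system}
        uni = cls(
            mass_cap=mass_cap,
            g_table=dict(g_table),
            psi_table=psi_table,
            psi_default=float(psi_high),
            **kwargs,
        )
        return uni, system

    def psi_for(self, pair: ReactionPair) -> float:
        return self.psi_table.get(pair, self.psi_default)

    def pairs(self) -> list[ReactionPair]:
        return enumerate_pairs(self.mass_cap)

    def all_reactions(self) -> list[DirectedReaction]:
        """Every directed reaction in the universe (both directions of every
        pair), in canonical pair order, synthesis before decomposition."""
        out: list[DirectedReaction] = []
        for pair in self.pairs():
            out.append(pair.synthesis())
            out.append(pair.decomposition())
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        low = sorted(
            (p for p in self.psi_table), key=lambda p: (p.total, p.lo)
        )
        return {
            "mass_cap": self.mass_cap,
            "g_table": {int(m): float(g) for m, g in sorted(self.g_table.items())},
            "psi_pairs": {f"{p.lo}+{p.hi}": float(self.psi_table[p]) for p in low},
            "psi_default": float(self.psi_default),
            "temperature": self.temperature,
            "pressure": self.pressure,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Universe":
        psi_table = {}
        for key, psi in data.get("psi_pairs", {}).items():
            lo, hi = (int(tok) for tok in key.split("+"))
            psi_table[ReactionPair(lo, hi)] = float(psi)
        return cls(
            mass_cap=int(data["mass_cap"]),
            g_table={int(m): float(g) for m, g in data["g_table"].items()},
            psi_table=psi_table,
            psi_default=float(data.get("psi_default", DEFAULT_PSI_HIGH)),
            temperature=float(data.get("temperature", 298.15)),
            pressure=float(data.get("pressure", 100.0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
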
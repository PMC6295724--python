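"""Physical possibility of a reaction system.

A listed reaction system is *physically possible* when some assignment of
standard Gibbs energies of formation makes every listed reaction strictly
spontaneous, i.e. the homogeneous system

    sum G(reactants) - sum G(products) > 0      (one row per reaction)

has a solution.  Because the system is homogeneous, strict feasibility is
equivalent to feasibility of ``row . G >= 1`` for every row, which is decided
here by exact integer/rational Fourier-Motzkin elimination.  Each derived
inequality carries the nonnegative multipliers over the original reactions
that produced it, so the procedure returns either

* a **witness**: an exact rational ``g_table`` under which every reaction is
  strictly downhill, or
* a **certificate**: nonnegative integer weights, not all zero, whose
  weighted net stoichiometry cancels every species (the weighted sum of the
  reactions is ``nothing -> nothing``, so they cannot all be downhill).

Exactly one of the two exists (Gordan's theorem); exact arithmetic keeps the
enumeration counts built on top of this decision tolerance-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Mapping, Sequence

from .universe import DirectedReaction, ReactionSystem, as_system, delta_g_standard

__all__ = [
    "FeasibilityResult",
    "is_physically_possible",
    "validate_witness",
    "validate_certificate",
    "unit_cancellation_certificate",
]

# Safety valve: Fourier-Motzkin can in principle blow up; for the small
# systems of this model (<= ~13 rows, <= ~7 species) it never comes close.
_MAX_CONSTRAINTS = 200_000


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of a feasibility decision.

    ``witness`` (mass -> Fraction) is present iff feasible; ``certificate``
    (one nonnegative integer weight per reaction, in input order, scaled to
    smallest integers) is present iff infeasible.
    """

    feasible: bool
    witness: dict[int, Fraction] | None = None
    certificate: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "witness": None
            if self.witness is None
            else {int(m): float(g) for m, g in sorted(self.witness.items())},
            "certificate": None
            if self.certificate is None
            else list(self.certificate),
        }


def _net_vectors(system: ReactionSystem, species: Sequence[int]) -> list[list[int]]:
    """Row per reaction: reactant counts minus product counts per species."""
    index = {m: k for k, m in enumerate(species)}
    rows = []
    for r in system:
        row = [0] * len(species)
        for m in r.reactants:
            row[index[m]] += 1
        for m in r.products:
            row[index[m]] -= 1
        rows.append(row)
    return rows


def _normalise(coeffs: tuple[int, ...], rhs: int, mult: tuple[int, ...]):
    g = 0
    for v in coeffs:
        g = gcd(g, v)
    g = gcd(g, rhs)
    for v in mult:
        g = gcd(g, v)
    if g > 1:
        coeffs = tuple(v // g for v in coeffs)
        rhs //= g
        mult = tuple(v // g for v in mult)
    return coeffs, rhs, mult


def is_physically_possible(
    reactions: ReactionSystem | Sequence[DirectedReaction | str],
    mass_cap: int | None = None,
) -> FeasibilityResult:
    """Decide whether a reaction list admits strictly spontaneous energies.

    Feasible iff some g_table makes every listed reaction strictly downhill.
    The empty list is trivially feasible.  ``mass_cap``, when given, only
    validates that no species exceeds it.
    """
    system = as_system(reactions)
    if mass_cap is not None:
        for r in system:
            bad = [m for m in r.species() if m > mass_cap]
            if bad:
                raise ValueError(f"species {bad} in {r} exceed mass cap {mass_cap}")
    if not system:
        return FeasibilityResult(feasible=True, witness={})

    species = sorted({m for r in system for m in r.species()})
    rows = _net_vectors(system, species)
    m = len(system)

    # Constraints: coeffs . G >= rhs with rhs > 0, each carrying integer
    # multipliers over the original rows.  Start with row_i . G >= 1.
    constraints: list[tuple[tuple[int, ...], int, tuple[int, ...]]] = []
    for i, row in enumerate(rows):
        mult = tuple(1 if j == i else 0 for j in range(m))
        constraints.append(_normalise(tuple(row), 1, mult))

    n = len(species)
    remaining = list(range(n))
    # Bookkeeping for witness back-substitution: (var, constraints alive when
    # the variable was eliminated).
    levels: list[tuple[int, list[tuple[tuple[int, ...], int, tuple[int, ...]]]]] = []

    while remaining:
        # A constraint with all-zero coefficients reads 0 >= rhs > 0: the
        # multipliers are a cancellation certificate.
        for coeffs, rhs, mult in constraints:
            if all(v == 0 for v in coeffs):
                return FeasibilityResult(feasible=False, certificate=mult)

        # Greedy elimination order: fewest pairwise combinations first.
        def _cost(var: int) -> int:
            pos = sum(1 for c, _, _ in constraints if c[var] > 0)
            neg = sum(1 for c, _, _ in constraints if c[var] < 0)
            return pos * neg - pos - neg

        var = min(remaining, key=_cost)
        remaining.remove(var)
        levels.append((var, constraints))

        pos = [c for c in constraints if c[0][var] > 0]
        neg = [c for c in constraints if c[0][var] < 0]
        zero = [c for c in constraints if c[0][var] == 0]

        new: dict[tuple[int, ...], tuple[int, tuple[int, ...]]] = {}
        for zc in zero:
            coeffs, rhs, mult = zc
            old = new.get(coeffs)
            if old is None or rhs > old[0]:
                new[coeffs] = (rhs, mult)
        for cp, rp, mp in pos:
            a = cp[var]
            for cn, rn, mn in neg:
                b = -cn[var]
                # b * (pos) + a * (neg) eliminates var, stays in >= form.
                coeffs = tuple(b * x + a * y for x, y in zip(cp, cn))
                rhs = b * rp + a * rn
                mult = tuple(b * x + a * y for x, y in zip(mp, mn))
                coeffs, rhs, mult = _normalise(coeffs, rhs, mult)
                old = new.get(coeffs)
                if old is None or rhs > old[0]:
                    new[coeffs] = (rhs, mult)
        constraints = [(c, r, u) for c, (r, u) in new.items()]
        if len(constraints) > _MAX_CONSTRAINTS:  # pragma: no cover - guard
            raise RuntimeError("Fourier-Motzkin blow-up; system too large")

    for coeffs, rhs, mult in constraints:
        if all(v == 0 for v in coeffs):
            return FeasibilityResult(feasible=False, certificate=mult)

    # Feasible: back-substitute a rational witness in reverse order.
    values: dict[int, Fraction] = {}
    for var, cons in reversed(levels):
        lower: Fraction | None = None
        upper: Fraction | None = None
        for coeffs, rhs, _ in cons:
            a = coeffs[var]
            if a == 0:
                continue
            rest = sum(
                Fraction(coeffs[j]) * values[j]
                for j in range(n)
                if j != var and coeffs[j] != 0
            )
            bound = (Fraction(rhs) - rest) / a
            if a > 0:
                lower = bound if lower is None else max(lower, bound)
            else:
                upper = bound if upper is None else min(upper, bound)
        if lower is not None and upper is not None:
            values[var] = (lower + upper) / 2
        elif lower is not None:
            values[var] = lower + 1
        elif upper is not None:
            values[var] = upper - 1
        else:
            values[var] = Fraction(0)

    witness = {species[j]: values[j] for j in range(n)}
    return FeasibilityResult(feasible=True, witness=witness)


def validate_witness(
    reactions: ReactionSystem | Sequence[DirectedReaction | str],
    g_table: Mapping[int, float | Fraction],
) -> bool:
    """True iff every reaction is strictly spontaneous under ``g_table``."""
    system = as_system(reactions)
    return all(delta_g_standard(r, g_table) < 0 for r in system)


def unit_cancellation_certificate(
    reactions: ReactionSystem | Sequence[DirectedReaction | str],
) -> tuple[int, ...] | None:
    """Find a 0/1-weight cancellation certificate, if one exists.

    A *unit-weight* certificate is a subset of the reactions whose plain sum
    cancels every species — the "add up the reactions and everything cancels"
    screen.  It is a strictly weaker infeasibility test than
    :func:`is_physically_possible`: some infeasible systems only cancel with
    integer weights >= 2 and are invisible to this screen (the smallest
    examples live at mass cap 6).  Returns the 0/1 weight tuple or None.
    """
    from itertools import combinations

    system = as_system(reactions)
    species = sorted({m for r in system for m in r.species()})
    rows = _net_vectors(system, species)
    n = len(system)
    for size in range(2, n + 1):
        for comb in combinations(range(n), size):
            acc = [0] * len(species)
            for i in comb:
                row = rows[i]
                for j in range(len(species)):
                    acc[j] += row[j]
            if all(v == 0 for v in acc):
                return tuple(1 if i in comb else 0 for i in range(n))
    return None


def validate_certificate(
    reactions: ReactionSystem | Sequence[DirectedReaction | str],
    weights: Sequence[int],
) -> bool:
    """Check a cancellation certificate: nonnegative, not all zero, and the
    weighted net stoichiometry (products minus reactants) is zero for every
    species."""
    system = as_system(reactions)
    if len(weights) != len(system):
        return False
    if any(w < 0 for w in weights) or all(w == 0 for w in weights):
        return False
    net: dict[int, int] = {}
    for w, r in zip(weights, system):
        for mm in r.products:
            net[mm] = net.get(mm, 0) + w
        for mm in r.reactants:
            net[mm] = net.get(mm, 0) - w
    return all(v == 0 for v in net.values())
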
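"""Stoichiometric classification of reaction systems.

Summing a system's low-barrier reactions (each counted once) and cancelling
species that appear on both sides yields the system's *overall reaction*.
On top of that summation sit sufficient criteria distinguishing how a
reaction set, fed by reservoir resources, can sustain itself:

* **self-driven** - every reaction has at least one reactant produced by
  some *other* reaction in the set (the set feeds itself);
* **collectively catalytic** - self-driven, and every intermediate (a
  species on both the reactant and the product side) is exactly balanced:
  the set turns resources into end products at a steady rate, the
  intermediates acting as a catalytic cycle (citric-acid-cycle-like);
* **self-replicating** - self-driven, at least one intermediate is
  overproduced and none is over-consumed: intermediate populations grow
  exponentially (formose-like).

The criteria are sufficient, not necessary, so subset searches over a
chemistry produce lower bounds on how many chemistries contain such systems.
Everything here is purely stoichiometric; no dynamics are simulated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .universe import DirectedReaction, ReactionSystem, as_system

__all__ = [
    "COLLECTIVELY_CATALYTIC",
    "SELF_REPLICATING",
    "SELF_DRIVEN_OTHER",
    "NOT_SELF_DRIVEN",
    "SpeciesBalance",
    "ClassificationReport",
    "species_balance",
    "intermediates",
    "overall_reaction",
    "is_self_driven",
    "classify",
    "find_subsystems",
]

COLLECTIVELY_CATALYTIC = "collectively_catalytic"
SELF_REPLICATING = "self_replicating"
SELF_DRIVEN_OTHER = "self_driven_other"
NOT_SELF_DRIVEN = "not_self_driven"


@dataclass(frozen=True)
class SpeciesBalance:
    """Occurrence counts of one species when the reactions are summed with
    unit multiplicity (multiset occurrences within a single reaction count
    with multiplicity: ``4 -> 2 + 2`` contributes 2 to the product side of
    species 2)."""

    species: int
    reactant_count: int
    product_count: int

    @property
    def net(self) -> int:
        return self.product_count - self.reactant_count


@dataclass(frozen=True)
class ClassificationReport:
    """Label plus the certificates behind it.

    ``resources_inferred`` are species consumed but never produced within
    the set (externally supplied); ``end_products`` are produced but never
    consumed; ``overall_net`` maps species to the net coefficient of the
    overall reaction (negative = consumed).
    """

    label: str
    intermediates: frozenset[int]
    resources_inferred: frozenset[int]
    end_products: frozenset[int]
    overall_net: dict[int, int] = field(hash=False)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "intermediates": sorted(self.intermediates),
            "resources": sorted(self.resources_inferred),
            "end_products": sorted(self.end_products),
            "overall_net": {int(k): v for k, v in sorted(self.overall_net.items())},
        }


def species_balance(system: ReactionSystem | Sequence) -> list[SpeciesBalance]:
    """Per-species reactant/product occurrence counts, each reaction counted
    once, in ascending species order."""
    system = as_system(system)
    if not system:
        raise ValueError("species_balance requires a nonempty system")
    react: Counter[int] = Counter()
    prod: Counter[int] = Counter()
    for r in system:
        react.update(r.reactants)
        prod.update(r.products)
    return [
        SpeciesBalance(m, react[m], prod[m])
        for m in sorted(set(react) | set(prod))
    ]


def intermediates(system: ReactionSystem | Sequence) -> set[int]:
    """Species appearing on both the reactant and the product side."""
    return {
        b.species
        for b in species_balance(system)
        if b.reactant_count > 0 and b.product_count > 0
    }


def overall_reaction(system: ReactionSystem | Sequence) -> dict[int, int]:
    """Net coefficients after summing all reactions and cancelling fully.

    Negative coefficient = net consumed, positive = net produced; balanced
    species are omitted.  The mass-weighted sum of coefficients is always
    zero.
    """
    return {
        b.species: b.net for b in species_balance(system) if b.net != 0
    }


def is_self_driven(system: ReactionSystem | Sequence) -> bool:
    """True iff every reaction has >= 1 reactant among the products of the
    *other* reactions in the set (a single reaction is never self-driven)."""
    system = as_system(system)
    if not system:
        raise ValueError("is_self_driven requires a nonempty system")
    all_products = [set(r.products) for r in system]
    for i, r in enumerate(system):
        fed = False
        for j, prods in enumerate(all_products):
            if j != i and prods.intersection(r.reactants):
                fed = True
                break
        if not fed:
            return False
    return True


def classify(system: ReactionSystem | Sequence) -> ClassificationReport:
    """Apply the sufficient stoichiometric criteria, in order.

    Not self-driven -> ``not_self_driven``.  Self-driven with every
    intermediate balanced -> ``collectively_catalytic``.  Self-driven with
    some intermediate overproduced and none over-consumed ->
    ``self_replicating``.  Anything else self-driven (some intermediate
    over-consumed) -> ``self_driven_other``, an honest bucket covering e.g.
    nonsustaining sets that burn their own intermediates.  The first two
    positive labels are mutually exclusive: balanced cancelling contradicts
    overproduction.
    """
    system = as_system(system)
    balances = species_balance(system)
    inter = {
        b.species for b in balances if b.reactant_count > 0 and b.product_count > 0
    }
    resources = frozenset(
        b.species for b in balances if b.product_count == 0
    )
    ends = frozenset(b.species for b in balances if b.reactant_count == 0)
    overall = {b.species: b.net for b in balances if b.net != 0}

    if not is_self_driven(system):
        label = NOT_SELF_DRIVEN
    else:
        nets = [b.net for b in balances if b.species in inter]
        if all(v == 0 for v in nets):
            label = COLLECTIVELY_CATALYTIC
        elif any(v > 0 for v in nets) and not any(v < 0 for v in nets):
            label = SELF_REPLICATING
        else:
            label = SELF_DRIVEN_OTHER
    return ClassificationReport(
        label=label,
        intermediates=frozenset(inter),
        resources_inferred=resources,
        end_products=ends,
        overall_net=overall,
    )


def find_subsystems(
    reactions: ReactionSystem | Sequence,
    min_size: int = 2,
    max_reactions: int = 20,
) -> list[tuple[tuple[int, ...], ClassificationReport]]:
    """Exhaustive search for qualifying (self-driven) subsets.

    Returns every subset of size >= ``min_size`` whose classification is not
    ``not_self_driven``, as ``(indices, report)`` with indices into the input
    list, ordered by subset size then lexicographic indices.  ``min_size``
    defaults to 2 because a lone reaction cannot be fed by "other" reactions.
    """
    system = as_system(reactions)
    if len(system) > max_reactions:
        raise ValueError(
            f"{len(system)} reactions exceeds the exhaustive-search cap "
            f"{max_reactions}; raise max_reactions explicitly to proceed"
        )
    out = []
    for size in range(max(min_size, 1), len(system) + 1):
        for idx in combinations(range(len(system)), size):
            subset = tuple(system[i] for i in idx)
            report = classify(subset)
            if report.label != NOT_SELF_DRIVEN:
                out.append((idx, report))
    return out
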
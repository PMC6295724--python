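"""Exhaustive enumeration of artificial chemistries.

An *artificial chemistry* (AC) at mass cap L is one ternary assignment over
all reaction pairs with total mass <= L: each pair is either high-barrier,
or low-barrier with one chosen spontaneous direction.  With P pairs there
are ``3**P`` ACs (9 pairs and 19,683 ACs at L = 6).

This module counts, per L,

* how many ACs are physically possible (their low-barrier reaction list is
  strictly feasible; the empty list counts),
* how many of those *contain* a self-driven system - a subset (size >= 2) of
  their low-barrier reactions in which every reaction is fed by another -
* and lower bounds on how many contain collectively catalytic or
  self-replicating systems: ACs whose full low-barrier list (>= 2 reactions)
  satisfies the balanced-cancelling, resp. overproduction plus no-overintake
  criteria.  (Subset-existence would give a larger - still valid - lower
  bound; whole-list classification is the convention this census adopts.
  Subset searches remain available through
  :func:`intchem.stoichiometry.find_subsystems`.)

Two performance facts are exploited.  Feasibility is antitone in the
low-barrier set (any superset of an infeasible list is infeasible), so the
ternary assignment tree is pruned as soon as a prefix is infeasible.
Containment is monotone (a superset of an AC containing a qualifying subset
still contains it), so qualifying subsets are precomputed once per L over
the whole directed-reaction alphabet, reduced to their minimal elements and
matched against each AC by bitmask inclusion.  A naive unpruned path is kept
alongside for cross-validation at small L.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Literal, Sequence

from .feasibility import is_physically_possible, unit_cancellation_certificate
from .stoichiometry import (
    COLLECTIVELY_CATALYTIC,
    NOT_SELF_DRIVEN,
    SELF_REPLICATING,
    classify,
)
from .universe import DirectedReaction, ReactionPair, enumerate_pairs

__all__ = [
    "ArtificialChemistry",
    "EnumerationRow",
    "enumerate_acs",
    "count_physically_possible",
    "count_containing",
    "table1",
    "naive_counts",
]

Target = Literal["self_driven", "collectively_catalytic", "self_replicating"]

#: Above this many pairs an exhaustive run is refused unless the caller
#: raises the cap (3**P assignments; 12 pairs at L = 7 is ~531k).
DEFAULT_MAX_PAIRS = 12

HIGH_BARRIER = 0
LOW_SYNTHESIS = 1
LOW_DECOMPOSITION = 2


@dataclass(frozen=True)
class ArtificialChemistry:
    """One ternary assignment over the canonical pair list at ``mass_cap``.

    ``assignment[k]`` refers to the k-th pair in canonical order (ascending
    total, then ascending smaller member).
    """

    mass_cap: int
    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        n_pairs = len(enumerate_pairs(self.mass_cap))
        if len(self.assignment) != n_pairs:
            raise ValueError(
                f"assignment covers {len(self.assignment)} pairs, "
                f"expected {n_pairs} at L={self.mass_cap}"
            )
        if any(a not in (0, 1, 2) for a in self.assignment):
            raise ValueError("assignment entries must be 0, 1 or 2")

    @property
    def pairs(self) -> list[ReactionPair]:
        return enumerate_pairs(self.mass_cap)

    @property
    def low_barrier_reactions(self) -> tuple[DirectedReaction, ...]:
        out = []
        for pair, a in zip(self.pairs, self.assignment):
            if a == LOW_SYNTHESIS:
                out.append(pair.synthesis())
            elif a == LOW_DECOMPOSITION:
                out.append(pair.decomposition())
        return tuple(out)


@dataclass(frozen=True)
class EnumerationRow:
    """One row of the AC census at a given mass cap."""

    mass_cap: int
    total_acs: int
    physically_possible: int
    with_self_driven: int
    with_cc_lower_bound: int
    with_sr_lower_bound: int

    def percentages(self) -> dict[str, float]:
        """Shares of the physically possible ACs, in percent."""
        pp = self.physically_possible
        if pp == 0:
            return {"self_driven": 0.0, "cc": 0.0, "sr": 0.0}
        return {
            "self_driven": 100.0 * self.with_self_driven / pp,
            "cc": 100.0 * self.with_cc_lower_bound / pp,
            "sr": 100.0 * self.with_sr_lower_bound / pp,
        }

    def to_dict(self) -> dict:
        d = {
            "mass_cap": self.mass_cap,
            "total_acs": self.total_acs,
            "physically_possible": self.physically_possible,
            "with_self_driven": self.with_self_driven,
            "with_cc_lower_bound": self.with_cc_lower_bound,
            "with_sr_lower_bound": self.with_sr_lower_bound,
        }
        d["percentages"] = self.percentages()
        return d


def _check_cap(mass_cap: int, max_pairs: int) -> list[ReactionPair]:
    if mass_cap < 2:
        raise ValueError("mass_cap must be >= 2")
    pairs = enumerate_pairs(mass_cap)
    if len(pairs) > max_pairs:
        raise ValueError(
            f"{len(pairs)} pairs at L={mass_cap} exceeds max_pairs={max_pairs} "
            f"(3**{len(pairs)} assignments); raise max_pairs to proceed"
        )
    return pairs


def enumerate_acs(
    mass_cap: int, max_pairs: int = DEFAULT_MAX_PAIRS
) -> Iterator[ArtificialChemistry]:
    """Yield every AC exactly once, in base-3 order over the canonical pair
    list (pair 0 is the least significant digit)."""
    pairs = _check_cap(mass_cap, max_pairs)
    n = len(pairs)
    for code in range(3**n):
        digits = []
        c = code
        for _ in range(n):
            digits.append(c % 3)
            c //= 3
        yield ArtificialChemistry(mass_cap, tuple(digits))


# ---------------------------------------------------------------------------
# Fast survey: one pass per L, cached
# ---------------------------------------------------------------------------

def _directed_alphabet(pairs: Sequence[ReactionPair]):
    """Directed reactions indexed 2k (synthesis) / 2k+1 (decomposition)."""
    reactions = []
    for pair in pairs:
        reactions.append(pair.synthesis())
        reactions.append(pair.decomposition())
    reactants = [r.reactants for r in reactions]
    products = [r.products for r in reactions]
    return reactions, reactants, products


def _mask_label(idxs, reactants, products) -> str:
    """Classification label of the reaction subset given by indices; a
    stripped-down equivalent of :func:`intchem.stoichiometry.classify`."""
    prods = [set(products[i]) for i in idxs]
    for pos, i in enumerate(idxs):
        rs = reactants[i]
        if not any(
            q != pos and (rs[0] in prods[q] or (len(rs) > 1 and rs[1] in prods[q]))
            for q in range(len(idxs))
        ):
            return NOT_SELF_DRIVEN
    react_count: dict[int, int] = {}
    prod_count: dict[int, int] = {}
    for i in idxs:
        for mm in reactants[i]:
            react_count[mm] = react_count.get(mm, 0) + 1
        for mm in products[i]:
            prod_count[mm] = prod_count.get(mm, 0) + 1
    nets = [
        prod_count[mm] - react_count[mm]
        for mm in react_count
        if mm in prod_count
    ]
    if all(v == 0 for v in nets):
        return COLLECTIVELY_CATALYTIC
    if any(v > 0 for v in nets) and not any(v < 0 for v in nets):
        return SELF_REPLICATING
    return "self_driven_other"


def _minimal_masks(masks: list[int]) -> list[int]:
    """Minimal elements under bitmask inclusion (input need not be sorted)."""
    minimal: list[int] = []
    for m in sorted(masks, key=lambda x: x.bit_count()):
        if not any(k & m == k for k in minimal):
            minimal.append(m)
    return minimal


def _minimal_self_driven(pairs) -> list[int]:
    """Minimal self-driven subsets over the directed alphabet.

    Containment of a self-driven subset is monotone in the low-barrier set,
    so an AC contains one iff its bitmask is a superset of a minimal
    self-driven mask.  Subsets containing both directions of a pair can
    never occur inside an AC, so only conflict-free subsets (one of {none,
    synthesis, decomposition} per pair) are enumerated: 3**P of them.
    """
    _, reactants, products = _directed_alphabet(pairs)
    n = len(pairs)
    sd: list[int] = []
    # Iterate conflict-free subsets as base-3 codes; sizes < 2 never qualify.
    for code in range(3**n):
        idxs = []
        mask = 0
        c = code
        for k in range(n):
            a = c % 3
            c //= 3
            if a:
                i = 2 * k + (a - 1)
                idxs.append(i)
                mask |= 1 << i
        if len(idxs) < 2:
            continue
        if _mask_label(idxs, reactants, products) != NOT_SELF_DRIVEN:
            sd.append(mask)
    return _minimal_masks(sd)


def _feasible_masks(pairs, screen: str = "exact") -> list[int]:
    """Bitmasks (over the directed alphabet) of the low-barrier sets of all
    physically possible ACs, found by depth-first assignment with pruning:
    any superset of an infeasible reaction list is infeasible.

    ``screen="exact"`` uses the exact strict-feasibility decision;
    ``screen="unit_cancellation"`` uses the weaker 0/1-weight cancellation
    screen (kept as a diagnostic: at mass cap 6 it admits 138 assignments
    that exact feasibility refutes with weight->=2 certificates).
    """
    reactions, _, _ = _directed_alphabet(pairs)
    n = len(pairs)
    feasible: list[int] = []
    if screen == "exact":
        def infeasible(current): return not is_physically_possible(current).feasible
    elif screen == "unit_cancellation":
        def infeasible(current): return unit_cancellation_certificate(current) is not None
    else:
        raise ValueError(f"unknown screen {screen!r}")

    def recurse(k: int, current: list[DirectedReaction], mask: int) -> None:
        if current and infeasible(current):
            return
        if k == n:
            feasible.append(mask)
            return
        recurse(k + 1, current, mask)  # high-barrier: no new constraint
        for off in (0, 1):
            i = 2 * k + off
            current.append(reactions[i])
            recurse(k + 1, current, mask | (1 << i))
            current.pop()

    recurse(0, [], 0)
    return feasible


_SURVEY_CACHE: dict[tuple[int, str], dict] = {}


def _survey(
    mass_cap: int, max_pairs: int = DEFAULT_MAX_PAIRS, screen: str = "exact"
) -> dict:
    key = (mass_cap, screen)
    if key in _SURVEY_CACHE:
        return _SURVEY_CACHE[key]
    pairs = _check_cap(mass_cap, max_pairs)
    feasible = _feasible_masks(pairs, screen)
    minimal_sd = _minimal_self_driven(pairs)
    _, reactants, products = _directed_alphabet(pairs)

    sd = cc = sr = 0
    for m in feasible:
        if any(q & m == q for q in minimal_sd):
            sd += 1
        idxs = [i for i in range(2 * len(pairs)) if m >> i & 1]
        if len(idxs) >= 2:
            label = _mask_label(idxs, reactants, products)
            if label == COLLECTIVELY_CATALYTIC:
                cc += 1
            elif label == SELF_REPLICATING:
                sr += 1
    row = EnumerationRow(
        mass_cap=mass_cap,
        total_acs=3 ** len(pairs),
        physically_possible=len(feasible),
        with_self_driven=sd,
        with_cc_lower_bound=cc,
        with_sr_lower_bound=sr,
    )
    result = {"row": row, "feasible_masks": feasible, "minimal_self_driven": minimal_sd}
    _SURVEY_CACHE[key] = result
    return result


def count_physically_possible(
    mass_cap: int, max_pairs: int = DEFAULT_MAX_PAIRS, screen: str = "exact"
) -> int:
    """Number of ACs whose low-barrier list is strictly feasible (the empty
    list counts as feasible).  ``screen="unit_cancellation"`` counts under
    the weaker diagnostic screen instead (see :func:`_feasible_masks`)."""
    return _survey(mass_cap, max_pairs, screen)["row"].physically_possible


def count_containing(
    mass_cap: int,
    target: Target,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    screen: str = "exact",
) -> int:
    """Number of physically possible ACs containing the target system.

    ``self_driven`` counts ACs with >= 1 self-driven subset (size >= 2) of
    their low-barrier reactions.  ``collectively_catalytic`` /
    ``self_replicating`` count ACs whose full low-barrier list meets the
    respective criteria - lower bounds twice over, since the criteria are
    sufficient rather than necessary and qualifying proper subsets are not
    credited (see the module docstring)."""
    survey = _survey(mass_cap, max_pairs, screen)
    row = survey["row"]
    if target == "self_driven":
        return row.with_self_driven
    if target == "collectively_catalytic":
        return row.with_cc_lower_bound
    if target == "self_replicating":
        return row.with_sr_lower_bound
    raise ValueError(f"unknown target {target!r}")


def table1(
    mass_caps: Sequence[int],
    max_pairs: int = DEFAULT_MAX_PAIRS,
    screen: str = "exact",
) -> list[EnumerationRow]:
    """The AC census, one row per mass cap."""
    return [_survey(L, max_pairs, screen)["row"] for L in mass_caps]


# ---------------------------------------------------------------------------
# Naive reference path (cross-validation at small L)
# ---------------------------------------------------------------------------

def naive_counts(mass_cap: int, max_pairs: int = 9) -> EnumerationRow:
    """Unpruned brute force: feasibility per AC, subset search per AC via the
    generic classifier.  Exponentially slower than the survey path but
    independent of its pruning and bitmask machinery; the two must agree
    exactly."""
    pairs = _check_cap(mass_cap, max_pairs)
    total = pp = sd = cc = sr = 0
    for ac in enumerate_acs(mass_cap, max_pairs):
        total += 1
        low = ac.low_barrier_reactions
        if not is_physically_possible(low).feasible:
            continue
        pp += 1
        has_sd = False
        for size in range(2, len(low) + 1):
            if has_sd:
                break
            for idx in combinations(range(len(low)), size):
                if classify([low[i] for i in idx]).label != NOT_SELF_DRIVEN:
                    has_sd = True
                    break
        sd += has_sd
        if len(low) >= 2:
            label = classify(low).label
            cc += label == COLLECTIVELY_CATALYTIC
            sr += label == SELF_REPLICATING
    return EnumerationRow(mass_cap, total, pp, sd, cc, sr)
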
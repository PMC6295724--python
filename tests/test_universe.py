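import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intchem import (
    DirectedReaction,
    ReactionPair,
    Universe,
    activation_energy,
    as_system,
    constants_from_conditions,
    delta_g_standard,
    enumerate_pairs,
    is_spontaneous,
    rate_constant,
)

G_CYCLE = {1: -780, 2: -500, 3: -490, 4: -190, 5: -830, 6: -900}
G_FORMOSE = {1: 220, 2: -760, 3: -970, 4: -1160}


class TestReactionTypes:
    def test_pair_is_unordered(self):
        assert ReactionPair(4, 2) == ReactionPair(2, 4)
        assert ReactionPair(2, 4).total == 6

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            ReactionPair(0, 3)

    @pytest.mark.parametrize(
        "text,reactants,products",
        [
            ("1 + 2 -> 3", (1, 2), (3,)),
            ("4 -> 2 + 2", (4,), (2, 2)),
            ("6->1+5", (6,), (1, 5)),
        ],
    )
    def test_parse_roundtrip(self, text, reactants, products):
        r = DirectedReaction.parse(text)
        assert r.reactants == reactants
        assert r.products == products
        assert sum(r.reactants) == sum(r.products)
        assert r.reverse.reverse == r

    def test_mass_violating_reaction_rejected(self):
        with pytest.raises(ValueError):
            DirectedReaction.parse("1 + 2 -> 4")


class TestEnumeratePairs:
    @pytest.mark.parametrize("mass_cap,expected", [(6, 9), (2, 1), (7, 12), (1, 0)])
    def test_counts(self, mass_cap, expected):
        assert len(enumerate_pairs(mass_cap)) == expected

    def test_matches_brute_force_and_order(self):
        for cap in range(2, 21):
            pairs = enumerate_pairs(cap)
            brute = {
                (i, j)
                for i in range(1, cap + 1)
                for j in range(i, cap + 1)
                if i + j <= cap
            }
            assert {(p.lo, p.hi) for p in pairs} == brute
            assert len(pairs) == len(brute)
            keys = [(p.total, p.lo) for p in pairs]
            assert keys == sorted(keys)


class TestEnergetics:
    def test_cycle_decomposition_energy(self):
        r = DirectedReaction.parse("5 -> 1 + 4")
        assert delta_g_standard(r, G_CYCLE) == -140

    def test_formose_decomposition_energy(self):
        r = DirectedReaction.parse("4 -> 2 + 2")
        assert delta_g_standard(r, {2: -760, 4: -1160}) == -360

    def test_all_equal_energies_give_zero(self):
        r = DirectedReaction.parse("1 + 2 -> 3")
        assert delta_g_standard(r, {1: 0, 2: 0, 3: 0}) == 0
        # zero net change: neither direction is (strictly) spontaneous
        assert not is_spontaneous(r, {1: 0, 2: 0, 3: 0})
        assert not is_spontaneous(r.reverse, {1: 0, 2: 0, 3: 0})

    def test_missing_species_identified(self):
        with pytest.raises(KeyError, match="5"):
            delta_g_standard(DirectedReaction.parse("5 -> 1 + 4"), {1: 0, 4: 0})

    def test_cycle_spontaneity(self):
        assert is_spontaneous(DirectedReaction.parse("2 + 4 -> 6"), G_CYCLE)
        assert not is_spontaneous(DirectedReaction.parse("1 + 5 -> 6"), G_CYCLE)
        assert is_spontaneous(DirectedReaction.parse("6 -> 1 + 5"), G_CYCLE)

    @given(
        g=st.lists(
            st.integers(min_value=-1500, max_value=300), min_size=6, max_size=6
        ),
        lo=st.integers(1, 3),
        hi=st.integers(1, 3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_direction_exclusivity(self, g, lo, hi):
        """For nonzero net energy change exactly one direction is downhill."""
        g_table = {m + 1: g[m] for m in range(6)}
        pair = ReactionPair(lo, hi)
        syn, dec = pair.synthesis(), pair.decomposition()
        if delta_g_standard(syn, g_table) != 0:
            assert is_spontaneous(syn, g_table) != is_spontaneous(dec, g_table)
        else:
            assert not is_spontaneous(syn, g_table)
            assert not is_spontaneous(dec, g_table)

    def test_activation_energy_branches(self):
        r = DirectedReaction.parse("5 -> 1 + 4")  # downhill by 140
        assert activation_energy(r, G_CYCLE, 10.0) == 10.0
        uphill = r.reverse  # uphill by 140
        assert activation_energy(uphill, G_CYCLE, 10.0) == 150.0

    @given(
        g=st.lists(
            st.integers(min_value=-1500, max_value=300), min_size=6, max_size=6
        ),
        lo=st.integers(1, 3),
        hi=st.integers(1, 3),
        psi=st.floats(min_value=0.5, max_value=200),
    )
    @settings(derandomize=True, max_examples=100)
    def test_thermodynamic_consistency(self, g, lo, hi, psi):
        """Barrier difference between directions equals the net energy change."""
        g_table = {m + 1: g[m] for m in range(6)}
        pair = ReactionPair(lo, hi)
        syn, dec = pair.synthesis(), pair.decomposition()
        diff = activation_energy(syn, g_table, psi) - activation_energy(
            dec, g_table, psi
        )
        assert diff == pytest.approx(delta_g_standard(syn, g_table), abs=1e-9)
        assert activation_energy(syn, g_table, psi) >= psi > 0


class TestRateConstants:
    @pytest.fixture()
    def cycle_universe(self):
        uni, _ = Universe.from_low_barrier(
            6, G_CYCLE, ["5 -> 1 + 4", "6 -> 1 + 5", "2 + 4 -> 6"]
        )
        return uni

    def test_low_barrier_rate(self, cycle_universe):
        # closed form with the printed constants: 6.21e12 * exp(-0.403*10)
        k = rate_constant(DirectedReaction.parse("5 -> 1 + 4"), cycle_universe)
        assert k == pytest.approx(6.21e12 * math.exp(-0.403 * 10), rel=0.01)
        assert k == pytest.approx(1.10e11, rel=0.01)

    def test_high_barrier_rate(self, cycle_universe):
        # a spontaneous high-barrier reaction: psi = 100.  The rounded
        # kappa=0.403 amplifies to ~4% at this barrier, so the check is a
        # magnitude check; the exact barrier dependence is covered below.
        k = rate_constant(DirectedReaction.parse("3 -> 1 + 2"), cycle_universe)
        assert k == pytest.approx(2.0e-5, rel=0.10)

    def test_barrier_ratio(self, cycle_universe):
        k_low = rate_constant(DirectedReaction.parse("5 -> 1 + 4"), cycle_universe)
        k_high = rate_constant(DirectedReaction.parse("3 -> 1 + 2"), cycle_universe)
        assert k_low / k_high == pytest.approx(
            math.exp(cycle_universe.kappa * 90), rel=1e-9
        )


class TestConstants:
    def test_printed_values(self):
        beta, kappa = constants_from_conditions(298.15, 100.0)
        assert beta == pytest.approx(6.21e12, rel=5e-3)
        assert kappa == pytest.approx(0.403, rel=5e-3)

    def test_kappa_inverse_in_temperature(self):
        _, k1 = constants_from_conditions(298.15)
        _, k2 = constants_from_conditions(2 * 298.15)
        assert k1 / k2 == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            constants_from_conditions(-1.0)


class TestUniverse:
    def test_g_table_must_cover_universe(self):
        with pytest.raises(ValueError, match="missing"):
            Universe(mass_cap=4, g_table={1: 0.0, 2: 0.0})

    def test_serialization_roundtrip(self):
        uni, _ = Universe.from_low_barrier(
            6, G_CYCLE, ["5 -> 1 + 4", "2 + 4 -> 6"], psi_low=12.0, psi_high=90.0
        )
        again = Universe.from_dict(uni.to_dict())
        assert again.to_dict() == uni.to_dict()
        assert again.psi_for(ReactionPair(1, 4)) == 12.0
        assert again.psi_for(ReactionPair(3, 3)) == 90.0

    def test_all_reactions_conserve_mass(self):
        uni, _ = Universe.from_low_barrier(8, {m: 0.0 for m in range(1, 9)}, [])
        rxns = uni.all_reactions()
        assert len(rxns) == 2 * len(enumerate_pairs(8))
        assert all(sum(r.reactants) == sum(r.products) for r in rxns)
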
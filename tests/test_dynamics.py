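import numpy as np
import pytest

from intchem import (
    DirectedReaction,
    SimulationConfig,
    Universe,
    delta_g_standard,
    gibbs_ledger,
    gillespie_run,
    growth_mode,
    load_fixture,
    meanfield_run,
    propensity,
    rate_constant,
    write_trace_tsv,
)


class TestPropensity:
    def test_reservoir_fed_synthesis(self):
        fx = load_fixture("scheme1")
        uni = fx.universe()
        p = propensity(
            DirectedReaction.parse("2 + 4 -> 6"),
            {2: 1000, 4: 1},
            uni,
            solvent_count=1e6,
        )
        # omega * 1000 * 1 / (1e6 + 1001)
        assert p == pytest.approx(1.1e8, rel=0.02)

    def test_zero_count_reactant_gives_zero(self):
        fx = load_fixture("scheme1")
        uni = fx.universe()
        assert propensity(
            DirectedReaction.parse("2 + 4 -> 6"), {2: 1000, 4: 0}, uni, 1e6
        ) == 0
        assert propensity(
            DirectedReaction.parse("1 + 1 -> 2"), {1: 1}, uni, 1e6
        ) == 0  # a single molecule cannot meet itself

    def test_decomposition_outruns_synthesis(self):
        """With the same rate constant, decomposition beats synthesis by the
        dilution factor N_j/(S+N) < 1."""
        fx = load_fixture("scheme2")
        uni = fx.universe()
        counts = {1: 1000, 2: 50, 4: 50}
        k = rate_constant(DirectedReaction.parse("4 -> 2 + 2"), uni)
        p_dec = propensity(DirectedReaction.parse("4 -> 2 + 2"), counts, uni, 1e6)
        p_syn = propensity(
            DirectedReaction.parse("1 + 2 -> 3"), counts, uni, 1e6, rate_k=k
        )
        assert p_dec > p_syn


class TestGillespie:
    def test_cycle_grows_waste_linearly_and_conserves_the_cycle(self, scheme1_trace):
        tr = scheme1_trace
        cycle = tr.counts[:, 3] + tr.counts[:, 4] + tr.counts[:, 5]
        assert np.all(cycle == 1)
        assert growth_mode(tr, 1) == "linear"
        # two waste molecules per consumed resource, up to the unfinished turn
        assert abs(tr.counts[-1, 0] - 2 * tr.resource_consumed[2][-1]) <= 2

    def test_resource_is_clamped_at_every_sample(self, scheme1_trace):
        assert np.all(scheme1_trace.counts[:, 1] == 1000)

    def test_mass_conservation_against_the_reservoir_ledger(self, scheme5_trace):
        """Total mass changes only by the mass flux through the reservoir."""
        tr = scheme5_trace
        masses = np.arange(1, 7)
        total = tr.counts @ masses
        influx = 2 * tr.resource_consumed[2]  # resource mass = 2 per molecule
        assert np.all(total - total[0] == influx)

    def test_formose_replicates_exponentially(self, scheme2_trace):
        assert growth_mode(scheme2_trace, 2) == "exponential"
        assert growth_mode(scheme2_trace, 3) == "exponential"

    def test_same_seed_reproduces_identical_traces(self):
        fx = load_fixture("scheme2")
        a = gillespie_run(fx.config(seed=42, max_events=2000))
        b = gillespie_run(fx.config(seed=42, max_events=2000))
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.event_reactions, b.event_reactions)
        assert np.array_equal(a.counts, b.counts)

    def test_empty_system_stops_cleanly(self):
        uni, _ = Universe.from_low_barrier(4, {m: 0.0 for m in range(1, 5)}, [])
        cfg = SimulationConfig(universe=uni, max_events=100, seed=0)
        tr = gillespie_run(cfg)
        assert tr.stop_reason == "no_reactions_possible"
        assert tr.n_events == 0

    def test_max_time_stop(self):
        fx = load_fixture("scheme1")
        tr = gillespie_run(fx.config(seed=0, max_time=1e-9))
        assert tr.stop_reason == "max_time"
        assert tr.sample_times[-1] <= 1e-9

    def test_event_totals_match_event_list(self, scheme1_trace):
        tr = scheme1_trace
        assert sum(tr.reaction_event_totals.values()) == tr.n_events
        # the three cycle reactions dominate and fire nearly equally often
        counts = sorted(tr.reaction_event_totals.values(), reverse=True)[:3]
        assert min(counts) > 0.3 * max(counts)

    def test_equilibrium_of_a_single_pair_matches_detailed_balance(self):
        """Time-averaged N_2 over synthesis-pair pressure reproduces the
        ratio of the two rate constants (exactness of the sampler)."""
        uni, _ = Universe.from_low_barrier(2, {1: 0.0, 2: 5.0}, ["2 -> 1 + 1"])
        cfg = SimulationConfig(
            universe=uni, initial_counts={1: 40}, solvent_count=100.0,
            max_events=60_000, seed=5,
        )
        tr = gillespie_run(cfg)
        dt = np.diff(tr.sample_times)
        n1, n2 = tr.counts[:-1, 0], tr.counts[:-1, 1]
        pairs_pressure = n1 * (n1 - 1) / (100.0 + n1 + n2)
        ratio = (n2 * dt).sum() / (pairs_pressure * dt).sum()
        k_syn = rate_constant(DirectedReaction.parse("1 + 1 -> 2"), uni)
        k_dec = rate_constant(DirectedReaction.parse("2 -> 1 + 1"), uni)
        assert ratio == pytest.approx(k_syn / k_dec, rel=0.05)


class TestMeanField:
    def test_formose_ode_grows_all_three_intermediates(self):
        fx = load_fixture("scheme2")
        cfg = fx.config(seed=0, max_time=4e-7)
        sol = meanfield_run(cfg, np.linspace(0.0, 4e-7, 300), stop_at_population=1e6)
        for sp in (2, 3, 4):
            assert growth_mode(sol, sp) == "exponential"
        # the tetrose stays orders of magnitude below the lighter sugars
        assert sol.counts[-1, 3] < 0.01 * sol.counts[-1, 1]

    def test_all_zero_initial_state_stays_zero(self):
        uni, _ = Universe.from_low_barrier(
            4, {1: 220, 2: -760, 3: -970, 4: -1160}, ["1 + 2 -> 3"]
        )
        cfg = SimulationConfig(universe=uni, max_time=1e-6, seed=0)
        sol = meanfield_run(cfg, np.linspace(0.0, 1e-6, 50))
        assert np.allclose(sol.counts, 0.0)

    def test_cycle_ode_slope_matches_stochastic_mean(self):
        fx = load_fixture("scheme1")
        slopes = []
        for seed in range(4):
            tr = gillespie_run(fx.config(seed=seed, max_events=15_000, record_every=10))
            t, n1 = tr.species_series(1)
            half = len(t) // 2
            slopes.append(np.polyfit(t[half:], n1[half:], 1)[0])
        sol = meanfield_run(fx.config(seed=0, max_time=1e-4), np.linspace(0, 5e-5, 200))
        t, n1 = sol.species_series(1)
        half = len(t) // 2
        ode_slope = np.polyfit(t[half:], n1[half:], 1)[0]
        assert ode_slope == pytest.approx(np.mean(slopes), rel=0.10)


class TestGrowthMode:
    T = np.linspace(1.0, 2.0, 120)

    def test_synthetic_shapes(self):
        assert growth_mode((self.T, 100 + 80 * self.T)) == "linear"
        assert growth_mode((self.T, 5 * np.exp(4 * self.T))) == "exponential"
        assert growth_mode((self.T, np.full_like(self.T, 7.0))) == "bounded"
        assert growth_mode((self.T, np.exp(3 * self.T**2))) == "superexponential"

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            growth_mode((self.T[:8], self.T[:8]))

    def test_needs_species_for_traces(self, scheme1_trace):
        with pytest.raises(ValueError, match="species"):
            growth_mode(scheme1_trace)


class TestGibbsLedger:
    def test_replicator_raises_its_own_gibbs_energy(self, scheme5_trace):
        led = gibbs_ledger(scheme5_trace, {3, 4, 5, 6}, resource=2, waste=1)
        t = led["t"]
        # the living part climbs while the whole system still runs downhill
        fit_living = np.polyfit(t, led["g_living"], 1)[0]
        fit_total = np.polyfit(t, led["g_total"], 1)[0]
        assert fit_living > 0
        assert fit_total < 0
        assert led["g_living"][-1] > 0 > led["g_total"][-1]

    def test_ledger_equals_per_event_energy_bookkeeping(self, scheme5_trace):
        """G_total reproduces the cumulative net standard Gibbs change of
        the event sequence, event by event."""
        tr = scheme5_trace
        led = gibbs_ledger(tr, {3, 4, 5, 6}, resource=2, waste=1)
        g = load_fixture("scheme5").g_table
        dg = np.array([float(delta_g_standard(r, g)) for r in tr.reactions])
        cumulative = np.concatenate([[0.0], np.cumsum(dg[tr.event_reactions])])
        assert np.allclose(
            led["g_total"], cumulative[tr.sample_events], rtol=1e-9, atol=1e-6
        )

    def test_eventless_trace_gives_zero_series(self):
        fx = load_fixture("scheme5")
        tr = gillespie_run(fx.config(seed=0, max_time=1e-30))
        led = gibbs_ledger(tr, {3, 4, 5, 6}, resource=2, waste=1)
        for key in ("g_replicating", "g_resource", "g_waste", "g_living", "g_total"):
            assert np.all(led[key] == 0.0)

    def test_inconsistent_species_rejected(self, scheme5_trace):
        with pytest.raises(ValueError, match="reservoir"):
            gibbs_ledger(scheme5_trace, {3, 4}, resource=5, waste=1)
        with pytest.raises(ValueError, match="outside"):
            gibbs_ledger(scheme5_trace, {3, 99}, resource=2, waste=1)


class TestTraceOutput:
    def test_tsv_and_metadata(self, tmp_path, scheme1_trace):
        out = tmp_path / "trace.tsv"
        meta = tmp_path / "trace.json"
        write_trace_tsv(scheme1_trace, str(out), metadata_path=str(meta))
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["time", "n1", "n2", "n3", "n4", "n5", "n6"]
        assert len(lines) == 1 + len(scheme1_trace.sample_times)
        import json

        sidecar = json.loads(meta.read_text())
        assert sidecar["seed"] == scheme1_trace.seed
        assert sidecar["stop_reason"] == "max_events"
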
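# intchem — integer-mass artificial chemistry

`intchem` is a simulator and analysis toolkit for a minimal, thermodynamically
consistent model of chemical reaction systems, built for questions about the
origin of self-replication: can catalysis and self-replication arise in a
reaction network that contains no catalysts and no replicator by construction,
and how common are the universes in which they can?

It is aimed at origin-of-life and systems-chemistry modellers who want a
small, fully specified sandbox in which energetics, kinetics and mass
conservation are all handled exactly.

## The model

Every molecule type is an integer mass *i* (written *ī*); the only elementary
reactions are synthesis *ī* + *j̄* → (i+j) and decomposition (i+j) → *ī* + *j̄*,
so mass conservation is automatic.  Each type carries a standard Gibbs energy
of formation *G°ᵢ* (kJ/mol); a reaction is **spontaneous** iff it runs
strictly downhill.  Each reaction pair carries a barrier height ψ above the
higher end of its energy profile, giving transition-state-theory rate
constants

    k = β · exp(−κ · ΔG‡),      β = k_B T / h,   κ = 1 / (R T)

with ΔG‡ = ψ for the spontaneous direction and ψ + |ΔG°| for the reverse, so
the two directions are thermodynamically consistent by construction.  At
298.15 K, β ≈ 6.21 × 10¹² s⁻¹ and κ ≈ 0.403 mol/kJ.  Pairs are **low-barrier**
(ψ = 10, fast) or **high-barrier** (ψ = 100, rare "innovation" events); a
reaction system is written as its list of low-barrier spontaneous reactions.
Populations evolve in a well-mixed ideal-gas volume with *S* solvent
molecules: synthesis fires at `k·NᵢNⱼ/(S+N)`, decomposition at `k·N_{i+j}`,
and selected *resource* species are clamped to a reservoir count *Q*.

On top of the model sit:

* **Physical possibility** — does *any* assignment of formation energies make
  every listed reaction strictly spontaneous?  Decided in exact rational
  arithmetic; the answer always comes with a machine-checkable certificate
  (a strict witness `g_table`, or nonnegative integer weights whose combined
  reaction cancels every species — by Gordan's theorem exactly one exists).
* **Stoichiometric classification** — a reaction set is *self-driven* when
  every reaction is fed by another; summing the reactions once and examining
  the intermediates separates *collectively catalytic* systems (all
  intermediates balanced; a catalytic cycle such as the citric acid cycle)
  from *self-replicating* ones (some intermediate overproduced, none
  over-consumed; the formose reaction).
* **Census of artificial chemistries** — at mass cap L every pair is
  high-barrier or low-barrier-with-a-direction, giving 3^P universes (19,683
  at L = 6); the census counts the physically possible ones and those
  containing self-driven / collectively catalytic / self-replicating systems.
* **Dynamics** — an exact Gillespie sampler over *all* pairs (so rare
  innovations can happen), mean-field ODEs, growth-mode diagnostics
  (bounded / linear / exponential / superexponential), the critical
  side-reaction rate multiplier, and a Gibbs-energy ledger that splits the
  system's energy into replicating, resource and waste parts — exact to the
  event.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import numpy as np
from intchem import (
    classify, critical_eta, gillespie_run, growth_mode,
    is_physically_possible, load_fixture, table1,
)

# the formose reaction: sugar replicated from formaldehyde
formose = ["1 + 2 -> 3", "1 + 3 -> 4", "4 -> 2 + 2"]
report = classify(formose)
print(report.label)              # self_replicating
print(report.overall_net)        # {1: -2, 2: 1}  ->  overall  1 + 1 -> 2

# adding 2 -> 1+1 closes an impossible loop: the four reactions sum to
# nothing, so no energy assignment makes them all spontaneous
res = is_physically_possible(["2 -> 1 + 1"] + formose)
print(res.feasible, res.certificate)   # False (1, 1, 1, 1)

# stochastic dynamics from one seed molecule and a formaldehyde reservoir
fx = load_fixture("scheme2")
trace = gillespie_run(fx.config(seed=1, max_events=30_000))
print(trace.final_counts())      # {1: 1000, 2: 5086, 3: 3680, 4: 5}
print(growth_mode(trace, species=2))   # exponential

# census of all 729 five-molecule chemistries
row = table1([5])[0]
print(row.physically_possible, row.with_self_driven,
      row.with_cc_lower_bound, row.with_sr_lower_bound)   # 681 152 5 10

# side reaction 2+5 -> 7 kills replication once it matches the cycle's speed
eta = critical_eta(load_fixture("scheme4").config(seed=0, max_time=1.0),
                   "2 + 5 -> 7", species=2)
print(round(eta, 2))             # 1.0
```

The numbers mean: the formose set replicates (its summed reaction turns two
units of feedstock into one extra seed molecule); the closed loop is
physically impossible with the unit-weight cancellation (1,1,1,1) as proof;
a single seed molecule amplifies to thousands against a clamped reservoir
and the growth is classified exponential; 681 of the 729 five-molecule
universes admit consistent energies, 152 of those can feed themselves, with
at least 5 containing a catalytic cycle and 10 a replicator; and the
replicator survives the competing side reaction exactly until the side
reaction's rate constant reaches the shared low-barrier value (η = 1).

The same operations are available from a shell:

```bash
intchem fixtures
intchem classify --fixture scheme2
intchem feasibility "2 -> 1+1" "1+2 -> 3" "1+3 -> 4" "4 -> 2+2"
intchem enumerate -L 4 -L 5 --tsv census.tsv
intchem simulate --fixture scheme1 --seed 1 --max-events 20000 \
    --out trace.tsv --metadata trace.json
intchem ode --fixture scheme2 --t-end 3e-7 --out ode.tsv
```

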
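# Methods

This note documents the model implemented by `intchem`, the defaults it
ships with, the numerical and design choices behind each module, and what
the test suite does and does not establish.

## Model and assumptions

Molecules are identified by a positive integer mass; molecules of equal mass
are identical (no isomers, no atomic composition, no forbidden
transformations).  The only elementary reactions are binary synthesis and
unary decomposition into two parts, so any reaction conserves mass by
construction and any species is reachable from lighter ones.  The system is
a well-mixed ideal gas at constant temperature and pressure; the mixing
entropy of the gas is neglected in all energy bookkeeping.

Energetics follow transition-state theory.  Each molecule type carries a
standard Gibbs energy of formation `G_i` (kJ/mol); each reaction pair
carries a barrier `psi > 0` (kJ/mol) above the higher end of its profile.
The spontaneous direction of a pair (the strictly downhill one) has
activation energy `psi`; the reverse adds the uphill gap, which enforces
`dG_act(syn) − dG_act(dec) = dG°(syn)` identically — detailed-balance
consistency that the unit tests check property-wise.  A reaction with
`dG° = 0` is treated as nonspontaneous in both directions; strict
feasibility elsewhere means this boundary case never occurs in a listed
low-barrier system.

Rate constants are `beta · exp(−kappa · dG_act)` with `beta = k_B·T/h` and
`kappa = 1/(R·T)` (≈ 6.21e12 s⁻¹ and 0.403 mol/kJ at 298.15 K, the package
default).  Pressure is carried in configs for completeness but enters
neither constant.  Defaults: `psi = 10` for listed (low-barrier) pairs and
`psi = 100` for everything else, making low-barrier reactions ~5·10¹⁵-fold
faster at equal driving force.

## Physical possibility (feasibility)

A listed reaction system is physically possible iff some `G` assignment
makes every listed reaction strictly downhill, i.e. the homogeneous system
`A·G > 0` (one row per reaction: reactant minus product counts) is
feasible.  By scale invariance this equals feasibility of `A·G ≥ 1`,
decided by Fourier–Motzkin elimination in exact integer/rational
arithmetic.  Each derived inequality carries its nonnegative multipliers
over the original rows, so the outcome is always certified: a rational
witness `g_table` when feasible, or nonnegative integer weights (scaled to
smallest terms) whose weighted reaction sum cancels every species when not.
Gordan's theorem guarantees exactly one of the two exists, and both are
re-validated by independent checkers.  Exactness matters because the census
consumes these decisions as integers; a float LP with a tolerance would
make the counts tolerance-dependent.

Witness values are arbitrary-scale rationals.  For generated fixtures they
are scaled into the conventional −1500..300 kJ/mol range of real formation
energies; the range is cosmetic for feasibility and is not enforced on user
input.

A deliberately weaker diagnostic, `unit_cancellation_certificate`, searches
0/1-weight (subset-sum) cancellations only — the natural by-hand test of
"add the reactions up and see whether everything cancels".  Up to mass cap
5 it coincides with exact feasibility.  At mass cap 6 it misses exactly 138
of the 2,996 infeasible chemistries, whose certificates need weights ≥ 2
(smallest example: `1+1→2, 4→1+3, 2+2→4, 5→1+4, 6→1+5, 3+3→6` with weights
(2,2,1,1,1,1)).  Census figures computed with the screen instead of the
exact decision are therefore inflated at L ≥ 6 — 16,825 instead of 16,687
"possible" six-molecule chemistries, 6,886 instead of 6,748 containing
self-driven systems — which is worth knowing when comparing against figures
computed elsewhere with subset-style screens.  The screen is exposed as
`screen="unit_cancellation"` purely for such diagnostics; every default
path uses the exact decision.

## Stoichiometric classification

All criteria work on the plain sum of the listed reactions, each counted
once (unit multiplicity; multiset occurrences inside one reaction count
with multiplicity).  Definitions:

* **self-driven** — every reaction has at least one reactant that is a
  product of some *other* reaction in the set.  A single reaction can never
  qualify, hence the subset-search floor of two reactions.
* **collectively catalytic** — self-driven and every intermediate (species
  on both sides) has equal reactant- and product-side counts.
* **self-replicating** — self-driven, some intermediate has a positive net
  and none has a negative net.
* **self_driven_other** — self-driven with some over-consumed intermediate
  (a set that burns its own stock); kept as an honest residual bucket.

The two positive labels are mutually exclusive (a summation cannot be both
all-zero and somewhere-positive over the intermediates).  The criteria are
sufficient, not necessary — dynamics are never consulted — so census
columns built on them are lower bounds.  Resources are inferred, not
declared: species consumed but never produced are treated as externally
supplied.  Searching integer multipliers > 1 when summing was considered
and rejected: it makes the positive labels overlap (one weighting can
balance the intermediates while another overproduces them) and would change
the meaning of the census columns.

## The census of artificial chemistries

At mass cap L there are P pairs (`i ≤ j`, `i+j ≤ L`) and `3^P` artificial
chemistries (each pair high-barrier, low-synthesis or low-decomposition).
Per chemistry the census decides:

* **physically possible** — exact feasibility of its low-barrier list (the
  empty list counts);
* **contains self-driven** — some subset (size ≥ 2) of its low-barrier
  reactions is self-driven;
* **collectively catalytic / self-replicating lower bounds** — its full
  low-barrier list (≥ 2 reactions) meets the respective criteria.  This
  whole-list convention is deliberate; crediting qualifying proper subsets
  would give larger (still valid) lower bounds, e.g. 4 instead of 2
  replicator-containing chemistries at L = 4, and `find_subsystems` exists
  for that analysis.

Performance: infeasibility is inherited by supersets, so the ternary
assignment tree is pruned at the first infeasible prefix; self-driven
containment is inherited by supersets of the low-barrier set, so the
minimal self-driven subsets over the 2P directed reactions are precomputed
once and matched by bitmask inclusion.  The optimised path is asserted
bit-identical to an unpruned brute-force path at L ≤ 5.  L = 6 runs in
seconds; L = 7 (12 pairs, 531,441 chemistries) is supported by the same
code but takes on the order of an hour and is not part of the default test
run.

## Dynamics

The stochastic sampler is the exact event-by-event algorithm with the
standard two-uniform draw per event (one seeded generator; the seed is
recorded in the trace).  All pairs with total ≤ L are simulated, each at
its own barrier, so high-barrier innovations occur at their true (tiny)
rates.  Identical-reactant synthesis uses `N_i(N_i−1)/(S+N)` — proper
combinatorics, indistinguishable from `N_i²` at reservoir scale but correct
at `N_i = 1`.  Resources are reset to Q after every event, and the *net*
difference accumulates in the consumption ledger `F` (for a resource that
is never produced this equals gross consumption); net rather than gross is
used so that the mass and energy ledgers close exactly, and the choice is
recorded here because the two differ when a resource is also produced.
Traces store every event time and reaction index, and population snapshots
every `record_every` events, so event statistics stay exact while memory
stays bounded.

The mean-field path integrates `dN/dt = S_matrix · gamma(N)` with the same
rate expressions (identical-pair term clipped at zero for fractional
populations), resources clamped, using LSODA with `rtol 1e-8 / atol 1e-10`
by default; an optional terminal event stops runaway exponential
trajectories at a population cap.  Integrator failures raise with the
solver's message.

**Growth-mode classification** uses the trailing half of the samples (≥ 10
required): superexponential if the log-slopes of three equal sub-windows
are positive and each exceeds the previous by > 5 %; exponential if the
log-linear fit has R² ≥ 0.98 with positive slope (when both the log and the
straight-line fit pass 0.98 — short windows make a line and a gentle
exponential look alike — the larger R² wins); linear if the straight-line
fit has R² ≥ 0.98 with positive slope; bounded if the window's relative
range is under 5 % (or ≤ 2 counts) or nothing fits.  The thresholds are
stated so the tests are deterministic.

**Critical side-reaction multiplier.**  The side reaction's rate constant
is scaled by a dimensionless η ≥ 0 (equivalently a `−ln(η)/kappa` offset on
its activation energy).  For each η the mean-field equations of the
*listed* network are integrated — the rare high-barrier channels are
excluded here because, over the long horizons the asymptotic growth sign
needs, channels like the slow re-decomposition of the side product feed
back at exponentially small rates and blur the threshold (including them
shifts the apparent threshold from 1.0 to ≈ 1.5 for the reference system).
Growth is declared when the trajectory hits a population cap or gains at
least a fifth of an e-fold over the fit window with the population clearly
off the integrator's tolerance floor; the η-bracket with a sign change is
bisected to width 0.005 and the midpoint returned.  For the
formose-plus-interceptor system with equal low-barrier constants the
eigenvalue condition gives exactly η = 1, which the bisection recovers to
±0.01.

**Gibbs ledger.**  With all series referenced to zero at t = 0:
`G_replicating = Σ N_i·G_i` over the replicating species, `G_resource =
−F·G_resource`, `G_waste = N_waste·G_waste`, `G_living = G_replicating +
G_resource`, `G_total = G_living + G_waste`.  When the partition covers
every reacting species, `G_total` equals the cumulative net `dG°` of the
event sequence exactly (float roundoff aside), which the tests assert
event-by-event.  The reference system shows `G_living` rising while
`G_total` falls: a replicator raising its own free energy by consuming
resources faster than it exports waste entropy.

## Scheme fixtures and the synthetic data they generate

The library ships the model systems used throughout: the citric-acid-cycle
reduction (`scheme1`, collectively catalytic, resource 2̄, Q = 1000, seeded
by one 4̄), the formose reduction (`scheme2`, self-replicating, resource 1̄,
seeded by one 2̄), formose with a benign (`scheme3`) and a lethal
(`scheme4`) side reaction, the energy-climbing replicator with its ledger
parameters (`scheme5`), a catalytic relay whose overall reaction stands in
for a single low-barrier step (`scheme6`), and the impossible four-reaction
loop (`scheme7`).  Schemes 1, 2 and 5 carry their conventional printed
energy tables; the side-reaction and relay fixtures need energies for
species no table prescribes, and those were chosen here (only the listed
reactions constrain them).  Solvent count S = 1e6 and reservoir Q = 1000
throughout, which puts the dilution factor Q/(S+N) near 1e-3 at the start
of every run.

`scheme_table2_synthetic` (alias `scheme_table2`) is a *reconstruction*:
the staged-evolution system is specified only as an architecture — formose;
a three-reaction collectively catalytic system on resource 3̄ triggered by
the first 5̄; a 13-reaction self-replicator on a mass-12 species — so this
fixture realises it concretely as formose + {3+5→8, 3+8→11, 11→5+6}
(overall 3+3→6) + the chain {12+1→13, …, 23+1→24, 24→12+12} (overall
12×1̄→12̄), with a hand-built energy table making all 19 reactions
spontaneous and the three triggering innovations (1+1→2, 2+3→5, 6+6→12)
downhill.  Its barrier gap is `psi_high = 40` rather than 100: the stage
*ordering* is gap-independent, but the number of simulated events needed to
see the full cascade scales with the population at which the next
innovation fires (∝ `exp(kappa·gap/2)`), and 40 keeps innovations ~2·10⁵
-fold rarer than low-barrier traffic while letting the three stages
complete within ~1.5 million events, a desk-scale run.  At the
conventional gap of 90 the same cascade needs on the order of 10⁹–10¹²
events — physically identical, computationally out of reach for an exact
event-by-event sampler (and acceleration schemes are out of scope).

`generate_random_universe` rejection-samples pair/direction assignments
until exactly feasible, returns the witness scaled into −1500..300 kJ/mol
and fills unlisted masses uniformly from the same range; it is
deterministic in its seed.

What the synthetic systems do *not* emulate: real stoichiometries other
than binary/unary, isomer diversity, solvent chemistry, spatial structure
or compartments, temperature/pressure variation, and mixing entropy.
Passing tests therefore establish properties of the model class, not
predictions for any laboratory system.

## Test-suite problem sizes

The default suite runs the census exhaustively at L = 4, 5, 6 (81 / 729 /
19,683 chemistries), cross-validates feasibility against brute-force
certificate search over all chemistries at L ≤ 5, uses stochastic runs of
2·10⁴–4·10⁴ events for the single-scheme properties, six replicate runs per
arm for the side-reaction comparison (pilot spread of the growth-rate
estimator ≈ 5 %, asserted to 10 %), and five seeds of up to 4·10⁶ events
for the staged cascade.  Whole suite: ~6 minutes on one CPU.

## Known limitations

* The census columns for collectively catalytic / self-replicating
  containment are lower bounds by design (sufficient criteria, whole-list
  convention); exact containment would require dynamics or a complete
  subset theory.
* The "nonsustaining" self-driven residual is identified only negatively
  (`self_driven_other`), not characterised.
* L = 7 census runs are hour-scale in pure Python; beyond that the 3^P
  growth makes exhaustive enumeration impractical and no sampling estimator
  is provided.
* Fourier–Motzkin has worst-case exponential blow-up; for this problem
  family (≤ ~13 rows, ≤ 7 unknowns) it stays tiny, and a hard constraint
  cap guards the pathological case.
* The growth-mode classifier is a decision rule tuned for these dynamics'
  clean regimes; trajectories near regime boundaries (short windows, heavy
  noise) default conservatively to `bounded`.
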
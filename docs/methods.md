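# Methods

This note documents the models and procedures implemented in `rubiscoflux`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Constraint-based core

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions)
with per-reaction flux bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹) and a biomass
objective reaction. Flux balance analysis (FBA) maximizes the biomass flux
subject to steady state, `S·v = 0`. All linear programs are solved with
SciPy's HiGHS interface in one fixed configuration, so runs are
deterministic. Because LP optima can be degenerate, no analysis relies on
the particular vertex the solver returns: where the flux of a single
reaction matters, flux variability analysis (FVA) brackets it by minimizing
and maximizing that flux with the objective constrained to a fraction of its
optimum (an epsilon of 1e-9 is subtracted from the floor to avoid spurious
infeasibility at fraction 1).

Conventions and numerical choices:

* Uptake through an exchange reaction is negative flux; `set_carbon_source`
  only ever touches lower bounds. When a single carbon source is selected,
  every other exchange is closed to uptake unless its species is on an
  inorganic whitelist (CO₂, O₂, water, phosphate, ammonium, trace ions...)
  matched against the exchange id; models carry no elemental formulas, so
  the id is the only available signal, and a `keep_open` argument overrides
  it.
* Objective values below 1e-6 mmol·gDW⁻¹·h⁻¹ count as "no growth": LP
  solvers return tiny nonzeros on blocked models.
* Documents omitting bounds get (0, 1000) for irreversible and
  (−1000, 1000) for reversible reactions.
* The JSON dialect is canonical on disk and serializes with sorted ids so
  diffs are stable; the SBML reader imports only species, reactions, and
  fbc bounds/objective — stoichiometry is what the analyses need, not
  curation metadata.

## Growth-coupled strain design

The screen asks: which small deletion sets make growth impossible *unless*
the two-reaction Calvin-cycle detour is active? The detour is
phosphoribulokinase (Prk, Ru5P → RuBP) plus rubisco (RuBP + CO₂ → 2×3PG);
rubisco's stoichiometry of exactly two 3-phosphoglycerate per carboxylation
is load-bearing throughout. Every subset of candidate reactions of size ≤ 2
is tested on every carbon source by a pair of FBAs (detour blocked / detour
open); a set qualifies when at least one source shows dependence (growth
< 1e-6 without, ≥ 1e-6 with). The enumeration is exhaustive — no pruning —
so completeness can be checked against brute force.

Qualifying designs are scored by a coupling curve: biomass is pinned at
`n_grid = 5` evenly spaced values in (0, μ_max] and the minimum rubisco flux
is found at each; the reported *slope* and *intercept* come from an ordinary
least-squares line through the grid. The grid itself is stored on the
candidate so any alternative coupling functional (slope at zero biomass,
slope at the optimum, area under the curve) can be recomputed without
re-solving. A slope of 2 on the toy network means every unit of biomass
drags two units of carboxylation with it.

`predicted_rubisco_3pg_fraction` reports rubisco's share of 3PG production
as 100 × (2·v_rubisco) / (total production flux into the 3PG pool), with
production summed over positive contributions only and rubisco counted as
two molecules per carboxylation. Counting *molecules* (rather than
carboxylation events) is deliberate: it makes the FBA prediction directly
comparable to the labeling estimate below, whose pool-dilution convention
(d = 1/2) also works per molecule. The uncertainty range re-evaluates the
ratio at the two FVA extremes of rubisco flux.

The candidate list defaults to all non-exchange, non-biomass,
non-heterologous reactions; what counts as "central metabolism" is
model-specific and therefore caller-controlled. The uptake bound for each
carbon source defaults to 10 mmol·gDW⁻¹·h⁻¹ and is exposed everywhere, as
no single value is canonical. The toy Prk reaction omits the ATP cost
because the toy carries no energy metabolism; on a real model the
`prk_cofactors` field of `HeterologousSpec` supplies it.

## Rubisco kinetics

CO₂ and O₂ compete for the enzyme-RuBP complex, so each gas is a
competitive inhibitor of the other's reaction:

    v_C = kcat_C [CO₂] / ([CO₂] + K_C (1 + [O₂]/K_O))
    v_O = kcat_O [O₂]  / ([O₂]  + K_O (1 + [CO₂]/K_C))

Competitive inhibition leaves v_max untouched — saturating CO₂ reaches
kcat_C at any O₂ — and the ratio obeys v_C/v_O = S_C/O·[CO₂]/[O₂] with
S_C/O = (kcat_C/K_C)/(kcat_O/K_O), an algebraic identity the tests hold to
1e-12. Concentrations are dissolved-gas μM; 270 μM is used as the default
O₂ background (air-equilibrated medium at growth temperature). Kinetic
constants vary widely between rubiscos and with temperature/pH, so they are
required inputs with a documented example set (kcat_C 10 s⁻¹, K_C 150 μM,
kcat_O 1 s⁻¹, K_O 200 μM) rather than silent defaults. Henry-law and
pH/temperature corrections are out of scope.

## Labeling inference

Growth on ~99 atom % ¹³C substrate makes biomass nearly fully labeled;
¹²C can then enter essentially only from ambient CO₂ via rubisco. Serine is
the sentinel: it inherits the three carbons of 3PG, and 3PG is made both by
lower glycolysis (all substrate carbons) and by rubisco, where one of the
two product molecules carries the CO₂-derived carbon at the carboxyl
position.

Mixture model. Let `b` be the per-carbon ¹²C probability of purely
substrate-derived carbon, `c` the ¹²C fraction of intracellular CO₂
(default 0.989, ambient CO₂ net of natural ¹³C abundance), `d` the fraction
of rubisco-derived 3PG molecules carrying the CO₂ carbon (default 1/2), and
`x` the fraction of 3PG production due to rubisco. Then the unconditional
carboxyl ¹²C fraction is `b + x·d·(c−b)` and total serine ¹²C is
`b + x·d·(c−b)/3`. The background `b` is *measured* from a
rubisco-independent control strain (mean total-serine ¹²C across control
replicates) rather than computed from nominal substrate purity, because the
control absorbs every systematic effect — purity, natural abundance,
amino-acid turnover — in one number. The estimator errors out when `c ≤ b`
(no contrast between the CO₂ channel and background).

Two measurement modes invert this model per experiment replicate:

* `total_serine`: `x = 3(f¹²C_exp − b)/(d(c−b))` from the carbon-weighted
  isotopologue average f¹³C = Σᵢ fᵢ·i/N, f¹²C = 1 − f¹³C.
* `carboxyl_mrm`: the MRM channels split serine M+2 ions by the ¹³C/¹²C
  state of the carboxyl carbon (A = 61.1 m/z, carboxyl ¹³C; B = 62.1 m/z,
  carboxyl ¹²C). Because the measurement conditions on M+2 — exactly one
  ¹²C among three carbons — the channel ratio is a conditional probability,
  q12 = p(1−b) / (p(1−b) + 2b(1−p)) for unconditional carboxyl ¹²C
  fraction p (positions independent). The estimator inverts this
  conditioning first, then applies the mixture formula, so both modes
  estimate the same quantity; on shared forward-model data they agree
  within Monte-Carlo error. A useful corollary: for a pure-background
  control, q12 = 1/3 exactly, independent of b.

Estimates are reported per replicate with their unweighted mean and
minimum; values outside [0, 1] are clipped and flagged — never silently.
Amino acids other than serine pass through the label-fraction arithmetic
but are excluded from the flux estimator. `compare_to_fba` records the
estimate against the FBA point/FVA range with an inside-range flag and the
absolute gap.

## Growth statistics

Endpoint summaries use the t-distribution interval mean ± t_{n−1,0.975}·SE
across biological replicates. The intervention effect is the difference of
arm means of OD600 at an evaluation time, with linear interpolation between
samples. Its uncertainty comes from a percentile bootstrap (default
n_boot = 10000, level 0.999) that resamples *whole replicate curves* with
replacement within each arm — the biological replicate is the exchangeable
unit, which avoids modeling the autocorrelation of points along one curve.
Output is reproducible given the seed. Tables may carry a `dilution`
column (turbid cultures measured in five- or tenfold dilution); the reader
multiplies it back in.

Known limitation: with very few replicates per arm the percentile bootstrap
undercovers. The widest interval replicate resampling can produce is the
range of resampled effects, and with 3 i.i.d. replicates per arm the true
effect falls outside that range with probability 2·(3!·3!)/6! = 0.10
regardless of n_boot, so the real coverage of a nominal 99.9% interval is
at most ≈90%. The interval is still a useful variability summary at n = 3,
but its nominal level should not be taken literally below n ≈ 5 per arm;
BCa or t-intervals are the usual remedies and the level/n_boot are exposed
for that reason.

## Synthetic data

Every generator is a pure function of its spec (seed included), so all
fixtures are regenerated at test time.

* Toy network (`make_toy_model`): glycerol → G3P → F6P, a lumped
  non-oxidative pentose-phosphate reaction 2 F6P + G3P → 2 Ru5P + Ri5P
  (15 carbons each side — the network is carbon-balanced by construction,
  so mass balance doubles as a carbon audit), the isomerase Ru5P → Ri5P,
  free CO₂ exchange, biomass consuming 1 G3P + 1 Ri5P, and optionally the
  Prk/rubisco detour. Deleting the isomerase makes Ru5P a dead end that
  only the detour can drain. The hand-derived LP values — biomass 3.75
  (wild type), 0 (Δrpi), 5.0 with rubisco flux 10 (Δrpi + detour), coupling
  slope 2, rubisco 3PG share 66.7% — are regression-locked in the tests.
  Energy cofactors are deliberately absent; the toy is an LP oracle, not a
  physiology model.
* Labeling simulator (`simulate_labeling`): per replicate, serine carbons
  are independent Bernoulli draws — carboxyl ¹²C probability
  b + x_true·d·(c−b) in the experiment arm, b elsewhere and in the control
  (b = 1 − purity, reading "99% ¹³C" as atom fraction; CO₂ natural
  abundance lives in c, substrate purity in b, kept separate because they
  are physically separate channels). Isotopologue counts are multinomial
  at the configured depth (default 1e5) and the M+2 count is split
  binomially into the two MRM channels. Defaults mirror the experimental
  design: 4 biological replicates, x_true 0.14, purity 0.99, c 0.989,
  d 0.5. Not emulated: LC-MS peak shapes, amino-acid-specific turnover,
  position-dependent backgrounds, multi-element isotope corrections — so
  passing recovery tests demonstrates correctness of the inversion, not
  robustness to instrument systematics.
* Growth simulator (`simulate_growth_curves`): shared-shape logistic
  trajectories; the experiment arm's capacity is raised so the arm
  difference at `t_eval` equals the configured effect exactly in the
  noise-free limit (default effect 0.6 OD at 80 h, noise sd 0.02 OD,
  3 replicates per arm). Noise is i.i.d. Gaussian per sample, truncated at
  zero; real curves have autocorrelated noise, evaporation artifacts, and
  lag-phase variability the simulator does not attempt.

## Pipeline

`run(config)` executes the selected stages (design, rates, labeling,
growth) in a fixed order and returns a JSON-serializable report carrying a
schema version, the package version, and a full config echo — re-running
from the echo with the same seed reproduces the report. One global seed is
fanned out to stochastic stages by fixed offsets (+1 labeling, +2 growth)
so a stage can be re-run in isolation. Reports are written atomically
(write-then-rename). The same stages are reachable as shell subcommands
(`rubiscoflux design-strains | rates | infer-labeling | growth-effect |
simulate | run`).

## Problem sizes

The default test and acceptance runs use the nine-reaction toy network, a
3-reaction candidate pool (6 subsets), labeling depth 1e5 with 4 replicates
per arm, bootstrap n_boot 10000, and 200 regenerations for the coverage
experiment; everything completes in seconds on one core while leaving the
statistical assertions well-powered.
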
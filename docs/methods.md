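# Methods

## The Model Rule Matrix

All cytokine interaction rules of the simulator are stored in one real
matrix: rows are rules, columns are the computationally relevant entities
(the mediator concentrations plus the lattice damage and infection signals),
and element (r, j) is the coefficient with which entity j contributes to
rule r. A zero element means the connection does not exist, so rule
existence and rule strength share one representation and the calibration
engine can both re-weight and effectively create or delete rules. The matrix
flattens row-major into the genome vector the GA operates on; flattening
order is an arbitrary convention fixed here by round-trip tests. All
coefficients are dimensionless and constrained to [-2, 2].

The reference shape is 18 rules x 24 entities = 432 free parameters; both
dimensions are configuration-driven, and the reduced simulator shipped here
uses its own 10 x 10 catalogue (10 cell-type/output-mediator rules over
8 mediators + damage + infection).

## The reduced immune simulator

The simulator is deliberately a *reduced* model of the endothelial–blood
interface: the smallest structure that exercises every mechanism the
calibration engine needs (rule-matrix-driven production, stochastic
divergence of outcomes, range envelopes, mortality). It is not a cell-level
reproduction of any published C++ simulator.

**Space and time.** A toroidal H x W lattice of endothelial sites (default
40 x 40; the desk configuration uses 20 x 20). One step is 10 simulated
minutes by default (30 in the desk configuration); a 22-day horizon is
3168 steps. Each site carries a damage level in [0, 1] and an infection
level in [0, 1]; each mediator has a non-negative concentration field.

**Agents.** Macrophages (12), neutrophils (12), TH0/TH1/TH2 cells (6/5/5)
move one lattice step per tick: uphill on their attractant field when a
neighbouring site beats the current one, otherwise in a seeded-random
direction. All innate and T cells are recruited up the TNFα gradient by
default. Counts are configuration values chosen to keep desk-scale runtime
low while leaving visible census noise in the dynamics.

**Rules.** Each rule belongs to one cell type and names one output mediator.
Wherever an agent of that type stands, the rule adds
`max(0, Σ_j M[r,j] · input_j) · production_scale` to the output mediator at
that site. Inputs are the *start-of-step* local concentrations plus the
local damage and infection levels (synchronous difference-equation
semantics: with decay 1 and scale 1 on a 1-site torus the update reduces
exactly to the rule equations, clamped at zero, which the tests exploit).
Per-site concentrations saturate at a cap (default 50) representing
receptor/secretion saturation.

**Step order** is fixed for reproducibility: (1) mediator diffusion
(4-neighbour averaging, coefficient 0.2) and exponential decay (0.1/step);
(2) agent movement; (3) rule firing; (4) the harm phase — infection spread
and toxigenesis (microbial parameters; zero in sterile burns), phagocyte
clearance of local infection, and systemic collateral damage; (5) repair;
(6) environmental re-exposure (a random site re-infected with the given
per-step probability).

**Collateral damage and mortality.** Because the disease being modelled is
*systemic* inflammation, collateral endothelial damage is driven by the
lattice-mean pro-inflammatory load: every site gains
`toxicity · mean(TNFα) / (1 + inhibition · mean(IL-10))` damage per step
(defaults 0.008 and 0.1). The patient dies when the mean damage fraction
first exceeds 0.80, heals when damage and infection are exactly zero, and
is censored at the horizon otherwise. Repair removes a constant
`host_resilience` damage per site per step (default 0.007 in the reference
burn), which makes complete healing reachable in finite time; a numerical
floor (10⁻³) snaps near-zero damage to zero. All damaged tissue is treated
as recoverable — the only notion of death is the systemic 80% threshold.

**Why outcomes diverge.** With the default rule matrix, TNFα is strongly
autocrine and TNFα also recruits its own producers. A chance co-location of
innate agents can therefore nucleate a local runaway ("ignition") that
spreads and kills; whether ignition happens before the wound heals is a
genuinely stochastic race. Identical injuries and parameters then split
into died and healed cohorts purely through seeded randomness, which is the
property the mortality term of the fitness needs. Near the mortality
transition a minority of replicates can remain unresolved (censored) at the
22-day horizon; they count as survivors in the mortality fraction.

**Injury description.** Five dimensionless parameters: injury size
(fraction of the lattice initially at damage 1, as a contiguous patch),
microbial invasiveness, microbial toxigenesis, environmental toxicity, and
host resilience. A severe burn is sterile: both microbial parameters zero,
injury size 0.5 (the cohort definition is burns over half the body
surface).

**Randomness.** Each replicate owns one counter-based (Philox) generator
keyed by its seed; per-step draws are consumed in a fixed order regardless
of branches, so a trajectory depends only on (params, genome, seed) and not
on how replicates are batched. Replicate seeds derive from a root seed via
`SeedSequence.generate_state`.

## Normalization, envelopes, fitness

Model outputs are lattice totals per mediator per step; clinical data are
per-cytokine [min, max] ranges at 15 sampling times over 22 days (first at
3 h). Both sides are divided by the per-cytokine *clinical maximum* (the
largest range upper bound over time), which puts every cytokine on a
comparable scale so the per-cytokine weights are meaningful. A cytokine
whose clinical maximum is zero is left unscaled, with a warning.

An envelope is the per-(cytokine, time point) min/max of normalized totals
over stochastic replicates (default 50 at full scale, 10 at desk scale —
fewer replicates give visibly unstable ranges), sampling each clinical time
at the nearest recorded step; a replicate that died earlier contributes its
last observed value carried forward, keeping the envelope rectangular. The
envelope also carries the replicate mortality fraction R_m.

The fitness is the printed max-difference form

    F = Σ_{i,t} w_i |max(Cᵉ_{i,t}) − max(Cᵐ_{i,t})| + k |R_e − R_m|

with the min-difference term available behind `range_mode="minmax"` for the
fuller "range difference" reading. The sampling times 48 h and 8 d are held
out of both fitness and bioplausibility to guard against overfitting.
`compute_fitness` compares whatever scale it is given and never
re-normalizes (the evaluation pipeline normalizes both sides first). The
mortality coefficient k is not dictated by the source data; the default
k = 10 makes a 0.1 mortality mismatch cost one fitness unit, the same
order as one cytokine-timepoint mismatch. IL-10's weight defaults to 2:
with equal weights a near-zero IL-10 trajectory is cheap for the optimizer,
and doubling the IL-10 contribution suffices to recover its day-5 pulse.

**Non-viability**: a parameterization whose simulation dies before the
first clinical sampling time (3 h) is biologically impossible; by default
*any* early-dying replicate triggers rejection (the strictest reading;
switchable to *all*). **Bioplausibility**: the envelope lies inside the
clinical ranges, boundary inclusive, at every cytokine and evaluated time
point — such a parameterization cannot be invalidated by the data and
enters the ensemble archive.

## The genetic algorithm

Minimizing, generational, real-valued. Initialization is i.i.d. uniform on
[-2, 2]. Selection is repeated size-2 tournaments (sampling without
replacement within a tournament, with replacement across tournaments; ties
broken by a seeded coin flip). Crossover is the uniform continuous form
c₁ᵢ = βᵢ p₁ᵢ + (1−βᵢ) p₂ᵢ, c₂ᵢ = βᵢ p₂ᵢ + (1−βᵢ) p₁ᵢ with an independent
βᵢ ~ U(0,1) per gene — independence per gene is what makes the operator
*uniform*; a single-β mode is available. Children conserve p₁ + p₂
gene-wise and cannot leave the gene bounds. Mutation draws one random
number per child against r_m = 0.01 + 0.002·g_n (capped at 1; the cap is
unreachable in a 250-generation run) and, on success, replaces one
uniformly chosen gene with a fresh U(−2, 2) draw; the growing rate
deliberately re-injects diversity as the population converges.

Elitism follows the pool-replacement form — the worst
⌊elite_fraction · size⌋ members of the breeding pool are replaced by the
best of the previous generation — and, additionally, the elite candidates
pass verbatim (mutation bypassed, stored fitness kept) into the next
generation. Without that second half a best genome could be lost in
crossover, and the best-fitness trace could not be guaranteed monotone;
with it, monotonicity is a theorem the tests assert. Elites keep the
fitness from their original evaluation rather than being re-scored with
fresh replicate seeds, again to keep the trace monotone.

Non-viable candidates are replaced by a uniformly drawn viable candidate of
the same generation; if generation 0 has none, the population is redrawn a
bounded number of times before aborting with a diagnostic. Every
bioplausible candidate enters the append-only ensemble archive (identical
genomes stored once). Per generation the loop records best/mean fitness and
the total diversity — the sum over genome positions of the
across-population range of that position, at most 4 x genome length.

Evaluation seeds derive from (root seed, generation, candidate index), so
candidate evaluations are pure functions of (genome, seeds): stateless,
order-independent, and reproducible under any execution schedule. The
shipped loop evaluates sequentially; the contract is what matters for
parallel deployments. Full-scale study constants (population 1024, 250
generations, 50 replicates) are exposed via `GAConfig.full_scale()`; the
defaults are the desk equivalents (64 / 30 / 10) sized so a complete
calibration runs in minutes on one CPU.

## Fixtures and what the tests do (and do not) show

`make_clinical_like_targets` emulates only the *shape* of the motivating
burn-cohort dataset — 5 cytokines, 15 sampling times over 22 days starting
at 3 h, 50% cohort mortality, an IL-10 pulse peaking at day 5, range widths
around half the upper bound — with seeded log-normal-like pulses. No
numerical cytokine level from any real cohort is encoded: none is available
in machine-readable form, and inventing one would be worse than synthesis.

`make_surrogate_targets` converts the replicate envelope of a *known*
genome into a target file (mortality rate = observed R_m). By construction
the generating genome scores exactly F = 0 with matched seeds and is
bioplausible, so end-to-end recovery is testable without any real data:
the desk GA must beat its initial best fitness against these targets, and
the diversity trace must decline from its near-maximal start. Passing
these tests shows the calibration machinery works as specified on data the
simulator can produce; it says nothing about fidelity to real burn
patients, which would require the original clinical ranges.

One caveat on ensemble retention: a replicate self-envelope is a much
tighter target than a heterogeneous cohort's ranges, so desk calibrations
against un-inflated surrogate targets typically retain nothing — envelope
containment at every cytokine and time point essentially singles out the
generating genome. Retention is therefore exercised directly (the
generating genome with matched seeds is bioplausible by construction, and
the archive logic is unit-tested); with genuinely wide clinical ranges the
archive is expected to grow the way the diversity analysis assumes.

`make_reference_calibrated_genome` calibrates a hand-written,
immunologically signed base matrix (damage/infection → TNFα/GCSF; TNFα
autocrine and IL-10-inducing; IL-10 suppressive; intermediates relaying to
the IFNγ/IL-4 T-helper axis) to ~50% replicate mortality by bisecting a
single global scale factor, followed by a refinement pass that re-scores
the neighbourhood of the bisection result with more replicates (defaults:
150 replicates per bisection step, 400 per refinement point). The procedure
is deterministic given its seed; the packaged
`data/reference_genome.json` is its output with default arguments and is
what the acceptance script and the mortality tests load. At 50 replicates
the 95% binomial band around 0.5 is 18–32 deaths, which is the acceptance
band used.

## Numerical choices and degenerate inputs

- Ties in chemotaxis resolve to the first maximal neighbour
  (deterministic); ties in tournaments to a seeded coin flip.
- Fields are clamped non-negative by construction (rectified production,
  multiplicative decay); damage is clipped to [0, 1]; infection to [0, 1].
- A 1x1 torus is legal (all neighbours are the site itself), which is how
  the single-cell rule-equation check runs.
- `injury_size = 0` with a sterile injury heals at step 0; an injury filling
  the torus saturates damage at 1 everywhere.
- Envelope construction requires at least one replicate; empty target or
  mismatched cytokine/time axes raise immediately.
- Boundary-inclusive bioplausibility uses an absolute tolerance of 1e-9 to
  absorb floating-point division noise.

## Known limitations

- The simulator is a reduced abstraction: no precursor populations, oxygen
  or receptor logic; cytokine totals are dimensionless lattice sums, so
  only range *shape* on a normalized scale is meaningful.
- Mortality calibration targets the default 40x40 configuration; other
  grids need recalibration (the desk 20x20 configuration is used for GA
  mechanics, not for mortality claims).
- Near the mortality transition some replicates stay censored at the
  horizon; mortality counts deaths only, so censoring biases R_m downward
  at most by the censored fraction.
- The GA explores the neighbourhood of one convergence path; the archive is
  a sample of the bioplausible set, not an exhaustive characterization.
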
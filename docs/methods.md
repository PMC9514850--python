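# Methods

## Overview

`difflux` implements a differential metabolic-flux analysis for comparing a
condition (e.g. dystrophic myoblasts) against a baseline through the lens of
a constraint-based metabolic model. The chain of methods is:

1. collapse gene-level expression fold changes to reaction level through
   gene–protein–reaction (GPR) rules;
2. scale the baseline model's reaction bounds by those fold changes to
   obtain the condition-specific model, optionally under GECKO-style enzyme
   constraints;
3. run flux variability analysis (FVA) on both models;
4. score each reaction with the flux fold change
   `ffc = (MaxFlux_condition + 1) / (MaxFlux_baseline + 1)`;
5. classify reactions as up/downregulated with a dual absolute-threshold +
   percentile rule on `log2(ffc)`;
6. test each pathway (subsystem) for over-representation of labelled
   reactions with a one-sided hypergeometric test under Benjamini–Hochberg
   FDR control.

A separate module tests promoter ChIP-signal over-representation for a gene
list against resampled background promoters (±1 kb TSS windows).

## Models and constraints

A model is a stoichiometric network with per-reaction flux bounds
(mmol·gDW⁻¹·h⁻¹), GPR rules, and a subsystem label per reaction. Flux
analysis operates on the steady-state polytope {v : S·v = 0, lb ≤ v ≤ ub}.
All bounds are finite, capped at magnitude 1000, so every LP is bounded.

**Enzyme layer.** A reaction may carry a turnover number `kcat` (h⁻¹) and an
enzyme molar mass `mw` (mg·mmol⁻¹); the model carries a shared protein pool
(mg·gDW⁻¹). `apply_enzyme_constraints` augments the network in the canonical
GECKO style, encoded purely stoichiometrically: each enzymatic reaction
consumes an enzyme pseudo-metabolite at rate 1/kcat, a draw reaction
converts pool mass into that enzyme at cost `mw`, and a single pool exchange
bounded by the pool supplies all draws. At steady state this enforces
`v_j ≤ kcat_j·u_j` and `Σ_j mw_j·u_j ≤ pool` (usage is exactly `v/kcat`,
i.e. minimal; allowing idle enzyme would not change the feasible flux set,
since idle enzyme only wastes pool). A single enzymatic reaction therefore
has effective vmax `kcat·pool/mw`. Reversible enzymatic reactions are first
split into irreversible forward/backward halves sharing one enzyme; reported
FBA/FVA values are re-merged net fluxes (forward − backward), so enzyme
augmentation can only shrink each reaction's flux range. Isozyme handling
beyond the OR-rule collapse (e.g. separate pools per isozyme) is not
modelled.

**Expression integration.** Fold changes are linear-scale and strictly
positive; genes with missing (NaN) values are unperturbed. A reaction's fold
change is the GPR collapse with AND → min (a complex is limited by its
scarcest subunit) and OR → max (isozymes provide alternative capacity);
missing genes are dropped from their operator's operand list, and a reaction
whose genes are all missing keeps its baseline bounds. Both operators are
configurable (`min`, `max`, `mean`, `sum`). The collapsed fold change `f`
scales the bounds symmetrically — upper bound when positive, lower bound
when negative — after clipping to `[1/scale_cap, scale_cap]`
(default cap 64) so a single extreme gene cannot blow up the LP. The enzyme
layer (kcat, mw, pool) is never rescaled: expression evidence modulates
pathway capacity, not catalytic constants.

## Flux variability analysis

FVA solves two LPs per reaction (min and max of its flux) with the HiGHS
solvers behind `scipy.optimize.linprog`; the solver is interchangeable —
any LP routine meeting the 1e-6 feasibility tolerance gives the same
results. By default no biomass objective is imposed (pure feasibility FVA
over the constrained polytope); an optional `fraction_of_optimum` cut
intersects the polytope with `objective ≥ fraction × FBA optimum` first.
Fluxes with magnitude below 1e-9 are snapped to 0 so downstream
classification is reproducible across solvers.

## Differential statistic and classification

`ffc = (c + 1)/(b + 1)` on the per-reaction FVA maxima; the +1 pseudo-flux
makes two silent reactions neutral (ffc = 1) instead of 0/0. A corrected
term ≤ 0 (max flux ≤ −1) puts the ratio outside the log2 domain; such
reactions are flagged `invalid`, excluded from percentile computation and
never labelled, rather than being silently transformed.

A reaction is **up** iff `log2(ffc) > 1` *and* above the 95th percentile of
the valid log2 distribution; **down** iff `log2(ffc) < −0.1` *and* below
the 5th percentile. Percentiles use linear interpolation between closest
ranks (index = (n−1)·q) and comparisons are strict, which guarantees at most
⌈5%⌉ of reactions per direction and labels nothing when the distribution is
degenerate (all ties). Thresholds and percentiles are configurable
(`ClassificationConfig`).

Pathway-level log2 fold changes aggregate the valid member reactions with a
configurable statistic (mean by default; median and sum available — the
choice of representative is genuinely open and is therefore surfaced rather
than fixed).

## Pathway enrichment

For each direction, the universe is the set of reactions with a valid ffc,
hits are the reactions labelled with that direction, and each subsystem is
tested with the upper-tail hypergeometric probability P(X ≥ k) (computed via
`scipy.stats.hypergeom.sf`, verified against exact rational enumeration).
BH adjustment is applied within each direction's family of pathway tests by
default; a pooled two-direction family is available
(`family="pooled"`), since whether the two directions share one FDR family
is a reporting choice, not a property of the data.

## Promoter-signal over-representation

Input: per-gene, per-bin non-negative ChIP coverage over a ±1 kb TSS window
(strand-oriented, bins half-open), one matrix per TF track, plus a gene
universe. The statistic for a gene list is the mean over listed genes of the
per-gene summed window signal. The null resamples `B` same-size gene sets
uniformly without replacement (default from the whole universe; a `fixed`
mode first draws a single pool of 1000 background promoters and resamples
from it). The empirical p is the add-one estimator
`(1 + #{null ≥ observed}) / (B + 1)`, so the smallest attainable p is
1/(B+1) and the estimator is exactly uniform on its grid under the null.
Bonferroni correction is applied across tracks; significance is called at
corrected p < 0.05. The heatmap table assigns non-significant TFs signal 0
and max-scales the rest to [0, 1]. The statistic is equivariant under adding
a constant to every gene's signal, and results are a deterministic function
of the seed.

## Synthetic data

The generator provides desk-scale stand-ins for the three real inputs
(genome-scale model, RNA-Seq fold-change table, ChIP signal matrices).

**Toy model.** One linear chain per pathway from a shared source metabolite
to a shared sink; each pathway has its own uptake and secretion exchange
(bound 1000, subsystem `exchange`), internal reactions have bound 10 and a
GPR over 1–3 fresh genes (random AND or OR for multi-gene rules). Each
intermediate metabolite also has a supplementary uptake and an overflow leak
with bound equal to the chain bound. This is deliberate: a strict chain at
steady state forces a single shared bottleneck — identical FVA maxima — onto
all of its reactions, which collapses the per-reaction log2-ffc distribution
into exact ties (so the strict percentile criterion can never fire) and lets
one unresponsive step (all genes missing) abolish the whole chain's
response. The side exchanges act like the bypass routes of real networks:
each reaction's maximum stays capped by its own expression-scaled bound,
while an unresponsive neighbour attenuates propagation by one bound-unit per
step instead of blocking it. The optional enzyme layer draws kcat
log-uniform in [1, 100] h⁻¹ and mw uniform in [10, 100] mg·mmol⁻¹, with the
pool sized to support half of the summed nominal chain capacity, so baseline
maxima are positive but the pool can bind.

**Expression.** Gene fold change = `2^(pathway effect + N(0, noise_sd))`
(lognormal noise keeps positivity and matches how DE fold changes are
distributed); default noise_sd 0.2 on the log2 scale. A `nan_fraction`
(default 0.1) of genes is set missing uniformly, except that a planted
pathway is never silenced entirely. Defaults of 8 pathways × 4 reactions,
planted log2 effect +3 on one pathway, are the study conditions used by the
acceptance checks.

**Promoter signal.** i.i.d. lognormal(0, 1) signal per gene × bin; one track
multiplies the enriched genes' rows by the effect multiplier, a second track
is left untouched as a null.

What the synthetic data does *not* emulate: genome-scale network topology
(loops, cofactor coupling, compartments), correlated expression noise,
read-count-derived uncertainty in fold changes, and spatially structured
ChIP peaks. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated, not that the biological conclusions of
any real dataset would be recovered.

## Numerical choices

- LP tolerance 1e-6; |flux| < 1e-9 snapped to 0.
- Bound magnitude cap 1000 (bounds beyond it are clamped with a warning).
- Percentile method: linear interpolation between closest ranks.
- Ties in enrichment ranking broken by (q, p, subsystem name) for
  deterministic output.
- All randomness flows through `numpy.random.default_rng` seeded from the
  spec/config seed; generator sub-streams use `SeedSequence([seed, k])` so
  model, expression and signal draws are independent but reproducible.
- Output tables carry a header comment with version, a hash of the analysis
  parameters (excluding output location), and the seed; no timestamps, so
  identical runs are byte-identical.

## Problem sizes

The verification suite runs the full pipeline at 8 pathways × 4 reactions
(96 reactions after exchanges, ~192 LPs per model pair) across 100 seeds for
recovery and calibration checks, enumerates hypergeometric tails exactly for
N ≤ 12, checks FVA against vertex enumeration on networks of ≤ 6 reactions,
and uses B = 999 resamples for the planted promoter test (B = 199 for the
200-replicate calibration loop). These sizes were chosen to exercise every
code path at desk scale; all scale linearly (FVA: 2n LPs) if enlarged.

## Known limitations

- The bound-scaling scheme (multiplicative, symmetric) is one of several
  published ways to impose expression on a model; discretised on/off schemes
  are not implemented.
- Pure feasibility FVA means reactions are scored by their *capacity*, not
  by flux at a biomass optimum; use `fraction_of_optimum` for the latter.
- The hypergeometric universe is the valid-ffc reaction set; reactions whose
  corrected maxima are non-positive are excluded from both universe and
  hits.
- The promoter test treats bins exchangeably (summed window signal); it does
  not model positional structure around the TSS beyond the window itself.
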
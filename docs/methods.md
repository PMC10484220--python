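# Methods

## Scope and model

`fluxshift` predicts how steady-state metabolic flux redistributes when a
gene's reactions are suppressed (knock-out, KO) or forced
(over-expression, OE) in a constraint-based metabolic model, and
summarizes the shifts per pathway subsystem. It also implements the
upstream differential-expression (DE) table filtering used to select
perturbation targets. It does not fit DE models (counts are expected to
be processed by a dedicated tool such as DESeq2 upstream), does not
perform enrichment or survival analysis, and does not evaluate
gene-protein-reaction boolean rules: perturbations act directly on named
reactions.

All flux computation happens on the polytope
{v : S·v = 0, lb ≤ v ≤ ub}, where S is the metabolites × reactions
stoichiometric matrix. Fluxes are treated as dimensionless solver units,
nominally mmol·gDW⁻¹·h⁻¹; no unit conversion is performed.

## Wild-type reference flux

The published perturbation protocol compares perturbed flux to "the
original model", without fixing how the original flux is computed. FBA
alone is insufficient because its optimum is typically a face, not a
point, and any downstream per-reaction comparison would inherit the
solver's arbitrary vertex choice. The package therefore defines the
wild-type reference as the **minimum-Euclidean-norm FBA optimum**: an LP
(HiGHS) finds the optimal objective value z*, then a QP minimizes ‖v‖₂
subject to the same constraints plus c·v = z*. This point is unique
(strict convexity on an affine section of a polytope) and hence
deterministic across runs and platforms. A model with an empty or
all-zero objective is a configuration error rather than "any feasible
point", because silently arbitrary references would poison the
classification stage.

## MOMA

The perturbed flux is the minimizer of Σⱼ (vⱼ − wⱼ)² over the perturbed
polytope — the standard minimization-of-metabolic-adjustment QP. The sum
runs over *all* reactions, exchanges included. Reactions present in the
perturbed model but missing from the reference contribute wⱼ = 0, a
conservative choice consistent with the downstream "unidentified"
handling. The solution is unique; the reported objective value is the
attained squared distance.

### QP solution path

No dedicated QP library is assumed. The solver:

1. finds a feasible starting point (or a certificate of infeasibility)
   with a zero-objective LP;
2. runs SLSQP (scipy) with analytic gradient and Jacobian on a
   unit-rescaled copy of the problem (all bounds and the reference are
   divided by their largest magnitude, making tolerances scale-free);
3. refines the result by an exact KKT solve on the detected active set:
   variables within 1e−6 of a bound are pinned, the equality-constrained
   quadratic subproblem is solved in closed form via least squares, and
   the refined point is accepted only if it is primal feasible and every
   active-bound multiplier has the inward sign. Otherwise the SLSQP
   iterate is kept.

The refinement pins well-conditioned solutions to ~1e−10. The test suite
cross-checks this path against an independently written ADMM projection
oracle (operator splitting with closed-form proximal steps; a different
algorithm family with no shared code) on 50 seeded random models, and
cross-checks FBA against cobrapy/GLPK.

### Tolerances

Mass-balance and bound tolerance 1e−6, QP convergence 1e−8 (all in flux
units, configurable via `SolverTolerances`). Solutions are validated
against max |S·v| in tests rather than trusted blindly.

## Perturbation presets

The published HMGCS2 protocols are reproduced verbatim
(`hmgcs2_presets`): colon KO lower-bounds HMR1437/HMR4604/HMR1573 at 9;
colon OE upper-bounds them at 4000; liver KO lower-bounds the five
reactions (adding HMR0027, HMR0030) at 0; liver OE sets (2000, 4000).
The colon-KO bound of 9 *forces* at least 9 flux units through the
targets — the opposite of a knock-out. Whether it is a typo for 0 cannot
be resolved from the text, so fidelity wins: the preset is as printed, a
non-suppressible warning is emitted, and `ko_bound_override` /
`strict_ko` expose the conventional alternatives without silent
substitution. Override targets missing from a model are collected and
reported "unidentified", never fatal, because real GSMs differ in
reaction inventories.

## Flux-change classification

With Δ = v_pert − v_orig, the direction label is up-/down-regulated when
|Δ| exceeds max(0.1·|v_orig|, floor) in the corresponding direction,
else no-change. Three numerical choices:

* the relative threshold uses |v_orig| so the rule is well defined for
  negative fluxes of reversible reactions, and direction is judged on
  the signed Δ;
* 10% of a zero flux is zero, so any solver noise would otherwise be
  classified; an absolute floor (default 1e−6, the solver tolerance
  scale) is combined with the relative rule via max();
* a Δ at exactly the threshold is no-change (strict rule); an isclose
  guard (relative 1e−9) keeps binary round-off from breaking exact ties.

KO and OE arms combine into verdicts keyed to the KO response:
down-in-KO ∧ up-in-OE ⇒ flux-decreasing; up-in-KO ∧ down-in-OE ⇒
flux-increasing; both no-change ⇒ unchanged. A change in only one arm is
*inconsistent* and excluded from the subsystem counts — the protocol is
silent on this case, and counting one-armed responses as calls would
overstate certainty. Missing targets are *unidentified*. Subsystem
summaries report both raw counts and count/total fractions (the
published bar plots are ambiguous between the two), sorted by decreasing
fraction of flux-decreasing reactions.

## Synthetic data

**Toy ketogenesis network** (8 metabolites, 13 reactions, fixed and
hash-asserted): glucose uptake ≤ 10 feeds glycolysis (2 ATP + 2
pyruvate) and pyruvate dehydrogenase; oxidative phosphorylation burns
acetyl-CoA at 10 ATP each but is capped at 12; the ketone branch
(ACAT → HMGCS2x → HMGL → acetoacetate export) disposes of acetyl-CoA at
zero ATP cost; fatty-acid synthesis (8 acetyl-CoA + 7 ATP) and
β-oxidation close a lipid loop with a small import allowance. The OXP
cap is the deliberate design choice: it creates excess acetyl-CoA at
the wild-type optimum (ATPM = 140, ketone branch at 4), so a knock-out
of the HMGCS2 analog has real flux to reroute — into fatty-acid
synthesis, which the KO/OE run exhibits. One physiological pattern of
the real system is *not* reproducible here: wild-type β-oxidation flux
is exactly 0 (at the 140-ATP optimum the ATP balance forces FAS = 0 and
the minimum-norm reference zeroes the fat-import loop), so the KO
cannot *decrease* FAO on this fixture; the corresponding acceptance
assertion documents this as an expected failure rather than being
weakened.

**Random feasible models** are generated witness-first: internal fluxes
are sampled, per-metabolite exchange fluxes are set to balance exactly,
and every bound is sampled to bracket its witness value strictly —
feasibility is guaranteed by construction, without solver calls, and the
witness doubles as a regression guard and MOMA reference in tests.

**Synthetic DE tables** draw log2FC ~ N(±effect, 0.1·effect) with
p_adj ~ U(1e−12, 1e−4) for true positives and log2FC ~ N(0, null_sd)
with p_adj ~ U(0.5, 1) for nulls; p-values are generated directly
because the DE fit itself is out of scope — only the filtering rules are
under test. Defaults (1000 genes, 10% up, 10% down, effect 3.0, null sd
0.1, no NA injection) give effectively zero misclassification
probability, so truth recovery is exact. NA injection (optional
fraction) always hits p_adj and only sometimes log2FC, mirroring DE
fits where an untestable gene lacks an adjusted p-value; this also
means the published NA→1 conversion (which would let a lone NA log2FC
*pass* the |log2FC| > 0.58 cutoff, since 1 > 0.58) can never promote an
NA row to significance. Generated tables do not emulate count-level
realism (library size, dispersion, outliers): passing tests show the
filtering logic is correct, not that any DE fit is.

## DEG filtering

Cutoffs are strict (> 0.58, < 0.01) as printed, so boundary rows are
excluded. NA cleaning is applied *before* filtering — the conservative
reading of the published NA→1 conversion, under which an NA-p_adj gene
can never be called. The low-count prefilter (mean raw count < 1 across
samples) operates on raw count matrices and is decoupled from any DE
fit. Gene identity is the case-sensitive symbol string; alias resolution
is deliberately out of scope because it is annotation-version-dependent.

## Pipeline determinism and problem sizes

The end-to-end run (load → FBA → KO/OE MOMA → classify → summarize) is
deterministic: identical configs produce byte-identical TSVs and
metadata (stage wall times go to the log, not the report). Flux output
uses 9 significant digits — diff-stable but below solver tolerance. The
test and acceptance workloads use desk-scale problems (the 13-reaction
fixture; 50 random models of ≤ 12 reactions), chosen so the entire suite
exercises every code path in seconds while remaining large enough to
produce non-trivial active sets in the QP; the solvers themselves are
dense-matrix based and are appropriate up to a few thousand reactions.

## Known limitations

* Reaction-level perturbation only; no GPR logic, so multi-gene isozyme
  or complex effects must be encoded by the caller.
* MOMA is the only perturbation predictor (no ROOM, no FVA); the
  reference is the only FBA mode exposed.
* SBML support covers L3 core with fbc-style bounds/objective and
  groups/notes subsystems; kinetic laws are ignored with a warning.
* The dense active-set refinement assumes the LP/QP scale is set by the
  largest bound; pathologically ill-conditioned stoichiometries (mixed
  1e−6/1e6 coefficients) may fall back to unrefined SLSQP accuracy.
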
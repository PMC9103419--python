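# Methods

## The decision model

An instance couples p experts, n attributes and m alternatives through
ordinal preferences only. Expert priority ranks i, per-expert attribute
ranks j and per-(expert, attribute) alternative ranks r index a weight
tensor `W_ijk ≥ 0` normalised to sum to one. The solved weights maximise Z,
the minimum scaled adjacent-rank gap, subject to

    Z ≤ i·j·r·(W_ij(r) − W_ij(r+1))   for consecutive alternative ranks,
    Z ≤ i·j·m'·W_ij(m')               at the last rank position m'.

The multipliers are always *rank positions* (the expert's priority rank,
that expert's rank of the attribute, that expert's rank of the alternative),
never identity indices — getting this wrong silently re-weights the panel.
Z is strictly positive at the optimum for every valid instance: the uniform
tensor is feasible with a positive objective.

Aggregation is marginal summation: `W_i = Σ_jk W_ijk`, `W_j = Σ_ik W_ijk`,
`W_k = Σ_ij W_ijk`. Attribute weights are keyed by attribute *identity* —
each expert contributes the weight they placed on that attribute at their
own rank position for it — which is the only reading under which a
per-attribute table is well defined when experts disagree about attribute
order.

## Expert prioritisation

Panel priority is lexicographic over four ordinal profile fields, in order:
role (end-user/caregiver ≻ therapist/physiotherapist ≻ developer),
professional position (professionals/scientists/intellectuals ≻ technicians
and mid-level ≻ elementary occupations), experience bracket (compared by
lower bound: >20 ≻ 15–20 ≻ 10–15 ≻ 5–10 ≻ 1–5 years) and education
(doctorate down to primary, a conventional attainment ordering). The
bundled nine-expert panel is fully separated before education is ever
reached, so any reasonable education ordering gives the same result there.
Identical profiles share a dense rank and are flagged rather than broken
arbitrarily; the solver accepts tied expert ranks (the shared dense rank is
the multiplier).

## Ties and missing rankings

Ranks are dense everywhere (1,1,2 — not competition-style 1,1,3), which
keeps the telescoping chain well defined over distinct rank positions.
Alternatives tied at a rank occupy one chain position; one representative
carries the chain inequalities and the members' weights are constrained
equal, so the construction reduces exactly to the standard model when ties
are absent. An attribute an expert did not rank contributes no variables
and the expert's remaining attribute ranks are compacted to 1..n_i —
imputing a worst rank instead would fabricate preference information the
expert never expressed. Documented consequence: with missing data the
expert marginals deviate from the 1/i proportionality law.

## Solution routes

Two independent routes are implemented and cross-checked.

* **LP**: the constraint system is assembled in a deterministic variable
  order (expert rank, attribute rank, alternative rank, catalogue order for
  ties) and solved in double precision with HiGHS through
  `scipy.optimize.linprog`. Deterministic ordering makes outputs
  bit-reproducible across runs on one platform.
* **Closed form** (complete strict instances only): all inequalities are
  tight at the optimum, giving `W_ij(r) = Z/(i·j)·Σ_{s=r..m} 1/s` and
  `Z = 1/(m·Σ_ij 1/(i·j))`. Two identities follow and are asserted in the
  tests: `Σ_r Σ_{s=r..m} 1/s = m` (each expert-attribute block's share is
  independent of m), and the expert-weight law `W_i = (1/i)/H_p`, which is
  what makes the case-study expert table reproducible even though the raw
  rankings behind it were never published.

The `auto` solver takes the closed form when the instance is complete and
strict and the LP otherwise; both are always callable explicitly, and the
test suite requires max-abs agreement within 1e-8 on random instances. A
third, structurally independent LP assembly lives in the test suite as an
oracle for the builder itself.

Numerical choices: normalisation and marginal sums are checked to 1e-9;
weights equal within 1e-9 are reported as tied ranks, with catalogue order
used for display only and flagged; reports round half-up to 4 decimals
while machine-readable outputs keep full precision.

## Synthetic data

The generator draws rankings from the Mallows model: P(permutation) ∝
exp(−θ·d_K) with d_K the Kendall-tau (discordant-pair) distance to a
reference order, sampled exactly by repeated insertion (item t inserted at
position s with probability ∝ exp(−θ)^(t−s)). θ = 0 is uniform over
permutations; θ ≥ ~20 is numerically a point mass at the reference (θ is
capped at 50). This family was chosen because it is the standard ordinal
noise model with a tractable exact sampler. Ties are injected by merging
adjacent rank positions with probability `tie_prob` after sampling, which
preserves the underlying order; attributes are dropped independently with
probability `missing_prob`, with at least one attribute always retained per
expert. Expert profiles are sampled uniformly over the panel category
scales, but the instance's priority order is a sampled permutation, so
strictness does not depend on profile collisions; the fixed case-study
panel is available separately, never sampled.

What the generator emulates: complete strict elicitations, tied judgements,
skipped attributes, and noise concentrated around a shared ground truth.
What it does not: correlation between an expert's profile and their
opinions, attribute-specific noise levels, or strategic behaviour — passing
recovery tests therefore demonstrates the pipeline's statistical behaviour
under an idealised panel, not performance on any real elicitation.

Default experiment sizes — 100 random instances for the dual-route check,
200 replicates of 9-expert panels at θ = 2 for noisy recovery, 10⁴ draws
for the uniformity test — were chosen to keep the full suite in the
tens-of-seconds range while leaving the statistical assertions comfortable
margins.

## Case-study fixture

The panel (nine experts with role/position/experience/education), the
six-entry attribute catalogue and the four platform alternatives are
bundled verbatim. The raw per-expert rankings were never published, so
`case_study_instance` substitutes seeded synthetic complete strict rankings
(labelled as such in its docstring); the expert significance table is
invariant to that substitution, while the attribute and alternative tables
are treated as structural references only (row counts, sum-to-one), not
numeric targets — recovering the originals from aggregate weights is an
underdetermined inverse problem.

## Known limitations

* No fuzzy, grey, robust or cardinal-input model variants.
* Tied *expert* ranks use the shared dense rank as multiplier; other
  conventions (mean rank) exist and would change weights slightly.
* The leave-one-expert-out re-ranking compacts the remaining experts'
  ranks, which under complete strict data makes the sub-instance expert
  weights identical across removals — sensitivity shows up only through the
  removed expert's preferences, which is the intended reading.
* CSV round-trips preserve the full preference structure but not attribute
  or alternative display names (the trio format does not carry them).
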
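# Methods

This note documents the models and numerical choices behind
`agemajority`: the decision tree itself, the geometric maturity indices
it consumes, the synthetic maturation-cohort generator, and the
calibration and evaluation machinery. It records design decisions made
where the design was genuinely open, and what the passing tests do and
do not establish.

## 1. The decision tree

The tree is a fixed, deterministic traversal (physical examination →
Tanner gate → seven-teeth gate → third-molar banding → clavicle), with
four probability-bearing leaves whose adult probabilities are carried
**verbatim as percentages** (99.9, 96, 60, 16). These are empirical
conditionals from a reference sample, not model outputs; the package
never re-derives them. `DecisionConfig` exposes them, together with the
banding thresholds (0.08, 0.15) and an explicit *adult declaration
threshold* (default 95 %) that formalises which leaves justify declaring
adulthood (99.9 and 96) and which fall under the statutory minor
presumption (60 and 16).

Open points resolved here, conservatively (doubt favours the subject):

* **The boundary I₃ₘ = 0.08** is unassigned by the verbal thresholds
  ("less than 0.08" / "over 0.08"); it is placed in the middle — less
  adult — band.
* **Unassessable third molar with clavicle below stage 4.** One reading
  applies the 96 % figure; the other holds that below stage 4 the
  clavicle cannot be used (about 46 % of such subjects are adults). The
  default is the conservative indeterminate-with-presumption outcome;
  `unassessable_molar_immature_clavicle_policy="apply_96"` selects the
  other reading. Both are tested.
* **Schmeling stage 3** is not an approved estimation stage. It is
  accepted as input, branches as "below stage 4", and the outcome
  carries an explanatory note.
* **"More than 99.9 %"** is emitted as the machine value 99.9 with
  `probability_is_lower_bound=True`.
* **MINOR vs PRESUMED_MINOR.** The teeth gate, whose failures were
  empirically always under 16, yields MINOR; low-probability leaves
  (60 %, 16 %) yield PRESUMED_MINOR citing the statutory presumption.
  INDETERMINATE is reserved for missing-required-evidence and
  abnormal-growth referrals; merely-incomplete evidence never raises an
  exception.

The hand/wrist modality is accepted in the input schema (as a
completeness flag, a Bo/Ca value, or digitised polygons) but never
consulted by the traversal; a property test pairs hand-present against
hand-absent over every branch combination and asserts identical
outcomes.

## 2. Geometric indices

* `polygon_area` / `union_area` use exact polygon clipping (shapely's
  GEOS engine); overlapping bone areas are counted once, per the
  overlap-once rule for the carpal bones. Polygons are validated at
  construction: at least three vertices, simple, strictly positive
  area. Units are mm (the radiographic convention; the index ratios are
  dimensionless).
* `Bo/Ca` = union area of the delineated bone regions (eight carpal
  bones plus ulnar and radial epiphyses) over the carpal-region area.
  Whatever regions the caller supplies as `bone_regions` contribute to
  Bo; the package does not second-guess the delineation.
* **I₃ₘ** is a plain sum of open-apex gap widths over tooth length. The
  canonical lower third molar has two roots, but any gap count is
  accepted (the sum generalises). Gaps at or below a configurable
  epsilon (default 0.0 — exact) count as closed; an empty or all-zero
  gap list returns exactly 0.0 with no floating-point leakage from the
  division path.
* A Monte-Carlo point-in-union oracle exists **only in the tests**; the
  acceptance suite checks 50 random overlapping instances at 10⁶ points
  against the exact union within three standard errors.

## 3. The cohort generator

Each simulated subject carries a true age and latent maturation-event
ages; every observable assessment is a pure deterministic threshold
function of them (`observe`), so a subject can be "radiographed" at any
age and observation at the event age itself already shows the event
(at the closure age, I₃ₘ is exactly 0).

Event-age distributions are truncated normals whose truncation limits
encode the hard population constraints — hand completion ≤ 16 years,
seven-teeth completion ≤ 17 years, clavicle stage-4 onset ≥ 19 years —
so **no seed can violate them**; the config validator rejects any
parameterisation that loosens the limits. Defaults (all ages in years):

| parameter | default | rationale |
|---|---|---|
| age range / mix | uniform over [14, 24) | sampling design unstated; an empirical per-year mix weighted by the reference OPT counts (`age_distribution="table1"`, years 14–22) is provided |
| sex ratio | 0.5 | no sex-specific probabilities are reported to calibrate against |
| Tanner-5 age | TN(14.3, 1.0, [12, 16.5]) | puberty completes mid-teens |
| hand completion | TN(14.8, 0.8, [12.5, 16]) | hard bound 16 |
| seven-teeth completion | TN(15.6, 0.8, [13, 17]) | hard bound 17 |
| unassessable molar | 6 %, age-independent | reported share; independence checked by χ² at α = 0.01 |
| I₃ₘ initial value (at 14) | TN(2.0, 0.3, [0.5, 3.5]) | an open-rooted molar at 14 has gaps of the order of the tooth length |
| I₃ₘ decay rate | TN(0.5, 0.25, [0.15, 1.5]) /yr | per-subject heterogeneity; see below |
| apex closure age | TN(20.0, 1.5, [17.5, 27]) | the third molar is the last tooth to close (after the seven-teeth bound); upper tail past 24 leaves some molars open in range |
| clavicle stage-4 age | TN(21.2, 1.8, [19, 27]) | hard lower bound 19 |
| stage-5 delay, stage-3/2 gaps | TN(2.0, 0.8), TN(1.5, 0.6) | ossification stages are years apart |
| dental–clavicular correlation | 0.5 | shared maturation tempo (Gaussian copula on the latent scale, keeping truncation exact) |

The I₃ₘ trajectory is a subject-level exponential decay anchored at age
14 and shifted to reach **exactly zero** at the subject's closure age:
I₃ₘ(a) = A·(e^(−k(a−14)) − e^(−k(c−14))) for a < c, 0 thereafter, with A
fixed by the initial value. The curve family is config-isolated so
alternatives can be swapped; only monotone maturation is essential.
Per-subject decay-rate heterogeneity matters: slow decayers spend long
spells in the middle band at young ages and keep I₃ₘ ≥ 0.15 into
adulthood, which is what lets the 60 % and 16 % conditionals hold
simultaneously — a single global rate cannot reconcile them.

**Randomness contract.** One root seed; each variable draws from its own
child stream spawned in a fixed order, so enlarging a cohort extends it
without perturbing earlier subjects, and identical configs give
byte-identical serialised cohorts.

## 4. Calibration

`calibrate_simulator` tunes the generator so the simulated conditionals
P(adult | branch) match their reported values. Default targets: 96 %
(I₃ₘ < 0.08, clavicle below stage 4), 60 % (middle band), 16 % (top
band), 46 % (all subjects below clavicle stage 4), plus the rare joint
event (fused clavicle with I₃ₘ > 0.08) at its reported 2 %. The search
is a seeded two-stage coordinate descent with common random numbers
(each candidate scored on a fresh 50,000-subject cohort drawn from the
config seed, so the objective is deterministic): first the closure-age
mean and spread, decay-rate mean, and clavicular fusion-age mean against
the conditional targets; then the dental–clavicular correlation against
the full target set (it barely perturbs the conditionals). A final
confirmation cohort must match every target within ±2 percentage
points, else a `CalibrationError` reports the achieved values. The
shipped defaults already sit near the calibrated optimum, so the search
is a refinement, not a rescue.

Two targets are bound-driven and need no search: P(adult | clavicle
stage ≥ 4) = 100 % exactly (fusion requires age ≥ 19 > 18), and
P(adult | teeth incomplete) = 0 (completion bound 17 < 18).

**The joint event is only order-of-magnitude reproducible.** Its
reference estimate is a single subject among ~50 clavicle films. Under
any single coherent cohort that also satisfies the four conditional
targets, the simulated joint rate stays a few tenths of a percent: the
96 % low-band conditional forces almost all subjects to cross I₃ₘ = 0.08
before 19, while stage 4 is unreachable before 19. The calibrated rate
(~0.1–0.2 %) is statistically compatible with observing 1 of 50 (exact
binomial, α = 0.01 — the level used for the other distributional
checks) but below the 2 % point estimate; the reported percentages come
from different subsamples with different age mixes and need not cohere
exactly in one cohort. Positive dental–clavicular correlation
*suppresses* the joint event (late dental maturers also fuse late), so
the calibration pulls the correlation down from its 0.5 default, to
roughly 0.2–0.45 depending on seed.

## 5. Evaluation

`estimate_branch_probabilities` classifies a labeled cohort through the
actual decision tree (not the vectorised calibration path — a dedicated
test asserts the two agree subject by subject) and reports one row per
reached leaf with Wilson 95 % intervals (chosen over Wald for the small
branches), plus the below-stage-4 marginal computed over every subject
with a clavicle assessment irrespective of the other gates, reported
alongside — not inside — the leaf table. "Adult" means true age ≥ 18.0
exactly; ages are continuous (chronological age is a date difference,
not an integer). `misclassification_report` counts both error
directions and flags every overestimated minor individually, since
overestimation is the error that must be avoided.

## 6. What the tests do and do not show

The simulator emulates the *structure* of a maturation cohort: latent
event ages, hard population bounds, band conditionals, an
age-independent unassessable-molar share. It does not emulate
radiographic images, inter-rater staging variability, digitisation
noise, sex-specific maturation offsets (no sex-split probabilities are
reported to calibrate them), or population shifts (socio-economic or
ethnic); passing tests therefore establish internal consistency of the
decision logic and the generator's fidelity to the stated constraints —
not external validity of the reported probabilities for any new
population. Problem sizes were chosen to make Monte-Carlo error small
relative to the tolerances: 20,000 subjects for bound and rate checks,
50,000 for conditional recovery (branch-level standard errors of
0.3–1 pp).

## 7. Numerical choices

* Banding is half-open: [0, 0.08), [0.08, 0.15), [0.15, ∞); the 0.08
  boundary falls in the middle band, 0.15 in the top band.
* Truncated-normal sampling goes through the inverse CDF of uniform
  draws — sequence-stable, exactly bounded, copula-compatible.
* Wilson bounds are clamped to [0, 1] and widened by at most one ulp to
  contain the point estimate (boundary float fuzz at p̂ ∈ {0, 1}).
* Cohort CSVs round-trip exactly (`float_precision="round_trip"` on
  read; shortest-repr floats on write); observations are reconstructed
  from the latent ages through `observe`, which is pure.
* Subject files use an explicit `schema_version` (major-version gated),
  empty-cell-means-absent, and reject explicit "NA" and unknown columns
  by name.
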
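# Methods

## Setting and data model

The pipeline analyses admitted-patient-care records in the English HES
schema: one row per finished consultant episode, carrying a pseudonymous
patient identifier, admission/discharge and episode start/end dates at day
resolution, admission method, discharge method and destination, hospital
code, sex, age, up to 20 ICD-10 diagnosis positions and up to 24 OPCS-4
procedure positions. A *spell* — one hospital admission — is the set of
contiguous episodes sharing patient, admission date and hospital. The
analysis window runs 1 April 2007 to 31 March 2015; all date arithmetic uses
whole days and 365.25 days per year.

## Code sets and matching

All cohort definitions are driven by named code sets in one YAML file.
Codes are normalised to the dotless HES form (uppercase, dot stripped, at
most four significant characters). Matching follows classification
semantics: a 3-character member denotes a whole section and matches by
prefix (`T83` matches `T831`); a 4-character member matches exactly. A set
may also force `exact` or `prefix` for every member.

Only the code lists printed in the analysis's main text are fixed:
insertion (`M533`, `M536`, `M521`), prolapse surgery (`P242 P245 P246 P236
P237 Q544 Q545 Q546`), incontinence (`N393 N394 R32`), implied incontinence
(`T831 T834 T835 T836 T838 T839 Z466`), endoscopy (`M45`, `M77`),
catheterisation (`M302 M382 M471 M474 M478 M479 M481`), and the complication
sections `T81`, `R33`, `T83`, `Y73`. The remaining sets (mesh
removal/repair/renewal procedure codes, confounder / benign / rescue
procedure lists, peri-procedural attribution, 30-day complication and
qualifier sections) come from supplementary material that is not publicly
printed; the shipped configuration carries clearly labelled placeholder
membership and is meant to be edited for any real extract. Every downstream
rule reads the configuration, never hard-coded lists, and the synthetic
generator uses the same file, so ground truth and pipeline agree on whatever
membership is configured.

## Cleaning

Exact duplicates are removed on the full administrative tuple — patient,
admission date and method, discharge date, destination and method, hospital,
sex, age and all codes. Episode start/end dates are deliberately **not** in
the key: real duplicate feeds repeat whole rows, while genuine sibling
episodes of one spell differ in their code content. Exclusions follow in a
fixed order: patients with any non-female admission; patients with missing
age or age under 18; episodes with invalid or missing admission method;
episodes with missing admission date; episodes admitted after the recorded
in-hospital death (death date = discharge date of the earliest episode whose
discharge method codes death). Sex and age act patient-wise; the validity
rules act episode-wise, so a patient survives if only a follow-up episode is
unusable — if the index spell itself is affected the patient drops out
naturally at phenotyping. An episode with missing admission date removes
only that episode, a genuinely open choice flagged here. The attrition log
records per-rule episode and whole-patient removals and the identity
`in − Σ removed = out` is asserted on every run.

## Index spells and cohorts

Per patient, the candidate index spell is the earliest in-window spell
containing an insertion code and none of the prolapse-surgery or mesh
revision (removal/repair/renewal) codes. A candidate preceded by *any*
earlier mesh-surgery spell (including pre-window insertions) is excluded as
prior/concomitant mesh surgery, as is a patient whose only insertion spells
carry disqualifying codes. Surviving candidates must carry a coded or
implied incontinence diagnosis. Mesh type is TVT/TOT/SS by insertion code;
two distinct insertion codes make a combination procedure. A spell is
unconfounded when every non-insertion procedure is in the benign-concomitant
or rescue sets or is an endoscopy/catheterisation descriptor (these are
reported as descriptors for both cohorts, so they cannot confound);
combination procedures are always confounded — the only assignment
consistent with the published stratum totals, which leave no unconfounded
combination stratum.

## Readmission events

The readmission clock starts at the index spell's *discharge* date, and the
30-day window covers days 1–30 inclusive (a readmission cannot overlap the
index stay). A 30-day readmission is a complication when its primary
diagnosis is in the complication sections or is qualified by a
qualifier-section code appearing later in the same episode's diagnosis list;
further mesh surgery is flagged from procedure codes; anything else is
routine. After day 30, complications require a `T83`-section diagnosis or a
`Y73` qualifier, and further surgery is sub-typed removal → repair →
renewal → insertion (priority order when several codes co-occur). An
admission counted as a 30-day complication is never re-emitted as further
surgery (double-count suppression); a 30-day further-surgery admission
*without* complication coding stays in the further-surgery totals, since the
suppression rule as stated covers only complication-driven admissions.
Multiple qualifying codes in one admission collapse to one event per kind.
Time to first mesh-related readmission is censored at 31 March 2015 or at
in-hospital death.

## Estimators

* **Crude incidence** = 1000 × readmissions / person-years; reported
  person-years are total follow-up (index discharge to study end or death),
  matching the convention in which repeat readmissions keep contributing to
  both numerator and denominator.
* **Proportions** use Wilson score 95% intervals; at cohort sizes in the
  tens of thousands these reproduce the published one-decimal intervals and
  behave better than the normal approximation for the small SS strata.
* **Kaplan–Meier** is fitted with lifelines; Greenwood's variance
  S²Σ dᵢ/(Yᵢ(Yᵢ−dᵢ)) and a log-scale CI S·exp(±1.96·se(log S)) (clipped to
  [0, 1]) are computed from the risk table. Ties follow the events-before-
  censorings convention. All-censored input yields the degenerate S ≡ 1 with
  a warning.
* **Kernel hazard**: Nelson–Aalen increments dᵢ/Yᵢ smoothed with an
  Epanechnikov kernel, default global bandwidth 0.5 years (configurable; the
  bandwidth trades variance against the ability to resolve the early-risk
  peak, and 0.5 y resolves a two-year feature comfortably). Near t = 0 and
  the largest observed time the kernel mass is renormalised over the
  admissible support — a simple boundary correction that is unbiased for
  locally constant hazards, in contrast to uncorrected smoothing which
  halves the estimate at the boundaries. Output is scaled to events per
  1000 person-years. Interior values agree with lifelines' smoothed
  Nelson–Aalen estimate; the boundary correction and controllable grid are
  why the estimator is implemented here.

## Synthetic cohorts

The generator emulates the national study conditions: index admissions
uniform over the 8-year window (follow-up therefore 0–8 years, mean ≈ 4);
mesh-type mix from the published totals (61.4% TVT, 37.6% TOT, 0.9% SS,
0.07% combinations); 26.3% confounded; 99.8% elective; 25% endoscopy and 2%
catheterisation coding; peri-procedural complication classes drawn
independently at rates summing to ≈ 2.4%; first complication and
further-surgery readmissions drawn from separate piecewise-constant hazards
concentrated in years 0–2 (defaults 9→4 and 20→8 per 1000 person-years,
≈ 16/1000 overall — the published cohort-wide scale); further-surgery
subtypes weighted as published (47% removal, 18% repair, 35% insertion,
renewal rare); in-hospital death as an exponential competing process at
0.0019/year encoded through the HES discharge-method field; 5% routine
30-day readmissions; 5% of index spells lacking an SUI diagnosis and 1.5%
with prior mesh surgery (exercising the exclusion paths); 0.3% verbatim
duplicate rows and 0.2% corrupted demographics (≈ 0.5% of rows, the scale of
the dirty rows the national extract shed). `SimulationConfig.clean()` zeroes
the noise and exclusion rates for exact-recovery runs. Event days are drawn
by inverse-transform from the integrated hazard and rounded to whole days;
same-day collisions between the two event kinds shift the surgery by one day
so admissions within a patient have distinct dates. Per-seed output is
byte-identical.

Closed-form companions `expected_event_count` / `expected_person_years`
integrate the configured hazard against the uniform censoring and
exponential death process (piecewise-exact inner integrals, quadrature over
the censoring distribution) and are the ground truth for the recovery
checks.

What the generator does **not** model: inter-hospital transfers, private-
sector and outpatient care, emigration or out-of-hospital death, coding
drift over time, correlation between baseline covariates and readmission
risk, and more than one readmission per event kind. Passing recovery tests
therefore demonstrate that the pipeline's logic and estimators are correct
under the coded conventions — not that real extracts are free of the coding
and capture biases discussed for administrative data.

## Problem sizes and numerics

Recovery checks run at 10⁴ patients (phenotype recovery, oracle
equivalence against a brute-force enumerator), ≈ 10⁵ episodes (attrition
accounting) and 2 × 10⁴ patients (survival parameter recovery), sizes at
which binomial/Poisson noise is far smaller than any defect the checks
guard against. Crude-rate recovery is judged against the 95% Poisson
interval of the closed-form expectation; the 5-year Kaplan–Meier against
± 3 Greenwood standard errors of exp(−H(5)); the hazard plateau against
± 3 approximate standard errors √(0.6·h/(Y(t)·b)). Quartiles use linear
interpolation; annual activity uses NHS financial years (April–March);
rounding to printed precision happens only at the reporting edge, never
inside estimators.

## Known limitations

Placeholder code-set membership (above) is the main one: absolute synthetic
complication frequencies are only as meaningful as the configured lists.
Spell linkage uses the minimal deterministic key (patient, admission date,
hospital) rather than extract-specific episode-linkage fields, so transfers
between hospitals on the same day appear as separate spells. Death is
treated as censoring (no competing-risks estimator), and no cross-stratum
or confounded-vs-unconfounded outcome comparison is attempted — severity
information needed for baseline matching does not exist in the coded data.
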
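# meshcohort

A tested pipeline for cohort analysis of surgical-mesh procedures for stress
urinary incontinence (SUI) over episode-level hospital-admission records in
the English Hospital Episode Statistics (HES) admitted-patient-care schema.

Real HES extracts are obtainable only under licence, so the package ships a
synthetic-data generator that emits HES-like episode tables with known ground
truth — duplicates, invalid demographics, multi-episode admissions,
concomitant-procedure mixes, complication coding, hazard-driven readmissions,
in-hospital deaths and administrative censoring — making every downstream
stage testable end to end.

## What the pipeline does

1. **Code sets** (`codesets`) — named OPCS-4 / ICD-10 code sets (mesh
   insertion `M53.3`/`M53.6`/`M52.1`, pelvic-organ-prolapse surgery,
   incontinence diagnoses `N39.3`/`N39.4`/`R32`, implied diagnoses
   `T83.1/.4/.5/.6/.8/.9`/`Z46.6`, complication sections `T81`, `T83`, `Y73`,
   `R33`, …) loaded from editable YAML, with dotless normalisation and
   section-prefix matching (3-character codes match their whole section).
2. **Cleaning** (`cleaning`) — exact-duplicate removal on the full
   administrative field tuple; exclusion of non-female and under-18/missing-age
   patients, invalid/missing admission method or date, and post-death
   episodes; every rule logged in an attrition trail with the identity
   `episodes_in − Σ removals = episodes_out` enforced.
3. **Phenotyping** (`cohort`) — episodes grouped into spells (one hospital
   admission); the *index spell* is the earliest in-window admission with a
   first-time mesh-insertion code, no disqualifying concomitant surgery and a
   coded/implied SUI diagnosis; mesh type (TVT / TOT / SS / combination) and
   confounding status are classified per patient.
4. **Events** (`complications`) — peri-procedural complications with
   attribution (procedural / device / urinary / other); 30-day readmission
   taxonomy (routine / complication / further surgery); long-term mesh
   complications (`T83` or `Y73`-qualified) and further mesh surgery
   (removal / repair / insertion / renewal) with double-count suppression;
   time to first mesh-related readmission, censored at study end or death.
5. **Survival** (`survival`) — person-years; crude incidence per 1000
   person-years; Wilson score intervals; Kaplan–Meier with Greenwood variance
   (S(t) = Π(1 − dᵢ/Yᵢ)); Epanechnikov kernel-smoothed hazard
   ĥ(t) = Σᵢ K_b(t − tᵢ)·dᵢ/Yᵢ with boundary correction.
6. **Reporting** (`reporting`, `cli`) — table-shaped outputs (index
   descriptors, readmission-count distribution, readmission reasons with
   rates and 5-year event-free %), attrition flow, financial-year activity
   counts, and a `meshcohort` CLI over the whole chain.

## Worked example

```python
from meshcohort import SimulationConfig, run_pipeline

bundle = run_pipeline(config=SimulationConfig(n_patients=5000, seed=42))
print(bundle.attrition)
print(bundle.table3)
```

prints (abridged) an attrition log

```
                    rule  episodes_removed  patients_removed
        exact_duplicates                30                 0
          sex_not_female                 7                 4
 age_missing_or_under_18                 5                 3
invalid_admission_method                 3                 1
  missing_admission_date                 1                 0
    episodes_after_death                 0                 0
```

— 46 dirty rows removed, after which 4677 of 5000 patients receive an index
spell (the rest lack an SUI diagnosis or had prior mesh surgery), 3417 of
them unconfounded — and, for the unconfounded cohort, the readmission table

```
mesh_type  patients  person_years  any_total  any_patients  any_rate_per_1000py  free_5y_pct  free_5y_lo  free_5y_hi
      TVT      2134        8547.9        165           159                 19.3         91.2        89.8        92.7
      TOT      1248        4914.9        104           103                 21.2         90.9        89.1        92.7
       SS        35         142.4          1             1                  7.0         92.3        78.9       100.0
      All      3417       13605.2        270           263                 19.8         91.1        90.0        92.2
```

`any_total` counts mesh-related readmissions (complications of a previous
mesh, or further mesh surgery), `any_rate_per_1000py` the crude incidence
over the stratum's person-years, and `free_5y_pct` the Kaplan–Meier
percentage still free of any mesh-related readmission five years after the
index procedure, with its 95% CI.

The same run from a shell:

```bash
meshcohort all --seed 42 --out report/
```

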
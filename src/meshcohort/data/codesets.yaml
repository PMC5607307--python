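# Named OPCS-4 / ICD-10 code sets driving cohort definition, complication
# detection and readmission classification.
#
# Codes are written dotless (HES style).  match_mode "auto" applies section
# semantics per member: 3-character members are treated as prefixes (whole
# classification sections), 4-character members match exactly.
#
# Sets marked PLACEHOLDER carry membership that is not fixed by the published
# main-text code lists; they are deliberately editable.  Replace them with a
# site's full supplementary lists before analysing real extracts.  The
# synthetic-data generator reads the same file, so ground truth and pipeline
# always agree on whatever membership is configured.

mesh_insertion:            # first-time mid-urethral mesh insertion for SUI
  scheme: OPCS-4
  codes: [M533, M536, M521]   # TVT, TOT, suprapubic sling

pop_surgery:               # pelvic organ prolapse surgery (disqualifies index)
  scheme: OPCS-4
  codes: [P242, P245, P246, P236, P237, Q544, Q545, Q546]

mesh_removal:              # PLACEHOLDER: complete/partial removal of prior mesh
  scheme: OPCS-4
  codes: [M537]

mesh_repair:               # PLACEHOLDER: further procedure on a prior mesh
  scheme: OPCS-4
  codes: [M538]

mesh_renewal:              # PLACEHOLDER: removal + replacement with new mesh
  scheme: OPCS-4
  codes: [M539]

incontinence_diagnosis:    # coded diagnosis of urinary incontinence
  scheme: ICD-10
  codes: [N393, N394, R32]    # R32 is a 3-char section -> prefix match

implied_incontinence:      # fitting of a urinary prosthesis implies SUI
  scheme: ICD-10
  codes: [T831, T834, T835, T836, T838, T839, Z466]

confounder_procedures:     # PLACEHOLDER: concomitant procedures likely to
  scheme: OPCS-4           # influence outcomes (e.g. hysterectomy,
  codes: [Q07, Q08, M523]  # colposuspension)

benign_concomitant:        # PLACEHOLDER: concomitant procedures unlikely to
  scheme: OPCS-4           # affect outcomes (diagnostic examinations)
  codes: [Q55]

rescue_procedures:         # PLACEHOLDER: rescue procedures associated with
  scheme: OPCS-4           # the insertion itself (urethral operations)
  codes: [M73]

endoscopy:                 # endoscopic examination of bladder and/or urethra
  scheme: OPCS-4
  codes: [M45, M77]

catheterisation:           # urinary or suprapubic catheter intervention
  scheme: OPCS-4
  codes: [M302, M382, M471, M474, M478, M479, M481]

periproc_complication:     # in-spell complication diagnoses with attribution.
  scheme: ICD-10           # DEVICE membership is a PLACEHOLDER chosen not to
  match_mode: auto         # overlap the implied_incontinence list.
  codes: [T81, R33, R30, T830, T832, T833, T837, Y73, T88]
  attribution:
    T81: PROCEDURAL
    R33: URINARY
    R30: URINARY
    T830: DEVICE
    T832: DEVICE
    T833: DEVICE
    T837: DEVICE
    Y73: DEVICE
    T88: OTHER

thirty_day_complication:   # PLACEHOLDER: primary-diagnosis complication codes
  scheme: ICD-10           # for 30-day readmissions (complications of
  codes: [T80, T81, T82, T83, T84, T85, T86, T87, T88]  # surgical/medical care)

complication_qualifiers:   # PLACEHOLDER: supplementary-position qualifier
  scheme: ICD-10           # sections marking a primary diagnosis as a
  codes: [Y73, Y83, Y84]   # complication of care

longterm_complication:     # complications of genitourinary prosthetic devices
  scheme: ICD-10
  codes: [T83]

longterm_qualifiers:       # devices associated with adverse incidents
  scheme: ICD-10
  codes: [Y73]
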
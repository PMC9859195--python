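# agemajority

Rule-based forensic assessment of the **age of majority** (18 years) from
dental and skeletal maturity indicators, for forensic odontologists,
legal-medicine practitioners, and researchers who need a transparent,
auditable implementation of the step-wise decision flow used for
undocumented young people (e.g. unaccompanied minors), together with a
synthetic maturation-cohort simulator that makes every branch of the flow
testable without radiographs.

## The decision flow

A subject's evidence is traversed through a fixed tree; doubt always
resolves in the subject's favour (*in dubio pro reo*):

1. **Physical examination.** Visible signs of abnormal growth divert to an
   expert referral (indeterminate; minor age presumed). Unless both
   recorded secondary sexual characteristics are at **Tanner stage 5**, the
   subject is presumed a minor.
2. **Seven-teeth gate.** If any root of the seven left mandibular teeth
   (FDI 31–37) is not completely developed, the subject is a **minor**
   (empirically such subjects are under 16–17).
3. **Third molar.** The maturity index

   I₃ₘ = Σ (open-apex gap widths) / tooth length,  I₃ₘ = 0 when the apices
   are fully closed,

   is banded at 0.08 and 0.15:
   * I₃ₘ < 0.08 → the **clavicle** decides: Schmeling stage ≥ 4 means
     adult with probability **> 99.9 %**, a lower stage (or no clavicle
     film) means **96 %**;
   * 0.08 ≤ I₃ₘ < 0.15 → adult probability **60 %** (presumed minor);
   * I₃ₘ ≥ 0.15 → adult probability **16 %** (presumed minor).
4. **Unassessable third molar** (agenesis, extraction, rotation — about 6 %
   of subjects): the clavicle is read directly (stage ≥ 4 → adult at
   99.9 %; below stage 4 the clavicle cannot separate adults from minors —
   about 46 % of such subjects are adults — so the default outcome is
   indeterminate with the minor presumption).

Hand/wrist maturity (the Bo/Ca carpal-area ratio, also implemented) is
deliberately **never consulted** by the tree: subjects with incomplete
hand/wrist maturity are under 16 and already fail the seven-teeth gate, so
a wrist film adds radiation without information.

## Worked example

```python
from agemajority import (
    ApexMeasurement, ClavicleAssessment, PhysicalExam, SevenTeethAssessment,
    SEVEN_TEETH_FDI, SubjectAssessment, ThirdMolarAssessment, classify, explain,
)

subject = SubjectAssessment(
    subject_id="case-0421",
    exam=PhysicalExam(sex="m", tanner_pubic_hair=5, tanner_second_characteristic=5),
    teeth=SevenTeethAssessment(apices_closed={f: True for f in SEVEN_TEETH_FDI}),
    third_molar=ThirdMolarAssessment(
        assessable=True,
        measurement=ApexMeasurement(open_apex_gaps=(0.5, 0.3), tooth_length=16.0),
    ),
    clavicle=ClavicleAssessment(schmeling_stage=4),
)
print(explain(classify(subject)))
```

prints

```
Subject: case-0421
Classification: ADULT
Leaf: i3m_low_clavicle_mature
Probability of having reached 18 years: > 99.9%
Path: physical_exam -> tanner_gate -> teeth_gate -> third_molar -> i3m_band:below_0.08 -> clavicle_gate -> i3m_low_clavicle_mature
Evidence used: physical_exam, teeth, third_molar, clavicle
```

The I₃ₘ here is (0.5 + 0.3)/16 = 0.05 < 0.08, so the clavicle is
consulted; at Schmeling stage 4 the subject is declared adult with the
reported > 99.9 % probability, and the audit trail records every node
traversed.

The same machinery is scriptable from the shell:

```bash
agemajority simulate --n 1000 --seed 7 --out cohort.csv
agemajority evaluate --cohort cohort.csv \
    --out-branches branches.csv --out-misclass misclass.json
agemajority fixture      # the packaged reference sample-distribution table
```

## The simulator

`simulate_cohort` draws seeded cohorts aged 14–24 with latent
maturation-event ages (hand completion, seven-teeth completion,
third-molar apex closure, Schmeling stage transitions, Tanner stage 5)
that honour the hard population constraints: incomplete hand ⇒ under 16,
incomplete teeth ⇒ under 17, clavicle stage ≥ 4 ⇒ at least 19.
`calibrate_simulator` tunes the third-molar closure curve and the
clavicular fusion ages so the simulated conditionals
P(adult | branch) reproduce the reported 96 / 60 / 16 / 46 percentages.
See `docs/methods.md` for the model, its parameters, and its limits.

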
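excluded_diagnoses:
- chf
- mi
- pulmonary_embolism
pneumonia_required_meds:
- antibiotic
- systemic_steroid
steroid_codiagnoses:
- allergic_lung_disease
- interstitial_lung_disease
steroid_codiagnosis_required_meds:
- antibiotic
- systemic_steroid
outpatient_severity:
- - antibiotic
  - moderately_severe
- - systemic_steroid
  - moderately_severe
- - home_antibiotic_steroid
  - moderate
- - inhaler_escalation
  - mild
outpatient_fallback: very_mild
merge_window_days: 30
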
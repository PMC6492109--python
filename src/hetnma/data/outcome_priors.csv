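outcome,m_pred,s_pred,m_arm,s_arm
all_cause_mortality,-4.28,1.61,-4.83,1.69
obstetric_outcomes,-3.33,1.60,-3.88,1.69
cause_specific_mortality_major_morbidity,-3.52,1.61,-4.08,1.70
resource_use_hospital_stay_process,-2.21,1.60,-2.76,1.69
surgical_device_success_failure,-1.86,1.61,-2.42,1.70
withdrawals_dropouts,-2.85,1.60,-3.40,1.69
internal_external_structure,-2.53,1.61,-3.09,1.70
general_physical_health,-2.37,1.61,-2.93,1.70
adverse_events,-1.97,1.60,-2.52,1.69
infection_new_disease,-2.55,1.60,-3.10,1.69
signs_symptoms_condition,-2.13,1.60,-2.68,1.69
pain,-1.85,1.60,-2.40,1.69
quality_of_life,-2.59,1.62,-3.15,1.71
mental_health,-2.20,1.62,-2.76,1.71
biological_markers,-1.83,1.60,-2.38,1.69
subjective_outcomes,-2.75,1.61,-3.31,1.70
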
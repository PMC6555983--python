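criterion,patients_remaining
total_patients,10
ge2_kidney_dx_claims,10
first_line_agent_index,9
age_ge_18,9
continuous_enrollment,9
no_tcc_agent,8
no_other_primary_cancer,7
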
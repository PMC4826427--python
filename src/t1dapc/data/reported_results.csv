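# Headline quantities printed in the published study text, used as inputs to
# the consistency checks (not reproducible without the national registers).
quantity,value
total_cancers,9149
total_person_years_a_thousand,4064.0
total_person_years_b_thousand,3983.0
cases_with_known_dx_date,7792
duration_known_pct,85.2
prostate_hr_men,0.56
prostate_reduction_pct,44

hr_all_cancers_men,1.01
hr_all_cancers_women,1.07
hr_first_year_men,2.28
hr_first_year_women,2.34
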
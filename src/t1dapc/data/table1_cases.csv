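# First-primary cancer cases in persons with diabetes diagnosed under age 40,
# by site, sex and country, as printed in the published five-country study table.
# Empty cells were printed NA (data not available).
site,sex,AU,DK,FI,SC,SE
All sites,men,504,401,1000,253,1882
All sites,women,600,641,1408,280,2180
Non-sex-specific,men,443,352,832,222,1480
Non-sex-specific,women,364,351,680,146,1122
Oesophagus,men,9,4,16,9,29
Oesophagus,women,3,1,5,7,14
Stomach,men,12,6,47,5,64
Stomach,women,13,14,50,4,39
Colon,men,,26,56,18,173
Colon,women,,16,66,9,119
Rectum,men,,13,46,15,84
Rectum,women,,10,41,6,57
Colorectal,men,61,39,102,33,257
Colorectal,women,60,26,107,15,176
Liver,men,14,9,34,12,44
Liver,women,7,6,8,3,17
Pancreas,men,19,15,54,7,52
Pancreas,women,8,9,41,5,30
Lung,men,41,39,119,37,134
Lung,women,29,38,58,19,128
Melanoma,men,86,21,60,16,122
Melanoma,women,72,59,59,15,103
Breast,women,184,184,546,99,710
Cervix,women,11,48,36,14,85
Endometrium,women,25,40,97,12,149
Ovary,women,22,25,80,11,114
Prostate,men,41,12,148,11,341
Testis,men,22,37,23,20,57
Kidney,men,21,23,67,14,62
Kidney,women,15,15,47,4,37
Bladder,men,12,17,49,11,124
Bladder,women,2,7,16,6,35
Brain/CNS,men,17,31,35,18,79
Brain/CNS,women,13,42,32,28,98
Thyroid,men,15,6,18,4,15
Thyroid,women,45,29,104,12,51
Non-Hodgkin lymphoma,men,30,26,56,21,111
Non-Hodgkin lymphoma,women,19,14,46,8,56
Hodgkin lymphoma,men,11,11,14,,20
Hodgkin lymphoma,women,2,4,9,,9
Multiple myeloma,men,2,4,14,3,26
Multiple myeloma,women,2,5,8,0,13
Leukaemia,men,,14,39,13,38
Leukaemia,women,,16,33,9,28
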
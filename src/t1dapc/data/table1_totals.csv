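# Printed sex subtotals and row totals of the published case-count table.
site,subtotal_men,subtotal_women,total
All sites,4040,5109,9149
Non-sex-specific,3329,2663,5992
Oesophagus,67,30,97
Stomach,134,120,254
Colon,273,210,483
Rectum,158,114,272
Colorectal,492,384,876
Liver,113,41,154
Pancreas,147,93,240
Lung,370,272,642
Melanoma,305,308,613
Breast,,1723,1723
Cervix,,194,194
Endometrium,,323,323
Ovary,,252,252
Prostate,553,,553
Testis,159,,159
Kidney,187,118,305
Bladder,213,66,279
Brain/CNS,180,213,393
Thyroid,58,241,299
Non-Hodgkin lymphoma,244,143,387
Hodgkin lymphoma,56,24,80
Multiple myeloma,53,28,81
Leukaemia,104,86,190
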
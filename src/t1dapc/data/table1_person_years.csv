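# Person-years (thousands) of T1D follow-up by sex and country, both footnote
# variants: a = follow-up to first primary tumour of any kind or study end;
# b = follow-up to death or study end (used for site-specific analyses).
variant,sex,AU,DK,FI,SC,SE,subtotal
a,men,255.5,255.6,547.9,178.7,737.5,1975.1
a,women,255.4,289.0,636.8,145.5,631.8,1957.7
b,men,255.5,258.9,553.8,179.5,746.0,1993.7
b,women,255.4,293.9,648.0,146.8,645.2,1989.3
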
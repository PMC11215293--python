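# Template lumen diet table (synthetic example values, not a curated diet).
# Columns: pool metabolite id, lower bound, upper bound (mmol·gDW⁻¹·h⁻¹);
# negative lower bound supplies the metabolite to the pool.
metabolite_id	lower	upper
glc__D_e	-10	1000
fru_e	-5	1000
but_e	0	1000
ac_e	0	1000
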
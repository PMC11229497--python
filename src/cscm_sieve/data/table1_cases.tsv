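case_id	material	breed	sex	bw_kg	ga_days
1	Carcass	Red Danish x Holstein	Female	7.3	272
2	Carcass	Holstein	Female	30.5	278
3	Carcass	Holstein	Male	32.0	277
4	Tissue	Holstein	Male	NA	280
5	Tissue	Holstein	Male	NA	285
6	Carcass	Holstein	Male	32.7	272
7	Carcass	Holstein	Female	27.4	283
8	Carcass	Holstein	Male	37.3	NA
9	Tissue	Holstein	Male	NA	296
10	Carcass	Holstein	Female	30.0	288
11	Carcass	Holstein	Male	27.1	266
12	Carcass	Holstein	Male	32.5	276
13	Carcass	Holstein	Male	26.0	295
14	Tissue	Holstein	Male	NA	278
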
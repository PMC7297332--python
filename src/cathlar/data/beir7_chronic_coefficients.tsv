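# PROVENANCE: lifetime attributable risk per 100,000 persons continuously
# exposed to 10 mSv per year from age 18 to age 65 (BEIR VII chronic-exposure
# scenario, report Table 12D-3).  Incidence values (M 3059, F 4295) are the
# all-cancer figures quoted for this scenario.  Mortality values are
# back-calculated from the corresponding published all-cancer mortality
# percentages for occupational doses of 3.49 and 1.30 mSv/yr under linear
# no-threshold scaling (0.59%/0.22% male, 0.83%/0.31% female), and are
# consistent with the report's chronic-exposure mortality table to the
# precision those percentages carry.
sex	outcome	lar_per_100k
M	incidence	3059
F	incidence	4295
M	mortality	1691
F	mortality	2379
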
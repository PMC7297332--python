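# PROVENANCE: BEIR VII Phase 2 report (National Research Council, 2006),
# preferred site-specific ERR/EAR risk models as transcribed from the
# report's cancer-incidence/mortality model tables (Tables 12-2 and 12-3).
#
# Solid sites: excess = beta * D * exp(gamma*estar) * (a/age_pivot)^eta with
# estar = (min(e,30)-30)/10, D in Sv, a = attained age, age_pivot 60.
# Female breast (EAR-only, pooled-cohort model): excess =
# beta * D * exp(gamma*(e-exposure_pivot)/10) * (a/50)^eta with eta switching
# to eta_old at attained age age_knot = 50.
# Thyroid is ERR-only.  Leukemia (linear-quadratic):
# excess = beta * D * (1 + theta*D) * exp(gamma*estar + delta*ln(t/25)
# + phi*estar*ln(t/25)), t = years since exposure.
#
# ERR beta is per Sv; EAR beta is per 10^4 person-year-Sv.  Latency: 5 y for
# solid sites, 2 y for leukemia.  DDREF 1.5 divides the solid dose term.
# err_weight is the ERR share of the log-scale ERR/EAR transport combination
# (0.7 generally, 0.3 for lung, 1 thyroid, 0 breast).
site	kind	model	sex	beta	gamma	eta	theta	delta	phi	eta_old	age_knot	age_pivot	exposure_pivot	err_weight
stomach	solid	err	M	0.21	-0.3	-1.4						60		0.7
stomach	solid	err	F	0.48	-0.3	-1.4						60		0.7
stomach	solid	ear	M	4.9	-0.41	2.8						60		0.7
stomach	solid	ear	F	4.9	-0.41	2.8						60		0.7
colon	solid	err	M	0.63	-0.3	-1.4						60		0.7
colon	solid	err	F	0.43	-0.3	-1.4						60		0.7
colon	solid	ear	M	3.2	-0.41	2.8						60		0.7
colon	solid	ear	F	1.6	-0.41	2.8						60		0.7
liver	solid	err	M	0.32	-0.3	-1.4						60		0.7
liver	solid	err	F	0.32	-0.3	-1.4						60		0.7
liver	solid	ear	M	2.2	-0.41	2.8						60		0.7
liver	solid	ear	F	1.0	-0.41	2.8						60		0.7
lung	solid	err	M	0.32	-0.3	-1.4						60		0.3
lung	solid	err	F	1.4	-0.3	-1.4						60		0.3
lung	solid	ear	M	2.3	-0.41	5.2						60		0.3
lung	solid	ear	F	3.4	-0.41	5.2						60		0.3
breast	solid	err	F	0.51	0.0	-2.0						60		0.0
breast	solid	ear	F	9.4	-0.51	3.5				1.1	50	50	25	0.0
prostate	solid	err	M	0.12	-0.3	-1.4						60		0.7
prostate	solid	ear	M	0.11	-0.41	2.8						60		0.7
uterus	solid	err	F	0.055	-0.3	-1.4						60		0.7
uterus	solid	ear	F	1.2	-0.41	2.8						60		0.7
ovary	solid	err	F	0.38	-0.3	-1.4						60		0.7
ovary	solid	ear	F	0.7	-0.41	2.8						60		0.7
bladder	solid	err	M	0.5	-0.3	-1.4						60		0.7
bladder	solid	err	F	1.65	-0.3	-1.4						60		0.7
bladder	solid	ear	M	1.2	-0.41	2.8						60		0.7
bladder	solid	ear	F	0.75	-0.41	2.8						60		0.7
thyroid	solid	err	M	0.53	-0.83	0.0						60		1.0
thyroid	solid	err	F	1.05	-0.83	0.0						60		1.0
other	solid	err	M	0.27	-0.3	-1.4						60		0.7
other	solid	err	F	0.45	-0.3	-1.4						60		0.7
other	solid	ear	M	6.2	-0.41	2.8						60		0.7
other	solid	ear	F	4.8	-0.41	2.8						60		0.7
leukemia	leukemia	err	M	1.1	-0.4		0.87	-0.48	0.42			60		0.7
leukemia	leukemia	err	F	1.2	-0.4		0.87	-0.48	0.42			60		0.7
leukemia	leukemia	ear	M	1.62	0.29		0.88	0.0	0.56			60		0.7
leukemia	leukemia	ear	F	0.93	0.29		0.88	0.0	0.56			60		0.7
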
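	AGER	SFTPC	TMEM100	FABP4	SPP1	WIF1	COL11A1	CYP4B1	FCN3	ADH1B	CLDN18
AGER	0	0.643	0.436	0.515	0.531	0.496	0.363	0.348	0.545	0.364	0.567
SFTPC	0.643	0	0.373	0.410	0.410	0.570	0.432	0.550	0.441	0.544	0.550
TMEM100	0.436	0.373	0	0.305	0.270	0.226	0.159	0.239	0.600	0.433	0.319
FABP4	0.515	0.410	0.305	0	0.317	0.257	0.070	0.310	0.201	0.384	0.407
SPP1	0.531	0.410	0.270	0.270	0	0.373	0.375	0.155	0.277	0.273	0.462
WIF1	0.496	0.570	0.226	0.226	0.257	0	0.241	0.390	0.371	0.470	0.446
COL11A1	0.363	0.432	0.159	0.159	0.079	0.241	0	0.236	0.326	0.253	0.265
CYP4B1	0.348	0.550	0.239	0.239	0.319	0.390	0.236	0	0.264	0.497	0.239
FCN3	0.545	0.441	0.600	0.600	0.201	0.371	0.326	0.264	0	0.312	0.370
ADH1B	0.364	0.544	0.433	0.433	0.384	0.470	0.253	0.497	0.312	0	0.404
CLDN18	0.567	0.550	0.319	0.407	0.462	0.446	0.265	0.239	0.370	0.404	0
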
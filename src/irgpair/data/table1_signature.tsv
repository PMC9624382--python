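IRG1	IRG2	Coefficient
IGF1R	IGF2R	-0.280680737393679
CD74	CRABP2	-0.129381388033907
HSPA2	NEDD4	-0.431472955510512
CIITA	TLR7	-0.0861166676605254
CIITA	PLXNB3	-0.1318512759267
MICA	PLXNB1	0.397483055209339
RELB	CCR1	-0.126764197388246
RFXAP	IGLV6-57	0.0399268657548744
TAPBPL	IGF2R	-0.266631594480481
CXCL14	HMOX1	-0.0424869848483334
CCL8	CD3D	0.123645099256706
S100B	PLXNB3	-0.0745978715504017
APOBEC3G	PLXNB3	-0.349449105911909
TRIM5	IL27RA	0.187761415761893
TYK2	PTK2	-0.237158486425192
MSR1	|IL18	0.2957793442697
PPARG	PLXNB3	-0.128237814963708
VAV1	ITGAL	0.318667102339933
RAC2	C3AR1	-0.319397161742718
IGHD	BTC	-0.00256266119415776
IGHD	SCG2	-0.019365921132164
IGHD	NPR3	-0.252893524646672
IGHD	ZAP70	-0.194457565172438
SEMA3B	SEMA6C	-0.192591720762394
SEMA3B	BTC	-0.18492459694902
ACVRL1	IL27RA	0.116702510407455
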
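PredictTLS	17-gene TLS signature predictive of immune-checkpoint-blockade response	CCL8	CXCL9	CXCL10	CXCL11	CXCR3	CCR3	CCR5	ICAM1	CXCL13	CD40	CD38	DERL3	SSR4	PDCD1	TIGIT	CD274	PIM2
COXIS_CP	Cancer-promoting inflammatory genes of the COX-IS score	VEGFA	CCL2	IL8	CXCL1	CXCL2	CSF3	IL6	IL1B	IL1A
COXIS_CI	Cancer-inhibitory inflammatory genes of the COX-IS score	CCL5	CXCL9	CXCL10	CXCL11	IL12A	IL12B	IFNG	CD8A	CD8B	GZMA	GZMB	EOMES	PRF1	STAT1	TBX21
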
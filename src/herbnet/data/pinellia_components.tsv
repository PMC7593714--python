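id	name	OB	DL
5484202	24-Ethylcholest-4-en-3-one	36.08	0.76
193148	Cavidine	35.64	0.81
5281605	Baicalein	33.52	0.21
64982	Baicalin	40.12	0.75
222284	beta-Sitosterol	36.91	0.75
5280794	Stigmasterol	43.83	0.76
5282768	Gondoic acid	30.7	0.2
389888	Coniferin	31.11	0.32
5365687	10,13-Eicosadienoic acid	39.99	0.2
92110	Cycloartenol	38.69	0.78
64959	beta-D-Ribofuranoside, xanthine-9	44.72	0.21
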
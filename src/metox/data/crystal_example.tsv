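name	residue_label	ssasa_model	ssasa_crystal	dsasa_model	dsasa_crystal	wcn_model	wcn_crystal	oh_model	oh_crystal
Abituzumab	H:34	3.26	0.00	1.89	0.44	1.05	0.67	0.71	0.42
Abituzumab	H:69	0.00	0.00	0.01	0.81	0.04	1.26	1.00	0.72
Abituzumab	H:80	0.00	0.00	0.01	0.03	0.00	0.02	0.00	0.00
Abituzumab	H:100A	2.16	0.00	1.06	0.02	1.34	0.01	1.00	1.07
Ofatuzumab	H:34	0.00	0.00	0.03	0.01	0.00	0.10	0.00	0.00
Ofatuzumab	H:82	0.00	0.00	0.01	0.01	0.00	0.00	0.98	0.95
Ofatuzumab	H:100E	0.00	0.00	0.29	0.05	0.08	0.00	1.00	1.00
Vesencumab	H:34	0.17	3.02	0.37	0.67	0.00	0.06	0.00	0.00
Vesencumab	H:82	0.00	0.00	0.00	0.01	0.00	0.00	1.00	0.98
Vesencumab	H:100B	132.22	85.17	116.89	84.36	18.57	12.32	0.62	2.27
Vesencumab	H:100F	15.64	1.93	5.03	3.24	2.80	3.31	1.94	2.00
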
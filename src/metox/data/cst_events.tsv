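name	n_fd_met	observed_events	pred_adimab	pred_ssasa	pred_dsasa	pred_wcn	pred_wcn_oh
Abituzumab	4	0	0	0	0	0	0
Dinutuximab	4	2	2	2	1	2	2
Duligotuzumab	2	0	0	0	0	0	0
Eldelumab	5	2	2	2	2	2	2
Fletikumab	3	0	0	0	0	0	0
Golimumab	4	0	0	0	0	0	0
Imgatuzumab	3	1	0	0	0	0	0
Lintuzumab	3	0	0	0	0	0	0
Lirilumab	3	1	0	0	0	0	1
Natalizumab	3	0	0	0	0	0	0
Ofatumumab	3	0	0	0	0	0	0
Tocilizumab	2	1	0	0	0	0	1
Tovetumab	3	0	0	0	0	0	0
Vesencumab	4	2	1	1	1	1	2
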
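molecule	met_id	position	ox_percent	pred_ssasa	pred_dsasa	pred_wcn	pred_wcn_oh
mAb1	Met#1	LFR1	1.7	0	0	0	0
mAb1	Met#2	HFR2	3.4	0	0	0	0
mAb1	Met#3	HFR3	1.4	0	0	0	0
mAb2	Met#4	HFR2	3.7	0	0	0	0
mAb2	Met#5	HFR3	0.0	0	0	0	0
mAb3	Met#6	LFR1	1.3	0	0	0	0
mAb3	Met#7	HFR2	34.2	1	1	1	1
mAb3	Met#8	HFR2	2.1	0	0	0	0
mAb3	Met#9	HFR3	9.7	1	1	1	1
mAb3	Met#10	HFR4	65.6	1	1	1	1
mAb4	Met#11	LFR2	3.3	0	0	0	0
mAb4	Met#12	HFR2	2.1	0	0	0	0
mAb4	Met#13	HFR3	0.5	0	0	0	0
mAb4	Met#14	HFR3	1.2	0	0	0	0
mAb4	Met#15	CDRH3	10.0	0	0	0	1
mAb5	Met#16	HFR2	1.9	0	0	0	0
mAb5	Met#17	HFR3	2.2	0	0	0	0
mAb5	Met#18	CDRH3	3.1	1	0	0	0
mAb6	Met#19	LFR1	1.2	0	0	0	0
mAb6	Met#20	LFR1	5.0	1	1	1	1
mAb6	Met#21	HFR2	1.3	0	0	0	0
mAb7	Met#22	HFR2	2.2	0	0	0	0
mAb7	Met#23	HFR3	1.1	0	0	0	0
mAb7	Met#24	HFR4	39.3	1	1	1	1
ADC1	Met#25	HFR2	0.3	0	0	0	0
ADC2	Met#26	LFR1	4.6	1	0	0	0
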
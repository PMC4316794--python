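lg	map_cm	snps	scaffolds_anchored	anchored_bp	pct_assembly	scaffolds_oriented	oriented_bp	pct_oriented	rate_cm_per_mb
I	91.5	53	14	35370099	9.8	11	35197227	9.7	2.6
II	100.8	40	9	26185771	7.2	8	26070550	7.2	3.9
III	86.8	39	9	29379469	8.1	7	28223253	7.8	3.0
IV	76.8	65	18	33106231	9.2	10	30831195	8.5	2.3
V	110.5	29	6	28332775	7.8	4	19742536	5.5	3.9
VI	113.6	54	13	35927859	9.9	7	33605504	9.3	3.2
VII	105.8	57	14	26760857	7.4	9	26066430	7.2	4.0
VIII	103.2	56	14	32500408	9.0	9	28100052	7.8	3.2
IX	98.4	39	7	24101567	6.7	7	24101567	6.7	4.1
X	67.2	56	16	25347316	7.0	8	18851255	5.2	2.7
XI	107.3	60	14	31429130	8.7	13	31190979	8.6	3.4
XII	91.0	32	7	26394393	7.3	6	25034488	6.9	3.8
Total	1162.0	580	141	354835875	98.2	99	327015036	90.5	3.3
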
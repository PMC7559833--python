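panel	item	f1	f2	f3	f4	f5	mean	V	L	U
physicians	1	0	0	0	2	8	4.80	0.95	0.83	0.98
physicians	2	0	1	0	3	6	4.40	0.85	0.70	0.92
physicians	3	0	0	3	2	5	4.20	0.80	0.65	0.89
physicians	4	0	0	1	2	7	4.60	0.90	0.76	0.96
physicians	5	0	0	1	1	8	4.70	0.92	0.80	0.97
physicians	6	0	0	1	3	6	4.50	0.87	0.73	0.94
physicians	7	0	0	1	3	6	4.50	0.87	0.73	0.94
physicians	8	0	0	0	3	7	4.70	0.92	0.80	0.97
physicians	9	0	0	3	3	4	4.10	0.77	0.62	0.87
physicians	10	0	0	3	2	5	4.20	0.80	0.65	0.89
physicians	11	0	0	2	5	3	4.10	0.77	0.62	0.87
physicians	12	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	13	0	0	1	2	7	4.60	0.90	0.76	0.96
physicians	14	0	0	1	4	5	4.40	0.85	0.70	0.92
physicians	15	0	0	2	2	6	4.40	0.85	0.70	0.92
physicians	16	0	0	2	1	7	4.50	0.87	0.73	0.94
physicians	17	0	0	1	3	6	4.50	0.87	0.73	0.94
physicians	18	0	0	2	3	5	4.30	0.82	0.68	0.91
physicians	19	0	0	1	2	7	4.60	0.90	0.76	0.96
physicians	20	0	0	1	3	6	4.50	0.87	0.73	0.94
physicians	21	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	22	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	23	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	24	0	0	2	3	5	4.30	0.82	0.68	0.91
physicians	25	0	0	2	3	5	4.30	0.82	0.68	0.91
physicians	26	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	27	0	0	1	3	6	4.50	0.87	0.73	0.94
physicians	28	0	0	1	5	4	4.30	0.82	0.68	0.91
physicians	29	0	0	2	4	4	4.20	0.80	0.65	0.89
physicians	30	0	0	0	5	5	4.50	0.87	0.73	0.94
nurses	1	0	0	0	4	6	4.60	0.90	0.76	0.96
nurses	2	0	0	2	5	3	4.10	0.77	0.62	0.87
nurses	3	0	0	2	2	6	4.40	0.85	0.70	0.92
nurses	4	0	0	0	5	5	4.50	0.87	0.73	0.94
nurses	5	0	0	0	4	6	4.60	0.90	0.76	0.96
nurses	6	0	0	2	3	5	4.30	0.82	0.68	0.91
nurses	7	0	0	1	4	5	4.40	0.85	0.70	0.92
nurses	8	0	0	1	2	7	4.60	0.90	0.76	0.96
nurses	9	0	0	1	2	7	4.60	0.90	0.76	0.96
nurses	10	0	0	1	5	4	4.30	0.82	0.68	0.91
nurses	11	0	0	0	3	7	4.70	0.92	0.80	0.97
nurses	12	0	0	2	4	4	4.20	0.80	0.65	0.89
nurses	13	0	0	1	1	8	4.70	0.92	0.80	0.97
nurses	14	0	0	0	2	8	4.80	0.95	0.83	0.98
nurses	15	0	0	1	3	6	4.50	0.87	0.73	0.94
nurses	16	0	0	1	1	8	4.70	0.92	0.80	0.97
nurses	17	0	0	0	2	8	4.80	0.95	0.83	0.98
nurses	18	0	0	0	1	9	4.90	0.97	0.87	0.99
nurses	19	0	1	0	1	8	4.60	0.90	0.76	0.96
nurses	20	0	0	0	1	9	4.90	0.97	0.87	0.99
nurses	21	0	0	0	3	7	4.70	0.92	0.80	0.97
nurses	22	0	0	0	0	10	5.00	1.00	0.91	1.00
nurses	23	0	0	0	1	9	4.90	0.97	0.87	0.99
nurses	24	0	1	1	4	4	4.10	0.77	0.62	0.87
nurses	25	0	0	0	2	8	4.80	0.95	0.83	0.98
nurses	26	0	1	2	2	5	4.10	0.77	0.62	0.87
nurses	27	0	1	2	2	5	4.10	0.77	0.62	0.87
nurses	28	0	1	1	2	6	4.30	0.82	0.68	0.91
nurses	29	0	0	0	3	7	4.70	0.92	0.80	0.97
nurses	30	0	0	0	1	9	4.90	0.97	0.87	0.99
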
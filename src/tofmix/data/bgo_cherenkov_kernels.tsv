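kernel_id	fwhm_fast_ps	fwhm_slow_ps	alpha_fast
1	179.8	660.3	0.594
2	193.3	749.9	0.547
3	208.7	784.5	0.527
4	212.8	758.0	0.521
5	224.3	829.5	0.521
6	201.8	772.0	0.575
7	198.2	765.2	0.491
8	214.4	790.4	0.472
9	210.5	776.7	0.446
10	211.4	769.4	0.414
11	209.1	816.8	0.537
12	217.0	817.6	0.486
13	213.8	781.1	0.427
14	233.9	822.5	0.437
15	211.8	791.4	0.385
16	211.8	791.4	0.501
17	229.7	830.1	0.478
18	227.8	822.0	0.421
19	239.5	824.5	0.421
20	257.2	876.1	0.446
21	220.5	817.9	0.501
22	236.6	836.0	0.455
23	240.0	861.9	0.427
24	242.0	879.5	0.419
25	263.8	897.3	0.419
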
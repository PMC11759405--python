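participant	model	stage	feature	r
1	narx	1	hr_filtered	0.431
1	narx	2	rsp_running_rate	0.53
1	narx	3	inhal_depth	0.563
1	lr	1	rsp_running_rate	0.194
1	lr	2	hr_deriv	0.218
1	lr	3	hr_running_rate	0.234
2	narx	1	hr_filtered	0.515
2	narx	2	gsr_running_rate	0.568
2	narx	3	rsp_rate_deriv	0.591
2	lr	1	gsr_filtered	0.256
3	narx	1	hr_filtered	0.757
3	lr	1	gsr_running_rate	0.108
3	lr	2	exhal_depth	0.194
3	lr	3	exp_time	0.272
3	lr	4	gsr_deriv	0.379
3	lr	5	rsp_running_rate	0.443
4	narx	1	hr_filtered	0.635
4	narx	2	rsp_rate_deriv	0.646
4	narx	3	hr_running_rate	0.668
4	lr	1	gsr_running_rate	0.155
4	lr	2	hr_running_rate	0.274
4	lr	3	hr_deriv	0.306
4	lr	4	inhal_depth	0.371
5	narx	1	exp_time	0.575
5	narx	2	gsr_deriv	0.639
5	narx	3	hr_filtered	0.666
5	lr	1	gsr_filtered	0.214
5	lr	2	exhal_depth	0.267
5	lr	3	gsr_deriv	0.305
5	lr	4	exp_time	0.354
6	narx	1	hr_filtered	0.789
6	narx	2	gsr_deriv	0.835
6	lr	1	exhal_depth	0.23
7	narx	1	rsp_rate	0.459
7	narx	2	hr_filtered	0.523
7	narx	3	gsr_running_rate	0.544
7	lr	1	rsp_rate_deriv	0.149
7	lr	2	gsr_running_rate	0.181
8	narx	1	rsp_running_rate	0.623
8	lr	1	hr_filtered	0.19
8	lr	2	exhal_depth	0.334
8	lr	3	exp_time	0.374
8	lr	4	rsp_rate	0.388
9	narx	1	rsp_running_rate	0.504
9	narx	2	inhal_depth	0.539
9	lr	1	hr_filtered	0.149
10	narx	1	hr_filtered	0.557
10	narx	2	hr_deriv	0.616
10	lr	1	gsr_running_rate	0.132
10	lr	2	rsp_rate_deriv	0.159
10	lr	3	rsp_running_rate	0.217
10	lr	4	hr_deriv	0.248
11	narx	1	inhal_depth	0.653
11	narx	2	rsp_rate_deriv	0.697
11	lr	1	hr_running_rate	0.161
11	lr	2	exhal_depth	0.251
12	narx	1	inhal_depth	0.806
12	narx	2	gsr_running_rate	0.85
12	narx	3	hr_filtered	0.866
12	lr	1	gsr_running_rate	0.351
12	lr	2	exp_time	0.379
12	lr	3	rsp_running_rate	0.406
12	lr	4	gsr_filtered	0.522
12	lr	5	gsr_deriv	0.709
13	narx	1	gsr_filtered	0.506
13	narx	2	hr_filtered	0.586
13	narx	3	exp_time	0.703
13	lr	1	gsr_running_rate	0.303
13	lr	2	hr_deriv	0.358
14	narx	1	hr_filtered	0.607
14	narx	2	rsp_rate_deriv	0.694
14	narx	3	exhal_depth	0.719
14	lr	1	gsr_running_rate	0.198
14	lr	2	hr_deriv	0.208
15	narx	1	insp_time	0.631
15	narx	2	gsr_running_rate	0.645
15	lr	1	gsr_deriv	0.16
15	lr	2	insp_time	0.171
16	narx	1	rsp_rate	0.575
16	narx	2	inhal_depth	0.665
16	narx	3	rsp_running_rate	0.726
16	lr	1	gsr_running_rate	0.218
16	lr	2	hr_deriv	0.346
17	narx	1	insp_time	0.501
17	narx	2	gsr_deriv	0.568
17	narx	3	exp_time	0.622
17	lr	1	gsr_filtered	0.232
17	lr	2	hr_filtered	0.367
17	lr	3	hr_running_rate	0.402
18	narx	1	hr_filtered	0.506
18	narx	2	exp_time	0.598
18	narx	3	rsp_running_rate	0.69
18	lr	1	insp_time	0.17
18	lr	2	hr_deriv	0.214
18	lr	3	rsp_rate_deriv	0.229
19	narx	1	hr_filtered	0.513
19	narx	2	gsr_deriv	0.63
19	narx	3	exhal_depth	0.662
19	lr	1	rsp_rate_deriv	0.128
20	narx	1	exp_time	0.475
20	narx	2	insp_time	0.632
20	lr	1	insp_time	0.097
20	lr	2	rsp_rate_deriv	0.138
21	narx	1	hr_filtered	0.542
21	narx	2	hr_running_rate	0.571
21	narx	3	rsp_rate	0.593
21	lr	1	rsp_rate	0.027
21	lr	2	rsp_rate_deriv	0.039
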
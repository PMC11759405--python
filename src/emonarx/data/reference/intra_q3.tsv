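participant	model	stage	feature	r
1	narx	1	gsr_filtered	0.465
1	narx	2	exhal_depth	0.522
1	narx	3	gsr_deriv	0.611
1	lr	1	gsr_deriv	0.0367
1	lr	2	insp_time	0.0786
1	lr	3	exp_time	0.108
1	lr	4	inhal_depth	0.127
2	narx	1	exhal_depth	0.382
2	narx	2	hr_filtered	0.457
2	narx	3	gsr_running_rate	0.492
2	lr	1	hr_filtered	0.0875
2	lr	2	gsr_deriv	0.13
2	lr	3	rsp_rate	0.178
3	narx	1	insp_time	0.511
3	narx	2	hr_deriv	0.584
3	narx	3	inhal_depth	0.616
3	lr	1	rsp_rate_deriv	0.269
3	lr	2	hr_deriv	0.307
4	narx	1	gsr_filtered	0.518
4	narx	2	gsr_running_rate	0.562
4	narx	3	hr_filtered	0.595
4	lr	1	gsr_filtered	0.258
4	lr	2	gsr_deriv	0.276
4	lr	3	exhal_depth	0.385
4	lr	4	exp_time	0.402
5	narx	1	exp_time	0.511
5	narx	2	inhal_depth	0.639
5	narx	3	hr_filtered	0.669
5	lr	1	gsr_filtered	0.108
5	lr	2	hr_running_rate	0.169
6	narx	1	hr_filtered	0.778
6	narx	2	rsp_rate	0.823
6	lr	1	insp_time	0.382
6	lr	2	rsp_running_rate	0.405
7	narx	1	hr_filtered	0.493
7	narx	2	rsp_rate	0.557
7	narx	3	rsp_rate_deriv	0.589
7	lr	1	gsr_filtered	0.42
8	narx	1	exp_time	0.576
8	narx	2	rsp_rate	0.672
8	narx	3	insp_time	0.703
8	lr	1	gsr_running_rate	0.127
8	lr	2	hr_filtered	0.187
8	lr	3	gsr_filtered	0.217
8	lr	4	gsr_deriv	0.242
9	narx	1	rsp_running_rate	0.454
9	narx	2	exp_time	0.572
9	narx	3	gsr_filtered	0.628
9	lr	1	rsp_rate	0.127
9	lr	2	exp_time	0.173
10	narx	1	hr_filtered	0.612
10	narx	2	rsp_running_rate	0.636
10	narx	3	insp_time	0.665
10	lr	1	inhal_depth	0.182
11	narx	1	rsp_rate	0.459
11	narx	2	gsr_deriv	0.5
11	narx	3	rsp_running_rate	0.511
11	lr	1	gsr_running_rate	0.234
11	lr	2	insp_time	0.311
11	lr	3	hr_deriv	0.337
12	narx	1	rsp_running_rate	0.709
12	lr	1	gsr_running_rate	0.174
12	lr	2	hr_filtered	0.198
12	lr	3	gsr_filtered	0.224
12	lr	4	exp_time	0.252
13	narx	1	inhal_depth	0.532
13	narx	2	gsr_running_rate	0.606
13	narx	3	rsp_rate	0.651
13	lr	1	hr_filtered	0.264
13	lr	2	gsr_running_rate	0.276
13	lr	3	hr_deriv	0.294
14	narx	1	gsr_filtered	0.628
14	narx	2	gsr_deriv	0.716
14	narx	3	inhal_depth	0.758
14	lr	1	hr_running_rate	0.206
14	lr	2	gsr_deriv	0.274
14	lr	3	inhal_depth	0.392
14	lr	4	gsr_filtered	0.45
15	narx	1	insp_time	0.47
15	narx	2	gsr_filtered	0.538
15	narx	3	gsr_running_rate	0.575
15	lr	1	gsr_filtered	0.262
16	narx	1	exhal_depth	0.525
16	narx	2	exp_time	0.56
16	narx	3	inhal_depth	0.575
16	lr	1	rsp_rate_deriv	0.102
16	lr	2	gsr_deriv	0.133
17	narx	1	insp_time	0.473
17	narx	2	hr_filtered	0.585
17	narx	3	rsp_running_rate	0.619
17	lr	1	hr_running_rate	0.016
17	lr	2	inhal_depth	0.077
17	lr	3	gsr_filtered	0.261
18	narx	1	gsr_running_rate	0.542
18	narx	2	insp_time	0.589
18	narx	3	exhal_depth	0.609
18	lr	1	hr_deriv	0.341
19	narx	1	rsp_rate	0.467
19	narx	2	hr_running_rate	0.49
19	narx	3	exhal_depth	0.537
19	lr	1	rsp_rate_deriv	0.182
19	lr	2	exp_time	0.204
20	narx	1	inhal_depth	0.569
20	narx	2	insp_time	0.652
20	narx	3	exp_time	0.737
20	lr	1	hr_filtered	0.304
20	lr	2	gsr_filtered	0.332
21	narx	1	hr_filtered	0.475
21	narx	2	exhal_depth	0.546
21	narx	3	exp_time	0.636
21	lr	1	hr_running_rate	0.142
21	lr	2	gsr_deriv	0.166
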
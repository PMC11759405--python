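participant	model	stage	feature	r
1	narx	1	gsr_filtered	0.598
1	narx	2	rsp_running_rate	0.634
1	narx	3	hr_deriv	0.717
1	lr	1	insp_time	0.229
1	lr	2	exp_time	0.295
2	narx	1	exp_time	0.408
2	narx	2	gsr_running_rate	0.488
2	narx	3	rsp_rate	0.516
2	lr	1	hr_filtered	0.053
3	narx	1	hr_filtered	0.713
3	narx	2	rsp_running_rate	0.739
3	narx	3	rsp_rate_deriv	0.754
3	lr	1	gsr_running_rate	0.107
3	lr	2	gsr_filtered	0.164
3	lr	3	inhal_depth	0.236
3	lr	4	hr_filtered	0.273
4	narx	1	hr_filtered	0.567
4	narx	2	exp_time	0.64
4	narx	3	hr_running_rate	0.726
4	lr	1	gsr_filtered	0.364
4	lr	2	gsr_deriv	0.432
5	narx	1	exp_time	0.684
5	narx	2	hr_running_rate	0.698
5	lr	1	rsp_rate_deriv	0.158
5	lr	2	exp_time	0.189
6	narx	1	exp_time	0.761
6	narx	2	gsr_filtered	0.786
6	lr	1	gsr_filtered	0.215
6	lr	2	hr_deriv	0.267
7	narx	1	rsp_rate	0.72
7	narx	2	rsp_rate_deriv	0.748
7	lr	1	rsp_rate_deriv	0.105
7	lr	2	rsp_running_rate	0.167
7	lr	3	rsp_rate	0.241
7	lr	4	hr_deriv	0.27
8	narx	1	gsr_filtered	0.565
8	narx	2	gsr_deriv	0.731
8	lr	1	gsr_running_rate	0.0983
8	lr	2	gsr_deriv	0.136
9	narx	1	exp_time	0.484
9	narx	2	hr_running_rate	0.664
9	narx	3	gsr_running_rate	0.717
9	lr	1	exp_time	0.102
9	lr	2	hr_deriv	0.132
9	lr	3	rsp_rate	0.184
9	lr	4	hr_filtered	0.228
9	lr	5	hr_running_rate	0.262
10	narx	1	gsr_filtered	0.521
10	narx	2	insp_time	0.601
10	narx	3	hr_running_rate	0.67
10	lr	1	gsr_running_rate	0.155
10	lr	2	gsr_filtered	0.234
10	lr	3	exhal_depth	0.264
11	narx	1	exp_time	0.533
11	narx	2	gsr_filtered	0.603
11	narx	3	exhal_depth	0.628
11	lr	1	hr_deriv	0.0911
11	lr	2	exp_time	0.132
12	narx	1	exp_time	0.651
12	lr	1	rsp_rate_deriv	0.0998
12	lr	2	rsp_rate	0.152
12	lr	3	hr_running_rate	0.186
12	lr	4	gsr_filtered	0.233
12	lr	5	exp_time	0.387
13	narx	1	exp_time	0.54
13	narx	2	gsr_running_rate	0.603
13	narx	3	rsp_rate	0.629
13	lr	1	gsr_filtered	0.246
13	lr	2	exhal_depth	0.302
13	lr	3	rsp_running_rate	0.329
13	lr	4	exp_time	0.359
14	narx	1	insp_time	0.609
14	narx	2	hr_deriv	0.635
14	narx	3	exhal_depth	0.696
14	lr	1	gsr_running_rate	0.0619
14	lr	2	exp_time	0.149
14	lr	3	hr_deriv	0.191
14	lr	4	hr_filtered	0.222
15	narx	1	gsr_filtered	0.577
15	narx	2	gsr_deriv	0.689
15	narx	3	gsr_running_rate	0.716
15	lr	1	inhal_depth	0.101
15	lr	2	rsp_rate	0.136
16	narx	1	gsr_running_rate	0.491
16	narx	2	hr_filtered	0.584
16	narx	3	exp_time	0.634
16	lr	1	gsr_filtered	0.437
16	lr	2	exp_time	0.528
17	narx	1	insp_time	0.628
17	narx	2	gsr_deriv	0.706
17	narx	3	hr_filtered	0.76
17	lr	1	exp_time	0.123
17	lr	2	hr_running_rate	0.149
18	narx	1	hr_filtered	0.559
18	narx	2	exp_time	0.699
18	narx	3	insp_time	0.759
18	lr	1	hr_filtered	0.172
19	narx	1	exp_time	0.654
19	narx	2	insp_time	0.747
19	narx	3	rsp_running_rate	0.761
19	lr	1	insp_time	0.203
19	lr	2	hr_running_rate	0.283
20	narx	1	exhal_depth	0.513
20	narx	2	gsr_filtered	0.562
20	narx	3	rsp_running_rate	0.583
20	lr	1	hr_filtered	0.096
21	narx	1	inhal_depth	0.477
21	lr	1	gsr_running_rate	0.32
21	lr	2	insp_time	0.382
21	lr	3	exhal_depth	0.412
21	lr	4	hr_running_rate	0.459
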
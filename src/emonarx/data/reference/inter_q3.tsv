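repeat	model	features	train	test	params	mean_r
1	narx	hr_filtered+rsp_rate+exp_time	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	4 10 9 1 8 6 5	0.62
1	narx	hr_filtered+rsp_rate+inhal_depth	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	8 9 11 4 2 9 9	0.61
1	narx	hr_filtered+rsp_rate+exhal_depth	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	5 11 11 2 8 4 10	0.625
1	narx	hr_filtered+exp_time+inhal_depth	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	4 10 11 4 5 6 11	0.608
1	narx	hr_filtered+exp_time+exhal_depth	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	4 11 10 7 2 2 9	0.602
1	narx	hr_filtered+inhal_depth+exhal_depth	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18	9 8 9 5 3 1 3	0.606
1	lr	gsr_filtered+gsr_deriv	2 5 6 7 8 9 12 14 15 16 17 19 20 21	1 3 4 10 11 13 18		-0.0174
2	narx	hr_filtered+rsp_rate+exp_time	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	8 8 10 7 11 6 4	0.547
2	narx	hr_filtered+rsp_rate+inhal_depth	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	7 9 8 6 8 10 8	0.567
2	narx	hr_filtered+rsp_rate+exhal_depth	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	8 9 9 1 10 9 10	0.532
2	narx	hr_filtered+exp_time+inhal_depth	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	9 8 9 10 2 5 6	0.547
2	narx	hr_filtered+exp_time+exhal_depth	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	8 9 10 4 7 1 1	0.552
2	narx	hr_filtered+inhal_depth+exhal_depth	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21	11 9 8 5 1 4 7	0.557
2	lr	gsr_filtered+gsr_deriv	1 2 3 4 5 6 7 8 10 12 14 15 16 18	9 11 13 17 19 20 21		0.0184
3	narx	hr_filtered+rsp_rate+exp_time	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	4 10 11 4 5 10 2	0.591
3	narx	hr_filtered+rsp_rate+inhal_depth	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	7 11 11 2 4 10 1	0.59
3	narx	hr_filtered+rsp_rate+exhal_depth	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	10 10 10 1 5 1 3	0.586
3	narx	hr_filtered+exp_time+inhal_depth	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	8 11 11 3 3 7 2	0.612
3	narx	hr_filtered+exp_time+exhal_depth	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	4 11 11 11 6 4 9	0.614
3	narx	hr_filtered+inhal_depth+exhal_depth	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16	8 11 11 4 3 2 7	0.595
3	lr	gsr_filtered+gsr_deriv	1 2 3 5 7 8 9 10 14 17 18 19 20 21	4 6 11 12 13 15 16		-0.00705
4	narx	hr_filtered+rsp_rate+exp_time	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	7 11 11 1 9 11 7	0.645
4	narx	hr_filtered+rsp_rate+inhal_depth	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	10 9 9 2 4 3 4	0.622
4	narx	hr_filtered+rsp_rate+exhal_depth	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	8 9 10 2 7 4 7	0.63
4	narx	hr_filtered+exp_time+inhal_depth	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	10 9 11 6 1 3 8	0.634
4	narx	hr_filtered+exp_time+exhal_depth	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	9 9 11 10 10 5 2	0.634
4	narx	hr_filtered+inhal_depth+exhal_depth	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21	8 11 11 1 11 7 10	0.642
4	lr	gsr_filtered+gsr_deriv	1 2 3 4 5 9 10 12 13 15 16 17 18 19	6 7 8 11 14 20 21		0.00624
5	narx	hr_filtered+rsp_rate+exp_time	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	5 9 9 9 6 6 6	0.583
5	narx	hr_filtered+rsp_rate+inhal_depth	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	10 9 9 10 8 5 10	0.572
5	narx	hr_filtered+rsp_rate+exhal_depth	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	5 10 11 8 1 9 2	0.571
5	narx	hr_filtered+exp_time+inhal_depth	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	8 9 9 5 5 3 6	0.582
5	narx	hr_filtered+exp_time+exhal_depth	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	5 10 10 9 3 4 3	0.568
5	narx	hr_filtered+inhal_depth+exhal_depth	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21	7 11 11 5 2 2 7	0.562
5	lr	gsr_filtered+gsr_deriv	1 2 3 4 6 7 8 12 13 14 16 18 19 20	5 9 10 11 15 17 21		-0.0175
6	narx	hr_filtered+rsp_rate+exp_time	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	10 10 10 1 7 4 3	0.572
6	narx	hr_filtered+rsp_rate+inhal_depth	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	9 9 10 3 2 7 4	0.574
6	narx	hr_filtered+rsp_rate+exhal_depth	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	8 8 11 2 6 9 9	0.57
6	narx	hr_filtered+exp_time+inhal_depth	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	9 10 10 4 5 9 10	0.57
6	narx	hr_filtered+exp_time+exhal_depth	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	9 9 11 6 3 10 9	0.565
6	narx	hr_filtered+inhal_depth+exhal_depth	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18	10 10 11 7 9 6 2	0.574
6	lr	gsr_filtered+gsr_deriv	1 4 5 6 7 8 9 12 13 15 16 19 20 21	2 3 10 11 14 17 18		-0.00669
7	narx	hr_filtered+rsp_rate+exp_time	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	4 11 9 9 6 8 8	0.542
7	narx	hr_filtered+rsp_rate+inhal_depth	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	6 10 11 2 9 3 9	0.548
7	narx	hr_filtered+rsp_rate+exhal_depth	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	11 8 10 2 8 8 9	0.549
7	narx	hr_filtered+exp_time+inhal_depth	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	4 10 10 8 4 3 7	0.578
7	narx	hr_filtered+exp_time+exhal_depth	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	3 11 9 9 1 11 8	0.584
7	narx	hr_filtered+inhal_depth+exhal_depth	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21	6 7 10 7 8 6 4	0.565
7	lr	gsr_filtered+gsr_deriv	1 2 4 6 7 8 9 10 11 13 14 18 19 20	3 5 12 15 16 17 21		0.00406
8	narx	hr_filtered+rsp_rate+exp_time	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	6 11 11 5 10 11 6	0.609
8	narx	hr_filtered+rsp_rate+inhal_depth	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	8 11 11 1 9 5 3	0.613
8	narx	hr_filtered+rsp_rate+exhal_depth	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	8 11 11 1 1 5 4	0.617
8	narx	hr_filtered+exp_time+inhal_depth	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	4 11 11 10 8 11 2	0.606
8	narx	hr_filtered+exp_time+exhal_depth	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	6 10 11 10 4 3 8	0.614
8	narx	hr_filtered+inhal_depth+exhal_depth	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20	8 11 11 3 7 4 2	0.616
8	lr	gsr_filtered+gsr_deriv	1 4 5 6 7 8 9 10 11 13 16 18 19 21	2 3 12 14 15 17 20		0.0322
9	narx	hr_filtered+rsp_rate+exp_time	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	5 10 10 1 6 9 2	0.607
9	narx	hr_filtered+rsp_rate+inhal_depth	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	5 10 8 5 8 10 6	0.575
9	narx	hr_filtered+rsp_rate+exhal_depth	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	8 9 9 8 10 1 7	0.58
9	narx	hr_filtered+exp_time+inhal_depth	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	1 10 7 10 5 1 10	0.63
9	narx	hr_filtered+exp_time+exhal_depth	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	1 8 9 9 6 4 6	0.603
9	narx	hr_filtered+inhal_depth+exhal_depth	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18	7 9 8 10 7 3 10	0.586
9	lr	gsr_filtered+gsr_deriv	1 2 3 4 6 7 9 13 14 15 17 19 20 21	5 8 10 11 12 16 18		0.023
10	narx	hr_filtered+rsp_rate+exp_time	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	3 11 9 10 11 11 2	0.598
10	narx	hr_filtered+rsp_rate+inhal_depth	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	7 9 9 2 6 3 4	0.589
10	narx	hr_filtered+rsp_rate+exhal_depth	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	6 11 10 2 2 3 4	0.588
10	narx	hr_filtered+exp_time+inhal_depth	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	5 10 11 8 3 7 11	0.598
10	narx	hr_filtered+exp_time+exhal_depth	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	5 11 11 11 2 9 11	0.599
10	narx	hr_filtered+inhal_depth+exhal_depth	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20	6 8 10 6 3 7 8	0.578
10	lr	gsr_filtered+gsr_deriv	2 5 6 7 8 9 10 11 13 14 17 18 19 21	1 3 4 12 15 16 20		-0.0194
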
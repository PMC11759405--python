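repeat	model	features	train	test	params	mean_r
1	narx	hr_filtered	1 2 3 5 6 7 8 11 14 15 16 17 19 21	4 9 10 12 13 18 20	7 8 11	0.572
1	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 2 3 5 6 7 8 11 14 15 16 17 19 21	4 9 10 12 13 18 20		0.0218
2	narx	hr_filtered	1 3 4 5 6 7 10 12 14 15 17 18 20 21	2 8 9 11 13 16 19	8 11 9	0.516
2	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 3 4 5 6 7 10 12 14 15 17 18 20 21	2 8 9 11 13 16 19		-0.0128
3	narx	hr_filtered	2 3 4 5 6 7 8 9 11 14 15 16 17 19	1 10 12 13 18 20 21	4 7 11	0.592
3	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	2 3 4 5 6 7 8 9 11 14 15 16 17 19	1 10 12 13 18 20 21		-0.00853
4	narx	hr_filtered	1 4 5 8 9 10 11 12 13 15 16 17 19 21	2 3 6 7 14 18 20	3 9 8	0.551
4	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 4 5 8 9 10 11 12 13 15 16 17 19 21	2 3 6 7 14 18 20		-0.00657
5	narx	hr_filtered	2 3 6 8 10 12 13 14 15 16 17 18 19 20	1 4 5 7 9 11 21	3 9 9	0.516
5	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	2 3 6 8 10 12 13 14 15 16 17 18 19 20	1 4 5 7 9 11 21		-0.0147
6	narx	hr_filtered	1 2 4 6 9 10 12 13 14 15 16 17 18 19	3 5 7 8 11 20 21	11 8 11	0.486
6	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 2 4 6 9 10 12 13 14 15 16 17 18 19	3 5 7 8 11 20 21		-0.0154
7	narx	hr_filtered	1 2 3 4 5 7 8 10 11 12 13 14 16 21	6 9 15 17 18 19 20	11 9 11	0.579
7	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 2 3 4 5 7 8 10 11 12 13 14 16 21	6 9 15 17 18 19 20		0.0102
8	narx	hr_filtered	1 2 3 7 8 9 10 11 13 14 15 17 18 21	4 5 6 12 16 19 20	11 11 10	0.596
8	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 2 3 7 8 9 10 11 13 14 15 17 18 21	4 5 6 12 16 19 20		-0.00858
9	narx	hr_filtered	1 4 5 6 9 10 12 13 16 17 18 19 20 21	2 3 7 8 11 14 15	3 6 11	0.528
9	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 4 5 6 9 10 12 13 16 17 18 19 20 21	2 3 7 8 11 14 15		0.0212
10	narx	hr_filtered	1 2 3 4 8 9 10 11 15 16 18 19 20 21	5 6 7 12 13 14 17	9 11 10	0.61
10	lr	gsr_running_rate+hr_deriv+rsp_rate_deriv	1 2 3 4 8 9 10 11 15 16 18 19 20 21	5 6 7 12 13 14 17		0.00742
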
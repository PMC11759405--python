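repeat	model	features	train	test	params	mean_r
1	narx	gsr_filtered+exp_time	1 2 3 5 6 7 8 11 14 15 16 17 19 21	4 9 10 12 13 18 20	2 2 3 3 8	0.505
1	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 5 6 7 8 11 14 15 16 17 19 21	4 9 10 12 13 18 20		-0.0174
2	narx	gsr_filtered+exp_time	1 2 3 4 5 8 9 10 12 14 16 18 20 21	6 7 11 13 15 17 19	7 10 4 8 8	0.47
2	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 4 5 8 9 10 12 14 16 18 20 21	6 7 11 13 15 17 19		-0.0244
3	narx	gsr_filtered+exp_time	1 2 4 5 6 9 11 14 15 17 18 19 20 21	3 7 8 10 12 13 16	8 7 5 11 5	0.416
3	lr	gsr_filtered+hr_filtered+exp_time	1 2 4 5 6 9 11 14 15 17 18 19 20 21	3 7 8 10 12 13 16		-0.0431
4	narx	gsr_filtered+exp_time	1 2 3 4 5 6 8 10 11 12 16 18 19 21	7 9 13 14 15 17 20	8 5 9 10 6	0.501
4	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 4 5 6 8 10 11 12 16 18 19 21	7 9 13 14 15 17 20		-0.0162
5	narx	gsr_filtered+exp_time	1 2 3 10 11 12 13 14 15 16 18 19 20 21	4 5 6 7 8 9 17	3 2 10 5 8	0.495
5	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 10 11 12 13 14 15 16 18 19 20 21	4 5 6 7 8 9 17		-0.00795
6	narx	gsr_filtered+exp_time	2 3 4 5 7 8 10 11 12 16 17 18 20 21	1 6 9 13 14 15 19	6 4 10 8 8	0.541
6	lr	gsr_filtered+hr_filtered+exp_time	2 3 4 5 7 8 10 11 12 16 17 18 20 21	1 6 9 13 14 15 19		0.0121
7	narx	gsr_filtered+exp_time	1 2 3 4 5 7 8 9 15 16 17 19 20 21	6 10 11 12 13 14 18	4 6 7 11 5	0.448
7	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 4 5 7 8 9 15 16 17 19 20 21	6 10 11 12 13 14 18		-0.00439
8	narx	gsr_filtered+exp_time	1 2 3 4 5 6 7 10 12 13 15 16 18 19	8 9 11 14 17 20 21	10 11 5 7 6	0.369
8	lr	gsr_filtered+hr_filtered+exp_time	1 2 3 4 5 6 7 10 12 13 15 16 18 19	8 9 11 14 17 20 21		-0.00228
9	narx	gsr_filtered+exp_time	2 3 4 5 6 7 9 10 12 14 16 18 20 21	1 8 11 13 15 17 19	1 11 11 2 10	0.627
9	lr	gsr_filtered+hr_filtered+exp_time	2 3 4 5 6 7 9 10 12 14 16 18 20 21	1 8 11 13 15 17 19		0.0139
10	narx	gsr_filtered+exp_time	2 3 4 6 7 8 9 10 11 13 14 19 20 21	1 5 12 15 16 17 18	10 9 7 9 5	0.491
10	lr	gsr_filtered+hr_filtered+exp_time	2 3 4 6 7 8 9 10 11 13 14 19 20 21	1 5 12 15 16 17 18		-0.00756
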
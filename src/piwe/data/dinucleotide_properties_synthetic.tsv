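tuple	property	value
AA	Twist	35.9088
AC	Twist	34.6145
AG	Twist	32.6545
AT	Twist	37.2571
CA	Twist	33.9805
CC	Twist	32.7512
CG	Twist	27.0282
CT	Twist	35.6531
GA	Twist	31.2256
GC	Twist	32.3115
GG	Twist	37.2629
GT	Twist	33.3973
TA	Twist	36.5474
TC	Twist	36.9419
TG	Twist	34.8703
TT	Twist	31.9356
AA	Tilt	0.2545
AC	Tilt	-2.3251
AG	Tilt	0.7906
AT	Tilt	-3.4723
CA	Tilt	2.8923
CC	Tilt	0.9795
CG	Tilt	0.4880
CT	Tilt	-2.1000
GA	Tilt	0.3124
GC	Tilt	-1.6158
GG	Tilt	-0.4926
GT	Tilt	2.7598
TA	Tilt	1.7908
TC	Tilt	-0.8865
TG	Tilt	3.0383
TT	Tilt	-0.4933
AA	Roll	0.2985
AC	Roll	-0.5093
AG	Roll	1.6736
AT	Roll	3.1574
CA	Roll	3.8203
CC	Roll	1.2247
CG	Roll	5.6540
CT	Roll	-1.5220
GA	Roll	4.7002
GC	Roll	-0.8273
GG	Roll	3.7124
GT	Roll	-7.4121
TA	Roll	4.7192
TC	Roll	0.8161
TG	Roll	1.0128
TT	Roll	-0.1067
AA	Shift	0.0639
AC	Shift	0.8279
AG	Shift	-0.1451
AT	Shift	-0.4349
CA	Shift	-0.4581
CC	Shift	-0.0791
CG	Shift	-0.6210
CT	Shift	-0.0313
GA	Shift	-0.5968
GC	Shift	-0.4115
GG	Shift	0.5959
GT	Shift	0.5567
TA	Shift	-0.0738
TC	Shift	0.1722
TG	Shift	-1.0845
TT	Shift	0.1808
AA	Slide	-0.3979
AC	Slide	0.6409
AG	Slide	-0.2076
AT	Slide	-0.5583
CA	Slide	-0.2666
CC	Slide	0.3212
CG	Slide	-1.3158
CT	Slide	0.7591
GA	Slide	-1.2648
GC	Slide	-0.1482
GG	Slide	-0.9879
GT	Slide	-0.2428
TA	Slide	-0.1372
TC	Slide	-0.0435
TG	Slide	0.0921
TT	Slide	-0.6185
AA	Rise	3.1593
AC	Rise	3.4467
AG	Rise	3.2380
AT	Rise	3.1663
CA	Rise	3.1735
CC	Rise	3.6054
CG	Rise	3.4060
CT	Rise	3.5144
GA	Rise	3.3908
GC	Rise	3.2232
GG	Rise	3.3181
GT	Rise	3.7081
TA	Rise	3.2012
TC	Rise	3.4238
TG	Rise	3.0168
TT	Rise	3.0426
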
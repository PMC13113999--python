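assay	ratio	conc_caa	conc_cha	scavenging_pct
DPPH	1:2	12.5	25	7.14
DPPH	1:2	25	50	13.35
DPPH	1:2	50	100	23.72
DPPH	1:2	100	200	48.58
DPPH	1:2	150	300	70.09
DPPH	1:1	12.5	12.5	19.51
DPPH	1:1	25	25	26.38
DPPH	1:1	50	50	41.46
DPPH	1:1	100	100	66.86
DPPH	1:1	150	150	90.23
DPPH	2:1	25	12.5	8.08
DPPH	2:1	50	25	13.35
DPPH	2:1	100	50	23.78
DPPH	2:1	200	100	44.65
DPPH	2:1	300	150	66.76
ABTS	1:2	2.5	5	3.53
ABTS	1:2	5	10	8.88
ABTS	1:2	10	20	16.00
ABTS	1:2	20	40	33.09
ABTS	1:2	30	60	49.36
ABTS	1:1	2.5	2.5	4.66
ABTS	1:1	5	5	11.53
ABTS	1:1	10	10	23.12
ABTS	1:1	20	20	46.29
ABTS	1:1	30	30	69.28
ABTS	2:1	5	2.5	3.92
ABTS	2:1	10	5	7.56
ABTS	2:1	20	10	17.67
ABTS	2:1	40	20	35.70
ABTS	2:1	60	30	53.86
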
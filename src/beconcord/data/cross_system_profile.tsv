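gene	class	human	het1a	epc2	rat
KRT1	squamous	down	na	down	up
KRT4	squamous	down	na	down	down
KRT5	squamous	down	na	down	up
KRT6	squamous	down	no_change	down	nd
KRT13	squamous	down	na	down	down
KRT14	squamous	down	na	down	up
KRT15	squamous	down	down	down	down
KRT16	squamous	down	no_change	down	na
KRT23	squamous	down	na	down	no_change
KRT24	squamous	down	na	down	na
KRT7	columnar	up	no_change	up	up
KRT8	columnar	up	up	no_change	up
KRT18	columnar	up	no_change	up	up
KRT20	columnar	up	na	na	up
TFF1	columnar	up	na	na	down
TFF2	columnar	up	na	na	na
TFF3	columnar	up	up	up	up
VIL1	columnar	up	up	na	no_change
MUC2	columnar	up	up	na	up
MUC3A/B	columnar	up	na	na	na
MUC5B	columnar	up	na	na	na
MUC6	columnar	up	na	na	na
MUC13	columnar	up	up	no_change	up
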
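cell_line	subtype
AU565	Lu
BT549	BaB
HCC1569	BaA
HCC1937	BaA
HCC1143	BaA
HCC1428	Lu
HCC202	Lu
MDAMB436	BaB
SUM185PE	Lu
600MPE	Lu
HCC1500	BaB
MDAMB231	BaB
SUM225CWN	BaA
SKBR3	Lu
MDAMB453	Lu
SUM1315MO2	BaB
SUM52PE	Lu
HSS78T	BaB
MCF12A	BaB
MDAMB157VII	Lu
HCC70	BaA
HCC1954	BaA
SUM149PT	BaB
GCC2185	Lu
LY2	Lu
MCF7	Lu
BT20	BaA
MCF10A	BaB
BT474	Lu
SUM159PT	BaB
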
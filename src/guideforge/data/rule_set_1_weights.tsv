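feature	position	weight
Intercept	-1	0.59763615
gc_low	-1	-0.2026259
gc_high	-1	-0.1665878
G	1	-0.2753771
A	2	-0.3238875
C	2	0.17212887
C	3	-0.1006662
C	4	-0.2018029
G	4	0.24595663
A	5	0.03644004
C	5	0.09837684
C	6	-0.7411813
G	6	-0.3932644
A	11	-0.466099
A	14	0.08537695
C	14	-0.013814
A	15	0.27262051
C	15	-0.1190226
T	15	-0.2859442
A	16	0.09745459
G	16	-0.1755462
C	17	-0.3457955
G	17	-0.6780964
A	18	0.22508903
C	18	-0.5077941
G	19	-0.4173736
T	19	-0.054307
G	20	0.37989937
T	20	-0.0907126
C	21	0.05782332
T	21	-0.5305673
T	22	-0.8770074
C	23	-0.8762358
G	23	0.27891626
T	23	-0.4031022
A	24	-0.0773007
C	24	0.28793562
T	24	-0.2216372
G	27	-0.6890167
T	27	0.11787758
C	28	-0.1604453
G	29	0.38634258
GT	1	-0.6257787
GC	4	0.30004332
AA	5	-0.8348362
TA	5	0.76062777
GG	6	-0.4908167
GG	11	-1.5169074
TA	11	0.7092612
TC	11	0.49629861
TT	11	-0.5868739
GG	12	-0.3345637
GA	13	0.76384993
GC	13	-0.5370252
TG	16	-0.7981461
GG	18	-0.6668087
TC	18	0.35318325
CC	19	0.74807209
TG	19	-0.36727187
AC	20	0.56820913
CG	20	0.32907207
GA	20	-0.8364568
GG	20	-0.7822076
TC	21	-1.029693
CG	22	0.85619782
CT	22	-0.4632077
AA	23	-0.5794924
AG	23	0.64907554
AG	24	-0.0773007
CG	24	0.27891626
TG	24	-0.4031022
GT	26	0.11787758
GG	28	-0.69774
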
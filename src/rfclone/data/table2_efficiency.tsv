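gene	gene_id	length_bp	vector	checked	positive	genome_start	genome_end
yaiS	946967	558	pET22b	8	7
ybaY	945070	574	pET22b	8	8
nfnB	945778	654	pET22b	8	6
yohK	949125	696	pET22b	8	8
rlmB	948694	732	pET22b	8	8
nhoA	947251	846	pET22b	8	7
dapA	946952	879	pET22b	8	8
deoC	948902	780	pET22b	8	6
deoA	948901	1230	pET22b	8	5
deoB	948910	1224	pET22b	8	8
deoD	945654	721	pET22b	8	7
yjjJ	944883	1332	pET22b	8	8
lplA	944865	1017	pET22b	8	8
ytjB	946089	645	pET22b	8	7
serB	948913	969	pET22b	8	8
radA	948912	1383	pET22b	8	7
yhdP	2847740	3801	pET22b	8	4
yjjK	948909	1668	pET22b	8	8
slt	948908	1938	pET22b	8	8
yjiQ	948866	561	pET22b	8	6
yjiR	949089	1413	pET22b	8	8
yjiS	948903	165	pET22b	8	8
yjiT	945056	1503	pET22b	8	6
yjiV	2847669	2937	pET22b	8	7
mcrC	948880	1047	pET22b	8	8
mcrB	949122	1380	pET22b	8	6
yjiW	7157066	399	pET22b	8	8
hsdS	948867	1395	pET22b	8	8
hsdM	948872	1590	pET22b	8	8
hsdR	948878	3513	pET22b	8	5
mrr	948898	915	pET22b	8	8
yjiA	948882	957	pET22b	8	8
recB	947286	3543	pET22b	8	5
yjiY	948914	2151	pET22b	8	8
tsr	948884	1656	pET22b	8	8
yjiZ	948879	1362	pET22b	8	7
yjjM	7159433	915	pET22b	8	8
yjjN	7159438	1023	pET22b	8	8
mdoB	7159439	2292	pET22b	8	4
yeeJ	946498	7077	pET22b	8	6
gasT	2520	306	pcDNA3.1	8	8
mcm6	4175	2466	pcDNA3.1	8	6
slc18a2	6571	1545	pcDNA3.1	8	7
Gene cluster 1		10000	pET22b	8	5
Gene cluster 2		15000	pET22b	8	6
Gene cluster 3		20000	pET22b	8	4	200485	220925
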
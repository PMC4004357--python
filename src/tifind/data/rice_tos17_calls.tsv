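row	by_tif	by_relocate	line	chrom	tail_junction	head_junction	tsd_size	tsd_tail	tsd_head	direction	confirmed
1	yes	yes	ttm2	chr04	30259052	30259056	5	GTTTC	GTTTC	forward	yes
2	yes	yes	ttm2	chr05	1925905	1925909	5	CTATC	CTATC	forward	yes
3	yes	yes	ttm2	chr10	22134718	22134714	5	CTTGC	CTTGC	reverse	yes
4	yes	yes	ttm2	chr10	22531003	22531007	5	ACTTT	ACTTT	forward	yes
5	yes	no	ttm5	chr01	34453645	34453641	5	CTTTG	CTTTG	reverse	yes
6	yes	yes	ttm5	chr02	1004769	1004765	5	ATACC	ATACC	reverse	yes
7	yes	yes	ttm5	chr02	31596628	31596632	5	CTAAT	CTAAT	forward	yes
8	yes	yes	ttm5	chr03	741226	741222	5	GCTGC	GCTGC	reverse	yes
9	yes	yes	ttm5	chr03	8304678	8304674	5	GAATA	GAATA	reverse	yes
10	yes	no	ttm5	chr06	24967881	24967877	5	TGCAT	TGCAT	reverse	yes
11	yes	no	ttm5	chr07	20064391	20064395	5	CTTAT	CTTAT	forward	yes
11	yes	no	ttm5	chr07	20080552	20080556	5	CTTAT	CTTAT	forward	yes
12	yes	yes	ttm5	chr09	12970618	12970614	5	CATGC	CATGC	reverse	yes
13	no	yes	ttm5	chr10	14739090	14739094	5	-	GAACT	forward	no
14	yes	no	ttm5	chr10	19069885	19069889	5	ACTTG	ACTTG	forward	yes
15	yes	yes	ttm5	chr10	21583054	21583058	5	CTTAT	CTTAT	forward	yes
16	yes	yes	ttm5	chr12	2155899	2155895	5	GGAAC	GGAAC	reverse	yes
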
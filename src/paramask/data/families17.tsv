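# Curated 17-family PCD cohort: variant-level evidence for a gene shadowed
# by a high-identity pseudogene.  One row per variant call; stage records
# whether the allele was resolved by masked short reads (SR) or required the
# long-read stage (LR).  A pseudogene-assigned row never counts toward the
# diagnosis.  The gene-assigned rows span 25 distinct cDNA descriptions even
# though the source accounting tallied 24 "different" variants; the rows are
# preserved as reported rather than reconciled.
family	allele	cdna	protein	acmg	zygosity	stage	locus	phase
1	1,2	c.15037_15048delinsGATGATATA	p.(Tyr5013_Pro5016delinsAspAspIle)	LP	hom	SR	gene	homozygous
2	1,2	c.15037_15048delinsGATGATATA	p.(Tyr5013_Pro5016delinsAspAspIle)	LP	hom	SR	gene	homozygous
3	1	c.8487_8489delinsCA	p.(Pro2830HisfsTer23)	LP	het	SR	gene	trans
3	2	c.1529del	p.(Phe510SerfsTer43)	P	het	SR	gene	trans
4	1	c.1529del	p.(Phe510SerfsTer43)	P	het	SR	gene	trans
4	2	c.6669+1G>A	p.?	LP	het	SR	gene	trans
5	1	c.1949G>A	p.(Arg650His)	VUS	het	SR	gene	trans
5	2	c.3640A>G	p.(Ile1214Val)	VUS	het	SR	gene	trans
6	1	c.10886_10902del	p.(Asp3629ValfsTer9)	LP	het	SR	gene	trans
6	2	c.14157T>G	p.(Tyr4719Ter)	LP	het	SR	gene	trans
7	1	c.3252dup	p.(Val1085ArgfsTer15)	P	het	SR	gene	trans
7	2	c.1670G>C	p.(Arg557Thr)	LP	het	SR	gene	trans
8	1,2	c.12444-1G>A	p.?	LP	hom	SR	gene	homozygous
9	1,2	c.10012G>T	p.(Glu338Ter)	P	hom	SR	gene	homozygous
10	1	c.283C>T	p.(Gln95Ter)	LP	het	SR	gene	trans
10	2	c.13680-3A>G	p.?	VUS	het	SR	gene	trans
11	1	c.2419_2422del	p.(Val807IlefsTer13)	LP	het	SR	gene	trans
11	2	c.5620-311_5788+1198del	p.?	LP	het	LR	gene	trans
12	1	c.6669+1G>A	p.?	LP	het	SR	gene	trans
12	2	c.5789-39A>G	p.?	VUS	het	SR	gene	trans
13	1	c.1095del	p.(Phe365LeufsTer64)	LP	het	SR	gene	trans
13	2	c.2376+752_2529+9004del	p.?	LP	het	LR	gene	trans
14	1	c.1147C>T	p.(Arg383Ter)	P	het	SR	gene	trans
14	2	c.4888A>T	p.(Lys1630Ter)	P	het	SR	gene	trans
15	1	c.12144dup	p.(Thr4049HisfsTer9)	LP	het	SR	gene	trans
15	2	c.2702G>T	p.(Gly901Val)	VUS	het	SR	gene	trans
16	1,2	c.7214_7215del	p.(Ser2405CysfsTer2)	LP	hom	SR	gene	homozygous
16	-	c.7956dup	p.(Glu2653ArgfsTer26)	LP	het	SR	pseudo	homozygous
17	1,2	c.13709del	p.(Pro4570LeufsTer22)	P	hom	SR	gene	homozygous
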
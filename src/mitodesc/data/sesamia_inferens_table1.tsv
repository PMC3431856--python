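# Annotation table of the Sesamia inferens mitogenome (GenBank JN039362),
# transcribed from the published description. Coordinates are 1-based closed.
# size_printed and spacer_printed carry the published "Size (bp)" and
# "Intergenic spacer" columns verbatim; they are reference values for QC,
# not inputs to any computation.
# length=15413
name	category	strand	start	end	size_printed	spacer_printed	anticodon	anticodon_start	anticodon_end	start_codon	stop_codon
trnM	tRNA	F	1	68	68	0	CAT	32	34	.	.
trnI	tRNA	F	69	133	65	-3	GAT	98	100	.	.
trnQ	tRNA	R	131	199	69	68	TTG	167	169	.	.
nad2	PCG	F	268	1284	1017	6	.	.	.	ATT	TAA
trnW	tRNA	F	1291	1358	68	-8	TCA	1322	1324	.	.
trnC	tRNA	R	1351	1423	73	4	GCA	1391	1393	.	.
trnY	tRNA	R	1428	1494	67	5	GTA	1460	1462	.	.
cox1	PCG	F	1500	3030	1531	3	.	.	.	CGA	T
trnL2	tRNA	F	3034	3100	67	0	TAA	3064	3066	.	.
cox2	PCG	F	3101	3782	682	0	.	.	.	ATT	T
trnK	tRNA	F	3783	3853	71	0	CTT	3813	3815	.	.
trnD	tRNA	F	3854	3919	66	0	GTC	3884	3886	.	.
atp8	PCG	F	3920	4087	168	-11	.	.	.	ATT	TAA
atp6	PCG	F	4077	4754	696	-1	.	.	.	ATG	TAA
cox3	PCG	F	4754	5542	789	2	.	.	.	ATG	TAA
trnG	tRNA	F	5545	5609	65	0	TCC	5575	5577	.	.
nad3	PCG	F	5610	5963	354	16	.	.	.	ATT	TAA
trnA	tRNA	F	5980	6048	69	2	TGC	6010	6012	.	.
trnR	tRNA	F	6051	6114	64	9	TCG	6078	6080	.	.
trnN	tRNA	F	6124	6188	65	2	GTT	6154	6156	.	.
trnS1	tRNA	F	6191	6256	66	0	GCT	6216	6218	.	.
trnE	tRNA	F	6257	6324	68	8	TTC	6287	6289	.	.
trnF	tRNA	R	6333	6399	67	-1	GAA	6364	6366	.	.
nad5	PCG	R	6399	8150	1752	0	.	.	.	ATT	TAA
trnH	tRNA	R	8151	8215	65	0	GTG	8183	8185	.	.
nad4	PCG	R	8216	9554	1339	44	.	.	.	ATG	T
nad4L	PCG	R	9599	9892	294	7	.	.	.	ATG	TAA
trnT	tRNA	F	9900	9969	70	0	TGT	9929	9931	.	.
trnP	tRNA	R	9970	10034	65	7	TGG	10002	10004	.	.
nad6	PCG	F	10042	10575	534	44	.	.	.	ATC	TAA
cob	PCG	F	10620	11768	1149	1	.	.	.	ATG	TAA
trnS2	tRNA	F	11770	11836	67	18	TGA	11802	11804	.	.
nad1	PCG	R	11855	12799	945	1	.	.	.	ATG	TAA
trnL1	tRNA	R	12801	12867	67	-1	TAG	12836	12838	.	.
rrnL	rRNA	R	12867	14251	1385	0	.	.	.	.	.
trnV	tRNA	R	14253	14318	66	0	TAC	14284	14286	.	.
rrnS	rRNA	R	14319	15102	784	0	.	.	.	.	.
AT_rich	control	F	15103	15413	311	0	.	.	.	.	.
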
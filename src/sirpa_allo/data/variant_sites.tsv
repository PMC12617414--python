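# SIRPA IgV-domain (exon 3) variant map, GRCh37/hg19 coordinates, forward strand.
# 15 SNPs + 1 deletion. SYNTHETIC STAND-IN: the rsID list is the published one,
# but positions and ref/alt alleles are placeholders pending transcription of
# the published per-haplotype allele table; replace this file to use real data.
# Which rsID is the deletion is configurable; rs561231326 is marked here.
site_id	chrom	position	ref	alt	site_type
rs555038801	20	1895100	A	G	SNP
rs755247899	20	1895112	C	T	SNP
rs143735290	20	1895131	G	A	SNP
rs17855609	20	1895140	C	G	SNP
rs17855610	20	1895158	T	C	SNP
rs17855611	20	1895171	A	C	SNP
rs17855612	20	1895183	G	T	SNP
rs1057114	20	1895197	A	G	SNP
rs138283486	20	1895210	C	A	SNP
rs149634649	20	1895224	G	C	SNP
rs386811662	20	1895236	T	G	SNP
rs17855615	20	1895251	C	A	SNP
rs17855616	20	1895266	A	T	SNP
rs139878822	20	1895278	G	A	SNP
rs114499682	20	1895290	T	A	SNP
rs561231326	20	1895305	CTG	-	DELETION
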
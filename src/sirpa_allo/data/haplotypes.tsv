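# SYNTHETIC STAND-IN haplotype panel for the five named SIRPA IgV alleles.
# Constructed so that V1 and V2 differ at 7 sites, V9/NV1/NV2 lie within
# Hamming distance 2 of V1 (the published new variants resemble V1), and the
# V1/V9 heterozygote is Sanger-ambiguous (also consistent with NV1/NV2).
# Replace together with variant_sites.tsv to use the real allele assignments.
name	rs555038801	rs755247899	rs143735290	rs17855609	rs17855610	rs17855611	rs17855612	rs1057114	rs138283486	rs149634649	rs386811662	rs17855615	rs17855616	rs139878822	rs114499682	rs561231326
V1	A	C	G	C	T	A	G	A	C	G	T	C	A	G	T	CTG
V2	A	C	A	G	C	C	T	G	C	G	T	C	A	G	T	-
V9	A	C	A	G	T	A	G	A	C	G	T	C	A	G	T	CTG
NV1	A	C	A	C	T	A	G	A	C	G	T	C	A	G	T	CTG
NV2	A	C	G	G	T	A	G	A	C	G	T	C	A	G	T	CTG
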
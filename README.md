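# sirpa-allo

Tools for analyzing how SIRPα IgV-domain polymorphism in liver-transplant
recipients and donors shapes the T-cell alloresponse and the risk of acute
rejection (AR). The package is aimed at transplant immunogenetics groups who
genotype the polymorphic SIRPα IgV domain (exon 3 of *SIRPA*) and want a
reproducible chain from raw per-site genotypes to a matched clinical
comparison.

The pipeline has five stages:

1. **Haplotype calling** (`sirpa_allo.haplotyping`). The IgV domain is
   genotyped at 16 sites (15 SNPs + 1 deletion); the phased combinations
   define the named haplotypes V1, V2, V9, NV1 and NV2. Sanger sequencing
   yields unphased per-site calls, so the caller enumerates every panel
   haplotype pair whose site-wise allele multisets match the data: a
   heterozygote consistent with more than one pair is *Sanger-ambiguous* and
   needs phased (amplicon NGS) data, which the exact-match phased caller
   resolves to named haplotypes or labels `NOVEL-k`.
2. **Functional collapse and alloresponse scoring** (`sirpa_allo.alloscore`).
   Rare alleles (V9, NV1, NV2, novel) are collapsed onto V1 by Hamming
   proximity ("V1-like"), leaving the functional dichotomy V1-like vs V2.
   Because V2 SIRPα binds CD47 more strongly and delivers a stronger
   costimulatory signal, each V2 allele is weighted 2 ("++") and each
   V1-like allele 1 ("+"). Direct and indirect antigen presentation both
   count, so a transplant pair's score is the sum over all four alleles
   (two recipient + two donor): an integer from 4 to 8, grouped into
   low {4,5}, intermediate {6} and high {7,8} alloresponse.
3. **CFSE deconvolution** (`sirpa_allo.cfse`). CFSE dye halves at each
   division, so a proliferation assay resolves into generation counts. A
   precursor that divides n times leaves 2^n daughters, so precursors_g =
   counts_g / 2^g, events_g = precursors_g × (2^g − 1), the proliferation
   index PI = Σ events / Σ precursors, and a stimulation index SI normalizes
   a condition's PI to a control (IgG1, or the self-response in a mixed
   lymphocyte reaction).
4. **Matched cohort comparison** (`sirpa_allo.cohort_stats`). AR incidence is
   compared between alloresponse groups after 1:1 greedy nearest-neighbor
   propensity matching (logistic model on eight covariates, caliper 0.1),
   with chi-square / Fisher and McNemar tests on the matched 2×2 table.
5. **Synthetic data** (`sirpa_allo.synthetic`). Generates every input the
   pipeline consumes — genotypes at the cohort allele frequencies (V1 35.7%,
   V2 62.4%, V9 1.3%, NV1/NV2 0.3% each), covariates, group-dependent AR
   outcomes and division-destiny CFSE histograms with ground truth — so the
   whole chain is testable without patient data.

The packaged haplotype panel is a clearly-labelled **synthetic stand-in**
(published rsIDs, constructed allele vectors); drop in your own
`variant_sites.tsv` / `haplotypes.tsv` to use real allele assignments.

## Worked example

```python
import sirpa_allo as sa

panel = sa.default_panel()

# Sanger-ambiguity: an unphased V1/V9 heterozygote is consistent with two pairs
g = sa.UnphasedGenotype.from_pair("subject-17", panel["V1"], panel["V9"])
call = sa.enumerate_consistent_pairs(g, panel)
print(call.status.value)                      # AMBIGUOUS
print(sorted("/".join(sorted(p)) for p in call.pairs))   # ['NV1/NV2', 'V1/V9']

# phased (NGS-like) data resolves it
resolved = sa.call_phased("subject-17", [panel["V1"].alleles, panel["V9"].alleles], panel)
print(resolved.status.value)                  # UNIQUE  -> V1/V9

# alloresponse score for a V1/V2 recipient with a V2/V2 donor
s = sa.pair_score(sa.FunctionalGenotype("V1", "V2"), sa.FunctionalGenotype("V2", "V2"))
print(s.score, s.group.value)                 # 7 HIGH

# CFSE-MLR: antidonor vs self proliferation
allo = sa.CFSEHistogram.from_mapping({0: 120, 1: 150, 2: 240, 3: 400}, "DONOR")
self_ = sa.CFSEHistogram.from_mapping({0: 300, 1: 80}, "SELF")
print(round(sa.proliferation_index(allo).pi, 3))          # 1.984
print(round(sa.mlr_stimulation_index(allo, self_).si, 3)) # 16.861

# synthetic cohort: matched LOW vs HIGH acute-rejection comparison
cohort = sa.simulate_cohort(sa.SimulationConfig(seed=1), panel)
matched = sa.match_groups(cohort, "LOW", "HIGH", caliper=0.1, seed=1)
res = sa.compare_ar(matched, dict(zip(cohort["id"], cohort["ar_within_90d"])))
print(matched.n_pairs, res.incidence_a, res.incidence_b, round(res.p_value, 4))
# 23 4.3 52.2 0.0003
```

The matched comparison reads: among 23 propensity-matched pairs of this
synthetic cohort, AR incidence was 4.3% in the low-alloresponse arm versus
52.2% in the high arm (chi-square p ≈ 0.0003) — the low group is protective,
the direction the scoring model encodes.

The same chain runs from the shell:

```bash
sirpa run-all --seed 11 --out-dir out/           # simulate → genotype → score → cfse → match
sirpa genotype --unphased out/genotypes_unphased.tsv \
               --phased out/haplotypes_phased.tsv --out out/calls.tsv
sirpa match --cohort out/cohort.csv --compare LOW:HIGH --caliper 0.1 --seed 17 \
            --out out/matched.json
```

`run-all` writes a `manifest.json` (seed, file digests, row counts); re-running
with the same seed reproduces it byte-for-byte.

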
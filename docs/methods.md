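# Methods

## Haplotype model and the consistency-set caller

The SIRPα IgV domain (exon 3 of *SIRPA*, GRCh37/hg19 forward strand) is
modelled as 16 ordered biallelic sites — 15 SNPs and one deletion — over
which each named haplotype (V1, V2, V9, NV1, NV2) is a phased allele vector.
A panel is valid when every haplotype spells ref or alt at each site, names
and vectors are unique, and positions increase in table order.

Unphased (Sanger-like) input gives an unordered allele pair per site. The
caller returns the *consistency set*: every unordered panel pair (i = j
allowed) whose site-wise allele multiset equals the observation at all
non-missing sites. One pair → `UNIQUE`; several → `AMBIGUOUS` (the Sanger
ambiguity that motivates reflex NGS); none → `FAILED`. Missing sites are
wildcards: they can only enlarge the set, which is conservative toward
ambiguity — the safe direction for a clinical reflex-test trigger. The
enumeration is exact (checked against brute force over all pairs on random
panels up to 8 haplotypes × 20 sites), and a genotype synthesized from any
panel pair always contains that pair in its consistency set.

Phased input (two allele vectors per subject) is matched exact-or-novel:
each vector must equal a panel haplotype at Hamming distance ≤ `max_mismatch`
(default 0, since the workflow reports discrete named haplotypes plus new
variants, not near-matches); otherwise it is labelled `NOVEL-k` with its
vector retained. `max_mismatch` also requires a *unique* nearest haplotype —
a tie is treated as novel rather than guessed.

### The packaged stand-in panel

The per-haplotype allele assignments are not published as machine-readable
text, so the packaged panel is an explicitly synthetic stand-in carrying the
published rsID list over constructed vectors chosen to reproduce the
workflow's structure: V1 and V2 differ at 7 of 16 sites; V9, NV1 and NV2 lie
within Hamming distance ≤ 2 of V1 (the new variants' repertoires resemble
V1's); and the V1/V9 heterozygote is Sanger-ambiguous, being consistent with
both {V1,V9} and {NV1,NV2}. Note a structural fact of consistency-set
calling: any pair consistent with a heterozygote's genotype must take one
allele from each true haplotype at every heterozygous site, so both members
of an alternative pair are "recombinants" of the true two. With all rare
alleles near V1, the V1/V2 genotype itself is therefore uniquely resolvable
under this stand-in — ambiguity lives inside the V1-like family. All
algorithms are panel-agnostic; replacing the two TSVs swaps in the real
panel. Which rsID is the deletion is not determined by the published list
order; the packaged table marks rs561231326 and this is configurable by
editing the TSV.

## Functional collapse

Downstream analysis uses the dichotomy V1-like vs V2, because the clinically
relevant contrast is CD47-binding strength. A haplotype collapses to V2 iff
it is strictly closer (Hamming) to the panel's V2 than to V1; ties collapse
to V1-like and are flagged, keeping the rare-allele convention conservative.
The collapse is total and stable over any panel containing V1 and V2, and
fixed on the anchors (V1 → V1-like, V2 → V2).

## Alloresponse score

Each V2 allele contributes weight 2 and each V1-like allele weight 1,
semiquantifying the CD47→T-cell costimulatory signal ("++" vs "+"). Both
recipient (indirect) and donor (direct) APC compartments present antigen, so
the pair score sums all four alleles, giving 4–8, partitioned into LOW
{4,5}, INTERMEDIATE {6}, HIGH {7,8}. The sum is symmetric in recipient and
donor and increases by exactly 1 per V1-like→V2 substitution; no extra
weighting is applied per APC origin, since only the additive scheme and its
range are specified by the model. Novel haplotypes are first collapsed
(nearest of V1/V2) before scoring, mirroring the treatment of V9/NV1/NV2;
unresolved genotypes are flagged and excluded with a logged count.

## CFSE deconvolution

Input is an already-binned generation histogram (gating, compensation and
peak-fitting are upstream of this package). With counts_g cells observed in
generation g:

- precursors_g = counts_g / 2^g (a divider leaves 2^g daughters),
- events_g = precursors_g × (2^g − 1) — the internal nodes of the complete
  binary lineage tree, i.e. the number of binary fissions,
- PI = Σ events_g / Σ precursors_g (0 for an all-undivided well),
- SI = PI(condition) / PI(control); a zero-PI control yields an explicit
  undefined result (NaN with both raw PIs attached), never a silent 0 or ∞.

"Events per precursor" admits a second reading — generations traversed,
events_g = precursors_g × g — which is available as
`events_model="generations"` for sensitivity checks; the lineage-tree
reading is the default because it is the one consistent with counting every
division of every descendant. PI and SI are scale-invariant and the
deconvolution satisfies the reconstruction identity
Σ precursors_g × 2^g = Σ counts_g exactly.

Counts may be non-integer (no rounding: the indices are ratios). The
resolution limit defaults to G = 8 generations; deeper bins pool into G,
which biases precursors upward by at most counts_{>G} × (2^{-G} − 2^{-g}) —
negligible at realistic dye resolution. Replicate wells are averaged after
PI computation by default (`average_pi(..., how="post")`); pooling counts
before ("pre") is provided as the alternative.

## Propensity matching and outcome tests

Group membership (pairwise: LOW vs INTERMEDIATE, LOW vs HIGH, INTERMEDIATE
vs HIGH) is modelled by logistic regression on eight covariates: recipient
age and sex, primary disease (autoimmune vs other), donor relationship
(first-degree vs other), HLA class I and class II mismatch counts, donor age
and sex. Complete-case analysis; dropped rows are logged. On complete
separation or a failed ML fit the model falls back to a ridge-penalized
logistic fit (scikit-learn, C = 1) and flags it.

Matching is greedy 1:1 nearest neighbor without replacement: the smaller
group is processed in descending propensity order, each subject taking its
nearest unmatched counterpart unless |Δps| exceeds the caliper (default 0.1
on the probability scale; `caliper_scale="logit_sd"` gives the common
0.1 × SD(logit ps) alternative). Exact-distance ties are broken by a seeded
RNG, so the pairing is deterministic given the seed. Order matters for
greedy matching, which is why it is fixed and documented; pair counts from
other software will differ if it orders differently.

Matched AR incidence is tested primarily by Pearson's chi-square on the 2×2
arm-by-outcome table, *without* continuity correction (the uncorrected test
is close to nominal size at the matched-cohort sizes used here; Yates'
correction is markedly conservative), switching to Fisher's exact test when
any expected cell is below 5. Because 1:1 matched data are paired, McNemar's
exact test on discordant pairs is always reported alongside. No
multiple-testing adjustment is applied across the three pairwise group
comparisons; reports note this. Rank comparisons (Mann–Whitney U unpaired,
Wilcoxon signed-rank paired) use exact null distributions for n ≤ 25 without
ties and the continuity-corrected normal approximation otherwise.

## Synthetic-data generator

The generator emulates the study conditions, not the biology:

- **Genotypes**: two haplotypes per subject drawn i.i.d. from allele
  frequencies V1 0.357, V2 0.624, V9 0.013, NV1 0.003, NV2 0.003 (cohort
  estimates); no linkage disequilibrium beyond i.i.d. draws. Phased tables
  are the draws; unphased tables drop phase.
- **Cohort**: default 154 recipient–donor pairs. Covariate defaults are
  chosen as typical for an adult living-donor liver-transplant program
  (recipient age 54 ± 10, donor age 38 ± 11 years, 25% autoimmune primary
  disease, 70% first-degree donors, HLA mismatch counts 0/1/2 with
  probabilities 0.2/0.5/0.3); AR ~ Bernoulli with group-dependent
  probabilities 0.10/0.30/0.45 (LOW/INT/HIGH) — a synthetic ordering that
  mirrors the reported direction of effect, not the study's estimates. A
  `confounding_age_shift` knob adds group-correlated recipient age to
  exercise the propensity adjustment; `n_per_group` fixes arm sizes for
  calibration designs.
- **CFSE**: each of N seeded precursors draws a division destiny d from a
  Poisson truncated to {0..G} (per-condition means; point-mass destinies
  available), contributing 2^d cells at generation d and 2^d − 1 events; the
  ground truth is returned for oracle tests. Optional multiplicative
  log-normal count noise (off by default). Real kinetics (time-dependent
  division rates, death) are not modelled; any discrete destiny distribution
  suffices to validate deconvolution.

Everything is deterministic given the config seed. Passing tests on this
generator demonstrate the *arithmetic and inferential machinery* — exact
deconvolution, calibrated type-I error, qualitative direction recovery —
not performance on real flow-cytometry or clinical data.

## Problem sizes and calibration checks

The suite's heavier checks use: 200 random panels (≤ 8 haplotypes × ≤ 20
sites) for caller-oracle equality; 500 random destiny configurations for
CFSE round-trips; 1,000 null replicates (30 subjects per arm, AR probability
0.3 in both) for the size of the matched comparison, asserted inside a 99%
binomial interval around 5%; and 200 replicates (60 per arm, AR 0.05 / 0.30
/ 0.45) for recovery of the protective-low conclusion, required in > 80%.
The full suite runs in well under a minute on one CPU.

## Known limitations

- The stand-in panel reproduces the ambiguity structure, not the real allele
  spellings; genotype-level results on packaged data are illustrative only.
- Greedy matching is order-dependent by construction; published pair counts
  cannot be reproduced without the individual-level data and the original
  software's ordering.
- Raw-read processing (trimming, alignment, variant calling), chromatogram
  base-calling, FCS parsing and peak deconvolution, survival/long-term
  outcomes, and SIRPG/SIRPγ genotyping are out of scope.
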
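# Methods

`boarmark` reimplements, end to end and in silico, a dual-marker assay
for telling domestic pigs (*Sus scrofa domestica*) from Central European
wild boars (*Sus scrofa scrofa*) and for spotting admixture between the
two gene pools.  The two markers are:

* **MC1R** (the coat-colour *extension* locus): three discriminating
  coding SNPs — c.370G>A (p.Asp124Asn), c.491C>T (p.Ala164Val) and
  c.727G>A — define three allele classes distinguishable by the panel:
  the wild type `E+` (370G/491C/727G), the recessive red `e`
  (370G/491T/727A) typical of Duroc, and a merged dominant-black /
  black-spotting class `ED` (370A/491C/727G) that covers the ED1, ED2,
  EP2 and EP3 alleles.  A fourth panel site, c.729A>G, is monomorphic
  (GG) in the cohorts and is carried as a non-discriminating call.
* **NR6A1 g.748C>T** (p.Pro192Leu, the vertebrae-number QTL mutation):
  C marks the wild-boar lineage, T the domestic lineage; a CT
  heterozygote is a first-generation hybrid.

The decision rule is: NR6A1 draws the wild/domestic line (CC → wild
boar, TT → domestic pig, CT → hybrid), and the MC1R diplotype upgrades
the verdict to `admixed_wild_boar` (CC with any domestic MC1R chromosome)
or annotates `admixed_domestic` (TT with a wild-type `E+` chromosome).

## Assay models and their assumptions

**In-silico PCR** matches the forward primer on the plus strand and the
reverse primer as its reverse complement strictly downstream, with a
configurable mismatch budget (default 0: the assays are designed PCRs,
not discovery scans).  Zero site pairs is "no product"; more than one is
"non-specific amplification".  The amplicon is primer-to-primer
inclusive.

**Diploid consensus sequences.**  Direct Sanger sequencing of a diploid
PCR product is modelled as a single consensus string in which
heterozygous positions carry the two-base IUPAC code (R = A/G,
Y = C/T).  No base-quality or chromatogram model is attempted; a base
incompatible with a locus' ref/alt pair is a hard "unexpected allele"
error rather than a soft call.

**PCR-RFLP.**  Digestion is complete and deterministic: the recognition
site is scanned on the plus strand (both shipped enzymes, BspHI
`T^CATGA` and BstUI `CG^CG`, are palindromic, so a plus-strand scan
covers both strands; non-palindromic sites are additionally scanned as
their reverse complement with the cut mirrored).  Diploid gel patterns
are the union of the two haplotypes' fragment multisets; co-migrating
bands merge within a configurable resolution (default 0 bp — all
published bands are distinct).  Partial digestion, star activity and
gel-mobility physics are out of scope.  Band keys decode patterns back
to genotypes; an unmatched pattern reports the nearest key entries
instead of guessing.

**TaqMan allelic discrimination** is exact probe containment with IUPAC
expansion on the template side only, so a template Y lights both
allele probes (CT) while each homozygote lights exactly one.  No
fluorescence-threshold or Ct model is attempted; the published
instrument settings are carried as panel metadata.

**Diplotype assignment** enumerates every phasing of the three-locus
genotype into two haplotypes and keeps the phasings in which both
haplotypes match a defined allele class.  All cohort genotypes resolve
uniquely (including the triple heterozygotes, whose only fully defined
phasing is `e/ED`); genuinely ambiguous genotypes are returned with the
full candidate set rather than an arbitrary choice, and unmatched
genotypes are flagged `unrecognized` with their raw patterns attached.
`EP3` deserves a note: it has no distinguishing pattern at the three
panel SNPs, so the classifier can never emit it; it exists only as
ground-truth annotation in the cohort specification and is flagged
"unresolvable by panel" wherever distances or labels touch it.

## The synthetic backbone

No sequence data for the original cohorts are deposited, so the package
engineers its own reference instance of the published coordinate
system.  The constraints the backbone must satisfy are taken from the
published band arithmetic, which is internally consistent only per
assay: the BspHI assay implies a 672 bp product (672 = 472 + 200) while
the BstUI fragments sum to 621 (289 + 222 + 110, and 332 = 222 + 110);
the separately published 575 bp figure matches neither and is kept as
metadata for the *sequenced window*.  The layout therefore uses one
physical 672 bp PCR product with per-assay digestion frames:

* the sequenced 575 bp window (anchored at reference position 181)
  starts at product offset 13; SNP offsets inside the window follow
  `offset = position − 181 + 1` (370 → 190, 727 → 547);
* the BspHI site spans c.370 (product offset 202) and cuts after product
  base 200, giving 200 + 472 in 5'→3' order — the orientation that puts
  the cut nearest the SNP's anchored offset;
* the BstUI assay digests the 621 bp sub-window at product offsets
  47..667, with a constitutive CGCG site (cut after window base 289) and
  a polymorphic one whose last base is c.727 (cut after window base
  511), giving 289/222/110 for 727G and 289/332 for 727A;
* c.729 sits two bases downstream of the polymorphic BstUI site with a
  fixed guard base between them so that the cohort's universal 729G
  cannot recreate a site.  The backbone reference carries 729A, making
  the site a *fixed difference* in cohort-vs-reference SNP discovery
  (the fourth variable position) rather than a segregating one.

Filler sequence is drawn from a seeded generator and redrawn (up to 50
attempts) until validation passes; validation digests all sixteen
allele combinations with both enzymes, demands exactly the designed
fragments, exactly one primer site pair per template, and
allele-exclusive probe footprints on the NR6A1 region.  Construction
therefore self-checks that all six published band patterns regenerate
before any cohort is emitted.

## The synthetic cohort

The default cohort specification encodes the published per-breed
composition: 24 wild boars (22 all-reference, 2 heterozygous at c.370),
17 Duroc (14 `e/e`, one triple heterozygote `e/ED`, one `E+/E+`, one
`ED/ED`), 13 Złotnicka White (11 `ED/ED`, 2 triple heterozygotes), 10
Puławska, 14 Polish Landrace (4 `ED/ED`, 10 `ED/EP3`) and 13 Polish
Large White (`ED/ED`), i.e. 91 study samples, plus 5 deliberate hybrids.
The Duroc triple heterozygote is coded (370 AG, 491 CT, 727 AG), which
is the only coding consistent with the published per-locus marginals
(370: 15 GG / 1 AG / 1 AA, etc.).  NR6A1 is fixed CC in wild boar and
TT in every breed; hybrids are CT.  Hybrid MC1R diplotypes pair one
wild-boar chromosome with one domestic chromosome, drawn from the two
pools' haplotype-class frequencies (46:2 and 2:31:90:11), seeded.

What the generator deliberately does **not** emulate: sequencing error,
allele dropout, chimeric PCR, within-class sequence variation (every
`ED`-class chromosome is literally identical), or any polymorphism
outside the four panel sites.  Passing tests therefore demonstrate that
the pipeline's logic is correct on clean data with the study's
composition — not that the assays are robust to noisy chromatograms or
to alleles the panel has never seen.

## Population layer

**Haplotype classes.**  Diplotypes are tallied into chromosome counts
per class per population (H1 = `e`, H2 = `E+`, H3 = `ED`, H4 = `EP3`),
pooling the five breeds as one domestic population (2n = 134) against
the wild boars (2n = 48); hybrids are excluded from the two-population
comparison.  The H4 column exists only because the ground-truth
specification carries the ED/EP3 split; the classifier alone would
merge it into H3.

**Fst.**  The default estimator is Weir & Cockerham's
variance-components theta with haploid-coded chromosomes: each
chromosome is one observation at a single multiallelic locus, per-allele
mean squares among and within populations are combined as
θ = Σa / Σ(a+b), and the implementation is cross-checked in the test
suite against an independent one-way-ANOVA oracle on 0/1 allele
indicators.  A locus monomorphic across both populations is reported as
*undefined*, never 0.  Sample-weighted Nei G\_ST is available behind a
flag.  On the published composition the haploid-coded θ is 0.63; the
originally reported value (0.3573) is not recoverable from the printed
genotype tables under this or any standard estimator variant we
examined (genotype-coded θ 0.63, per-site multilocus θ 0.41–0.42,
per-site mean θ 0.31, G\_ST 0.41–0.54, nucleotide-difference F\_ST
0.31–0.51), and presumably reflects sequence-level information
(additional segregating sites and phasing) present in the original
alignment but not in the published tables.  This discrepancy is a known
limitation, stated here rather than papered over.

**Haplotype network.**  A complete graph over the observed classes with
Hamming distances across the three discriminating SNPs
(d(E+,ED) = 1, d(E+,e) = 2, d(e,ED) = 3); minimum-spanning edges are
marked for display.  Edges touching EP3 carry `distance_defined=False`
because its sequence-level distance is not derivable from the panel.
With only four haplotypes, no median-joining median vectors are needed.

**Admixture model.**  The standard no-linkage admixture mixture model:
individual memberships q_i ~ Dirichlet(α,…,α), cluster allele
frequencies per locus ~ Dirichlet(λ=1), each allele copy drawn by
cluster-then-allele.  Inference is a vectorised Gibbs sampler that also
updates α by Metropolis–Hastings (uniform (0,10] prior, normal proposal
σ=0.05), as the reference implementation of this model family does —
with essentially unadmixed individuals and a single gene, α settles
near 0.03 and a fixed α=1 would badly over-smooth memberships.  The
correlated-allele-frequencies prior of the reference implementation is
*not* modelled (independent Dirichlets per cluster); model selection is
therefore expected to be noisier, which is why the cluster-number
result is framed as a majority vote.  L(K) is the posterior mean
log-likelihood over post-burn-in sweeps (the mean−variance/2 deviance
estimate is also recorded); Q and P are Rao-Blackwellised posterior
means.  An EM backend maximises the same likelihood with a provably
monotone trace and is used for the closed-form K=1 check.

**Input coding.**  `admixture_fit` accepts any `(n, loci, 2)` integer
genotype array.  The pipeline's default coding is one biallelic locus
per discriminating SNP site (370/491/727), mirroring an aligned-sequence
input where every segregating site is a locus; the haplotype-class-as-
one-multiallelic-locus coding is also provided.  The distinction
matters for model selection: under the single-locus coding the
wild/domestic split dominates the likelihood curvature so strongly that
Evanno's ΔK saturates at K = 2, whereas the per-site coding both
balances the information between the Duroc (`e`) and black (`ED`)
splits and makes K = 2 genuinely multimodal (two competing splits),
inflating the replicate variance at K = 2 — exactly the signal ΔK is
designed to exploit — and yielding K = 3 (wild boar / Duroc / other
breeds) in the large majority of master seeds.

**Scale.**  Desk scale (the default everywhere, including the tests) is
2,000 burn-in + 5,000 recorded sweeps; the original analysis's
100,000/200,000 is available as the `paper` scale preset.  One desk
scan (K = 1..6 × 10 replicates) takes about a minute on one core.

**Evanno ΔK** = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate
runs, defined for interior K only; a K with zero replicate standard
deviation is excluded with a warning, and a flat L profile yields no
optimum rather than an arbitrary one.  Because ΔK selection on 10
replicates is stochastic, the pipeline's headline K is a majority vote
over 5 master seeds; under the desk conditions individual master seeds
select K = 3 roughly three times in four, and the majority vote lands
on K = 3 in most, but not provably all, master-seed draws.

**Fixed-population testbed.**  The admixture recovery check simulates
two populations fixed for different alleles, 50 diploids each — sized
so the posterior allele-frequency mass on the "wrong" cluster
(λ/(2n+2λ) ≈ 1%) keeps every per-sample max-Q above 0.95.

## Numerical and degenerate-input choices

* Band patterns compare as descending-length multisets; resolution 0 is
  exact comparison, and merging keeps the larger band of a co-migrating
  group.
* Fragment boundaries: an enzyme cut after base `site_start +
  cut_offset − 1` (1-based); cuts at position 0 or at the molecule end
  are discarded as non-cuts.
* θ on identical populations is slightly negative (≈ −1/(n−1)), as an
  unbiased estimator should be; tests assert |θ| < 0.005 rather than 0.
* `evanno_delta_k` requires ≥3 consecutive K and ≥2 replicates and
  raises otherwise; `admixture_fit` warns (but runs) when K exceeds the
  number of distinct multilocus genotypes.
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence` spawns, so every pipeline product is
  reproducible from the single run seed, and replicate seeds never
  collide.

## Known limitations

* The published F_ST value cannot be reproduced from the published
  tables (see above); the package reports what the stated estimator
  yields on the stated input.
* EP3 is representable only as ground truth, never callable — a faithful
  consequence of the panel's three SNPs.
* The admixture model omits the correlated-frequencies prior and models
  a single gene; its cluster-number selection is a majority-vote
  statistic, not a deterministic one.
* The generator produces clean, noise-free consensus sequences; no
  claim is made about robustness to real chromatogram artefacts.
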
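# Methods

## Binary encoding of multi-allelic HLA variation

The HLA loci defeat the usual biallelic-variant machinery: a gene can carry
dozens of classical alleles, and an aligned protein position up to several
residues. We recode everything as binary presence/absence markers so that a
single haplotype model and a single 1-df regression handle all variant
classes uniformly:

* `HLA4` / `HLA2`: one marker per distinct 4-digit / 2-digit classical
  allele of a gene. A 4-digit label reduces deterministically to its
  2-digit family (`B*0702 → B*07`).
* `AA`: for every aligned position with at least two distinct symbols among
  the observed alleles, one marker per amino acid residue at that position.
  A position with three residues yields exactly three markers.
* `INDEL`: one marker per distinct gap run (deletion event, keyed by start
  position and length) or truncation (first `*`), taken from the same
  alignment.
* `SNP`: ordinary biallelic SNPs pass through; intragenic SNP markers are
  accepted as precomputed binary markers (no cDNA-level re-derivation).

Dosages are allele counts over an individual's two chromosomes, so for a
fully typed individual the `HLA4` dosages of a gene sum to exactly 2, and
the residue dosages of every gap-free position sum to exactly 2. At
positions where some alleles carry a gap, the residue dosages of gap
carriers sum to less than 2 — the complement is carried by the
corresponding `INDEL` marker, which is encoded separately by design. The
amino-acid genotype table is a linear image of the 4-digit table (dosage of
a residue = sum of dosages of the alleles carrying it); this identity is
enforced by test.

Individuals typed only at 2-digit resolution contribute to 2-digit markers
and are set missing at 4-digit markers (a `drop` policy is also available).
Sequences are consumed pre-aligned, one frame per gene; this package does
not run multiple sequence alignment.

Markers need genomic coordinates for the haplotype model's total order.
Each gene has an anchor coordinate (defaults approximate the physical gene
locations inside the 29–34 Mb window; configurable), and a residue marker
at protein position p sits at `anchor + 3p` (3 bp per codon). Exact
within-gene geometry is immaterial: what matters is that encoded markers
sit between the correct flanking SNPs, since copying posteriors at
co-anchored markers are interpolated from the same flanks.

## Reference-panel QC and phasing

SNP QC removes markers with minor allele frequency below 1%, missingness
above 5%, or exact Hardy–Weinberg P below 1e-6 (the exact test enumerates
the conditional heterozygote distribution given allele counts; mid-p off).
All three filters are computed on the input table, so the retained set is
independent of filter order. Encoded markers get a 0.01% presence-frequency
floor and are never HWE-tested: they are logically constrained one-hot
blocks, not freely segregating biallelic variants, so the HWE null has no
meaning for them.

Phasing is iterative conditional decoding under the same haplotype-copying
model used for imputation: each sweep re-phases every individual against
the current haplotypes of all others (10 sweeps by default). Three decoding
modes are used:

* **Posterior pair sampling** (small panels, early sweeps): an ordered pair
  of copying paths is drawn from the exact diploid forward filter by
  backward sampling. Deterministic argmax updates from a random
  initialization reliably lock into local optima — mutually reinforcing
  wrong splits; stochastic sweeps escape them, and the generator is seeded
  so runs remain reproducible.
* **Joint diploid Viterbi** (small panels, final two sweeps): the MAP
  ordered pair of paths. The per-site phase marginals of the diploid
  posterior are exactly 1/2 at heterozygous sites by exchangeability of the
  two haplotypes, so a joint decoding, not a site-wise argmax, is required.
* **Greedy forward pair decoding** (large panels, and target phasing inside
  imputation): two coupled copying chains advance left to right; each
  heterozygous site takes the orientation with larger joint forward mass.
  O(M·K), deterministic, and accurate when the panel is informative; a
  phase switch only affects haplotype-level outputs, since total dosages
  sum over both haplotypes.

The exact diploid decoders run on the K² ordered-pair state space and are
used when the conditioning panel has ≤ 80 haplotypes. Individuals with more
than 50% missing markers are excluded with a warning; residual missing
genotypes are hard-filled with the rounded panel expectation before
phasing. After phasing, each encoded gene block is projected onto the
allele-consistent one-hot configuration (orientation chosen to agree
maximally with the HMM phase), so every reference haplotype carries exactly
one classical allele per gene and one residue per position. Re-phasing an
already-phased panel is an identity (validated pass-through). Pedigree-
aware phasing is not implemented; unrelated individuals are a stated
precondition.

## The copying model

A sample haplotype is modelled as an imperfect mosaic of the K reference
haplotypes (Li–Stephens). Between adjacent markers at genetic distance d
Morgans (uniform map, default 1 cM/Mb) the copied reference switches to a
uniformly random one with probability `ρ = 1 − exp(−4·Ne·d/K)`, Ne = 15,000
by default. The emitted allele differs from the copied one with copy-error
probability θ; the default is the usual mutation-rate estimate
`θ = w / (2(K + w))` with `w = 1/Σ_{k<K} 1/k`. This transition family is
closed under composition and exactly additive in genetic distance, so
running the chain over the full marker grid (untyped markers as missing
emissions) is equivalent to decoding on typed sites and interpolating — the
implementation does the former.

Imputation of an individual: (1) phase the typed genotypes against the
panel (greedy pair decoding); (2) run the scaled haploid forward–backward
for each phased haplotype over all panel markers; (3) report, per marker,
the allele probability `p = θ + (1−2θ)·Σ_k γ_k a_k`. Genotype posteriors
combine the two haplotypes as independent given their copying posteriors:
`P2 = p₁p₂`, `P0 = (1−p₁)(1−p₂)`, `dosage = P1 + 2·P2` holds exactly.
Because each reference haplotype is one-hot within a gene, the dosages of a
gene's classical alleles sum to `2 + 2θ(A−2) ≈ 2` per individual — the
dosage-sum sanity check (tolerance 0.1) guards this invariant on every run.
Best-guess calls are posterior argmaxes with ties broken toward the lower
genotype and flagged; classical two-allele calls take the per-haplotype
maximum-posterior allele (flat posteriors fall back to the lowest marker id
with an ambiguity flag). Individuals with fewer than 10 typed markers are
imputed but flagged low-confidence.

The forward–backward and phasing loops are numba-compiled; the backward
pass is fused with dosage extraction at the requested output markers, so
the (M × K) posterior matrix is never materialized. Optional overlapping
windows (`HmmParams.window` markers, 20% overlap, centre splicing) bound
memory for very long grids; the default is whole-region decoding. Exact
correctness of the recursions is pinned by brute-force path-enumeration
oracles (all K^M haploid paths at K=6, M=8; all ordered pair paths at K=3,
M=5) at 1e-8.

Target harmonization before imputation: SNPs outside the MHC window are
dropped, target MAF < 2.5% dropped, alleles matched to the panel with
automatic strand flip when the complement matches, and A/T–C/G ambiguous
sites resolved by frequency matching when the panel frequency is at least
0.1 from 0.5 (otherwise dropped). Every action and drop reason is reported.

## Evaluation metrics

* `Acc(L)` at locus L: sum over individuals of the imputed dosages of their
  true alleles — both terms for heterozygotes, only the A1 term for
  homozygotes (the truth typing decides homozygosity) — divided by 2n.
  Soft dosages receive partial credit by construction; the measure is
  deliberately generous in the degenerate case where a hard call duplicates
  the other true allele of a heterozygote (the full dosage of a true allele
  counts), so its identity with allele-level concordance holds exactly when
  miscalls introduce alleles outside the true pair. Truth alleles with no
  marker (pruned or unseen in the panel) contribute dosage 0 and are
  listed. Individuals are included only when both truth alleles are typed
  at the evaluated resolution.
* Dosage `r²`: squared Pearson correlation over individuals; reported as
  missing when either vector is constant.
* Multi-residue `R²`: the centred vector form
  `(Σᵢ⟨Xᵢ−X̄, Yᵢ−Ȳ⟩)² / (Σᵢ‖Xᵢ−X̄‖²·Σᵢ‖Yᵢ−Ȳ‖²)`. The centred form is
  chosen so that it reduces exactly (tol 1e-10, tested) to the biallelic
  Pearson `r²` at 2-residue positions; the uncentred variant is available
  behind a flag for sensitivity analysis.
* Concordance: order-free multiset match of best-guess calls per individual
  (0, ½, 1), averaged; optionally restricted at the allele level to truth
  alleles above a frequency floor (used to report accuracy for common
  alleles). Comparisons are made only when the truth is typed at the same
  resolution.
* Calibration: dosages binned on [0, 2] (20 bins by default) against mean
  true hard dosage; a calibrated imputation puts bin means on the diagonal.

## Association testing

Per-marker tests regress case/control status on the posterior dosage
(probabilistic dosages, not best-guess calls, carry imputation uncertainty
into the test; logistic fits via maximum likelihood, Newton, with a BFGS
fallback and a separation flag — under separation only the likelihood-ratio
p is reported). The omnibus position test fits one effect per residue except
the most frequent (dropped to break the residues-sum-to-2 collinearity) and
refers the deviance difference against the intercept-only model to χ² with
(#residues − 1) df; because the dropped column is linearly dependent on the
others plus the intercept, the statistic is invariant to the reference
choice (tested to 1e-6). Zero-variance residues are dropped with a note and
the df adjusted. Raw p-values are reported without multiplicity correction;
covariates are supported but off by default.

Haplotype risk uses hard phased haplotype calls: haplotypes below a 0.5%
sample-frequency floor are pooled as "rare", and each haplotype's odds
ratio against the designated reference haplotype comes from the haplotype-
count model (two observations per individual). In the saturated categorical
model the profile likelihood of one haplotype's coefficient reduces exactly
to a two-binomial problem in that haplotype's and the reference's cells —
all other parameters profile out independently — so profile CIs are
computed by a 1-d inner maximization and bracketing root-solve.
Zero cells get the Haldane 0.5 correction and a flag; the reference-vs-
itself row carries OR = 1 exactly.

## The synthetic-data generator

A founder-mosaic model, not a coalescent: `n_founders` founder haplotypes
(default 40) carry random SNP alleles at ~5500 positions scattered over the
29–34 Mb window, and one classical allele per gene. Every sample haplotype
is an independent mosaic of founders (switch probability `1 − exp(−r·d)`
between adjacent loci, default r chosen for ~2 expected switches across the
window) with SNP copy errors at rate 0.002. The gene allele is that of the
founder active at the gene's anchor, and all encoded markers follow
deterministically through a generated residue table (~12 polymorphic
positions per gene, 2–3 residues each, one planted 2-residue deletion in
alternating genes), so encoded markers are exactly one-hot per haplotype
and the allele→residue linear identity holds by construction.

Classical allele frequencies target a Dirichlet draw (concentration 0.5
over 12 alleles per gene by default, a skewed spectrum): founders are
allocated to alleles by largest remainder, so realized frequencies match
the target to within 1/(2F) plus multinomial noise (verified by chi-square
goodness of fit at K = 10,000). Platform profiles expose a seeded random
subset of panel SNPs to targets ("sparse" ≈ 500, "dense" ≈ 5000, after the
panel's 1% MAF floor); targets are drawn from a haplotype pool disjoint
from the panel to avoid leakage inflating accuracy. Phenotypes are
Bernoulli draws from `logit P(case) = α + β·(causal residue count)` with α
calibrated to a target prevalence. For haplotype-OR studies a retrospective
design is used — case haplotype frequencies are the control frequencies
tilted by the planted OR — because that makes the planted value exactly the
estimand of the haplotype-count odds ratio (a prospective per-individual
logistic model would plant a non-collapsible, attenuated quantity).

What the generator does not emulate: genotyping error in the reference
typings, population structure and admixture, selection, gene conversion,
SNP ascertainment bias, and the real MHC recombination-hotspot landscape
(the map is uniform). Passing benchmarks on this generator therefore
demonstrates correctness of the machinery and the qualitative drivers of
performance (panel size beats SNP density; accuracy falls for rare
alleles), not the absolute accuracy attainable on real cohorts, which is
limited by the above.

## Benchmark problem sizes

The standard benchmark conditions are a panel of K = 1000 haplotypes with
~5500 SNPs, 200 disjoint target individuals, six genes (A, B, C, DQA1,
DQB1, DRB1), dense/sparse platform profiles, five simulation seeds, and
panel-size comparisons at K = 50/100/1000; under these conditions mean
4-digit concordance for alleles above 1% frequency exceeds 90%, dense is at
least sparse, and concordance is non-decreasing in K within seed error.
Association calibration uses 2000 permutation-null replicates (continuous
posterior-like dosages — hard-count permutation statistics are lattice-
valued and cannot be KS-tested against the uniform), a planted OR-2 residue
at n = 2000 over 20 phenotype seeds, and 100 replicates of the planted-OR-5
haplotype study.

## Numerical choices and degenerate inputs

Scaled (normalized) forward–backward recursions; switch probabilities
clipped to [1e-12, 1−1e-12]; ties in best-guess calls broken toward the
lower genotype count and flagged; flat classical-call posteriors fall back
to the lowest allele id with an ambiguity flag; constant dosage vectors are
rejected in association tests and reported as missing in correlations;
empty calibration bins report count 0 and a missing mean. The bit-exact
PLINK codec rejects bad magic bytes and truncated payloads with the byte
offset. Genome build is metadata only: the window is treated as pure
coordinates.

## Known limitations

* Target phasing inside imputation is greedy (forward-only): switch errors
  are possible in regions of weak LD, affecting multi-gene haplotype
  assignments more than dosages.
* The independence combination of the two haploid posteriors slightly
  understates genotype-posterior correlation relative to the exact diploid
  model (which is exponentially more expensive at K = 10,000 scale); the
  exact small-K decoder quantifies the gap in tests.
* Beagle's haplotype-cluster model is intentionally not reimplemented; the
  engine honours the same contract (posterior dosages, best-guess calls,
  phased haplotypes) with a fully specified, oracle-testable model instead.
* Imputation quality claims transfer to a real cohort only insofar as the
  reference panel represents the target population; a mismatched panel
  degrades accuracy unevenly across loci.
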
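# hlaimpute

Imputation of classical HLA alleles and amino acid polymorphisms from SNP
genotypes in the MHC region (chr6:29–34 Mb), with the downstream machinery
to evaluate imputation quality and to test imputed variants for disease
association.

## Who this is for

GWAS analysts who have SNP array data covering the MHC but no direct HLA
typing. The HLA genes are the most polymorphic loci in the human genome and
carry the largest known effect sizes in autoimmune and infectious disease,
but probe-based typing does not scale to large cohorts. Because linkage
disequilibrium in the MHC extends over long distances, a reference panel
that carries both dense SNPs and high-resolution HLA types lets you impute
classical alleles — and, crucially, the individual amino acid residues they
encode — into existing SNP data, then fine-map association signals to
specific coding positions.

## What it does

1. **Binary-marker encoding** (`hlaimpute.markers`). Every allele of every
   multi-allelic HLA variant becomes its own presence/absence marker: one
   marker per 2-digit and 4-digit classical allele (`HLA_A_0101`), one per
   residue at each polymorphic aligned protein position
   (`AA_DQB1_57_32660171_D` — a position with three residues yields three
   markers), and one per insertion/deletion/truncation event. A fully typed
   individual's dosages sum to 2 within each gene and each position.

2. **Reference-panel construction** (`hlaimpute.panel`). Standard SNP QC
   (MAF < 1%, missingness > 5%, exact Hardy–Weinberg P < 1e-6 removed), a
   0.01% frequency floor on encoded markers, position-sorted merging, and
   phasing into reference haplotypes by iterative conditional decoding
   under the haplotype-copying model, with encoded gene blocks projected
   onto consistent one-hot configurations.

3. **Imputation** (`hlaimpute.hmm`). A Li–Stephens haplotype-copying HMM:
   each sample haplotype is modelled as a mosaic of the K reference
   haplotypes with switch probability `1 − exp(−4·Ne·d/K)` per interval and
   copy-error rate θ. Typed genotypes are phased against the panel, then an
   exact haploid forward–backward over the full marker grid yields, for
   every marker: posterior dosages in [0, 2], genotype posteriors
   (P0, P1, P2) with `dosage = P1 + 2·P2` exactly, best-guess calls, and
   phased haplotypes. Dosages of a gene's classical alleles sum to ~2 per
   individual by construction.

4. **Evaluation** (`hlaimpute.evaluate`). Dosage accuracy per locus
   `Acc(L) = [Σ_het (D(A1)+D(A2)) + Σ_hom D(A1)] / 2n`, Pearson `r²`
   between imputed and typed dosages, a centred vector `R²` for
   multi-residue positions (reduces exactly to `r²` when a position has two
   residues), best-guess genotype concordance at 2- and 4-digit resolution,
   frequency correlation, and posterior-calibration curves.

5. **Association** (`hlaimpute.assoc`). Logistic regression of case/control
   status on allelic dosage per marker; omnibus amino-acid-position tests
   (deviance of the model with one effect per residue, reference residue
   dropped, χ² with #residues − 1 df); signal ranking; and haplotype odds
   ratios against a designated reference haplotype with profile-likelihood
   confidence intervals.

6. **Synthetic data** (`hlaimpute.simulate`). A founder-mosaic generator
   that reproduces the long-range LD between SNP backgrounds and HLA
   alleles, with Dirichlet allele-frequency spectra, generated residue
   tables, disjoint reference/target haplotype pools, platform profiles
   ("sparse" ≈ 500 typed SNPs, "dense" ≈ 5000), and phenotype simulation
   with a planted causal residue. All truth is recorded, so every stage of
   the pipeline is testable without external data.

## Worked example

```python
from hlaimpute import simulate, hmm, evaluate as ev

# reference panel of 200 haplotypes + 40 held-out target individuals
cfg = simulate.SimConfig(n_haplotypes=200, n_target=40, n_snps=800, seed=1)
sim = simulate.simulate_panel(cfg)
target, gold, truth = simulate.make_target(sim, profile="dense", seed=1)

encoded = [m.id for m in sim.panel.markers if m.kind != "SNP"]
result = hmm.impute(target, sim.panel, markers=encoded)

for gene in ("A", "B", "DRB1"):
    calls = hmm.call_classical(result, gene, resolution=4)
    conc, n = ev.concordance(calls, gold, resolution=4)
    acc = ev.accuracy(result.dosage, gold, gene, resolution=4)
    print(f"{gene:5s}  Acc = {acc.acc:5.1f}%   concordance = {conc:5.1f}%  (n = {acc.n})")
```

prints

```
A      Acc =  99.9%   concordance = 100.0%  (n = 40)
B      Acc =  99.8%   concordance = 100.0%  (n = 40)
DRB1   Acc =  98.1%   concordance =  98.8%  (n = 40)
```

`Acc` is the dosage-weighted accuracy at each locus (partial credit for
uncertain but partially correct posteriors); `concordance` is the fraction
of best-guess 4-digit allele calls matching the withheld gold-standard
typings of the 40 target individuals.

The same pipeline is available from a shell:

```bash
hlaimpute simulate --out work --seed 1 --haplotypes 200 --n-target 40
hlaimpute build-panel --bfile work/panel_snps --typings work/panel.typings.tsv \
    --sequences work/alleles.tsv --out work/rebuilt --seed 1
hlaimpute impute --panel work/panel --bfile work/target --out work/imp --seed 1
hlaimpute evaluate --panel work/panel --bfile work/target \
    --truth work/target.gold.tsv --out work/eval --seed 1
hlaimpute assoc --dosage work/imp.dosage.tsv --pheno pheno.tsv --out work/scan
```

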
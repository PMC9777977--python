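# candsnp

A candidate-gene SNP analysis toolkit for livestock reproduction studies,
built around the complete statistical pipeline of a SMAD1/SMAD2/SMAD3
litter-size study in Tibetan sheep (*Ovis aries*): 433 ewes genotyped at 10
exonic SNPs, litter size recorded over three parities, and gene expression
profiled by RT-qPCR across 13 tissues. The package is a library first (with
an `examples/` directory of narrative scripts) plus a thin `candsnp` CLI.

## What it computes

**Population genetics** (per biallelic locus, allele frequencies
*p*, *q*): gene homozygosity *Ho* = Σ*p*ᵢ², heterozygosity *He* = 1 − *Ho*,
effective allele number *Ne* = 1/*Ho*, and Botstein's polymorphism
information content *PIC* = 1 − Σ*p*ᵢ² − Σᵢ<ⱼ 2*p*ᵢ²*p*ⱼ², classified low
(< 0.25), moderate (0.25–0.5) or high (≥ 0.5). Hardy–Weinberg equilibrium is
tested both by the df = 1 χ² goodness-of-fit and by the exact conditional
test (full enumeration of heterozygote counts given the allele counts).

**Haplotypes and LD**: EM estimation of 2–4-locus haplotype frequencies from
unphased genotypes (uniform initialisation, monotone log-likelihood,
listwise deletion), pairwise *D* = *p*₍AB₎ − *p*₍A₎*p*₍B₎, *D′* = |*D*|/*D*ₘₐₓ and
*r*² = *D*²/(*p*₍A₎*p*₍a₎*p*₍B₎*p*₍b₎), and haplotype blocks by a documented
*D′*-threshold rule (default 98%).

**Litter-size association**: the fixed-effects model
*Y*ᵢⱼₙ = *μ* + *P*ᵢ + *G*ⱼ + *I*ᵢⱼ + *e*ᵢⱼₙ (parity, genotype, interaction)
fitted by least squares with Type III F tests, per-genotype mean ± SD/SEM
tables and compact letter displays from pairwise t tests on the pooled
residual variance.

**Relative expression**: 2^−ΔΔCt quantification normalised to a reference
gene and a calibrator tissue, with scale/reference-shift invariance, plus
one-way ANOVA tissue comparisons with letters.

**Sequence utilities**: ATG→stop ORF finding and translation, ProtParam-style
protein parameters (MW, pI, charged residues, GRAVY, instability and
aliphatic indices), percent-identity matrices, and Saitou–Nei
neighbor-joining trees in Newick.

**Synthetic data**: generators reproducing the study's shape — genotypes
under Hardy–Weinberg (or a stated deviation *F*), haplotype-pool blocks,
litter sizes as 1 + Bernoulli(twin probability) with logit-scale effects,
and 13-tissue × 3-animal × triplicate Ct tables — all bit-for-bit
reproducible from a seed.

The published genotype counts and litter-size summaries are bundled in
`candsnp.datasets` so the population-genetic results can be recomputed from
scratch without downloads.

## Worked example

```python
from candsnp import allele_frequencies, hwe_test, popgen_summary
from candsnp.datasets import snp_count_dataset

dataset = snp_count_dataset()          # 433 ewes x 10 SNPs from the counts
af = allele_frequencies(dataset, "g.45975G>A")
print({a: round(f, 2) for a, f in af.freqs.items()})
div = popgen_summary(af)
print(round(div.ho, 2), round(div.he, 2), round(div.ne, 2),
      round(div.pic, 2), div.pic_class)
res = hwe_test(dataset.genotype_counts("g.45975G>A"))
print(round(res.chi2, 2), round(res.p_chi2, 3))
```

prints

```
{'G': 0.85, 'A': 0.15}
0.75 0.25 1.34 0.22 low
2.77 0.096
```

i.e. at g.45975G>A the G allele is at 85%, expected homozygosity 0.75 gives
an effective allele number of 1.34, the marker is weakly informative
(PIC 0.22, "low"), and the genotype distribution is consistent with
Hardy–Weinberg equilibrium (χ² = 2.77, p = 0.096 > 0.05).

The same table for every locus, via the CLI:

```sh
candsnp popgen --genotypes genotypes.tsv --out popgen.tsv
```

Each `examples/*.py` script demonstrates one stage end to end (population
genetics, LD blocks, association with letters, relative expression,
sequence analysis, a full synthetic study) and prints what the numbers mean.

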
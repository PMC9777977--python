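# Methods

This note documents the models, conventions and design choices behind each
analysis stage, what the synthetic-data generators do and do not emulate,
and the package's known limitations.

## Data model

Genotypes are unphased diploid calls at biallelic SNPs, stored as
two-character strings with the reference allele first ("GA", never "AG" when
G is the reference); the missing token is `NN` and VCF `./.` maps to it.
Phase is never inferred at I/O time — ambiguity is resolved statistically in
the haplotype stage. Loci are identified by label (e.g. `g.45975G>A`, whose
suffix also encodes ref>alt); no genomic coordinates are modelled because
candidate-gene panels of this kind are reported by label, not assembly
position. Phenotype rows are (ewe, parity ∈ {1,2,3}, litter size ≥ 1); Ct
rows are (animal, tissue, gene, replicate, Ct > 0).

The bundled reference inputs (`candsnp.datasets`) are the published genotype
counts and litter-size summaries of the 433-ewe study. Two published count
conflicts are carried verbatim (149 vs 159 TC at g.45823T>C; 200 vs 190 CT
at g.5133C>T, with two count columns summing to 423 and 443 rather than
433); the package records both and resolves neither. `snp_count_dataset()`
expands counts into individuals locus by locus, so joint (multi-locus)
genotypes of that dataset carry no real linkage information.

## Diversity indices

With allele frequencies *p_i* estimated as allele count / 2n:

* Ho = Σ p_i² (expected homozygosity under random mating — not the observed
  homozygote fraction, which differs whenever the locus deviates from HWE),
* He = 1 − Ho, Ne = 1/Ho,
* PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j² (Botstein), classified low
  (< 0.25), moderate (0.25 ≤ PIC < 0.5) or high (≥ 0.5). The boundaries are
  conventionally written as strict inequalities on both sides; a tie rule is
  required and PIC = 0.25 is classed moderate.

All computation is in full precision; report rounding is half-away-from-zero
at two decimals and happens only at serialization (`report.round_half_up`).
Published two-decimal tables in this genre occasionally mix conventions —
for one bundled locus (g.440G>A) the printed Ne/PIC are consistent only with
frequencies rounded to two decimals *before* the index computation — so the
reproduction tests document that provenance explicitly rather than adopting
rounded-input arithmetic anywhere in the package.

## Hardy–Weinberg testing

The χ² test compares observed genotype counts with p²n, 2pqn, q²n from the
observed allele frequencies; df = (classes with E > 0) − 2 (1 for a fully
segregating biallelic locus). The exact test computes Levene's conditional
distribution of the heterozygote count given the minor-allele count, by full
enumeration in log-space, and sums the probabilities of all configurations
no more probable than the observed one (with a 1 + 1e−12 tie guard). The
exact test is preferred whenever an expected class count is small (the rare
homozygote at low minor-allele frequency); both are always reported.

## Haplotype EM and linkage disequilibrium

The EM treats each sample's multi-locus genotype as a mixture over its
compatible unordered haplotype pairs. The E-step weights pair (h₁, h₂)
proportionally to m·f(h₁)·f(h₂) with multiplicity m = 2 for heterozygous
pairs; a double heterozygote's two equally likely resolutions therefore get
weight 0.5 each with no arbitrary assignment. The M-step re-estimates
frequencies from expected counts. Initialisation is uniform, so the run is
deterministic; `seed` only drives optional random Dirichlet restarts.
Convergence: max |Δf| < 1e−8, capped at 1000 iterations; non-convergence
sets `converged=False` rather than raising. The log-likelihood is asserted
non-decreasing at every iteration. The locus cap is 4 (2⁴ haplotypes),
matching the largest haplotype span reported in this study design; samples
missing any requested locus are dropped listwise and logged.

D, D′ and r² follow the standard definitions (D′ normalised by
Dmax = min(p_A p_b, p_a p_B) for D > 0, min(p_A p_B, p_a p_b) for D < 0).
A monomorphic locus makes the coefficients undefined; the result is flagged,
not raised. Blocks use a documented D′-threshold rule — maximal runs of
contiguous same-gene loci whose adjacent pairs reach D′ ≥ 98% (default) —
instead of Gabriel confidence-interval blocks, which need genome-scale
marker density; 98% keeps sampling noise at n ≈ 433 from splitting truly
complete linkage. Runs are capped at 4 loci (the EM cap). Reported block
haplotypes are filtered at frequency ≥ 0.01.

## Litter-size association

The model Y = μ + parity + genotype + parity:genotype + e is fitted by
ordinary least squares on sum-to-zero (effects) coded design matrices. Term
tests are Type III: each term's SS is the SSE increase from deleting its
columns from the full design, which under effects coding matches the SPSS
GLM default. Empty parity×genotype cells make interaction columns
collinear; they are handled by pinv-based fitting (the rank deficit is
logged and reported as `dropped_columns`), not by re-parameterisation.
Degenerate data with zero residual variance report F = 0, p = 1 by
convention. Litter size here takes essentially two values (1 or 2 lambs),
so the Gaussian error assumption is an approximation adopted deliberately —
it is the standard analysis for this design; `fit_twin_logit` offers a
logistic alternative on the twin indicator, off by default. No
multiple-testing correction is applied across loci by default, matching
field practice for candidate-gene panels of ~10 SNPs.

Group tables report mean, SD and SEM (published tables of this kind are
ambiguous about which dispersion "±" denotes — the bundled study's values
are consistent with SD while its methods text says SEM — so both are
carried and report writers must label their choice). Compact letter
displays come from all pairwise two-sided t tests on the pooled one-way
residual variance (df = N − k); a Welch variant exists and falls back to
pooled, with a warning, when any group has n < 2. Letters are assigned by
maximal windows over mean-sorted groups that are pairwise non-significant;
groups differing at α never share a letter, with 'a' on the highest mean.
Unobserved genotype classes are reported as n = 0, "0.00 ± 0.00" rows with
no letter.

## Relative expression

Technical replicates are averaged (optionally median) per (animal, tissue,
gene) before any differencing; then ΔCt = Ct_target − Ct_reference per
animal, ΔΔCt = ΔCt − mean calibrator ΔCt, fold = 2^−ΔΔCt per animal.
Amplification efficiency is fixed at 2 (no efficiency correction — none
applies to this design). The default calibrator is the tissue with the
highest mean ΔCt (lowest expression), so folds are ≥ ~1; the choice only
rescales the axis. Two summaries are reported because they answer different
questions: `fold_point` = 2^(−mean ΔΔCt) is exactly 1 at the calibrator by
construction, while `fold_mean` ± SEM (arithmetic mean of per-animal folds,
the conventional bar-plot summary) exceeds 1 at the calibrator by Jensen's
inequality. Tissue comparison is one-way ANOVA on per-animal folds plus the
letter display; it requires ≥ 2 animals per tissue.

## Sequence utilities

ORF search reports every in-frame ATG→stop segment ≥ `min_len` on the
forward strand (reverse complement behind a flag, since the expected input
is cloned cDNA); coordinates are 0-based half-open and the length includes
the stop codon, so protein length = nt/3 − 1. Protein parameters follow
ProtParam conventions via Biopython (average isotopic masses; Bjellqvist pKa
set for pI; Kyte–Doolittle GRAVY; Guruprasad DIWV instability index);
the aliphatic index X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent
and the Asp+Glu / Arg+Lys counts are computed in-package. Instability > 40
classifies a protein unstable; GRAVY < 0 hydrophilic. Percent identity
counts matching columns among columns where neither sequence has a gap;
alignment itself is out of scope (a fixed-score global aligner is provided
for convenience only). Neighbor joining is Saitou–Nei with Q-matrix ties
broken on the smallest (row, col) pair and negative branch lengths clamped
to zero with the deficit moved to the sister branch; output is the standard
unrooted (trifurcating) Newick form.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: 433 ewes; the 10 study loci at their
published allele frequencies; genotypes drawn genotype-wise under HWE with
an optional inbreeding-like deviation F (P(Aa) = 2pq(1 − F)); blocked loci
drawn as two haplotypes per individual from a stated pool; parities uniform
on {1,2,3}; litter size 1 + Bernoulli(π) with logit π = logit(0.07) +
genotype/parity/interaction offsets, putting group means in the published
1.00–1.27 range; Ct tables of 13 tissues × 3 animals × 3 replicates with a
flat reference gene at Ct 18, target base Ct 27, a planted
spleen/uterus/ovary/lung advantage of 4/3/2.5/2 cycles, animal SD 0.1 and
replicate SD 0.15 cycles (typical qPCR technical noise). Every operation
draws from its own stream, derived as SeedSequence((seed, stream_id)) with
fixed per-operation ids, so outputs are bit-for-bit reproducible and adding
a stage never perturbs earlier draws.

Not emulated: relatedness/pedigree structure (real ewes from one flock are
related, which inflates association test sizes), genotyping error and
missingness mechanisms, selection, linked loci *between* genes, Ct
efficiency differences between genes, and animal-by-gene interactions.
Passing tests therefore certify the estimators against their own generative
assumptions, not against farm data.

## Numerical conventions and limitations

Tolerances: EM 1e−8 on frequencies; frequency-sum invariants at 1e−12;
symmetric-matrix check for NJ at 1e−9. The association F tests rely on a
Gaussian approximation to Bernoulli residuals — adequate at n ≈ 433 (the
simulated null rejection rate at α = 0.05 is within [0.03, 0.07]) but not
for very small groups. The exact HWE test enumerates all heterozygote
configurations, which is fast at candidate-gene scale but not intended for
biobank-scale allele counts. The count-expanded bundled dataset supports
single-locus statistics only. Sequence utilities validate strictly (IUPAC
nucleotides; 20 standard residues) and reject ambiguity codes beyond N.
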
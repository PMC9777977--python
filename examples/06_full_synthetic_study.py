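"""Generate a full synthetic study and run every analysis stage over it.

One seed drives four independent generator streams (genotypes, litter sizes,
Ct values, sequences), so the stages can be rerun or extended without
perturbing each other.  Equivalent shell pipeline:

    candsnp simulate --seed 42 --out-dir study/
    candsnp popgen --genotypes study/genotypes.tsv --out study/popgen.tsv
    candsnp assoc --genotypes study/genotypes.tsv \
                  --phenotypes study/phenotypes.tsv --out study/assoc.tsv
    candsnp expr --ct study/ct.tsv --target SMAD1 --out study/expr.tsv
"""

from candsnp import (
    SimulationConfig,
    join_genotypes_phenotypes,
    relative_expression,
    simulate_ct,
    simulate_genotypes,
    simulate_litter,
)
from candsnp.assoc import genotype_means
from candsnp.popgen import summarize_loci

cfg = SimulationConfig(seed=42)  # defaults: 433 ewes, 10 study loci, 13 tissues
genotypes = simulate_genotypes(cfg)
phenotypes = simulate_litter(genotypes, cfg)
ct = simulate_ct(cfg)

pg = summarize_loci(genotypes)
print("simulated diversity vs published frequencies (first 3 loci):")
print(pg[["locus", "ho", "he", "ne", "pic"]].head(3).round(3).to_string(index=False))

table = join_genotypes_phenotypes(genotypes, phenotypes, "g.14946G>A")
print(f"\nlitter size by g.14946G>A genotype (null model, mean ~ "
      f"{phenotypes['litter_size'].mean():.3f} overall):")
print(genotype_means(table).round(3).to_string())

rel = relative_expression(ct, "SMAD2", "GAPDH", calibrator="heart")
print(f"\nSMAD2 fold change in lung vs heart: "
      f"{rel.summary.loc['lung', 'fold_mean']:.2f} (planted 4.0)")

# Under the default (null) litter model all genotype groups share a letter;
# planting effects via SimulationConfig.genotype_effects turns this into a
# positive-control dataset for the association stage.
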
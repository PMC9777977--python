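"""Bundled reference inputs: the published SMAD1/2/3 Tibetan-sheep SNP study.

Genotype counts at 10 exonic SNPs in the SMAD1, SMAD2 and SMAD3 genes from a
population of 433 Tibetan ewes, plus the published per-genotype litter-size
summaries.  These printed counts are the desk-reproduction surface for the
population-genetic indices: every downstream quantity is computed from them
at run time.

Two published count inconsistencies are carried verbatim rather than
resolved: the genotype-frequency table prints 149 TC carriers at g.45823T>C
while the litter-size table implies 159 (29 + 159 + 245 = 433), and 200 CT
at g.5133C>T against 190.  ``LITTER_SIZE_GROUPS`` therefore has its own
``n`` column, which does not always match ``SNP_GENOTYPE_COUNTS``.
"""

from __future__ import annotations

import pandas as pd

from .io import GenotypeDataset, Locus

#: gene, locus label, exon, mutation type, canonical genotype -> count (n = 433)
SNP_GENOTYPE_COUNTS: list[dict] = [
    {"gene": "SMAD1", "locus": "g.45975G>A", "region": "exon 2",
     "mutation_type": "synonymous", "counts": {"GG": 318, "GA": 101, "AA": 14}},
    {"gene": "SMAD1", "locus": "g.440G>A", "region": "exon 7",
     "mutation_type": "synonymous", "counts": {"GG": 397, "GA": 36, "AA": 0}},
    {"gene": "SMAD1", "locus": "g.45823T>C", "region": "exon 2",
     "mutation_type": "synonymous", "counts": {"TT": 29, "TC": 149, "CC": 245}},
    {"gene": "SMAD1", "locus": "g.10729C>T", "region": "exon 5",
     "mutation_type": "synonymous", "counts": {"CC": 417, "CT": 16, "TT": 0}},
    {"gene": "SMAD2", "locus": "g.14946G>A", "region": "exon 8",
     "mutation_type": "synonymous", "counts": {"GG": 205, "GA": 193, "AA": 35}},
    {"gene": "SMAD3", "locus": "g.21447C>T", "region": "exon 7",
     "mutation_type": "synonymous", "counts": {"CC": 283, "CT": 135, "TT": 15}},
    {"gene": "SMAD3", "locus": "g.5133C>T", "region": "exon 4",
     "mutation_type": "synonymous", "counts": {"CC": 184, "CT": 200, "TT": 59}},
    {"gene": "SMAD3", "locus": "g.18965C>T", "region": "exon 6",
     "mutation_type": "synonymous", "counts": {"CC": 315, "CT": 108, "TT": 10}},
    {"gene": "SMAD3", "locus": "g.18905T>C", "region": "exon 6",
     "mutation_type": "missense", "counts": {"TT": 50, "TC": 184, "CC": 199}},
    {"gene": "SMAD3", "locus": "g.21551A>G", "region": "exon 7",
     "mutation_type": "synonymous", "counts": {"AA": 50, "AG": 186, "GG": 197}},
]

#: loci whose printed genotype counts are internally consistent across the
#: published tables (the two loci with conflicting counts are excluded)
CONSISTENT_LOCI: list[str] = [
    "g.45975G>A", "g.440G>A", "g.10729C>T", "g.14946G>A",
    "g.21447C>T", "g.18965C>T", "g.18905T>C", "g.21551A>G",
]

#: published per-genotype litter-size summaries (mean +/- dispersion as printed)
LITTER_SIZE_GROUPS: list[dict] = [
    {"locus": "g.45975G>A", "genotype": "GG", "n": 318, "mean": 1.07, "disp": 0.25},
    {"locus": "g.45975G>A", "genotype": "GA", "n": 101, "mean": 1.06, "disp": 0.24},
    {"locus": "g.45975G>A", "genotype": "AA", "n": 14, "mean": 1.14, "disp": 0.36},
    {"locus": "g.440G>A", "genotype": "GG", "n": 397, "mean": 1.07, "disp": 0.25},
    {"locus": "g.440G>A", "genotype": "GA", "n": 36, "mean": 1.11, "disp": 0.32},
    {"locus": "g.440G>A", "genotype": "AA", "n": 0, "mean": 0.00, "disp": 0.00},
    {"locus": "g.45823T>C", "genotype": "TT", "n": 29, "mean": 1.07, "disp": 0.26},
    {"locus": "g.45823T>C", "genotype": "TC", "n": 159, "mean": 1.05, "disp": 0.22},
    {"locus": "g.45823T>C", "genotype": "CC", "n": 245, "mean": 1.08, "disp": 0.27},
    {"locus": "g.10729C>T", "genotype": "CC", "n": 417, "mean": 1.07, "disp": 0.26},
    {"locus": "g.10729C>T", "genotype": "CT", "n": 16, "mean": 1.00, "disp": 0.00},
    {"locus": "g.10729C>T", "genotype": "TT", "n": 0, "mean": 0.00, "disp": 0.00},
    {"locus": "g.14946G>A", "genotype": "GG", "n": 205, "mean": 1.07, "disp": 0.25},
    {"locus": "g.14946G>A", "genotype": "GA", "n": 193, "mean": 1.08, "disp": 0.28},
    {"locus": "g.14946G>A", "genotype": "AA", "n": 35, "mean": 1.00, "disp": 0.00},
    {"locus": "g.21447C>T", "genotype": "CC", "n": 283, "mean": 1.06, "disp": 0.24},
    {"locus": "g.21447C>T", "genotype": "CT", "n": 135, "mean": 1.06, "disp": 0.24},
    {"locus": "g.21447C>T", "genotype": "TT", "n": 15, "mean": 1.27, "disp": 0.46},
    {"locus": "g.5133C>T", "genotype": "CC", "n": 184, "mean": 1.09, "disp": 0.28},
    {"locus": "g.5133C>T", "genotype": "CT", "n": 190, "mean": 1.04, "disp": 0.20},
    {"locus": "g.5133C>T", "genotype": "TT", "n": 59, "mean": 1.10, "disp": 0.30},
    {"locus": "g.18965C>T", "genotype": "CC", "n": 315, "mean": 1.07, "disp": 0.26},
    {"locus": "g.18965C>T", "genotype": "CT", "n": 108, "mean": 1.07, "disp": 0.26},
    {"locus": "g.18965C>T", "genotype": "TT", "n": 10, "mean": 1.00, "disp": 0.00},
    {"locus": "g.18905T>C", "genotype": "TT", "n": 50, "mean": 1.12, "disp": 0.33},
    {"locus": "g.18905T>C", "genotype": "TC", "n": 184, "mean": 1.05, "disp": 0.23},
    {"locus": "g.18905T>C", "genotype": "CC", "n": 199, "mean": 1.07, "disp": 0.26},
    {"locus": "g.21551A>G", "genotype": "AA", "n": 50, "mean": 1.12, "disp": 0.33},
    {"locus": "g.21551A>G", "genotype": "AG", "n": 186, "mean": 1.05, "disp": 0.23},
    {"locus": "g.21551A>G", "genotype": "GG", "n": 197, "mean": 1.07, "disp": 0.26},
]

#: the 13 sampled tissues (n = 3 animals, triplicate wells per gene)
TISSUES: list[str] = [
    "hypothalamus", "pituitary", "heart", "liver", "spleen", "lung", "kidney",
    "ovary", "uterus", "oviduct", "rumen", "duodenum", "longissimus dorsi",
]

TARGET_GENES: list[str] = ["SMAD1", "SMAD2", "SMAD3"]
REFERENCE_GENE: str = "GAPDH"


def study_loci() -> list[Locus]:
    """Locus metadata for the 10 study SNPs (alleles from the locus labels)."""
    out = []
    for rec in SNP_GENOTYPE_COUNTS:
        ref, alt = rec["locus"][-3], rec["locus"][-1]
        out.append(Locus(gene=rec["gene"], name=rec["locus"], ref_allele=ref,
                         alt_allele=alt, region=rec["region"],
                         mutation_type=rec["mutation_type"]))
    return out


def genotype_counts(locus: str) -> dict[str, int]:
    """Published genotype counts for one locus label."""
    for rec in SNP_GENOTYPE_COUNTS:
        if rec["locus"] == locus:
            return dict(rec["counts"])
    raise KeyError(locus)


def snp_count_dataset() -> GenotypeDataset:
    """Expand the published genotype counts into an individual-level dataset.

    Sample ids are ``ewe0001``..``ewe0433``; within each locus, genotypes are
    assigned to samples in canonical class order.  Loci are independent here
    (no joint genotypes were published), so only single-locus statistics of
    this dataset are meaningful.
    """
    loci = study_loci()
    n = max(sum(rec["counts"].values()) for rec in SNP_GENOTYPE_COUNTS)
    samples = [f"ewe{i + 1:04d}" for i in range(n)]
    cols = {}
    for rec in SNP_GENOTYPE_COUNTS:
        calls = []
        for gt, c in rec["counts"].items():
            calls.extend([gt] * c)
        calls.extend(["NN"] * (n - len(calls)))
        cols[rec["locus"]] = calls
    frame = pd.DataFrame(cols, index=pd.Index(samples, name="sample"))
    return GenotypeDataset(loci, frame)


def litter_size_table() -> pd.DataFrame:
    """Published litter-size group summaries as a DataFrame."""
    return pd.DataFrame(LITTER_SIZE_GROUPS)
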
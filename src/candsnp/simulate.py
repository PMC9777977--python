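"""Synthetic-data generators with the statistical structure of the study.

The defaults emulate the study conditions: 433 diploid ewes genotyped at the
10 exonic SMAD1/SMAD2/SMAD3 SNPs with the published allele frequencies,
litter sizes of 1 + Bernoulli(twin probability ~= 0.07) so group means fall
in the published 1.00-1.27 range, three parity classes, and a 13-tissue x
3-animal x triplicate Ct design with a flat reference gene.

Genotypes at independent loci are drawn genotype-wise with an optional
inbreeding-like Hardy-Weinberg deviation F:

    P(AA) = p^2 + Fpq,  P(Aa) = 2pq(1 - F),  P(aa) = q^2 + Fpq

Blocked loci are drawn as two haplotypes per individual from a stated pool
and collapsed to unphased genotypes.  Litter size uses a logistic twin
model: logit(pi) = logit(baseline) + genotype + parity + interaction
offsets.

Every stochastic call derives its generator from (seed, stream) via
``numpy.random.SeedSequence``, one fixed stream id per operation, so adding
a downstream stage never perturbs earlier draws and identical configs and
seeds are bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .io import GenotypeDataset, Locus

# fixed per-operation stream ids (the documented seed-splitting rule)
STREAM_GENOTYPES = 1
STREAM_LITTER = 2
STREAM_CT = 3
STREAM_SEQUENCE = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(stream))))


@dataclass
class SimLocus:
    """An independent simulated locus: metadata plus reference-allele frequency."""

    gene: str
    name: str
    ref_allele: str
    alt_allele: str
    p_ref: float

    def to_locus(self) -> Locus:
        return Locus(self.gene, self.name, self.ref_allele, self.alt_allele)


@dataclass
class SimBlock:
    """A haplotype block: loci drawn jointly from a haplotype frequency pool."""

    gene: str
    loci: list[Locus]
    pool: dict[str, float]  # haplotype allele-string -> frequency

    def __post_init__(self) -> None:
        total = sum(self.pool.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype pool sums to {total}, not 1")
        for hap in self.pool:
            if len(hap) != len(self.loci):
                raise ValueError(f"haplotype {hap!r} length != {len(self.loci)} loci")


def study_sim_loci() -> list[SimLocus]:
    """The 10 study loci with their published allele frequencies as truth."""
    out = []
    for rec in datasets.SNP_GENOTYPE_COUNTS:
        counts = rec["counts"]
        loc = next(l for l in datasets.study_loci() if l.name == rec["locus"])
        n = sum(counts.values())
        ref_count = sum(c * gt.count(loc.ref_allele) for gt, c in counts.items())
        out.append(SimLocus(loc.gene, loc.name, loc.ref_allele, loc.alt_allele,
                            p_ref=ref_count / (2 * n)))
    return out


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters (defaults are the study conditions)."""

    n_samples: int = 433
    loci: list[SimLocus] = field(default_factory=study_sim_loci)
    blocks: list[SimBlock] = field(default_factory=list)
    inbreeding_f: float = 0.0
    parity_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    twin_prob: float = 0.07                       # baseline P(litter = 2)
    genotype_effects: dict = field(default_factory=dict)   # locus -> {genotype: logit offset}
    parity_effects: dict = field(default_factory=dict)     # parity -> logit offset
    interaction_effects: dict = field(default_factory=dict)  # (locus, genotype, parity) -> offset
    tissues: list[str] = field(default_factory=lambda: list(datasets.TISSUES))
    n_animals: int = 3
    n_replicates: int = 3
    reference_gene: str = datasets.REFERENCE_GENE
    reference_ct: float = 18.0
    target_ct: dict = field(default_factory=dict)  # gene -> {tissue: mean Ct}
    animal_sd: float = 0.1
    replicate_sd: float = 0.15
    seed: int = 0


def default_target_ct(tissues: list[str] | None = None) -> dict:
    """A target-gene Ct profile with spleen/uterus/ovary/lung expressed highest.

    Base Ct 27 cycles; favoured tissues run 2-4 cycles lower (4-16x fold).
    """
    tissues = tissues or list(datasets.TISSUES)
    advantage = {"spleen": 4.0, "uterus": 3.0, "ovary": 2.5, "lung": 2.0}
    return {
        gene: {t: 27.0 - advantage.get(t, 0.0) for t in tissues}
        for gene in datasets.TARGET_GENES
    }


def simulate_genotypes(cfg: SimulationConfig, seed: int | None = None) -> GenotypeDataset:
    """Draw an unphased genotype dataset from the configured frequencies."""
    rng = _rng(cfg.seed if seed is None else seed, STREAM_GENOTYPES)
    n = cfg.n_samples
    samples = [f"ewe{i + 1:04d}" for i in range(n)]
    loci: list[Locus] = []
    cols: dict[str, list[str]] = {}
    f = cfg.inbreeding_f
    for sl in cfg.loci:
        p, q = sl.p_ref, 1.0 - sl.p_ref
        if p * q > 0 and not (-min(p, q) / max(p, q) <= f <= 1.0):
            raise ValueError(f"inbreeding F={f} infeasible for p={p}")
        probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        locus = sl.to_locus()
        draws = rng.choice(3, size=n, p=probs)
        labels = locus.genotype_labels
        loci.append(locus)
        cols[locus.name] = [labels[d] for d in draws]
    for block in cfg.blocks:
        haps = list(block.pool)
        hap_p = np.array([block.pool[h] for h in haps])
        h1 = rng.choice(len(haps), size=n, p=hap_p)
        h2 = rng.choice(len(haps), size=n, p=hap_p)
        for i, locus in enumerate(block.loci):
            loci.append(locus)
            cols[locus.name] = [
                locus.canonical_call(haps[a][i] + haps[b][i]) for a, b in zip(h1, h2)
            ]
    frame = pd.DataFrame(cols, index=pd.Index(samples, name="sample"))
    return GenotypeDataset(loci, frame)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def simulate_litter(
    dataset: GenotypeDataset, cfg: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate (sample, parity, litter_size) for every sample in ``dataset``.

    litter_size = 1 + Bernoulli(pi), logit pi = logit(baseline) + genotype
    + parity + interaction offsets.  A zero baseline with no offsets gives
    all-singleton litters.
    """
    rng = _rng(cfg.seed if seed is None else seed, STREAM_LITTER)
    n = dataset.n_samples
    parity = rng.choice([1, 2, 3], size=n, p=np.asarray(cfg.parity_probs))
    if cfg.twin_prob <= 0.0 and not cfg.genotype_effects and not cfg.parity_effects:
        pi = np.zeros(n)
    else:
        base = _logit(min(max(cfg.twin_prob, 1e-12), 1 - 1e-12))
        eta = np.full(n, base)
        for locus, offsets in cfg.genotype_effects.items():
            calls = dataset.calls[locus].to_numpy()
            eta += np.array([offsets.get(c, 0.0) for c in calls])
        for i, par in enumerate(parity):
            eta[i] += cfg.parity_effects.get(int(par), 0.0)
        for (locus, genotype, par), off in cfg.interaction_effects.items():
            mask = (dataset.calls[locus].to_numpy() == genotype) & (parity == par)
            eta[mask] += off
        pi = 1.0 / (1.0 + np.exp(-eta))
        if np.any(~np.isfinite(pi)) or np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("twin probability outside [0, 1] after offsets")
    litter = 1 + (rng.random(n) < pi).astype(int)
    return pd.DataFrame(
        {"sample": dataset.samples, "parity": parity.astype(int), "litter_size": litter}
    )


def simulate_ct(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate a long-format Ct table for targets plus the reference gene.

    Ct = gene/tissue mean + animal effect N(0, animal_sd) + replicate noise
    N(0, replicate_sd); the reference gene is flat across tissues.
    """
    rng = _rng(cfg.seed if seed is None else seed, STREAM_CT)
    target_ct = cfg.target_ct or default_target_ct(cfg.tissues)
    genes = list(target_ct) + [cfg.reference_gene]
    animals = [f"animal{i + 1}" for i in range(cfg.n_animals)]
    rows = []
    for tissue in cfg.tissues:
        for animal in animals:
            animal_effect = rng.normal(0.0, cfg.animal_sd) if cfg.animal_sd > 0 else 0.0
            for gene in genes:
                mean = (cfg.reference_ct if gene == cfg.reference_gene
                        else target_ct[gene][tissue])
                for rep in range(1, cfg.n_replicates + 1):
                    noise = rng.normal(0.0, cfg.replicate_sd) if cfg.replicate_sd > 0 else 0.0
                    rows.append(
                        {"animal": animal, "tissue": tissue, "gene": gene,
                         "replicate": rep, "ct": mean + animal_effect + noise}
                    )
    return pd.DataFrame(rows)


_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in ("TAA", "TAG", "TGA") and c != "ATG"]


def simulate_coding_sequence(
    orf_length: int, flank: int = 120, seed: int = 0
) -> tuple[str, int]:
    """A random coding sequence with one planted ATG..stop ORF.

    ``orf_length`` counts nucleotides including the stop codon and must be a
    multiple of 3 and >= 9.  Flanks are random but scrubbed of ATG triplets
    so the planted ORF is recoverable unambiguously on the forward strand.
    Returns (sequence, 0-based ORF start).
    """
    if orf_length % 3 != 0 or orf_length < 9:
        raise ValueError("orf_length must be a multiple of 3 and >= 9")
    rng = _rng(seed, STREAM_SEQUENCE)

    def scrubbed_flank(k: int) -> str:
        s = "".join(rng.choice(list("ACGT"), size=k))
        return s.replace("ATG", "ACG")

    n_internal = orf_length // 3 - 2
    internal = "".join(rng.choice(_SENSE_CODONS, size=n_internal))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    left = scrubbed_flank(flank)
    right = scrubbed_flank(flank)
    return left + "ATG" + internal + stop + right, flank
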
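"""EM haplotype-frequency estimation and linkage disequilibrium.

Unphased multi-locus genotypes are phase-ambiguous whenever a sample is
heterozygous at two or more loci.  Haplotype frequencies are estimated by the
classical expectation-maximisation algorithm: the E-step distributes each
genotype over its compatible ordered haplotype pairs in proportion to the
current frequency product, the M-step re-estimates frequencies from the
expected haplotype counts.  The log-likelihood is non-decreasing every
iteration (asserted), and with the default uniform initialisation the
algorithm is fully deterministic.

Pairwise disequilibrium for loci A/B with haplotype frequency ``p_AB``:

* ``D  = p_AB - p_A p_B``
* ``D' = |D| / D_max`` with ``D_max = min(p_A p_b, p_a p_B)`` for D > 0 and
  ``min(p_A p_B, p_a p_b)`` for D < 0; D' = 1 whenever at most three of the
  four gametes occur ("complete linkage")
* ``r^2 = D^2 / (p_A p_a p_B p_b)``

Blocks are reported by a documented D'-threshold rule (default 98%): maximal
runs of contiguous loci within a gene whose adjacent pairs all reach the
threshold.  This intentionally replaces Gabriel-style confidence-interval
block finding, which needs the genotyping-panel scale this design lacks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

MAX_BLOCK_LOCI = 4  # EM surface capped at 4 loci (2^4 haplotypes)


@dataclass
class HaplotypeFrequencies:
    """EM-estimated haplotype frequency spectrum over 2-4 loci."""

    loci: list[str]
    freqs: dict[str, float]  # allele string (one char per locus) -> frequency
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_samples: int  # complete (listwise) samples used

    def frequency(self, hap: str) -> float:
        return self.freqs.get(hap, 0.0)


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage-disequilibrium summary for one locus pair."""

    loci: tuple[str, str]
    d: float
    d_prime: float
    r2: float
    defined: bool  # False when either locus is monomorphic

    @property
    def d_prime_percent(self) -> int:
        return int(round(self.d_prime * 100))


@dataclass
class Block:
    """A run of contiguous loci in high LD, with its haplotype spectrum."""

    gene: str
    loci: list[str]
    rule: str
    haplotypes: dict[str, float]  # filtered at the reporting threshold


def _complete_genotype_rows(
    dataset: GenotypeDataset, loci: list[str]
) -> list[tuple[str, ...]]:
    sub = dataset.calls[loci]
    keep = (sub != MISSING).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("listwise deletion over %s: dropped %d samples", loci, dropped)
    return [tuple(row) for row in sub[keep].itertuples(index=False)]


def _expansions(genotype: tuple[str, ...]) -> list[tuple[tuple[str, ...], tuple[str, ...], int]]:
    """All unordered compatible haplotype pairs for a multi-locus genotype.

    Returns (hap1, hap2, multiplicity): multiplicity 2 for heterozygous pairs
    (two orderings), 1 for the fully homozygous genotype.  The first
    heterozygous locus is pinned to break the mirror symmetry.
    """
    het_idx = [i for i, call in enumerate(genotype) if call[0] != call[1]]
    base1 = [call[0] for call in genotype]
    base2 = [call[1] for call in genotype]
    if not het_idx:
        return [(tuple(base1), tuple(base2), 1)]
    out = []
    # the first het locus keeps its orientation; the rest vary freely
    for bits in itertools.product((0, 1), repeat=len(het_idx) - 1):
        h1, h2 = list(base1), list(base2)
        for i, bit in zip(het_idx[1:], bits):
            if bit:
                h1[i], h2[i] = h2[i], h1[i]
        out.append((tuple(h1), tuple(h2), 2))
    return out


def em_haplotype_frequencies(
    dataset: GenotypeDataset,
    loci: list[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    n_restarts: int = 0,
) -> HaplotypeFrequencies:
    """EM haplotype frequencies over 2-4 loci (listwise deletion of missing).

    Initialisation is the uniform haplotype distribution, so the result is
    deterministic; ``seed`` only drives the optional random restarts, whose
    best-likelihood solution is returned.
    """
    if not 2 <= len(loci) <= MAX_BLOCK_LOCI:
        raise ValueError(f"EM supports 2-{MAX_BLOCK_LOCI} loci, got {len(loci)}")
    for name in loci:
        dataset.locus(name)
    rows = _complete_genotype_rows(dataset, list(loci))
    if not rows:
        raise ValueError(f"no samples with complete genotypes at {loci}")

    # collapse identical genotypes and pre-expand once
    geno_counts: dict[tuple[str, ...], int] = {}
    for g in rows:
        geno_counts[g] = geno_counts.get(g, 0) + 1
    expansions = {g: _expansions(g) for g in geno_counts}

    hap_space = sorted({h for exp in expansions.values() for a, b, _ in exp for h in (a, b)})
    hap_index = {h: i for i, h in enumerate(hap_space)}
    n_hap = len(hap_space)
    n = len(rows)

    def run(f0: np.ndarray) -> tuple[np.ndarray, float, int, bool]:
        f = f0.copy()
        loglik_prev = -math.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            counts = np.zeros(n_hap)
            loglik = 0.0
            for g, c in geno_counts.items():
                exp = expansions[g]
                w = np.array([m * f[hap_index[a]] * f[hap_index[b]] for a, b, m in exp])
                tot = w.sum()
                if tot <= 0:  # genotype unexplained by current freqs: spread evenly
                    w = np.array([float(m) for *_ , m in exp])
                    tot = w.sum()
                    loglik += c * -745.0  # ~log of smallest positive double
                else:
                    loglik += c * math.log(tot)
                w = w / tot
                for (a, b, _m), wi in zip(exp, w):
                    counts[hap_index[a]] += c * wi
                    counts[hap_index[b]] += c * wi
            assert loglik >= loglik_prev - 1e-9, "EM log-likelihood decreased"
            loglik_prev = loglik
            f_new = counts / (2 * n)
            if np.max(np.abs(f_new - f)) < tol:
                f = f_new
                converged = True
                break
            f = f_new
        return f, loglik_prev, it, converged

    starts = [np.full(n_hap, 1.0 / n_hap)]
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            d = rng.dirichlet(np.ones(n_hap))
            starts.append(d)
    best = None
    for f0 in starts:
        result = run(f0)
        if best is None or result[1] > best[1]:
            best = result
    f, loglik, iters, converged = best
    if not converged:
        logger.warning("EM did not converge in %d iterations over %s", max_iter, loci)
    freqs = {"".join(h): float(f[i]) for h, i in hap_index.items() if f[i] > 0}
    return HaplotypeFrequencies(
        loci=list(loci),
        freqs=freqs,
        log_likelihood=float(loglik),
        n_iterations=iters,
        converged=converged,
        n_samples=n,
    )


def pairwise_ld(h: HaplotypeFrequencies) -> LDStats:
    """D, D' and r^2 from a two-locus haplotype frequency spectrum.

    Monomorphic loci make the coefficients undefined; the result is then
    flagged (``defined=False``) with NaN statistics rather than raising.
    """
    if len(h.loci) != 2:
        raise ValueError("pairwise_ld needs a 2-locus haplotype spectrum")
    alleles_a = sorted({hap[0] for hap in h.freqs})
    alleles_b = sorted({hap[1] for hap in h.freqs})
    pair = tuple(h.loci)
    if len(alleles_a) < 2 or len(alleles_b) < 2:
        return LDStats(pair, math.nan, math.nan, math.nan, defined=False)
    a, a2 = alleles_a[0], alleles_a[1]
    b, b2 = alleles_b[0], alleles_b[1]
    p_ab = h.frequency(a + b)
    p_a = h.frequency(a + b) + h.frequency(a + b2)
    p_b = h.frequency(a + b) + h.frequency(a2 + b)
    d = p_ab - p_a * p_b
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    d_prime = min(d_prime, 1.0)  # guard rounding overshoot
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return LDStats(pair, float(d), float(d_prime), float(min(r2, 1.0)), defined=True)


def ld_matrix(dataset: GenotypeDataset, loci: list[str] | None = None, **em_kwargs) -> pd.DataFrame:
    """Upper-triangular D' (fraction) matrix over the requested loci."""
    names = loci if loci is not None else dataset.locus_names
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            h = em_haplotype_frequencies(dataset, [a, b], **em_kwargs)
            out.loc[a, b] = pairwise_ld(h).d_prime
    return out


def find_blocks(
    dataset: GenotypeDataset,
    gene: str,
    dprime_threshold: float = 98.0,
    reporting_threshold: float = 0.01,
    **em_kwargs,
) -> list[Block]:
    """Greedy contiguous D'-threshold blocks for one gene.

    Adjacent locus pairs (in dataset order) with D' x 100 >= the threshold are
    chained into maximal runs; runs longer than :data:`MAX_BLOCK_LOCI` loci
    are split.  Each block carries EM haplotype frequencies filtered at the
    reporting threshold.
    """
    loci = [l.name for l in dataset.loci_for_gene(gene)]
    if len(loci) < 2:
        raise ValueError(f"gene {gene!r} has fewer than 2 loci")
    linked: list[bool] = []
    for a, b in zip(loci, loci[1:]):
        stats = pairwise_ld(em_haplotype_frequencies(dataset, [a, b], **em_kwargs))
        linked.append(stats.defined and stats.d_prime * 100 >= dprime_threshold)
    blocks: list[Block] = []
    run: list[str] = [loci[0]]
    for i, is_linked in enumerate(linked):
        if is_linked and len(run) < MAX_BLOCK_LOCI:
            run.append(loci[i + 1])
        else:
            if len(run) >= 2:
                blocks.append(_make_block(dataset, gene, run, dprime_threshold,
                                          reporting_threshold, em_kwargs))
            run = [loci[i + 1]]
    if len(run) >= 2:
        blocks.append(_make_block(dataset, gene, run, dprime_threshold,
                                  reporting_threshold, em_kwargs))
    return blocks


def _make_block(dataset, gene, run, dprime_threshold, reporting_threshold, em_kwargs) -> Block:
    h = em_haplotype_frequencies(dataset, run, **em_kwargs)
    haps = {k: v for k, v in sorted(h.freqs.items(), key=lambda kv: -kv[1])
            if v >= reporting_threshold}
    return Block(
        gene=gene,
        loci=list(run),
        rule=f"adjacent D' >= {dprime_threshold}%",
        haplotypes=haps,
    )
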
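"""EM haplotype frequencies, pairwise D'/r^2 and block finding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from candsnp import (
    GenotypeDataset,
    Locus,
    SimBlock,
    SimulationConfig,
    em_haplotype_frequencies,
    find_blocks,
    pairwise_ld,
    simulate_genotypes,
)
from candsnp.ld import HaplotypeFrequencies

from conftest import make_dataset


def hap_freqs(freqs: dict[str, float], loci=("a", "b")) -> HaplotypeFrequencies:
    return HaplotypeFrequencies(
        loci=list(loci), freqs=freqs, log_likelihood=0.0, n_iterations=0,
        converged=True, n_samples=0,
    )


# ---------------------------------------------------------------------------
# independent oracle: zooming grid maximization of the 2-locus multinomial
# likelihood over the haplotype-frequency simplex
# ---------------------------------------------------------------------------

def _genotype_loglik(genotypes, f):
    """Multinomial log-likelihood of unphased 2-locus genotypes.

    ``f`` maps the four haplotypes AB, Ab, aB, ab (encoded 0..3 as
    2*allele1 + allele2) to frequencies.  Double heterozygotes sum both
    phase resolutions.
    """
    ll = 0.0
    for (g1, g2), count in genotypes.items():
        # g = (n_alt at locus1, n_alt at locus2), each in {0,1,2}
        pairs = []
        a_alleles = [0, 0] if g1 == 0 else [1, 1] if g1 == 2 else [0, 1]
        b_alleles = [0, 0] if g2 == 0 else [1, 1] if g2 == 2 else [0, 1]
        seen = set()
        for b_perm in ({tuple(b_alleles), tuple(b_alleles[::-1])}):
            h1 = 2 * a_alleles[0] + b_perm[0]
            h2 = 2 * a_alleles[1] + b_perm[1]
            key = (min(h1, h2), max(h1, h2))
            if key in seen:
                continue
            seen.add(key)
            mult = 1 if h1 == h2 else 2
            pairs.append(mult * f[h1] * f[h2])
        p = sum(pairs)
        if p <= 0:
            return -math.inf
        ll += count * math.log(p)
    return ll


def grid_max_likelihood(genotypes, step=0.02, zooms=4):
    """Exhaustive grid search over the 3-simplex, repeatedly zoomed."""
    best_f, best_ll = None, -math.inf
    lo = np.zeros(4)
    hi = np.ones(4)
    for zoom in range(zooms + 1):
        grids = [np.arange(lo[i], hi[i] + step / 2, step) for i in range(3)]
        for f1 in grids[0]:
            for f2 in grids[1]:
                if f1 + f2 > 1 + 1e-9:
                    break
                for f3 in grids[2]:
                    f4 = 1.0 - f1 - f2 - f3
                    if f4 < -1e-9:
                        break
                    f = (f1, f2, f3, max(f4, 0.0))
                    ll = _genotype_loglik(genotypes, f)
                    if ll > best_ll:
                        best_ll, best_f = ll, f
        lo = np.clip(np.array(best_f) - 2 * step, 0, 1)
        hi = np.clip(np.array(best_f) + 2 * step, 0, 1)
        step /= 5
    return dict(zip(["AB", "Ab", "aB", "ab"], best_f)), best_ll


def _encode(dataset, loci):
    """Collapse a 2-locus dataset to {(n_alt1, n_alt2): count}."""
    out = {}
    l1, l2 = (dataset.locus(n) for n in loci)
    for _, row in dataset.calls[list(loci)].iterrows():
        g = (row[loci[0]].count(l1.alt_allele), row[loci[1]].count(l2.alt_allele))
        out[g] = out.get(g, 0) + 1
    return out


class TestEM:
    def test_unambiguous_phase_equals_gamete_counting(self):
        # nobody heterozygous at >= 2 loci: haplotypes directly countable
        d = make_dataset({"a": ["AA", "AA", "GG", "AG"], "b": ["CC", "CT", "CC", "CC"]})
        h = em_haplotype_frequencies(d, ["a", "b"])
        # gametes: AA/CC -> 2 AC; AA/CT -> AC + AT; GG/CC -> 2 GC; AG/CC -> AC + GC
        assert h.freqs["AC"] == pytest.approx(4 / 8)
        assert h.freqs["AT"] == pytest.approx(1 / 8)
        assert h.freqs["GC"] == pytest.approx(3 / 8)

    def test_matches_grid_likelihood_maximization_on_20_samples(self, two_locus_dataset):
        h = em_haplotype_frequencies(two_locus_dataset, ["a", "b"], tol=1e-12)
        genotypes = _encode(two_locus_dataset, ["a", "b"])
        oracle, oracle_ll = grid_max_likelihood(genotypes)
        key = {"AB": "AC", "Ab": "AT", "aB": "GC", "ab": "GT"}
        for hap4, hap in key.items():
            assert h.freqs.get(hap, 0.0) == pytest.approx(oracle[hap4], abs=1e-4)

    def test_parameter_recovery_from_four_snp_haplotype_pool(self):
        pool = {"CCCG": 0.59, "CCTG": 0.23, "CTCG": 0.20}
        total = sum(pool.values())
        pool = {k: v / total for k, v in pool.items()}
        loci = [Locus("SMAD3", f"l{i}", r, a) for i, (r, a) in
                enumerate([("C", "T"), ("C", "T"), ("C", "T"), ("A", "G")])]
        cfg = SimulationConfig(n_samples=433, loci=[],
                               blocks=[SimBlock("SMAD3", loci, pool)], seed=11)
        d = simulate_genotypes(cfg)
        h = em_haplotype_frequencies(d, [l.name for l in loci])
        for hap, truth in pool.items():
            assert h.frequency(hap) == pytest.approx(truth, abs=0.03)

    def test_estimates_converge_to_truth_with_sample_size(self):
        pool = {"AC": 0.5, "AT": 0.3, "GC": 0.2}
        loci = [Locus("G", "x", "A", "G"), Locus("G", "y", "C", "T")]
        errs = {}
        for n in (100, 1000):
            cfg = SimulationConfig(n_samples=n, loci=[],
                                   blocks=[SimBlock("G", loci, pool)], seed=5)
            d = simulate_genotypes(cfg)
            h = em_haplotype_frequencies(d, ["x", "y"])
            errs[n] = max(abs(h.frequency(k) - v) for k, v in pool.items())
        assert errs[100] < 0.08
        assert errs[1000] < 0.03

    def test_loglik_reported_and_restarts_agree_with_uniform_start(self, two_locus_dataset):
        h0 = em_haplotype_frequencies(two_locus_dataset, ["a", "b"])
        h5 = em_haplotype_frequencies(two_locus_dataset, ["a", "b"], seed=3, n_restarts=5)
        assert h5.log_likelihood >= h0.log_likelihood - 1e-9
        for hap, f in h0.freqs.items():
            assert h5.frequency(hap) == pytest.approx(f, abs=1e-5)

    def test_more_than_four_loci_rejected(self, study_counts_dataset):
        with pytest.raises(ValueError, match="2-4"):
            em_haplotype_frequencies(study_counts_dataset,
                                     study_counts_dataset.locus_names[:5])

    def test_no_complete_samples_is_an_error(self):
        d = make_dataset({"a": ["AA", "NN"], "b": ["NN", "CC"]})
        with pytest.raises(ValueError, match="complete"):
            em_haplotype_frequencies(d, ["a", "b"])


class TestPairwiseLD:
    def test_two_haplotype_spectrum_is_complete_disequilibrium(self):
        s = pairwise_ld(hap_freqs({"AB": 0.5, "ab": 0.5}))
        assert s.d == pytest.approx(0.25)
        assert s.d_prime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_independent_loci_have_zero_coefficients(self):
        f = {"AB": 0.6 * 0.7, "Ab": 0.6 * 0.3, "aB": 0.4 * 0.7, "ab": 0.4 * 0.3}
        s = pairwise_ld(hap_freqs(f))
        assert s.d == pytest.approx(0.0, abs=1e-12)
        assert s.d_prime == pytest.approx(0.0, abs=1e-9)
        assert s.r2 == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_example(self):
        s = pairwise_ld(hap_freqs({"AB": 0.6, "Ab": 0.2, "aB": 0.15, "ab": 0.05}))
        assert s.d == pytest.approx(0.6 - 0.8 * 0.75)
        assert s.d_prime == pytest.approx(0.0)

    def test_missing_gamete_class_forces_complete_dprime(self):
        # D' = 1 whenever at most 3 of the 4 gametes occur
        s = pairwise_ld(hap_freqs({"AB": 0.5, "Ab": 0.3, "aB": 0.2}))
        assert s.d_prime == pytest.approx(1.0)

    def test_monomorphic_locus_flagged_not_raised(self):
        s = pairwise_ld(hap_freqs({"AB": 0.7, "Ab": 0.3}))
        assert not s.defined and math.isnan(s.d_prime)

    @pytest.mark.parametrize("seed", range(5))
    def test_coefficients_bounded_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4))
        s = pairwise_ld(hap_freqs(dict(zip(["AB", "Ab", "aB", "ab"], f))))
        assert 0.0 <= s.d_prime <= 1.0
        assert 0.0 <= s.r2 <= 1.0


class TestBlocks:
    def _blocked_dataset(self, seed=2):
        l = lambda name: Locus("SMAD1", name, "A", "G")
        blocks = [
            SimBlock("SMAD1", [l("p"), l("q")], {"AA": 0.6, "GG": 0.4}),
            SimBlock("SMAD1", [l("r"), l("s")], {"AG": 0.7, "GA": 0.3}),
        ]
        cfg = SimulationConfig(n_samples=433, loci=[], blocks=blocks, seed=seed)
        return simulate_genotypes(cfg)

    def test_two_complete_blocks_found(self):
        d = self._blocked_dataset()
        blocks = find_blocks(d, "SMAD1", dprime_threshold=98.0)
        assert [b.loci for b in blocks] == [["p", "q"], ["r", "s"]]
        # within-block haplotype spectra have at most 3 gametes each
        for b in blocks:
            assert len(b.haplotypes) <= 3

    def test_independent_loci_yield_no_blocks(self):
        from candsnp.simulate import SimLocus

        cfg = SimulationConfig(
            n_samples=800,
            loci=[SimLocus("SMAD2", f"i{k}", "A", "G", 0.5) for k in range(3)],
            seed=9,
        )
        d = simulate_genotypes(cfg)
        assert find_blocks(d, "SMAD2", dprime_threshold=98.0) == []

    def test_zero_threshold_spans_contiguous_loci(self):
        d = self._blocked_dataset()
        blocks = find_blocks(d, "SMAD1", dprime_threshold=0.0)
        assert blocks[0].loci == ["p", "q", "r", "s"]

    def test_single_locus_gene_is_an_error(self):
        d = make_dataset({"only": ["AA", "AG"]}, genes={"only": "SMAD2"})
        with pytest.raises(ValueError, match="fewer than 2"):
            find_blocks(d, "SMAD2")
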
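"""Per-locus population-genetic indices and Hardy-Weinberg testing.

For a locus with allele frequencies :math:`p_i` under random mating the
classical single-locus diversity indices are

* gene homozygosity  ``Ho = sum p_i^2``  (expected, not the observed
  homozygote fraction),
* gene heterozygosity  ``He = 1 - Ho``,
* effective allele number  ``Ne = 1 / Ho``  (the number of equifrequent
  alleles that would give the same heterozygosity), and
* polymorphism information content (Botstein)
  ``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``,
  classified low (< 0.25), moderate (0.25-0.5) or high (>= 0.5).

Hardy-Weinberg equilibrium is tested both by the df=1 chi-square
goodness-of-fit on the three genotype classes and by the exact conditional
test (probability of the heterozygote count given the allele counts, summing
over all configurations no more probable than the observed one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset, Locus
from .report import round_half_up


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele and genotype frequencies at one biallelic locus."""

    locus: str
    freqs: dict[str, float]           # allele -> frequency
    n_typed: int                      # non-missing diploid samples
    genotype_counts: dict[str, int]   # canonical genotype label -> count

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative allele frequency")

    @property
    def genotype_freqs(self) -> dict[str, float]:
        return {g: c / self.n_typed for g, c in self.genotype_counts.items()}


@dataclass(frozen=True)
class DiversityStats:
    """Single-locus diversity summary (Ho, He, Ne, PIC and PIC class)."""

    locus: str
    ho: float
    he: float
    ne: float
    pic: float
    pic_class: str  # low / moderate / high


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg test result for one biallelic locus."""

    locus: str
    chi2: float
    df: int
    p_chi2: float
    p_exact: float | None
    expected: dict[str, float]  # genotype label -> expected count


def allele_frequencies_from_counts(
    counts: Mapping[str, int], locus: Locus | None = None, name: str = ""
) -> AlleleFrequencies:
    """Allele frequencies from genotype counts keyed by two-letter labels.

    ``p_A = (2 N_AA + N_Aa) / (2 n)``.  The locus argument is used only for
    the name and canonical label ordering; counts may use any label order.
    """
    allele_counts: dict[str, int] = {}
    n = 0
    for label, c in counts.items():
        if len(label) != 2:
            raise ValueError(f"genotype label {label!r} is not two characters")
        n += int(c)
        for a in label:
            allele_counts[a] = allele_counts.get(a, 0) + int(c)
    if n == 0:
        raise ValueError("no typed samples")
    freqs = {a: c / (2 * n) for a, c in allele_counts.items()}
    return AlleleFrequencies(
        locus=locus.name if locus else name,
        freqs=freqs,
        n_typed=n,
        genotype_counts={k: int(v) for k, v in counts.items()},
    )


def allele_frequencies(dataset: GenotypeDataset, locus: str) -> AlleleFrequencies:
    """Allele frequencies at ``locus`` from non-missing calls in ``dataset``."""
    counts = dataset.genotype_counts(locus)
    if sum(counts.values()) == 0:
        raise ValueError(f"all calls missing at locus {locus!r}")
    loc = dataset.locus(locus)
    # guarantee both alleles appear in the frequency map even when absent
    af = allele_frequencies_from_counts(counts, locus=loc)
    freqs = dict(af.freqs)
    for a in loc.alleles:
        freqs.setdefault(a, 0.0)
    return AlleleFrequencies(af.locus, freqs, af.n_typed, af.genotype_counts)


def popgen_summary(freqs: AlleleFrequencies) -> DiversityStats:
    """Ho/He/Ne/PIC from allele frequencies (full precision, no rounding)."""
    p = np.asarray(list(freqs.freqs.values()), dtype=float)
    ho = float(np.sum(p**2))
    he = 1.0 - ho
    ne = 1.0 / ho
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    pic = he - cross
    if pic < 0.25:
        pic_class = "low"
    elif pic < 0.5:
        pic_class = "moderate"  # PIC = 0.25 exactly classed moderate (tie rule)
    else:
        pic_class = "high"
    return DiversityStats(freqs.locus, ho=ho, he=he, ne=ne, pic=pic, pic_class=pic_class)


# ---------------------------------------------------------------------------
# Hardy-Weinberg testing
# ---------------------------------------------------------------------------


def _split_counts(counts: Mapping[str, int]) -> tuple[int, int, int, str, str]:
    """Return (n_hom_major, n_het, n_hom_minor, major, minor) from labels."""
    homs = {lab: c for lab, c in counts.items() if lab[0] == lab[1]}
    hets = {lab: c for lab, c in counts.items() if lab[0] != lab[1]}
    if len(hets) > 1:
        raise ValueError(f"more than one heterozygote class: {sorted(hets)}")
    alleles: dict[str, int] = {}
    for lab, c in counts.items():
        for a in lab:
            alleles[a] = alleles.get(a, 0) + int(c)
    if len(alleles) > 2:
        raise ValueError(f"more than two alleles: {sorted(alleles)}")
    ordered = sorted(alleles, key=lambda a: (-alleles[a], a))
    if len(ordered) == 1:
        ordered.append(next(iter(hets))[1] if hets else ordered[0])
    major, minor = ordered[0], ordered[-1]
    n_het = next(iter(hets.values()), 0)
    n_major = homs.get(major + major, 0)
    n_minor = homs.get(minor + minor, 0) if minor != major else 0
    return int(n_major), int(n_het), int(n_minor), major, minor


def exact_hwe_pvalue(n_het_obs: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg p-value (full enumeration).

    Conditions on the observed minor-allele count; sums the probability of
    every heterozygote-count configuration whose conditional probability does
    not exceed the observed one.
    """
    n = n_het_obs + n_hom1 + n_hom2
    n_minor = 2 * min(n_hom1, n_hom2) + n_het_obs
    if n_minor == 0:
        return 1.0
    lgam = math.lgamma

    def log_prob(n_het: int) -> float:
        n_hom_minor = (n_minor - n_het) // 2
        n_hom_major = n - n_het - n_hom_minor
        # P(het = n_het | n, n_minor), Levene's conditional distribution
        return (
            n_het * math.log(2)
            + lgam(n + 1)
            - lgam(n_het + 1)
            - lgam(n_hom_minor + 1)
            - lgam(n_hom_major + 1)
            + lgam(n_minor + 1)
            + lgam(2 * n - n_minor + 1)
            - lgam(2 * n + 1)
        )

    feasible = [
        h for h in range(n_minor % 2, n_minor + 1, 2)
        if (n_minor - h) // 2 >= 0 and n - h - (n_minor - h) // 2 >= 0
    ]
    probs = {h: math.exp(log_prob(h)) for h in feasible}
    p_obs = probs[n_het_obs]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))))


def hwe_test(
    counts: Mapping[str, int], method: str = "both", locus_name: str = ""
) -> HWEResult:
    """Hardy-Weinberg equilibrium test from biallelic genotype counts.

    ``method`` is ``"chi2"``, ``"exact"`` or ``"both"``.  The chi-square
    statistic is ``sum (O-E)^2 / E`` over the three genotype classes with
    expectations from the observed allele frequencies; df = (classes with
    E > 0) - 2.  The exact test fully enumerates heterozygote counts.
    """
    n_major, n_het, n_minor, major, minor = _split_counts(counts)
    n = n_major + n_het + n_minor
    if n == 0:
        raise ValueError("no typed samples")
    p = (2 * n_major + n_het) / (2 * n)
    q = 1.0 - p
    expected = {
        major + major: p * p * n,
        major + minor: 2 * p * q * n,
        minor + minor: q * q * n,
    }
    observed = {major + major: n_major, major + minor: n_het, minor + minor: n_minor}
    chi2 = 0.0
    n_classes = 0
    for g, e in expected.items():
        o = observed[g]
        if e > 0:
            chi2 += (o - e) ** 2 / e
            n_classes += 1
        elif o > 0:
            raise ValueError(f"genotype {g} observed {o} times but expected 0")
    df = max(n_classes - 2, 1)
    p_chi2 = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    p_exact = None
    if method in ("exact", "both"):
        p_exact = exact_hwe_pvalue(n_het, n_major, n_minor)
    if method == "exact":
        chi2_out, p_chi2_out = chi2, p_chi2  # still informative; keep both
    return HWEResult(
        locus=locus_name, chi2=float(chi2), df=df, p_chi2=p_chi2,
        p_exact=p_exact, expected=expected,
    )


def summarize_loci(dataset: GenotypeDataset) -> pd.DataFrame:
    """Full-precision per-locus summary table (one row per locus).

    Columns: gene, locus, genotype counts/frequencies, allele frequencies,
    Ho, He, Ne, PIC, PIC class, chi2, p_chi2, p_exact.
    """
    rows = []
    for locus in dataset.loci:
        af = allele_frequencies(dataset, locus.name)
        div = popgen_summary(af)
        hwe = hwe_test(af.genotype_counts, locus_name=locus.name)
        labels = locus.genotype_labels
        rows.append(
            {
                "gene": locus.gene,
                "locus": locus.name,
                "n_typed": af.n_typed,
                **{f"n_{g}": af.genotype_counts.get(g, 0) for g in labels},
                **{f"freq_{a}": af.freqs[a] for a in locus.alleles},
                "ho": div.ho,
                "he": div.he,
                "ne": div.ne,
                "pic": div.pic,
                "pic_class": div.pic_class,
                "chi2": hwe.chi2,
                "p_chi2": hwe.p_chi2,
                "p_exact": hwe.p_exact,
            }
        )
    return pd.DataFrame(rows)


def rounded_summary(dataset: GenotypeDataset, ndigits: int = 2) -> pd.DataFrame:
    """Report-style summary rounded half-away-from-zero at serialization."""
    df = summarize_loci(dataset)
    out = df.copy()
    for col in ("ho", "he", "ne", "pic", "chi2"):
        out[col] = [round_half_up(v, ndigits) for v in df[col]]
    for col in [c for c in df.columns if c.startswith("freq_")]:
        out[col] = [round_half_up(v, ndigits) for v in df[col]]
    return out
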
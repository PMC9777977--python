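"""Genotype, phenotype and qPCR-Ct table I/O and the shared data model.

The central object is :class:`GenotypeDataset`: a samples x loci table of
unphased diploid genotype calls at biallelic SNPs.  Calls are two-character
strings over each locus's reference/alternate alleles ("GA"), canonicalised
so the reference allele comes first; the missing token is ``"NN"``.  Phase is
never inferred at I/O time — it belongs to the haplotype/LD stage.

Phenotype tables (ewe, parity, litter size) and Ct tables (animal, tissue,
gene, replicate, Ct) are validated pandas DataFrames; loci carry their gene,
exon and mutation-type annotation but no genomic coordinates, since loci in
this kind of candidate-gene study are identified by label (``g.45975G>A``),
not assembly position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-genotype token in TSV files; VCF "./." maps onto it.
MISSING = "NN"

_BASES = set("ACGT")
# locus labels of the form "g.45975G>A" encode ref>alt
_NAME_ALLELES_RE = re.compile(r"([ACGT])>([ACGT])\s*$")


class ValidationError(ValueError):
    """A table violated the data model (bad allele, duplicate id, range error)."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with its annotation.

    ``mutation_type`` is one of ``{"synonymous", "missense", "other"}``;
    ``region`` is free text (typically the exon number).
    """

    gene: str
    name: str
    ref_allele: str
    alt_allele: str
    region: str = ""
    mutation_type: str = "other"

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in _BASES:
                raise ValidationError(
                    f"locus {self.name!r}: allele {a!r} is not a single A/C/G/T base"
                )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"locus {self.name!r}: ref and alt alleles are equal")
        if self.mutation_type not in {"synonymous", "missense", "other"}:
            raise ValidationError(
                f"locus {self.name!r}: unknown mutation_type {self.mutation_type!r}"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """Canonical genotype labels: ref-hom, het (ref first), alt-hom."""
        r, a = self.ref_allele, self.alt_allele
        return (r + r, r + a, a + a)

    def canonical_call(self, call: str) -> str:
        """Canonicalise a two-character call (e.g. "TC" -> "CT" if C is ref)."""
        if call == MISSING:
            return MISSING
        if len(call) != 2 or any(c not in (self.ref_allele, self.alt_allele) for c in call):
            raise ValidationError(
                f"locus {self.name!r}: call {call!r} uses alleles outside "
                f"{{{self.ref_allele}, {self.alt_allele}}} (or is not 2 characters)"
            )
        if call[0] == self.alt_allele and call[1] == self.ref_allele:
            return call[1] + call[0]
        return call


def _infer_locus(name: str, calls: Iterable[str], gene: str = "") -> Locus:
    """Build a Locus from a column: alleles from the ``X>Y`` suffix of the
    label when present, otherwise ref = most frequent observed allele."""
    m = _NAME_ALLELES_RE.search(name)
    if m:
        return Locus(gene=gene, name=name, ref_allele=m.group(1), alt_allele=m.group(2))
    counts: dict[str, int] = {}
    for call in calls:
        if call == MISSING:
            continue
        for c in str(call):
            counts[c] = counts.get(c, 0) + 1
    bad = set(counts) - _BASES
    if bad:
        raise ValidationError(f"locus {name!r}: non-nucleotide alleles {sorted(bad)}")
    if len(counts) > 2:
        raise ValidationError(f"locus {name!r}: more than two alleles {sorted(counts)}")
    if not counts:
        raise ValidationError(f"locus {name!r}: all calls missing, cannot infer alleles")
    ordered = sorted(counts, key=lambda a: (-counts[a], a))
    if len(ordered) == 1:  # monomorphic column: invent a distinct alt
        alt = next(b for b in "ACGT" if b != ordered[0])
        ordered.append(alt)
    return Locus(gene=gene, name=name, ref_allele=ordered[0], alt_allele=ordered[1])


class GenotypeDataset:
    """Samples x biallelic loci, unordered diploid calls with missing support.

    ``calls`` is a DataFrame indexed by sample id with one column per locus
    name, every cell a canonical two-character call or :data:`MISSING`.
    """

    def __init__(self, loci: Sequence[Locus], calls: pd.DataFrame):
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate locus names")
        if calls.index.duplicated().any():
            dupes = calls.index[calls.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if list(calls.columns) != names:
            raise ValidationError("calls columns do not match locus names")
        self.loci: list[Locus] = list(loci)
        self._by_name = {l.name: l for l in self.loci}
        canon = calls.copy()
        for locus in self.loci:
            col = canon[locus.name].astype(str)
            try:
                canon[locus.name] = [locus.canonical_call(c) for c in col]
            except ValidationError as exc:
                # re-raise naming the first offending sample
                for sample, c in zip(canon.index, col):
                    try:
                        locus.canonical_call(c)
                    except ValidationError:
                        raise ValidationError(f"sample {sample!r}: {exc}") from None
                raise
        self.calls: pd.DataFrame = canon

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_samples(self) -> int:
        return len(self.calls.index)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> Locus:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown locus {name!r}; have {self.locus_names}") from None

    def loci_for_gene(self, gene: str) -> list[Locus]:
        return [l for l in self.loci if l.gene == gene]

    def genotype_counts(self, name: str) -> dict[str, int]:
        """Counts of the three canonical genotype classes (missing excluded)."""
        locus = self.locus(name)
        col = self.calls[name]
        out = {g: 0 for g in locus.genotype_labels}
        for call in col:
            if call != MISSING:
                out[call] += 1
        return out

    def n_typed(self, name: str) -> int:
        return int((self.calls[name] != MISSING).sum())

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = self.calls.copy()
        df.index.name = "sample"
        df.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeDataset({self.n_samples} samples x {len(self.loci)} loci)"


def read_genotype_table(
    path: str | Path,
    dialect: str = "tsv",
    loci: Sequence[Locus] | None = None,
) -> GenotypeDataset:
    """Read a genotype table.

    ``tsv``: header ``sample<TAB>locus1<TAB>...``, one row per sample, calls
    two-character strings or ``NN``.  ``vcf``: VCF 4.x, GT field only, keeping
    biallelic SNP records (requires cyvcf2).  If ``loci`` metadata is given it
    must cover every column; otherwise alleles are parsed from ``X>Y`` locus
    label suffixes or inferred from the calls (ref = major allele).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: expected a sample column plus >=1 locus column")
        df = df.set_index(df.columns[0])
        if loci is None:
            loci = [_infer_locus(name, df[name]) for name in df.columns]
        else:
            by_name = {l.name: l for l in loci}
            missing = [c for c in df.columns if c not in by_name]
            if missing:
                raise ValidationError(f"{path}: no Locus metadata for columns {missing}")
            loci = [by_name[c] for c in df.columns]
        return GenotypeDataset(loci, df)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> GenotypeDataset:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    cols: list[list[str]] = []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNPs only
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in _BASES or alt not in _BASES:
            continue
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}{ref}>{alt}"
        loci.append(Locus(gene=str(var.CHROM), name=name, ref_allele=ref, alt_allele=alt))
        col = []
        for gt in var.genotypes:  # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                col.append(MISSING)
            else:
                alleles = [ref if a == 0 else alt for a in (a0, a1)]
                col.append("".join(alleles))
        cols.append(col)
    calls = pd.DataFrame(
        {l.name: c for l, c in zip(loci, cols)}, index=pd.Index(samples, name="sample")
    )
    return GenotypeDataset(loci, calls)


# ---------------------------------------------------------------------------
# phenotype and Ct tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["sample", "parity", "litter_size"]
CT_COLUMNS = ["animal", "tissue", "gene", "replicate", "ct"]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (sample, parity, litter_size): parity in {1,2,3}, litter >= 1."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns {missing}")
    out = df[PHENOTYPE_COLUMNS].copy()
    for col in ("parity", "litter_size"):
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals.dropna() % 1, 0):
            raise ValidationError(f"column {col!r} must be integer-valued")
        out[col] = vals.astype(int)
    if not out["parity"].isin([1, 2, 3]).all():
        bad = out.loc[~out["parity"].isin([1, 2, 3]), "sample"].tolist()
        raise ValidationError(f"parity outside 1-3 for samples {bad}")
    if (out["litter_size"] < 1).any():
        bad = out.loc[out["litter_size"] < 1, "sample"].tolist()
        raise ValidationError(f"litter_size < 1 for samples {bad}")
    out["sample"] = out["sample"].astype(str)
    return out.reset_index(drop=True)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype TSV (``sample  parity  litter_size``)."""
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def validate_ct(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table: Ct finite and > 0."""
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table lacks columns {missing}")
    out = df[CT_COLUMNS].copy()
    out["ct"] = pd.to_numeric(out["ct"], errors="coerce")
    if out["ct"].isna().any() or not np.isfinite(out["ct"]).all() or (out["ct"] <= 0).any():
        raise ValidationError("Ct values must be finite and > 0")
    for col in ("animal", "tissue", "gene"):
        out[col] = out[col].astype(str)
    out["replicate"] = out["replicate"].astype(int)
    return out.reset_index(drop=True)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a Ct TSV (``animal tissue gene replicate ct``)."""
    return validate_ct(pd.read_csv(path, sep="\t"))


def join_genotypes_phenotypes(
    genotypes: GenotypeDataset, phenotypes: pd.DataFrame, locus: str
) -> pd.DataFrame:
    """Inner-join genotype calls at one locus with litter-size phenotypes.

    Returns one row per sample with a non-missing genotype at ``locus``:
    columns (sample, genotype, parity, litter_size).  Samples missing the
    genotype are excluded and the count is logged.
    """
    genotypes.locus(locus)  # raises on unknown locus
    pheno = validate_phenotypes(phenotypes)
    calls = genotypes.calls[locus]
    merged = pheno.merge(
        calls.rename("genotype"), left_on="sample", right_index=True, how="inner"
    )
    if merged.empty:
        raise ValidationError("no overlapping samples between genotypes and phenotypes")
    n_missing = int((merged["genotype"] == MISSING).sum())
    if n_missing:
        logger.info("join at %s: dropped %d samples with missing genotype", locus, n_missing)
    merged = merged[merged["genotype"] != MISSING]
    return merged[["sample", "genotype", "parity", "litter_size"]].reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, sep="\t", index=False)


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_ct(df).to_csv(path, sep="\t", index=False)
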
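import numpy as np
import pandas as pd
import pytest

from candsnp import GenotypeDataset, Locus, datasets


@pytest.fixture(scope="session")
def study_counts_dataset() -> GenotypeDataset:
    """The bundled published genotype counts expanded to individuals."""
    return datasets.snp_count_dataset()


@pytest.fixture
def two_locus_dataset() -> GenotypeDataset:
    """Small handmade 2-locus dataset with phase-ambiguous samples."""
    loci = [Locus("G1", "a", "A", "G"), Locus("G1", "b", "C", "T")]
    calls = pd.DataFrame(
        {
            "a": ["AA", "AG", "AG", "GG", "AA", "AG", "AA", "AG", "GG", "AA"],
            "b": ["CC", "CT", "CC", "TT", "CT", "CT", "CC", "CC", "CT", "CC"],
        },
        index=pd.Index([f"s{i}" for i in range(10)], name="sample"),
    )
    return GenotypeDataset(loci, calls)


def make_dataset(columns: dict[str, list[str]], genes: dict[str, str] | None = None):
    """Build a GenotypeDataset from {locus_name: calls}; alleles inferred."""
    from candsnp.io import _infer_locus

    names = list(columns)
    idx = pd.Index([f"s{i}" for i in range(len(next(iter(columns.values()))))],
                   name="sample")
    frame = pd.DataFrame(columns, index=idx)
    loci = [_infer_locus(n, frame[n], gene=(genes or {}).get(n, "G")) for n in names]
    return GenotypeDataset(loci, frame)
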
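"""Shared fixtures: tiny hand-checkable genes and one emulated study corpus."""

import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from cubkit import (
    STANDARD_CODE,
    CodingSequence,
    CodonCountTable,
    count_codons,
    emulate_study,
    validate_cds,
)

TOY_SEQ = "ATGGCAGCAGCGTGGTAA"  # M A A A W + stop


@pytest.fixture
def toy_cds() -> CodingSequence:
    return CodingSequence(id="toy", seq=TOY_SEQ)


@pytest.fixture
def toy_counts(toy_cds) -> CodonCountTable:
    return count_codons(toy_cds)


@pytest.fixture(scope="session")
def study_corpus():
    """Emulated study corpus (24 paralog-like + 6 divergent genes), seed 1."""
    records, truth = emulate_study(1)
    tables = [
        count_codons(validate_cds(r, "strict", trim_trailing_stop=False))
        for r in records
    ]
    return records, tables, truth


def uniform_counts(gene_id: str = "uniform", per_codon: int = 60) -> CodonCountTable:
    """Exactly equal usage of every sense codon (the unbiased limit)."""
    return CodonCountTable(
        gene_id=gene_id,
        counts={c: per_codon for c in STANDARD_CODE.sense_codons},
    )


def deterministic_counts(gene_id: str = "det", per_family: int = 60) -> CodonCountTable:
    """One codon per family, heavily used (the maximal-bias limit)."""
    counts = {}
    for aa in STANDARD_CODE.amino_acids:
        counts[STANDARD_CODE.family(aa)[0]] = per_family
    return CodonCountTable(gene_id=gene_id, counts=counts)
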
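"""Codon counting — the 64-vector substrate every statistic is built on.

Stop codons encountered in the reading frame are *recorded* in the table but
excluded from ``total_codons`` (L) and from every synonymous-codon statistic
downstream; codons containing N are skipped entirely rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_code import ALL_CODONS, STANDARD_CODE, GeneticCode
from .sequences import CodingSequence


@dataclass
class CodonCountTable:
    """Per-gene codon counts X_ij.

    ``counts`` always carries all 64 codons; ``total_codons`` is the number
    of *sense* codons L, ``n_skipped`` the number of N-containing codons
    dropped during counting.
    """

    gene_id: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(ALL_CODONS, 0))
    n_skipped: int = 0

    def __post_init__(self) -> None:
        full = dict.fromkeys(ALL_CODONS, 0)
        full.update(self.counts)
        if any(v < 0 for v in full.values()):
            raise ValueError(f"{self.gene_id}: negative codon count")
        self.counts = full

    @property
    def total_codons(self) -> int:
        """L: number of sense codons (stops excluded)."""
        code = STANDARD_CODE
        return sum(self.counts[c] for c in code.sense_codons)

    @property
    def stop_count(self) -> int:
        return sum(self.counts[c] for c in STANDARD_CODE.stop_codons)

    def aa_counts(self, code: GeneticCode = STANDARD_CODE) -> dict[str, int]:
        """Counts per encoded amino acid over sense codons."""
        out = dict.fromkeys(code.amino_acids, 0)
        for codon in code.sense_codons:
            out[code.codon_to_aa[codon]] += self.counts[codon]
        return out

    def family_counts(self, aa: str, code: GeneticCode = STANDARD_CODE) -> dict[str, int]:
        return {c: self.counts[c] for c in code.family(aa)}

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(
            gene_id=f"{self.gene_id}+{other.gene_id}",
            counts=merged,
            n_skipped=self.n_skipped + other.n_skipped,
        )


def count_codons(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> CodonCountTable:
    """Exact codon multiset of reading frame 0.

    Codons containing ambiguous bases are skipped (counted in
    ``n_skipped``); stop codons are recorded in the table.
    """
    counts = dict.fromkeys(ALL_CODONS, 0)
    skipped = 0
    for codon in cds.codons():
        if "N" in codon:
            skipped += 1
            continue
        counts[codon] += 1
    return CodonCountTable(gene_id=cds.id, counts=counts, n_skipped=skipped)


def pool_counts(tables: list[CodonCountTable], label: str = "pooled") -> CodonCountTable:
    """Sum codon counts across genes (dataset-level substrate)."""
    if not tables:
        raise ValueError("cannot pool an empty list of count tables")
    merged = dict.fromkeys(ALL_CODONS, 0)
    for t in tables:
        for c in ALL_CODONS:
            merged[c] += t.counts[c]
    return CodonCountTable(
        gene_id=label, counts=merged, n_skipped=sum(t.n_skipped for t in tables)
    )
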
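"""Genetic-code model shared by every statistic in the package.

Only the standard nuclear code (NCBI translation table 1) ships; the table id
is kept as a field so organelle codes can be added without touching callers.
All synonymous-codon statistics work on *degenerate families*: the synonymous
codon sets of amino acids with two or more codons (Met and Trp are excluded,
stop codons always are).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid mapping plus synonymous-family bookkeeping.

    Attributes
    ----------
    table_id : NCBI translation table id (only 1 is shipped).
    codon_to_aa : mapping of the 64 DNA codons to one-letter amino acid
        symbols, with ``*`` for the three stops.
    """

    table_id: int = 1
    codon_to_aa: dict[str, str] = field(default_factory=dict)

    @staticmethod
    @lru_cache(maxsize=None)
    def standard() -> "GeneticCode":
        """The standard nuclear code: 61 sense codons, stops TAA/TAG/TGA."""
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP_SYMBOL
        return GeneticCode(table_id=1, codon_to_aa=mapping)

    # -- basic queries ---------------------------------------------------

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP_SYMBOL)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP_SYMBOL)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in ALL_CODONS:
            aa = self.codon_to_aa[c]
            if aa != STOP_SYMBOL and aa not in seen:
                seen.append(aa)
        return tuple(seen)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def family(self, aa: str) -> tuple[str, ...]:
        """Synonymous codons of ``aa``, in fixed TCAG order."""
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == aa)

    def degeneracy(self, aa: str) -> int:
        """Family size n_i; 1, 2, 3, 4 or 6 under the standard code."""
        return len(self.family(aa))

    @property
    def degenerate_aas(self) -> tuple[str, ...]:
        """Amino acids with >= 2 synonymous codons (drops Met, Trp)."""
        return tuple(aa for aa in self.amino_acids if self.degeneracy(aa) >= 2)

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 codons belonging to degenerate families."""
        keep = set(self.degenerate_aas)
        return tuple(c for c in self.sense_codons if self.codon_to_aa[c] in keep)


STANDARD_CODE = GeneticCode.standard()
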
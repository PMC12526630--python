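"""Coding-sequence records, FASTA I/O and CDS validation.

Sequences are handled in reading frame 0 of the record as supplied (the
inputs are CDS records, not genomic contigs); there is no ORF scanning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STANDARD_CODE, GeneticCode


class CdsValidationError(ValueError):
    """CDS fails strict validation; carries gene id and 1-based codon position."""

    def __init__(self, gene_id: str, message: str, codon_index: int | None = None):
        self.gene_id = gene_id
        self.codon_index = codon_index
        where = f" at codon {codon_index}" if codon_index is not None else ""
        super().__init__(f"{gene_id}: {message}{where}")


class FastaParseError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """An accession-like id plus a nucleotide string over {A,C,G,T,N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Frame-0 codons; a trailing overhang (<3 nt) is not returned."""
        n = len(self.seq) - len(self.seq) % 3
        return [self.seq[i : i + 3] for i in range(0, n, 3)]


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a (multi-)FASTA of coding sequences.

    Sequences are upper-cased and RNA ``U`` is normalized to ``T``.
    Characters outside {A,C,G,T,N} raise :class:`FastaParseError` naming the
    offending record.
    """
    records: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FastaParseError(
                f"record {rec.id!r}: invalid characters {sorted(bad)}"
            )
        records.append(CodingSequence(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def validate_cds(
    cds: CodingSequence,
    policy: Literal["strict", "lenient"] = "lenient",
    code: GeneticCode = STANDARD_CODE,
    trim_trailing_stop: bool = True,
) -> CodingSequence:
    """Validate/normalize a CDS for codon counting.

    By default both policies trim one trailing stop codon when present (set
    ``trim_trailing_stop=False`` to keep it recorded, e.g. so whole-CDS base
    composition includes the stop).  ``strict``
    raises :class:`CdsValidationError` on a length not divisible by 3, an
    internal stop, or any ``N``.  ``lenient`` truncates a 3' overhang and
    leaves N-containing codons in place (they are skipped at counting time)
    with a warning.
    """
    seq = cds.seq
    overhang = len(seq) % 3
    if overhang:
        if policy == "strict":
            raise CdsValidationError(
                cds.id, f"length {len(seq)} is not a multiple of 3"
            )
        warnings.warn(f"{cds.id}: truncating {overhang} nt 3' overhang")
        seq = seq[: len(seq) - overhang]

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if trim_trailing_stop and codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]

    # a kept trailing stop is not an *internal* stop
    n_check = len(codons)
    if not trim_trailing_stop and codons and codons[-1] in code.stop_codons:
        n_check -= 1
    for i, codon in enumerate(codons[:n_check]):
        if "N" in codon:
            if policy == "strict":
                raise CdsValidationError(cds.id, "ambiguous base N", codon_index=i + 1)
            continue
        if code.codon_to_aa[codon] == "*":
            if policy == "strict":
                raise CdsValidationError(cds.id, "internal stop codon", codon_index=i + 1)
            warnings.warn(f"{cds.id}: internal stop codon at codon {i + 1}")
    return CodingSequence(id=cds.id, seq="".join(codons))


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text one-accession-per-line gene list (blank lines, # comments ok)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
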
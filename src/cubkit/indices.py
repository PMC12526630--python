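"""Per-gene codon usage bias indices: ENC, CAI, CBI, GRAVY, AROMA.

ENC follows Wright's estimator with CodonW's edge handling (families with
fewer than two codons, or zero homozygosity, drop out of their degeneracy
class; a missing three-fold class average is imputed from the two- and
four-fold neighbours).  CAI is the Sharp-Li geometric mean of relative
adaptiveness; the packaged default reference is the published Sharp & Li
(1987) E. coli table.  CBI is Bennetzen-Hall.  GRAVY uses the
Kyte-Doolittle hydropathy scale; AROMA is the aromatic residue fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .counts import CodonCountTable
from .genetic_code import STANDARD_CODE, GeneticCode

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


class UndefinedIndexError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reference weights (CAI / CBI)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w per codon plus the optimal-codon set.

    Within every synonymous family the maximum w is 1; ``optimal_set``
    defaults to the codons attaining that maximum.
    """

    name: str
    w: dict[str, float]
    optimal_set: frozenset[str] = field(default_factory=frozenset)

    @staticmethod
    def from_weights(
        name: str, w: dict[str, float], code: GeneticCode = STANDARD_CODE
    ) -> "ReferenceWeights":
        """Normalize raw weights so max w = 1 per family; derive optimal set."""
        norm: dict[str, float] = {}
        optimal: set[str] = set()
        for aa in code.amino_acids:
            fam = code.family(aa)
            mx = max(w.get(c, 0.0) for c in fam)
            if mx <= 0:
                raise ValueError(f"reference has no positive weight for {aa}")
            for c in fam:
                norm[c] = w.get(c, 0.0) / mx
            if len(fam) > 1:
                optimal.update(c for c in fam if norm[c] == 1.0)
        return ReferenceWeights(name=name, w=norm, optimal_set=frozenset(optimal))

    @staticmethod
    def from_counts(
        name: str, table: CodonCountTable, code: GeneticCode = STANDARD_CODE
    ) -> "ReferenceWeights":
        """Build weights from the codon usage of a reference gene set."""
        return ReferenceWeights.from_weights(
            name, {c: float(table.counts[c]) for c in code.sense_codons}, code
        )

    @staticmethod
    def from_tsv(path: str | Path, name: str | None = None) -> "ReferenceWeights":
        """Two-column codon<TAB>weight table (header line optional)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if df.columns[0].upper() not in ("CODON",):
            df = pd.read_csv(path, sep="\t", comment="#", header=None)
        codons = df.iloc[:, 0].astype(str).str.upper().str.replace("U", "T")
        w = dict(zip(codons, df.iloc[:, 1].astype(float)))
        return ReferenceWeights.from_weights(name or Path(path).stem, w)

    @staticmethod
    def sharp_ecoli() -> "ReferenceWeights":
        """Sharp & Li (1987) E. coli relative adaptiveness (CodonW default)."""
        with resources.files("cubkit.data.cai").joinpath(
            "ecoli_sharp1987.tsv"
        ).open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        return ReferenceWeights.from_weights(
            "ecoli_sharp1987", dict(zip(df["codon"], df["w"].astype(float)))
        )


# ---------------------------------------------------------------------------
# effective number of codons
# ---------------------------------------------------------------------------

def _family_homozygosity(counts: dict[str, int]) -> tuple[int, float | None]:
    """Wright's F-hat for one family; None when n < 2."""
    n = sum(counts.values())
    if n < 2:
        return n, None
    s = sum((v / n) ** 2 for v in counts.values())
    return n, (n * s - 1.0) / (n - 1.0)


def enc(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Wright's effective number of codons, in [20, 61].

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean homozygosity of
    usable families (n >= 2, F-hat > 0) in each degeneracy class; a missing
    F3 is imputed as (F2 + F4)/2, and the result is capped at 61.
    """
    classes: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa in code.degenerate_aas:
        k = code.degeneracy(aa)
        _, f = _family_homozygosity(table.family_counts(aa, code))
        if f is not None and f > 0:
            classes[k].append(f)

    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    fbar: dict[int, float] = {}
    for k, fs in classes.items():
        if fs:
            fbar[k] = sum(fs) / len(fs)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in fbar]
    if missing:
        raise UndefinedIndexError(
            f"{table.gene_id}: no usable family in degeneracy class(es) {missing}"
        )
    value = 2.0 + sum(n_families[k] / fbar[k] for k in (2, 3, 4, 6))
    return min(value, 61.0)


# ---------------------------------------------------------------------------
# CAI and CBI
# ---------------------------------------------------------------------------

def cai(
    table: CodonCountTable,
    ref: ReferenceWeights | None = None,
    code: GeneticCode = STANDARD_CODE,
    w_floor: float = 0.01,
) -> float:
    """Sharp-Li codon adaptation index: geometric mean of w over sense
    codons of degenerate families (Met/Trp and stops never contribute)."""
    if ref is None:
        ref = ReferenceWeights.sharp_ecoli()
    log_sum = 0.0
    n = 0
    for codon in code.synonymous_codons:
        cnt = table.counts[codon]
        if cnt == 0:
            continue
        w = ref.w.get(codon, 0.0)
        if w <= 0:
            warnings.warn(
                f"{table.gene_id}: reference weight for {codon} is 0; "
                f"substituting floor {w_floor}"
            )
            w = w_floor
        log_sum += cnt * math.log(w)
        n += cnt
    if n == 0:
        raise UndefinedIndexError(f"{table.gene_id}: no codons usable for CAI")
    return math.exp(log_sum / n)


def cbi(
    table: CodonCountTable,
    ref: ReferenceWeights | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Bennetzen-Hall codon bias index in [-1, 1].

    (N_opt - N_ran) / (N_tot - N_ran), with N_ran the optimal-codon count
    expected under uniform synonymous usage.
    """
    if ref is None:
        ref = ReferenceWeights.sharp_ecoli()
    n_opt = 0
    n_tot = 0
    n_ran = 0.0
    for aa in code.degenerate_aas:
        fam = code.family(aa)
        fam_count = sum(table.counts[c] for c in fam)
        if fam_count == 0:
            continue
        k_opt = sum(1 for c in fam if c in ref.optimal_set)
        n_tot += fam_count
        n_opt += sum(table.counts[c] for c in fam if c in ref.optimal_set)
        n_ran += fam_count * k_opt / len(fam)
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        raise UndefinedIndexError(f"{table.gene_id}: degenerate CBI denominator")
    return (n_opt - n_ran) / (n_tot - n_ran)


# ---------------------------------------------------------------------------
# protein-level indices
# ---------------------------------------------------------------------------

def gravy_aroma(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """(GRAVY, AROMA) of the encoded residues.

    GRAVY is the mean Kyte-Doolittle hydropathy; AROMA the fraction of
    Phe/Tyr/Trp residues.
    """
    aa_counts = table.aa_counts(code)
    n = sum(aa_counts.values())
    if n == 0:
        raise UndefinedIndexError(f"{table.gene_id}: no sense codons")
    gravy = sum(KYTE_DOOLITTLE[aa] * c for aa, c in aa_counts.items()) / n
    aroma = sum(c for aa, c in aa_counts.items() if aa in AROMATIC) / n
    return gravy, aroma


@dataclass(frozen=True)
class BiasIndices:
    """The per-gene index panel."""

    gene_id: str
    enc: float
    cbi: float
    cai: float
    gravy: float
    aroma: float


def bias_indices(
    table: CodonCountTable,
    ref: ReferenceWeights | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> BiasIndices:
    if ref is None:
        ref = ReferenceWeights.sharp_ecoli()
    g, a = gravy_aroma(table, code)
    return BiasIndices(
        gene_id=table.gene_id,
        enc=enc(table, code),
        cbi=cbi(table, ref, code),
        cai=cai(table, ref, code),
        gravy=g,
        aroma=a,
    )


def indices_frame(rows: list[BiasIndices]) -> pd.DataFrame:
    """Index panel as a DataFrame in the conventional column order."""
    return pd.DataFrame(
        {
            "accession": [r.gene_id for r in rows],
            "ENC": [round(r.enc, 2) for r in rows],
            "CBI": [round(r.cbi, 3) for r in rows],
            "CAI": [round(r.cai, 3) for r in rows],
            "GRAVY": [round(r.gravy, 6) for r in rows],
            "AROMA": [round(r.aroma, 6) for r in rows],
        }
    )
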
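"""RSCU / RFSC tables, codon classification, and ΔRSCU optimal-codon discovery.

RSCU_ij = X_ij / ((1/n_i) Σ_j X_ij): the codon count relative to the uniform
expectation within its synonymous family (Sharp-Li).  RFSC_ij = X_ij / Σ_j X_ij
is the codon's share of the family, so RSCU = RFSC * n_i.  Dataset-level
tables are computed on *pooled* counts, never as means of per-gene tables.

High-frequency codons support the two published operationalisations:
``rfsc60`` (RFSC > 0.60) and ``avg150`` (usage exceeding the family's
synonymous average by >50%, i.e. RFSC > 1.5/n_i, equivalently RSCU > 1.5).

Optimal codons: genes are ranked by ENC; the lowest-ENC decile is the
high-expression pool and the highest-ENC decile the low-expression pool.
A codon is optimal when ΔRSCU = RSCU_high - RSCU_low >= 0.08 with
RSCU_high > 1 and RSCU_low < 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .counts import CodonCountTable, pool_counts
from .genetic_code import STANDARD_CODE, GeneticCode
from .indices import enc

DELTA_RSCU_THRESHOLD = 0.08
OVER_THRESHOLD = 1.6
UNDER_THRESHOLD = 0.6


@dataclass(frozen=True)
class RSCUTable:
    """RSCU and RFSC per sense codon for one gene or a pooled dataset.

    Families with zero total count yield ``nan`` (missing, not 0).
    """

    scope: str
    rscu: dict[str, float]
    rfsc: dict[str, float]

    def frame(self, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": code.codon_to_aa[c],
                "rscu": self.rscu[c],
                "rfsc": self.rfsc[c],
            }
            for c in code.sense_codons
        ]
        return pd.DataFrame(rows)


def rscu_rfsc(
    table: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> RSCUTable:
    """Compute RSCU and RFSC for every sense codon."""
    rscu: dict[str, float] = {}
    rfsc: dict[str, float] = {}
    for aa in code.amino_acids:
        fam = code.family(aa)
        tot = sum(table.counts[c] for c in fam)
        for c in fam:
            if tot == 0:
                rscu[c] = math.nan
                rfsc[c] = math.nan
            else:
                rfsc[c] = table.counts[c] / tot
                rscu[c] = rfsc[c] * len(fam)
    return RSCUTable(scope=table.gene_id, rscu=rscu, rfsc=rfsc)


def rscu(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> RSCUTable:
    return rscu_rfsc(table, code)


def rfsc(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> RSCUTable:
    return rscu_rfsc(table, code)


@dataclass
class CodonClassification:
    """Codon sets from RSCU thresholds plus ΔRSCU optimal-codon results."""

    preferred: set[str] = field(default_factory=set)      # RSCU > 1
    over: set[str] = field(default_factory=set)           # RSCU > 1.6
    under: set[str] = field(default_factory=set)          # RSCU < 0.6
    high_freq: set[str] = field(default_factory=set)
    optimal: set[str] = field(default_factory=set)
    delta_rscu: dict[str, float] = field(default_factory=dict)


def classify_codons(
    table: RSCUTable,
    hf_rule: Literal["rfsc60", "avg150"] = "rfsc60",
    code: GeneticCode = STANDARD_CODE,
) -> CodonClassification:
    """Threshold classification of a (pooled) RSCU/RFSC table.

    Only codons of degenerate families are classified; single-codon
    families (Met, Trp) always have RSCU = RFSC-share = 1 by construction
    and carry no bias information.
    """
    cls = CodonClassification()
    for c in code.synonymous_codons:
        r = table.rscu[c]
        f = table.rfsc[c]
        if math.isnan(r):
            continue
        if r > 1.0:
            cls.preferred.add(c)
        if r > OVER_THRESHOLD:
            cls.over.add(c)
        if r < UNDER_THRESHOLD:
            cls.under.add(c)
        n_i = code.degeneracy(code.codon_to_aa[c])
        if hf_rule == "rfsc60":
            if f > 0.60:
                cls.high_freq.add(c)
        elif hf_rule == "avg150":
            if f > 1.5 / n_i:
                cls.high_freq.add(c)
        else:
            raise ValueError(f"unknown hf_rule {hf_rule!r}")
    return cls


def _extreme_deciles(
    genes: list[CodonCountTable],
    quantile: float,
    code: GeneticCode,
) -> tuple[list[CodonCountTable], list[CodonCountTable]]:
    """(low-ENC genes, high-ENC genes); decile size round-half-up, min 1."""
    ranked = sorted(genes, key=lambda t: (enc(t, code), t.gene_id))
    k = max(1, int(math.floor(quantile * len(genes) + 0.5)))
    return ranked[:k], ranked[-k:]


def optimal_codons(
    genes: list[CodonCountTable],
    quantile: float = 0.10,
    code: GeneticCode = STANDARD_CODE,
) -> CodonClassification:
    """ΔRSCU optimal-codon discovery over an ENC-ranked gene set."""
    if len(genes) < 2:
        raise ValueError("optimal-codon analysis needs at least 2 genes")
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    if len(genes) < 2 / quantile:
        warnings.warn(
            f"only {len(genes)} genes for quantile {quantile}; "
            "extreme pools will be very small"
        )
    low_enc, high_enc = _extreme_deciles(genes, quantile, code)
    rscu_high = rscu_rfsc(pool_counts(low_enc, "high_expression"), code)
    rscu_low = rscu_rfsc(pool_counts(high_enc, "low_expression"), code)

    cls = CodonClassification()
    for c in code.synonymous_codons:
        hi = rscu_high.rscu[c]
        lo = rscu_low.rscu[c]
        if math.isnan(hi) or math.isnan(lo):
            cls.delta_rscu[c] = math.nan
            continue
        cls.delta_rscu[c] = hi - lo
        if hi - lo >= DELTA_RSCU_THRESHOLD and hi > 1.0 and lo < 1.0:
            cls.optimal.add(c)
    return cls


def classification_frame(
    table: RSCUTable,
    cls: CodonClassification,
    counts: CodonCountTable | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-codon table with counts, RSCU, RFSC and classification flags."""
    df = table.frame(code)
    if counts is not None:
        df["count"] = [counts.counts[c] for c in df["codon"]]
    df["preferred"] = df["codon"].isin(cls.preferred)
    df["over_represented"] = df["codon"].isin(cls.over)
    df["under_represented"] = df["codon"].isin(cls.under)
    df["high_frequency"] = df["codon"].isin(cls.high_freq)
    if cls.delta_rscu:
        df["delta_rscu"] = [cls.delta_rscu.get(c, math.nan) for c in df["codon"]]
        df["optimal"] = df["codon"].isin(cls.optimal)
    return df
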
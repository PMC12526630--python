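"""Nucleotide-composition panel per gene and dataset means.

Two conventions coexist in the CUB literature and both are exposed here:

* ``style="codonw"`` (default): the per-base silent third-position
  frequencies A3s/T3s/C3s/G3s use CodonW's denominators — for base b, only
  codons of families that *can* end in b are counted in the denominator.
  The four values therefore do not sum to 100.
* ``style="proportion"``: plain shares of the synonymous third-position
  base multiset; the four values sum to 100.

GC3s is a plain proportion over synonymous codons in both styles; AT3
follows the CAIcal convention (third positions of *all* sense codons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .counts import CodonCountTable
from .genetic_code import STANDARD_CODE, GeneticCode


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    """The per-gene composition column set, all in percent [0, 100]."""

    gene_id: str
    a_pct: float
    t_pct: float
    c_pct: float
    g_pct: float
    gc_pct: float
    at_pct: float
    gc1_pct: float
    gc2_pct: float
    gc12_pct: float
    gc3s_pct: float
    a3s_pct: float
    t3s_pct: float
    c3s_pct: float
    g3s_pct: float
    at3_pct: float

    _NUMERIC = (
        "a_pct", "t_pct", "c_pct", "g_pct", "gc_pct", "at_pct",
        "gc1_pct", "gc2_pct", "gc12_pct", "gc3s_pct",
        "a3s_pct", "t3s_pct", "c3s_pct", "g3s_pct", "at3_pct",
    )


def composition_profile(
    table: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    style: Literal["codonw", "proportion"] = "codonw",
) -> CompositionProfile:
    """Compute the full composition panel from a codon count table.

    Overall base percentages run over every recorded codon (stops
    included); GC1/GC2 and third-position metrics run over sense codons;
    "3s" metrics are restricted to synonymous codons (degeneracy >= 2).
    """
    counts = table.counts

    # overall base content, stops included
    base_tot = dict.fromkeys("ACGT", 0)
    n_nt = 0
    for codon, n in counts.items():
        if n == 0:
            continue
        for b in codon:
            base_tot[b] += n
            n_nt += n
    if n_nt == 0:
        raise UndefinedMetricError(f"{table.gene_id}: empty codon table")

    # positional counts over sense codons
    gc1 = gc2 = at3_num = sense_n = 0
    for codon in code.sense_codons:
        n = counts[codon]
        if n == 0:
            continue
        sense_n += n
        gc1 += n * (codon[0] in "GC")
        gc2 += n * (codon[1] in "GC")
        at3_num += n * (codon[2] in "AT")
    if sense_n == 0:
        raise UndefinedMetricError(f"{table.gene_id}: no sense codons")

    # synonymous third positions (degenerate families only)
    syn_base = dict.fromkeys("ACGT", 0)
    syn_n = 0
    fam_avail: dict[str, set[str]] = {}   # aa -> third-position bases available
    fam_n: dict[str, int] = {}
    for aa in code.degenerate_aas:
        fam = code.family(aa)
        fam_avail[aa] = {c[2] for c in fam}
        tot = 0
        for c in fam:
            n = counts[c]
            tot += n
            syn_base[c[2]] += n
        fam_n[aa] = tot
        syn_n += tot
    if syn_n == 0:
        raise UndefinedMetricError(f"{table.gene_id}: no synonymous codons")

    if style == "codonw":
        base3s = {}
        for b in "ACGT":
            den = sum(fam_n[aa] for aa in fam_avail if b in fam_avail[aa])
            base3s[b] = 100.0 * syn_base[b] / den if den else float("nan")
    elif style == "proportion":
        base3s = {b: 100.0 * syn_base[b] / syn_n for b in "ACGT"}
    else:
        raise ValueError(f"unknown style {style!r}")

    gc1_pct = 100.0 * gc1 / sense_n
    gc2_pct = 100.0 * gc2 / sense_n
    gc_pct = 100.0 * (base_tot["G"] + base_tot["C"]) / n_nt
    return CompositionProfile(
        gene_id=table.gene_id,
        a_pct=100.0 * base_tot["A"] / n_nt,
        t_pct=100.0 * base_tot["T"] / n_nt,
        c_pct=100.0 * base_tot["C"] / n_nt,
        g_pct=100.0 * base_tot["G"] / n_nt,
        gc_pct=gc_pct,
        at_pct=100.0 - gc_pct,
        gc1_pct=gc1_pct,
        gc2_pct=gc2_pct,
        gc12_pct=(gc1_pct + gc2_pct) / 2.0,
        gc3s_pct=100.0 * (syn_base["G"] + syn_base["C"]) / syn_n,
        a3s_pct=base3s["A"],
        t3s_pct=base3s["T"],
        c3s_pct=base3s["C"],
        g3s_pct=base3s["G"],
        at3_pct=100.0 * at3_num / sense_n,
    )


def dataset_means(
    profiles: list[CompositionProfile], label: str = "mean"
) -> CompositionProfile:
    """Unweighted arithmetic mean of each field across genes."""
    if not profiles:
        raise ValueError("dataset_means of an empty profile list")
    vals = {
        name: sum(getattr(p, name) for p in profiles) / len(profiles)
        for name in CompositionProfile._NUMERIC
    }
    return CompositionProfile(gene_id=label, **vals)


TABLE_COLUMNS = [
    ("gene_id", "accession"),
    ("t3s_pct", "T3s%"),
    ("c3s_pct", "C3s%"),
    ("a3s_pct", "A3s%"),
    ("g3s_pct", "G3s%"),
    ("gc_pct", "GC%"),
    ("at_pct", "AT%"),
    ("gc3s_pct", "GC3s%"),
    ("at3_pct", "AT3%"),
    ("gc1_pct", "GC1%"),
    ("gc2_pct", "GC2%"),
]


def composition_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Composition panel as a DataFrame in the conventional column order."""
    rows = []
    for p in profiles:
        row = {}
        for attr, col in TABLE_COLUMNS:
            v = getattr(p, attr)
            row[col] = round(v, 2) if isinstance(v, float) else v
        rows.append(row)
    return pd.DataFrame(rows)
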
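"""Expression proxies (SCUO, MILC), amino-acid usage, host compatibility
screening and Spearman correlation panels.

SCUO is the synonymous codon usage order: the count-weighted normalized
entropy deficit of the synonymous families, in [0, 1] (0 = uniform usage,
1 = a single codon per family).  MILC is the measure independent of length
and composition: MILC = (Σ_a M_a)/L - C with M_a = 2 Σ_c O_c ln(f_c/g_c)
the per-family deviation of observed within-family codon frequencies f
from an expected distribution g, and correction C = Σ_a(n_a - 1)/L - 0.5.

Host screening compares a gene set's per-1000 codon frequencies with a
host organism's table (EMBOSS cusp format); a codon whose ratio is <= 0.5
or >= 2 marks a divergent usage that may hinder heterologous expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CodonCountTable
from .genetic_code import STANDARD_CODE, GeneticCode


class UndefinedScoreError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SCUO and MILC
# ---------------------------------------------------------------------------

def scuo(table: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Synonymous codon usage order in [0, 1].

    Per degenerate family i with counts x_ij: O_i = (Hmax_i - H_i)/Hmax_i,
    H_i the Shannon entropy of the within-family frequencies and
    Hmax_i = ln n_i; SCUO is the count-weighted mean of the O_i.
    """
    num = 0.0
    total = 0
    for aa in code.degenerate_aas:
        fam = code.family(aa)
        n = sum(table.counts[c] for c in fam)
        if n == 0:
            continue
        h = -sum(
            (table.counts[c] / n) * math.log(table.counts[c] / n)
            for c in fam
            if table.counts[c] > 0
        )
        h_max = math.log(len(fam))
        num += n * (h_max - h) / h_max
        total += n
    if total == 0:
        raise UndefinedScoreError(f"{table.gene_id}: no degenerate-family codons")
    return num / total


def milc(
    table: CodonCountTable,
    expected: dict[str, float] | str = "uniform",
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Measure independent of length and composition.

    ``expected`` is either ``"uniform"`` (g = 1/n_i within each family) or
    a codon -> frequency mapping (e.g. dataset-mean usage) which is
    renormalized within each family.  Zero-count codons contribute 0; an
    observed codon with expected frequency 0 is an error.
    """
    L = table.total_codons
    if L < 1:
        raise UndefinedScoreError(f"{table.gene_id}: empty gene")

    m_sum = 0.0
    df_sum = 0
    for aa in code.amino_acids:
        fam = code.family(aa)
        n = sum(table.counts[c] for c in fam)
        if n == 0:
            continue
        if expected == "uniform":
            g = {c: 1.0 / len(fam) for c in fam}
        else:
            tot = sum(expected.get(c, 0.0) for c in fam)
            if tot <= 0:
                raise ValueError(f"expected distribution empty for family {aa}")
            g = {c: expected.get(c, 0.0) / tot for c in fam}
        for c in fam:
            o = table.counts[c]
            if o == 0:
                continue
            if g[c] <= 0:
                raise ValueError(
                    f"{table.gene_id}: observed codon {c} has expected frequency 0"
                )
            m_sum += 2.0 * o * math.log((o / n) / g[c])
        df_sum += len(fam) - 1
    correction = df_sum / L - 0.5
    return m_sum / L - correction


def dataset_codon_frequencies(
    tables: list[CodonCountTable], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Pooled sense-codon frequencies (for MILC's dataset-mean expectation)."""
    tot = {c: 0 for c in code.sense_codons}
    for t in tables:
        for c in code.sense_codons:
            tot[c] += t.counts[c]
    grand = sum(tot.values())
    if grand == 0:
        raise ValueError("no sense codons in dataset")
    return {c: v / grand for c, v in tot.items()}


@dataclass(frozen=True)
class ExpressionScores:
    gene_id: str
    scuo: float
    milc_uniform: float
    milc_dataset: float | None = None


# ---------------------------------------------------------------------------
# amino-acid usage
# ---------------------------------------------------------------------------

def aa_usage(
    genes: list[CodonCountTable], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """Pooled residue usage percentages over sense codons (sums to 100)."""
    tot = dict.fromkeys(code.amino_acids, 0)
    for t in genes:
        for aa, n in t.aa_counts(code).items():
            tot[aa] += n
    grand = sum(tot.values())
    if grand == 0:
        raise UndefinedScoreError("no sense codons in gene set")
    return {aa: 100.0 * n / grand for aa, n in tot.items()}


# ---------------------------------------------------------------------------
# host codon-usage tables and comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostUsageTable:
    """Codon usage of a candidate expression host, per 1000 codons."""

    host_name: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freq.values())
        if not math.isclose(total, 1000.0, abs_tol=1.0):
            raise ValueError(
                f"{self.host_name}: per-1000 frequencies sum to {total:.2f}"
            )


def read_cusp(path: str | Path, host_name: str | None = None) -> HostUsageTable:
    """Read an EMBOSS cusp-style table.

    Accepts the 5-column cusp layout (codon, amino acid, fraction, /1000,
    count) or a plain 2-column codon<TAB>per-1000 table; ``#`` lines are
    ignored.
    """
    freq: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        codon = parts[0].upper().replace("U", "T")
        if len(codon) != 3 or set(codon) - set("ACGT"):
            continue  # header line
        per1000 = float(parts[3]) if len(parts) >= 4 else float(parts[1])
        freq[codon] = per1000
    if not freq:
        raise ValueError(f"no codon rows parsed from {path}")
    return HostUsageTable(host_name=host_name or Path(path).stem, freq=freq)


def packaged_host_tables() -> dict[str, HostUsageTable]:
    """The six packaged host tables (synthetic stand-ins; see file headers)."""
    out = {}
    root = resources.files("cubkit.data.hosts")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".cusp"):
            name = entry.name.split(".")[0]
            with resources.as_file(entry) as p:
                out[name] = read_cusp(p, host_name=name)
    return out


@dataclass(frozen=True)
class HostComparison:
    """Per-codon gene/host frequency ratios and the divergent-codon set."""

    gene_label: str
    host_name: str
    ratio: dict[str, float]
    divergent: frozenset[str]

    @property
    def n_divergent(self) -> int:
        return len(self.divergent)


def host_compare(
    gene_counts: CodonCountTable,
    host: HostUsageTable,
    code: GeneticCode = STANDARD_CODE,
) -> HostComparison:
    """Compare per-1000 sense-codon frequencies against a host table.

    Ratio boundaries are inclusive: ratio <= 0.5 or >= 2 flags the codon
    as divergent.  A codon used by the gene but absent from the host gets
    an infinite ratio (divergent); a codon unused on both sides is skipped.
    """
    L = gene_counts.total_codons
    if L == 0:
        raise UndefinedScoreError(f"{gene_counts.gene_id}: empty gene")
    ratio: dict[str, float] = {}
    divergent: set[str] = set()
    for c in code.sense_codons:
        gene_f = 1000.0 * gene_counts.counts[c] / L
        host_f = host.freq.get(c, 0.0)
        if host_f == 0.0:
            if gene_f > 0.0:
                ratio[c] = math.inf
                divergent.add(c)
            continue
        r = gene_f / host_f
        ratio[c] = r
        if r <= 0.5 or r >= 2.0:
            divergent.add(c)
    return HostComparison(
        gene_label=gene_counts.gene_id,
        host_name=host.host_name,
        ratio=ratio,
        divergent=frozenset(divergent),
    )


def host_divergence_ranges(
    genes: list[CodonCountTable],
    hosts: dict[str, HostUsageTable],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-host min-max (across genes) of divergent-codon counts.

    Reproduces the "host (min-max codons)" ranking form; hosts sorted by
    ascending mean divergence (most compatible first).
    """
    rows = []
    for name, host in hosts.items():
        counts = [host_compare(t, host, code).n_divergent for t in genes]
        rows.append(
            {
                "host": name,
                "min_divergent": min(counts),
                "max_divergent": max(counts),
                "mean_divergent": sum(counts) / len(counts),
            }
        )
    df = pd.DataFrame(rows).sort_values("mean_divergent", kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Spearman correlation panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationPanel:
    pairs: list[tuple[str, str, float, float, bool]] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["x", "y", "rho", "p_value", "significant"]
        )


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return float(obs), count / total


def correlation_panel(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    exact_below: int = 10,
) -> CorrelationPanel:
    """Spearman rho and two-sided p for each requested column pair.

    Uses the t-approximation for n >= ``exact_below`` and an exact
    permutation test for smaller samples.  Constant columns yield
    rho = nan and are reported missing rather than dropped.
    """
    if len(table) < 4:
        raise ValueError("correlation panel needs at least 4 genes")
    out: list[tuple[str, str, float, float, bool]] = []
    for xn, yn in pairs:
        x = table[xn].to_numpy(dtype=float)
        y = table[yn].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"constant column in pair ({xn}, {yn}); rho undefined")
            out.append((xn, yn, math.nan, math.nan, False))
            continue
        if len(x) < exact_below:
            rho, p = _spearman_exact(x, y)
        else:
            rho, p = stats.spearmanr(x, y)
        out.append((xn, yn, float(rho), float(p), bool(p < alpha)))
    return CorrelationPanel(pairs=out)
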
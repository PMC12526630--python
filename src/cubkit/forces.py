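"""Mutation-vs-selection diagnostics: ENC plot, PR2 plot, neutrality
regression, and correspondence analysis of the gene x codon RSCU matrix.

The ENC plot compares each gene's observed ENC with Wright's expectation
under pure mutation pressure, ENC_exp(s) = 2 + s + 29/(s^2 + (1-s)^2) at
s = GC3s; genes far below the curve indicate selection on codon choice.
The PR2 plot places genes by AT bias A3/(A3+T3) and GC bias G3/(G3+C3) at
third codon positions, with (0.5, 0.5) the strand-parity equilibrium.
The neutrality plot regresses GC12 on GC3s: a slope near 1 means mutation
pressure dominates; near 0, selection.  Correspondence analysis ordinates
genes and codons in the chi-square metric of the 59-codon RSCU matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionProfile
from .counts import CodonCountTable
from .genetic_code import STANDARD_CODE, GeneticCode
from .indices import enc
from .rscu import rscu_rfsc

ENC_EXP_MAX = 61.04  # supremum of the expectation curve on [0, 1]


def enc_expected(gc3s: float) -> float:
    """Expected ENC under mutation pressure alone, at GC3s fraction s."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be a fraction in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class ENCPlotPoint:
    gene_id: str
    gc3s: float          # fraction in [0, 1]
    enc_obs: float
    enc_exp: float
    below_curve: bool


def enc_plot(
    genes: list[CodonCountTable], code: GeneticCode = STANDARD_CODE
) -> list[ENCPlotPoint]:
    """One (GC3s, ENC) point per gene against the expectation curve."""
    from .composition import composition_profile

    points = []
    for t in genes:
        gc3s = composition_profile(t, code).gc3s_pct / 100.0
        obs = enc(t, code)
        exp = enc_expected(gc3s)
        points.append(
            ENCPlotPoint(
                gene_id=t.gene_id,
                gc3s=gc3s,
                enc_obs=obs,
                enc_exp=exp,
                below_curve=obs < exp,
            )
        )
    return points


@dataclass(frozen=True)
class PR2Point:
    gene_id: str
    at_bias: float       # A3/(A3+T3)
    gc_bias: float       # G3/(G3+C3)
    quadrant: int        # 1..4, counter-clockwise from (+,+) about (0.5, 0.5)


def _quadrant(gc_bias: float, at_bias: float) -> int:
    right = gc_bias > 0.5
    top = at_bias > 0.5
    if right and top:
        return 1
    if top:
        return 2
    if not right:
        return 3
    return 4


def pr2_plot(
    genes: list[CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
    fourfold_only: bool = False,
) -> list[PR2Point | None]:
    """Third-position parity biases per gene.

    By default third positions of *all* sense codons are counted;
    ``fourfold_only=True`` restricts to fourfold-degenerate families for
    comparability with part of the literature.  A gene with A3+T3 = 0 or
    G3+C3 = 0 yields ``None`` (undefined point).
    """
    if fourfold_only:
        codons = [
            c
            for aa in code.amino_acids
            if code.degeneracy(aa) == 4
            for c in code.family(aa)
        ]
    else:
        codons = list(code.sense_codons)

    points: list[PR2Point | None] = []
    for t in genes:
        third = dict.fromkeys("ACGT", 0)
        for c in codons:
            third[c[2]] += t.counts[c]
        at = third["A"] + third["T"]
        gc = third["G"] + third["C"]
        if at == 0 or gc == 0:
            warnings.warn(f"{t.gene_id}: PR2 point undefined")
            points.append(None)
            continue
        at_bias = third["A"] / at
        gc_bias = third["G"] / gc
        points.append(
            PR2Point(
                gene_id=t.gene_id,
                at_bias=at_bias,
                gc_bias=gc_bias,
                quadrant=_quadrant(gc_bias, at_bias),
            )
        )
    return points


# ---------------------------------------------------------------------------
# neutrality regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityFit:
    """OLS of GC12 on GC3s with the conventional mutation/selection split."""

    slope: float
    intercept: float
    r: float             # Pearson
    p_value: float
    spearman_rho: float
    spearman_p: float
    n: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def neutrality_fit(profiles: list[CompositionProfile]) -> NeutralityFit:
    """Regress GC12 (y) on GC3s (x) across genes."""
    if len(profiles) < 3:
        raise ValueError("neutrality regression needs at least 3 genes")
    x = np.array([p.gc3s_pct for p in profiles])
    y = np.array([p.gc12_pct for p in profiles])
    if np.ptp(x) == 0:
        raise ValueError("GC3s has zero variance; regression undefined")
    res = stats.linregress(x, y)
    rho, sp = stats.spearmanr(x, y)
    return NeutralityFit(
        slope=res.slope,
        intercept=res.intercept,
        r=res.rvalue,
        p_value=res.pvalue,
        spearman_rho=float(rho),
        spearman_p=float(sp),
        n=len(profiles),
    )


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------

class CorrespondenceAnalysis:
    """Correspondence analysis of a non-negative matrix (e.g. RSCU values).

    Standard chi-square-metric CA: the matrix is scaled to the
    correspondence matrix P, standardized residuals
    (P - r c^T)/sqrt(r c^T) are decomposed by SVD, and principal
    coordinates are returned for rows (genes) and columns (codons).
    Follows the scikit-learn estimator protocol (``fit`` plus fitted
    attributes with trailing underscores).

    Attributes (after ``fit``)
    --------------------------
    row_coords_ : (n_rows, k) principal coordinates
    col_coords_ : (n_cols, k) principal coordinates
    inertia_ : per-axis inertia (squared singular values)
    inertia_pct_ : per-axis percentage of total inertia
    total_inertia_ : sum of inertias (= chi-square / grand total)
    """

    def __init__(self, n_components: int | None = None, tol: float = 1e-12):
        self.n_components = n_components
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "tol": self.tol}

    def set_params(self, **params) -> "CorrespondenceAnalysis":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "CorrespondenceAnalysis":
        if isinstance(X, pd.DataFrame):
            self.row_labels_ = list(X.index)
            self.col_labels_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.row_labels_ = list(range(X.shape[0]))
            self.col_labels_ = list(range(X.shape[1]))
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("CA needs a 2-D matrix with at least 2 rows")
        if np.any(X < 0) or np.any(~np.isfinite(X)):
            raise ValueError("CA input must be finite and non-negative")
        grand = X.sum()
        if grand <= 0:
            raise ValueError("CA input has non-positive grand total")

        P = X / grand
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        keep_r = r > 0
        keep_c = c > 0
        if not keep_r.all() or not keep_c.all():
            warnings.warn("dropping all-zero rows/columns from CA")
        P = P[np.ix_(keep_r, keep_c)]
        r = r[keep_r]
        c = c[keep_c]
        self._keep_rows_ = keep_r
        self._keep_cols_ = keep_c

        E = np.outer(r, c)
        S = (P - E) / np.sqrt(E)
        U, d, Vt = np.linalg.svd(S, full_matrices=False)
        nz = d > self.tol * max(d[0], 1.0) if d.size else np.array([], bool)
        # at most min(n-1, p-1) meaningful axes
        k_max = min(P.shape[0] - 1, P.shape[1] - 1)
        idx = np.flatnonzero(nz)[:k_max]
        if self.n_components is not None:
            idx = idx[: self.n_components]
        d = d[idx]
        U = U[:, idx]
        V = Vt[idx].T

        self.singular_values_ = d
        self.inertia_ = d**2
        self.total_inertia_ = float((S**2).sum())
        self.inertia_pct_ = (
            100.0 * self.inertia_ / self.inertia_.sum()
            if self.inertia_.size
            else np.array([])
        )
        self.row_coords_ = (U * d) / np.sqrt(r)[:, None]
        self.col_coords_ = (V * d) / np.sqrt(c)[:, None]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).row_coords_


@dataclass(frozen=True)
class COAResult:
    row_coords: pd.DataFrame     # genes x axes
    col_coords: pd.DataFrame     # codons x axes
    inertia_pct: np.ndarray
    total_inertia: float


def rscu_matrix(
    genes: list[CodonCountTable], code: GeneticCode = STANDARD_CODE
) -> pd.DataFrame:
    """Genes x 59-codon RSCU matrix (ATG, TGG and stops excluded).

    Missing-family entries (a family unobserved in a gene) are set to 0
    with a warning, keeping the matrix non-negative for CA.
    """
    cols = list(code.synonymous_codons)
    rows = {}
    n_missing = 0
    for t in genes:
        tab = rscu_rfsc(t, code)
        vals = []
        for c in cols:
            v = tab.rscu[c]
            if math.isnan(v):
                n_missing += 1
                v = 0.0
            vals.append(v)
        rows[t.gene_id] = vals
    if n_missing:
        warnings.warn(f"{n_missing} missing-family RSCU entries set to 0")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def correspondence_analysis(
    matrix: pd.DataFrame, n_components: int | None = None
) -> COAResult:
    """CA of a genes x codons RSCU matrix (thin wrapper over the estimator)."""
    ca = CorrespondenceAnalysis(n_components=n_components).fit(matrix)
    axes = [f"axis{i + 1}" for i in range(ca.row_coords_.shape[1])]
    row_index = [l for l, k in zip(ca.row_labels_, ca._keep_rows_) if k]
    col_index = [l for l, k in zip(ca.col_labels_, ca._keep_cols_) if k]
    return COAResult(
        row_coords=pd.DataFrame(ca.row_coords_, index=row_index, columns=axes),
        col_coords=pd.DataFrame(ca.col_coords_, index=col_index, columns=axes),
        inertia_pct=ca.inertia_pct_,
        total_inertia=ca.total_inertia_,
    )
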
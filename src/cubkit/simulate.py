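"""Synthetic CDS generation with controlled codon-usage structure.

Genes are sampled codon-by-codon: the amino acid from a fixed composition,
the codon from per-family synonymous weights.  Three bias modes:

* ``uniform`` — every synonymous codon equally likely (ENC -> 61, SCUO -> 0);
* ``dirichlet`` — per-gene family weights drawn from a Dirichlet whose
  concentration controls bias strength (small alpha = strong bias);
* ``deterministic`` — a single codon per family (ENC = 20, SCUO = 1).

An optional GC3 tilt reweights G/C-ending codons so the expected GC3s of
synonymous families hits a target.  ``emulate_study`` builds a corpus with
the structure of a plant paralog family study: two dozen near-identical
~1.8 kb paralogs with weak bias (dataset means near GC 49%, GC3s 52.5%,
ENC 56) plus a handful of divergent out-group genes.  Every draw is
reproducible from the seed, which is embedded in the gene ids.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .genetic_code import STANDARD_CODE, GeneticCode
from .sequences import CodingSequence

# Amino-acid composition emulating a plant polyphenol-oxidase-like protein:
# Leu/Pro/Asp/Lys-rich, Trp/Cys/Met-poor, aromatic fraction ~0.09.
PPO_LIKE_AA_WEIGHTS: dict[str, float] = {
    "L": 0.0931, "P": 0.0707, "D": 0.0655, "K": 0.0745, "A": 0.0629,
    "G": 0.0607, "S": 0.0746, "V": 0.0529, "T": 0.0522, "E": 0.0554,
    "N": 0.0512, "F": 0.0431, "I": 0.0510, "R": 0.0466, "Q": 0.0351,
    "Y": 0.0299, "H": 0.0250, "M": 0.0213, "W": 0.0190, "C": 0.0153,
}

# Log-scale spread of the fixed within-family weight profile used by
# emulate_study; calibrated once so the paralog set's mean ENC lands near
# the weak-bias regime (~56) at ~600 codons.
_STUDY_SIGMA = 0.52
_STUDY_GC3_TARGET = 0.525
_STUDY_LENGTH = 600          # codons, ~1.8 kb
_STUDY_N_PARALOGS = 24
_STUDY_N_OUTGROUPS = 6
_STUDY_MUTATION_RATE = 0.03  # per-codon synonymous resampling probability


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic gene set."""

    n_genes: int = 24
    length_codons: int = 600
    aa_weights: dict[str, float] = field(
        default_factory=lambda: dict(PPO_LIKE_AA_WEIGHTS)
    )
    bias_mode: str = "uniform"           # uniform | dirichlet | deterministic
    concentration: float = 1.0           # Dirichlet alpha scale
    gc3_target: float | None = None      # expected GC3s of synonymous codons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.length_codons < 10:
            raise ValueError("length_codons must be >= 10")
        if self.bias_mode not in ("uniform", "dirichlet", "deterministic"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        total = sum(self.aa_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            object.__setattr__(
                self,
                "aa_weights",
                {k: v / total for k, v in self.aa_weights.items()},
            )


# ---------------------------------------------------------------------------
# family-weight machinery
# ---------------------------------------------------------------------------

def _gc3_tilt(
    weights: dict[str, dict[str, float]],
    aa_weights: dict[str, float],
    target: float,
    code: GeneticCode,
    preserve_prefix: bool = False,
) -> dict[str, dict[str, float]]:
    """Reweight G/C-ending codons by a factor solved so the expected GC3s
    over synonymous families equals ``target``.

    With ``preserve_prefix=True`` the tilt acts within 2-nt-prefix groups,
    leaving first/second-position content untouched.
    """
    deg = [aa for aa in code.degenerate_aas if aa_weights.get(aa, 0) > 0]
    if not deg:
        raise ValueError("no degenerate families with positive amino-acid weight")

    def tilted(lam: float) -> dict[str, dict[str, float]]:
        out = {}
        for aa, fam_w in weights.items():
            w = {c: v * (lam if c[2] in "GC" else 1.0) for c, v in fam_w.items()}
            tot = sum(w.values())
            w = {c: v / tot for c, v in w.items()}
            if preserve_prefix and len(fam_w) > 1:
                w = _preserve_prefix_mass(w, code, aa)
            out[aa] = w
        return out

    def expected_gc3(lam: float) -> float:
        w = tilted(lam)
        num = den = 0.0
        for aa in deg:
            gc = sum(v for c, v in w[aa].items() if c[2] in "GC")
            num += aa_weights[aa] * gc
            den += aa_weights[aa]
        return num / den

    lo, hi = 1e-9, 1e9
    if not expected_gc3(lo) <= target <= expected_gc3(hi):
        raise ValueError(f"gc3_target {target} infeasible for the chosen families")
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if expected_gc3(mid) < target:
            lo = mid
        else:
            hi = mid
    return tilted(math.sqrt(lo * hi))


def _prefix_groups(fam: tuple[str, ...]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for c in fam:
        groups.setdefault(c[:2], []).append(c)
    return groups


def _preserve_prefix_mass(
    fam_w: dict[str, float], code: GeneticCode, aa: str
) -> dict[str, float]:
    """Rescale within 2-nt-prefix groups so each group keeps its uniform
    share of the family (n_group/n_family).

    Keeps first- and second-position base content a function of amino-acid
    composition alone, so third-position manipulation cannot leak into
    GC12 (the construction behind a near-zero neutrality slope).
    """
    fam = code.family(aa)
    out: dict[str, float] = {}
    for prefix, codons in _prefix_groups(fam).items():
        target_mass = len(codons) / len(fam)
        mass = sum(fam_w[c] for c in codons)
        for c in codons:
            out[c] = fam_w[c] / mass * target_mass
    return out


def _base_family_weights(code: GeneticCode) -> dict[str, dict[str, float]]:
    return {
        aa: {c: 1.0 / len(code.family(aa)) for c in code.family(aa)}
        for aa in code.amino_acids
    }


def _normalize(fam_w: dict[str, float]) -> dict[str, float]:
    tot = sum(fam_w.values())
    return {c: v / tot for c, v in fam_w.items()}


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _balanced_gene(
    rng: np.random.Generator,
    gene_id: str,
    length: int,
    aa_weights: dict[str, float],
    family_weights: dict[str, dict[str, float]],
    code: GeneticCode,
) -> CodingSequence:
    """A gene whose realized codon counts match the target profile as
    closely as integer counts allow; only the codon order is random."""
    aas = list(aa_weights)
    aa_n = _largest_remainder(np.array([aa_weights[a] for a in aas]), length)
    codons: list[str] = []
    for aa, n in zip(aas, aa_n):
        if n == 0:
            continue
        fam = code.family(aa)
        fam_n = _largest_remainder(
            np.array([family_weights[aa][c] for c in fam]), int(n)
        )
        for c, k in zip(fam, fam_n):
            codons.extend([c] * int(k))
    order = rng.permutation(len(codons))
    return CodingSequence(
        id=gene_id, seq="".join(codons[i] for i in order) + "TAA"
    )


def _sample_gene(
    rng: np.random.Generator,
    gene_id: str,
    length: int,
    aa_weights: dict[str, float],
    family_weights: dict[str, dict[str, float]],
    code: GeneticCode,
) -> CodingSequence:
    aas = list(aa_weights)
    p = np.array([aa_weights[a] for a in aas])
    p = p / p.sum()
    choices = rng.choice(len(aas), size=length, p=p)
    codons: list[str | None] = [None] * length
    for ai, aa in enumerate(aas):
        idx = np.flatnonzero(choices == ai)
        if idx.size == 0:
            continue
        fam = code.family(aa)
        w = np.array([family_weights[aa][c] for c in fam])
        draws = rng.choice(len(fam), size=idx.size, p=w / w.sum())
        for j, d in zip(idx, draws):
            codons[j] = fam[d]
    return CodingSequence(id=gene_id, seq="".join(codons) + "TAA")


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], dict]:
    """Generate a gene set from ``spec``; returns (records, truth record).

    The truth record stores the exact per-gene family weights actually
    sampled, so downstream estimates can be checked against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_family_weights(code)
    if spec.gc3_target is not None:
        base = _gc3_tilt(base, spec.aa_weights, spec.gc3_target, code)

    records: list[CodingSequence] = []
    truth_weights: dict[str, dict[str, dict[str, float]]] = {}
    for g in range(spec.n_genes):
        gene_id = f"synth{spec.seed}_g{g + 1:03d}"
        if spec.bias_mode == "uniform":
            fam_w = base
        elif spec.bias_mode == "deterministic":
            fam_w = {}
            for aa, w in base.items():
                best = max(sorted(w), key=lambda c: w[c])
                fam_w[aa] = {c: (1.0 if c == best else 0.0) for c in w}
        else:  # dirichlet
            fam_w = {}
            for aa, w in base.items():
                fam = list(w)
                if len(fam) == 1:
                    fam_w[aa] = dict(w)
                    continue
                alpha = spec.concentration * len(fam) * np.array([w[c] for c in fam])
                draw = rng.dirichlet(np.maximum(alpha, 1e-8))
                fam_w[aa] = dict(zip(fam, draw))
        records.append(
            _sample_gene(rng, gene_id, spec.length_codons, spec.aa_weights, fam_w, code)
        )
        truth_weights[gene_id] = {aa: dict(w) for aa, w in fam_w.items()}

    truth = {
        "spec": asdict(spec),
        "family_weights": truth_weights,
    }
    return records, truth


def _mutate_synonymous(
    rng: np.random.Generator,
    parent: CodingSequence,
    gene_id: str,
    rate: float,
    family_weights: dict[str, dict[str, float]],
    code: GeneticCode,
) -> CodingSequence:
    """Resample codons synonymously at ``rate``; amino acids never change."""
    codons = parent.codons()
    hits = np.flatnonzero(rng.random(len(codons)) < rate)
    out = list(codons)
    for i in hits:
        aa = code.codon_to_aa[codons[i]]
        if aa == "*" or code.degeneracy(aa) == 1:
            continue
        fam = code.family(aa)
        w = np.array([family_weights[aa][c] for c in fam])
        out[i] = fam[rng.choice(len(fam), p=w / w.sum())]
    return CodingSequence(id=gene_id, seq="".join(out))


def emulate_study(
    seed: int, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], dict]:
    """A study-like corpus: 24 near-identical weak-bias paralogs of ~1.8 kb
    plus 6 divergent out-group genes.

    Paralogs descend from one ancestor by synonymous-only point
    resampling, so their amino-acid profile (hence GC12) is fixed and
    pairwise identity stays >= 95%.
    """
    rng = np.random.default_rng(seed)
    base = _base_family_weights(code)

    # fixed mildly-uneven within-family profile (shared by all paralogs);
    # drawn from a generator seeded independently of `seed` so the profile
    # is a package constant, then tilted to the target GC3s
    profile_rng = np.random.default_rng(20250901)
    skewed = {}
    for aa, w in base.items():
        fam = list(w)
        if len(fam) == 1:
            skewed[aa] = dict(w)
            continue
        z = profile_rng.normal(0.0, _STUDY_SIGMA, size=len(fam))
        skewed[aa] = _normalize(dict(zip(fam, np.exp(z) / len(fam))))
    skewed = _gc3_tilt(skewed, PPO_LIKE_AA_WEIGHTS, _STUDY_GC3_TARGET, code, preserve_prefix=True)

    ancestor = _balanced_gene(
        rng, f"emu{seed}_cs001", _STUDY_LENGTH, PPO_LIKE_AA_WEIGHTS, skewed, code
    )
    records = [ancestor]
    for g in range(1, _STUDY_N_PARALOGS):
        records.append(
            _mutate_synonymous(
                rng,
                ancestor,
                f"emu{seed}_cs{g + 1:03d}",
                _STUDY_MUTATION_RATE,
                skewed,
                code,
            )
        )
    # trailing stop lost by codons() round trip on mutants: re-append
    records = [
        r if r.seq.endswith(("TAA", "TAG", "TGA")) and len(r.seq) % 3 == 0
        else CodingSequence(r.id, r.seq + "TAA")
        for r in records
    ]

    # divergent out-groups: perturbed amino-acid profile, own bias profile,
    # GC3s spread around the paralog value
    gc3_targets = np.linspace(0.44, 0.58, _STUDY_N_OUTGROUPS)
    aas = list(PPO_LIKE_AA_WEIGHTS)
    base_aa = np.array([PPO_LIKE_AA_WEIGHTS[a] for a in aas])
    base_aa = base_aa / base_aa.sum()
    for g in range(_STUDY_N_OUTGROUPS):
        aa_w = dict(zip(aas, rng.dirichlet(2000.0 * base_aa)))
        out_profile = {}
        for aa, w in base.items():
            fam = list(w)
            if len(fam) == 1:
                out_profile[aa] = dict(w)
                continue
            z = rng.normal(0.0, _STUDY_SIGMA, size=len(fam))
            out_profile[aa] = _normalize(dict(zip(fam, np.exp(z) / len(fam))))
        out_profile = _gc3_tilt(out_profile, aa_w, float(gc3_targets[g]), code, preserve_prefix=True)
        records.append(
            _balanced_gene(
                rng,
                f"emu{seed}_og{g + 1:03d}",
                _STUDY_LENGTH + int(rng.integers(-40, 41)),
                aa_w,
                out_profile,
                code,
            )
        )

    truth = {
        "seed": seed,
        "n_paralogs": _STUDY_N_PARALOGS,
        "n_outgroups": _STUDY_N_OUTGROUPS,
        "length_codons": _STUDY_LENGTH,
        "gc3_target": _STUDY_GC3_TARGET,
        "mutation_rate": _STUDY_MUTATION_RATE,
        "paralog_family_weights": {aa: dict(w) for aa, w in skewed.items()},
    }
    return records, truth


def plant_neutrality(
    n_genes: int = 24,
    length_codons: int = 700,
    gamma: float = 1.2,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[CodingSequence], dict]:
    """Gene set with a planted GC12-on-GC3s regression slope.

    Genes interpolate between two endpoint regimes: A (AT-leaning third
    positions, AT-codon-rich amino acids) and B (GC-leaning third
    positions, amino acids with G/C at the first two positions, boosted by
    ``gamma``).  Because first/second-position GC content is set almost
    entirely by amino-acid composition, a sizeable planted slope requires
    the composition itself to follow the GC3s gradient — mimicking
    genome-wide mutational pressure.  The truth record carries the
    noiseless regression slope over the per-gene expected (GC3s, GC12)
    pairs.
    """
    base = _base_family_weights(code)

    # amino-acid GC content at codon positions 1-2 (family-averaged)
    def aa_gc12(aa: str) -> float:
        fam = code.family(aa)
        return sum(((c[0] in "GC") + (c[1] in "GC")) / 2 for c in fam) / len(fam)

    base_aa = np.array([PPO_LIKE_AA_WEIGHTS[a] for a in PPO_LIKE_AA_WEIGHTS])
    gc12_vec = np.array([aa_gc12(a) for a in PPO_LIKE_AA_WEIGHTS])
    aa_names = list(PPO_LIKE_AA_WEIGHTS)

    def aa_endpoint(direction: float) -> dict[str, float]:
        w = base_aa * np.exp(direction * gamma * (gc12_vec - gc12_vec.mean()))
        w = w / w.sum()
        return dict(zip(aa_names, w))

    aa_a = aa_endpoint(-0.5)
    aa_b = aa_endpoint(+0.5)

    prof_a = _gc3_tilt(base, aa_a, 0.32, code)
    prof_b = _gc3_tilt(base, aa_b, 0.68, code)

    def expectations(
        aa_w: dict[str, float], w: dict[str, dict[str, float]]
    ) -> tuple[float, float]:
        """Expected (GC3s, GC12) in percent for one gene's exact weights."""
        gc12 = gc3 = den3 = 0.0
        for aa in code.amino_acids:
            for c, v in w[aa].items():
                gc12 += aa_w[aa] * v * ((c[0] in "GC") + (c[1] in "GC")) / 2.0
            if code.degeneracy(aa) >= 2:
                gc3 += aa_w[aa] * sum(v for c, v in w[aa].items() if c[2] in "GC")
                den3 += aa_w[aa]
        return 100.0 * gc3 / den3, 100.0 * gc12

    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, n_genes)
    records = []
    ex_x, ex_y = [], []
    for g, t in enumerate(ts):
        aa_w = {a: (1 - t) * aa_a[a] + t * aa_b[a] for a in aa_names}
        mix = {
            aa: {
                c: (1 - t) * prof_a[aa][c] + t * prof_b[aa][c]
                for c in code.family(aa)
            }
            for aa in code.amino_acids
        }
        x, y = expectations(aa_w, mix)
        ex_x.append(x)
        ex_y.append(y)
        records.append(
            _sample_gene(
                rng, f"neut{seed}_g{g + 1:03d}", length_codons, aa_w, mix, code
            )
        )
    ex_x = np.array(ex_x)
    ex_y = np.array(ex_y)
    slope_true = float(
        np.cov(ex_x, ex_y, bias=True)[0, 1] / np.var(ex_x)
    )
    truth = {
        "slope": slope_true,
        "expected_gc3s_pct": ex_x.tolist(),
        "expected_gc12_pct": ex_y.tolist(),
        "seed": seed,
    }
    return records, truth


def plant_optimal_codons(
    targets: tuple[str, ...],
    n_genes: int = 30,
    length_codons: int = 400,
    quantile: float = 0.10,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[CodingSequence], dict]:
    """Gene set with codons up-weighted only in a strongly-biased subset.

    A ``quantile`` fraction of genes are built with strong overall bias
    (they will occupy the low-ENC extreme) and heavy use of ``targets``;
    the remainder are near-uniform with ``targets`` mildly avoided.  The
    planted codons therefore satisfy the optimal-codon definition
    (RSCU_high > 1, RSCU_low < 1, positive ΔRSCU) by construction.
    """
    for t in targets:
        aa = code.codon_to_aa[t]
        if aa == "*" or code.degeneracy(aa) < 2:
            raise ValueError(f"target codon {t} is not in a degenerate family")
    rng = np.random.default_rng(seed)
    base = _base_family_weights(code)
    target_set = set(targets)

    n_biased = max(1, int(math.floor(quantile * n_genes + 0.5)))
    records = []
    for g in range(n_genes):
        biased = g < n_biased
        fam_w = {}
        for aa, w in base.items():
            fam = list(w)
            if len(fam) == 1:
                fam_w[aa] = dict(w)
                continue
            hit = [c for c in fam if c in target_set]
            if biased:
                if hit:
                    # favored target gets most of the family mass
                    ww = {c: (0.8 / len(hit) if c in target_set else 0.2 / (len(fam) - len(hit))) for c in fam}
                else:
                    # generic strong bias toward one codon lowers ENC
                    best = sorted(fam)[0]
                    ww = {c: (0.6 if c == best else 0.4 / (len(fam) - 1)) for c in fam}
            else:
                if hit:
                    ww = _normalize(
                        {c: (0.5 / len(fam) if c in target_set else 1.0 / len(fam)) for c in fam}
                    )
                else:
                    ww = dict(w)
            fam_w[aa] = ww
        records.append(
            _sample_gene(
                rng,
                f"plant{seed}_{'hi' if biased else 'lo'}{g + 1:03d}",
                length_codons,
                PPO_LIKE_AA_WEIGHTS,
                fam_w,
                code,
            )
        )
    truth = {"targets": sorted(target_set), "n_biased": n_biased, "seed": seed}
    return records, truth


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
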
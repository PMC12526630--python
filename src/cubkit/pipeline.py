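"""End-to-end orchestration: run every analysis stage on a CDS FASTA (or
the built-in study emulation) and write all result tables.

Outputs are TSV with a two-line header (column names, then a ``#``-prefixed
units/convention line) plus JSON for scalar summaries and a run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import composition_frame, composition_profile, dataset_means
from .counts import CodonCountTable, count_codons, pool_counts
from .expression import (
    aa_usage,
    correlation_panel,
    dataset_codon_frequencies,
    host_divergence_ranges,
    milc,
    packaged_host_tables,
    read_cusp,
    scuo,
)
from .forces import (
    correspondence_analysis,
    enc_plot,
    neutrality_fit,
    pr2_plot,
    rscu_matrix,
)
from .genetic_code import STANDARD_CODE
from .indices import ReferenceWeights, bias_indices, indices_frame
from .rscu import classify_codons, classification_frame, optimal_codons, rscu_rfsc
from .sequences import read_fasta, validate_cds, write_fasta
from .simulate import emulate_study

log = logging.getLogger("cubkit")

OUTPUT_FILES = [
    "composition.tsv", "indices.tsv", "rscu.tsv", "hf_codons.tsv",
    "optimal_codons.tsv", "host_comparison.tsv", "enc_plot.tsv", "pr2.tsv",
    "neutrality.json", "coa.tsv", "expression.tsv", "correlations.tsv",
    "aa_usage.tsv",
]

# The default Spearman panel: bias indices against composition metrics.
DEFAULT_CORRELATION_PAIRS = [
    ("ENC", m) for m in ("GC", "GC1", "GC2", "GC3s", "A3s", "T3s", "C3s", "G3s", "AT3")
] + [
    ("CAI", m) for m in ("GC", "GC1", "GC2", "GC3s", "A3s", "T3s", "C3s", "G3s", "AT3")
] + [
    ("GRAVY", m) for m in ("ENC", "A3s", "T3s", "C3s", "G3s", "GC3s")
] + [
    ("AROMA", m) for m in ("ENC", "A3s", "T3s", "C3s", "G3s", "GC3s")
] + [("SCUO", "MILC")]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    fasta: str | None = None          # None -> run on the study emulation
    groups: str | None = None         # sample-sheet TSV: accession<TAB>label
    focal_group: str | None = None    # dataset-level stats restricted to it
    hf_rule: str = "rfsc60"
    quantile: float = 0.10
    cai_reference: str | None = None  # TSV path; None -> packaged E. coli
    milc_expected: str = "uniform"    # uniform | dataset-mean
    host_dir: str | None = None       # directory of cusp tables; None -> packaged
    outdir: str = "cubkit_out"
    seed: int = 0
    policy: str = "lenient"

    def __post_init__(self) -> None:
        if not 0 < self.quantile <= 0.5:
            raise ValueError("quantile must be in (0, 0.5]")
        for p in (self.fasta, self.groups, self.cai_reference, self.host_dir):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_tsv(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        fh.write(f"# {units}\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def run_all(config: RunConfig) -> Path:
    """Run every stage and write all output tables; returns the out dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    code = STANDARD_CODE

    try:
        # ---- inputs -----------------------------------------------------
        stage = "input"
        if config.fasta is None:
            records, _ = emulate_study(config.seed)
            write_fasta(records, outdir / "simulated_input.fasta")
            groups = {
                r.id: ("focal" if "_cs" in r.id else "outgroup") for r in records
            }
            focal = "focal"
        else:
            records = read_fasta(config.fasta)
            groups = {r.id: "all" for r in records}
            focal = config.focal_group or "all"
            if config.groups:
                sheet = pd.read_csv(
                    config.groups, sep="\t", header=None, comment="#"
                )
                groups.update(dict(zip(sheet[0].astype(str), sheet[1].astype(str))))
                if config.focal_group is None:
                    focal = sheet[1].astype(str).iloc[0]
        log.info("read %d CDS records", len(records))

        stage = "validation"
        tables: list[CodonCountTable] = []
        for rec in records:
            try:
                tables.append(
                    count_codons(
                        validate_cds(
                            rec, config.policy, code, trim_trailing_stop=False
                        ),
                        code,
                    )
                )
            except Exception as exc:
                raise RuntimeError(f"stage {stage}, gene {rec.id}: {exc}") from exc
        focal_tables = [t for t in tables if groups.get(t.gene_id) == focal]
        if not focal_tables:
            focal_tables = tables

        ref = (
            ReferenceWeights.from_tsv(config.cai_reference)
            if config.cai_reference
            else ReferenceWeights.sharp_ecoli()
        )

        # ---- per-gene panels -------------------------------------------
        stage = "composition"
        profiles = [composition_profile(t, code) for t in tables]
        focal_ids = {t.gene_id for t in focal_tables}
        comp = composition_frame(profiles + [dataset_means(
            [p for p in profiles if p.gene_id in focal_ids],
            label=f"mean({focal})",
        )])
        _write_tsv(comp, outdir / "composition.tsv",
                   "percent; 3s metrics CodonW convention, AT3 over all sense codons")

        stage = "indices"
        idx_rows = [bias_indices(t, ref, code) for t in tables]
        _write_tsv(indices_frame(idx_rows), outdir / "indices.tsv",
                   f"ENC Wright; CAI/CBI reference {ref.name}; GRAVY Kyte-Doolittle")

        # ---- RSCU and codon sets ---------------------------------------
        stage = "rscu"
        pooled = pool_counts(focal_tables, label=focal)
        table = rscu_rfsc(pooled, code)
        cls = classify_codons(table, config.hf_rule, code)
        opt = optimal_codons(focal_tables, config.quantile, code)
        cls.optimal = opt.optimal
        cls.delta_rscu = opt.delta_rscu
        _write_tsv(classification_frame(table, cls, pooled, code),
                   outdir / "rscu.tsv",
                   f"pooled {focal} counts; hf_rule={config.hf_rule}")
        _write_tsv(
            pd.DataFrame([{
                "dataset": focal,
                "n_hf_codons": len(cls.high_freq),
                "hf_codons": ", ".join(sorted(cls.high_freq)),
            }]),
            outdir / "hf_codons.tsv", f"high-frequency rule {config.hf_rule}")
        _write_tsv(
            pd.DataFrame([{
                "dataset": focal,
                "n_optimal": len(cls.optimal),
                "optimal_codons": ", ".join(sorted(cls.optimal)),
                "quantile": config.quantile,
            }]),
            outdir / "optimal_codons.tsv", "delta-RSCU >= 0.08 rule")

        # ---- host comparison -------------------------------------------
        stage = "hosts"
        if config.host_dir:
            hosts = {
                p.stem.split(".")[0]: read_cusp(p)
                for p in sorted(Path(config.host_dir).glob("*.cusp"))
            }
        else:
            hosts = packaged_host_tables()
        host_df = host_divergence_ranges(focal_tables, hosts, code)
        _write_tsv(host_df, outdir / "host_comparison.tsv",
                   "divergent: gene/host per-1000 ratio <=0.5 or >=2, per gene min-max")

        # ---- selection-force diagnostics -------------------------------
        stage = "forces"
        encp = enc_plot(tables, code)
        _write_tsv(
            pd.DataFrame([p.__dict__ for p in encp]), outdir / "enc_plot.tsv",
            "gc3s fraction; enc_exp Wright mutation-only curve")
        pr2 = [p for p in pr2_plot(tables, code) if p is not None]
        _write_tsv(pd.DataFrame([p.__dict__ for p in pr2]), outdir / "pr2.tsv",
                   "third positions of all sense codons; center (0.5, 0.5)")
        nf = neutrality_fit(profiles)
        (outdir / "neutrality.json").write_text(json.dumps({
            "slope": nf.slope, "intercept": nf.intercept, "r": nf.r,
            "p_value": nf.p_value, "spearman_rho": nf.spearman_rho,
            "mutation_pct": nf.mutation_pct, "selection_pct": nf.selection_pct,
            "n": nf.n,
        }, indent=1))
        coa = correspondence_analysis(rscu_matrix(focal_tables, code))
        coa_rows = coa.row_coords.copy()
        coa_rows.insert(0, "item", coa_rows.index)
        coa_rows.insert(0, "kind", "gene")
        coa_cols = coa.col_coords.copy()
        coa_cols.insert(0, "item", coa_cols.index)
        coa_cols.insert(0, "kind", "codon")
        inertia = pd.DataFrame({
            "kind": "inertia_pct",
            "item": [f"axis{i+1}" for i in range(len(coa.inertia_pct))],
            "axis1": coa.inertia_pct,
        })
        _write_tsv(pd.concat([coa_rows, coa_cols, inertia], ignore_index=True),
                   outdir / "coa.tsv",
                   "principal coordinates of the 59-codon RSCU matrix")

        # ---- expression proxies and correlations -----------------------
        stage = "expression"
        g_mean = (
            dataset_codon_frequencies(focal_tables, code)
            if config.milc_expected == "dataset-mean"
            else None
        )
        expr = pd.DataFrame({
            "accession": [t.gene_id for t in tables],
            "SCUO": [scuo(t, code) for t in tables],
            "MILC_uniform": [milc(t, "uniform", code) for t in tables],
            "MILC_dataset": [
                milc(t, g_mean, code) if g_mean is not None else np.nan
                for t in tables
            ],
        })
        _write_tsv(expr, outdir / "expression.tsv",
                   "SCUO entropy-deficit; MILC vs uniform / dataset-mean expected")

        usage = aa_usage(focal_tables, code)
        _write_tsv(
            pd.DataFrame(sorted(usage.items(), key=lambda kv: -kv[1]),
                         columns=["amino_acid", "pct"]),
            outdir / "aa_usage.tsv", f"pooled {focal} residue percentages")

        stage = "correlations"
        metrics = pd.DataFrame({
            "ENC": [r.enc for r in idx_rows],
            "CAI": [r.cai for r in idx_rows],
            "GRAVY": [r.gravy for r in idx_rows],
            "AROMA": [r.aroma for r in idx_rows],
            "GC": [p.gc_pct for p in profiles],
            "GC1": [p.gc1_pct for p in profiles],
            "GC2": [p.gc2_pct for p in profiles],
            "GC3s": [p.gc3s_pct for p in profiles],
            "A3s": [p.a3s_pct for p in profiles],
            "T3s": [p.t3s_pct for p in profiles],
            "C3s": [p.c3s_pct for p in profiles],
            "G3s": [p.g3s_pct for p in profiles],
            "AT3": [p.at3_pct for p in profiles],
            "SCUO": expr["SCUO"],
            "MILC": expr["MILC_uniform"],
        }, index=[t.gene_id for t in tables])
        panel = correlation_panel(
            metrics.loc[[t.gene_id for t in focal_tables]], DEFAULT_CORRELATION_PAIRS
        )
        _write_tsv(panel.frame(), outdir / "correlations.tsv",
                   "Spearman rho, two-sided p; * p<0.05")

        # ---- manifest ---------------------------------------------------
        manifest = {
            "cubkit_version": __version__,
            "python": platform.python_version(),
            "n_genes": len(tables),
            "focal_group": focal,
            "focal_n": len(focal_tables),
            "config": {k: getattr(config, k) for k in vars(config)},
            "outputs": OUTPUT_FILES,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("wrote %d outputs to %s", len(OUTPUT_FILES), outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
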
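"""SCUO/MILC proxies, amino-acid usage, host screening and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit import (
    STANDARD_CODE,
    CodingSequence,
    CodonCountTable,
    HostUsageTable,
    aa_usage,
    correlation_panel,
    count_codons,
    enc,
    host_compare,
    milc,
    packaged_host_tables,
    read_cusp,
    scuo,
)
from cubkit.expression import dataset_codon_frequencies

from .conftest import deterministic_counts, uniform_counts

code = STANDARD_CODE


class TestScuo:
    def test_single_codon_per_family_is_1(self):
        assert scuo(deterministic_counts()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_usage_is_0(self):
        assert scuo(uniform_counts()) == pytest.approx(0.0, abs=1e-12)

    def test_value_in_unit_interval(self, study_corpus):
        _, tables, _ = study_corpus
        for t in tables:
            assert 0.0 <= scuo(t) <= 1.0

    def test_anticorrelated_with_enc_across_bias_strengths(self):
        from cubkit import SyntheticSpec, generate

        encs, scuos = [], []
        for conc, seed in ((8.0, 1), (1.0, 2), (0.2, 3), (0.05, 4)):
            spec = SyntheticSpec(
                n_genes=25, length_codons=300, bias_mode="dirichlet",
                concentration=conc, seed=seed,
            )
            for rec in generate(spec)[0]:
                t = count_codons(rec)
                encs.append(enc(t))
                scuos.append(scuo(t))
        rho, _ = stats.spearmanr(encs, scuos)
        assert rho < 0


class TestMilc:
    def test_observed_equals_expected_gives_minus_c(self):
        # exactly uniform within-family counts: every M_a = 0, MILC = -C
        t = uniform_counts(per_codon=10)
        L = t.total_codons
        df = sum(code.degeneracy(aa) - 1 for aa in code.amino_acids)
        assert milc(t) == pytest.approx(-(df / L - 0.5), abs=1e-12)

    def test_lower_bound_reached_only_at_uniform(self, study_corpus):
        _, tables, _ = study_corpus
        for t in tables[:5]:
            L = t.total_codons
            df = sum(
                code.degeneracy(aa) - 1
                for aa in code.amino_acids
                if any(t.counts[c] for c in code.family(aa))
            )
            assert milc(t) >= -(df / L - 0.5) - 1e-12

    def test_doubling_counts_changes_by_o_one_over_l(self, study_corpus):
        # deviation terms scale exactly; only the length correction moves,
        # by df/(2L)
        _, tables, _ = study_corpus
        t = tables[0]
        L = t.total_codons
        df = sum(
            code.degeneracy(aa) - 1
            for aa in code.amino_acids
            if any(t.counts[c] for c in code.family(aa))
        )
        assert abs(milc(t) - milc(t + t)) == pytest.approx(df / (2 * L), abs=1e-12)
        assert abs(milc(t) - milc(t + t)) < 50.0 / L

    def test_dataset_mean_expected_distribution(self, study_corpus):
        _, tables, _ = study_corpus
        g = dataset_codon_frequencies(tables)
        vals = [milc(t, g) for t in tables[:24]]
        # paralogs hew to the dataset mean, so deviation is smaller than
        # against the uniform expectation
        assert np.mean(vals) < np.mean([milc(t) for t in tables[:24]])

    def test_zero_expected_for_observed_codon_errors(self):
        t = CodonCountTable("g", {"GCA": 5, "GCT": 5})
        g = {c: 0.0 for c in code.sense_codons}
        g["GCT"] = 1.0
        with pytest.raises(ValueError, match="expected frequency 0"):
            milc(t, g)


class TestAaUsage:
    def test_poly_alanine(self):
        usage = aa_usage([count_codons(CodingSequence("g", "GCT" * 10))])
        assert usage["A"] == pytest.approx(100.0)

    def test_toy_maaaw(self, toy_counts):
        usage = aa_usage([toy_counts])
        assert usage["M"] == pytest.approx(20.0)
        assert usage["A"] == pytest.approx(60.0)
        assert usage["W"] == pytest.approx(20.0)

    def test_sums_to_100_and_ranks_match_generator(self, study_corpus):
        _, tables, _ = study_corpus
        usage = aa_usage(tables[:24])
        assert sum(usage.values()) == pytest.approx(100.0, abs=1e-9)
        top4 = sorted(usage, key=usage.get, reverse=True)[:4]
        assert "L" in top4                        # Leu-rich profile
        bottom3 = sorted(usage, key=usage.get)[:3]
        assert set(bottom3) <= {"W", "C", "M", "H"}


class TestHostCompare:
    @staticmethod
    def table_from_counts(t: CodonCountTable, name: str) -> HostUsageTable:
        L = t.total_codons
        return HostUsageTable(
            host_name=name,
            freq={c: 1000.0 * t.counts[c] / L for c in code.sense_codons},
        )

    def test_gene_vs_itself_has_no_divergence(self, study_corpus):
        _, tables, _ = study_corpus
        t = tables[0]
        host = self.table_from_counts(t, "self")
        assert host_compare(t, host).n_divergent == 0

    def test_boundary_ratio_2_is_divergent(self):
        t = CodonCountTable("g", {"GCA": 10, "GCT": 10})
        freq = {c: 0.0 for c in code.sense_codons}
        freq["GCA"] = 250.0   # gene usage 500/1000 -> ratio exactly 2
        freq["GCT"] = 750.0
        host = HostUsageTable("h", freq)
        cmp = host_compare(t, host)
        assert cmp.ratio["GCA"] == pytest.approx(2.0)
        assert "GCA" in cmp.divergent

    def test_unused_host_codon_is_infinite_and_divergent(self):
        t = CodonCountTable("g", {"GCA": 5, "GCT": 5})
        freq = {c: 0.0 for c in code.sense_codons}
        freq["GCT"] = 1000.0
        host = HostUsageTable("h", freq)
        cmp = host_compare(t, host)
        assert math.isinf(cmp.ratio["GCA"])
        assert "GCA" in cmp.divergent

    def test_role_exchange_symmetry(self, study_corpus):
        # with both usages on the per-1000 scale the ratio inverts, and the
        # <=0.5 / >=2 rule is symmetric
        _, tables, _ = study_corpus
        a, b = tables[0], tables[-1]
        div_ab = host_compare(a, self.table_from_counts(b, "b")).divergent
        div_ba = host_compare(b, self.table_from_counts(a, "a")).divergent
        common = {
            c for c in code.sense_codons if a.counts[c] > 0 and b.counts[c] > 0
        }
        assert div_ab & common == div_ba & common

    def test_packaged_tables_load(self):
        hosts = packaged_host_tables()
        assert set(hosts) == {
            "e_coli", "s_cerevisiae", "a_thaliana", "n_tabacum",
            "t_aestivum", "z_mays",
        }
        for h in hosts.values():
            assert sum(h.freq.values()) == pytest.approx(1000.0, abs=1.0)

    def test_cusp_round_trip(self, tmp_path):
        p = tmp_path / "tiny.cusp"
        p.write_text("#Codon AA Fraction Frequency Number\n"
                     "GCA A 0.5 600.0 60\nGCT A 0.5 400.0 40\n")
        host = read_cusp(p)
        assert host.freq == {"GCA": 600.0, "GCT": 400.0}


class TestCorrelationPanel:
    def test_monotone_identity_and_reversal(self):
        df = pd.DataFrame({"x": np.arange(12.0), "y": np.arange(12.0) ** 3,
                           "z": -np.arange(12.0)})
        panel = correlation_panel(df, [("x", "y"), ("x", "z")])
        (x, y, rho1, p1, s1), (_, _, rho2, p2, s2) = panel.pairs
        assert rho1 == pytest.approx(1.0)
        assert rho2 == pytest.approx(-1.0)
        assert s1 and s2

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        panel = correlation_panel(df, [("x", "y")])
        rho = panel.pairs[0][2]
        rx = stats.rankdata(df["x"])
        ry = stats.rankdata(df["y"])
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_exact_permutation_p_for_small_n(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 2, 3, 4, 5]})
        panel = correlation_panel(df, [("x", "y")])
        # perfect rank agreement among 5! orderings: two-sided p = 2/120
        assert panel.pairs[0][3] == pytest.approx(2 / 120)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="constant"):
            panel = correlation_panel(df, [("x", "y")])
        assert math.isnan(panel.pairs[0][2])
        assert not panel.pairs[0][4]

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            correlation_panel(pd.DataFrame({"x": [1.0], "y": [2.0]}), [("x", "y")])
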
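"""ENC plot, PR2 plot, neutrality regression and correspondence analysis."""

import numpy as np
import pytest
from scipy import stats

from cubkit import (
    STANDARD_CODE,
    CodonCountTable,
    CorrespondenceAnalysis,
    composition_profile,
    correspondence_analysis,
    enc_expected,
    enc_plot,
    neutrality_fit,
    pr2_plot,
    rscu_matrix,
)

from .conftest import deterministic_counts, uniform_counts

code = STANDARD_CODE


class TestEncExpected:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_errors(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                enc_expected(bad)

    def test_maximum_at_interior_point(self):
        grid = np.linspace(0, 1, 2001)
        vals = [enc_expected(s) for s in grid]
        s_max = grid[int(np.argmax(vals))]
        assert 0.4 < s_max < 0.6
        assert max(vals) <= 61.04


class TestEncPlot:
    def test_biased_genes_fall_below_curve(self):
        points = enc_plot([deterministic_counts()])
        assert points[0].below_curve
        assert points[0].enc_obs == pytest.approx(20.0)

    def test_uniform_genes_on_or_above_curve(self):
        points = enc_plot([uniform_counts(per_codon=200)])
        # unbiased usage sits at the top of the curve
        assert points[0].enc_obs >= points[0].enc_exp - 1.0

    def test_boundary_equality_is_not_below(self):
        points = enc_plot([uniform_counts()])
        p = points[0]
        assert p.below_curve == (p.enc_obs < p.enc_exp)


class TestPr2:
    @staticmethod
    def counts_with_thirds(a=0, t=0, g=0, c=0) -> CodonCountTable:
        # Ala codons realize any third-position multiset
        return CodonCountTable(
            "g", {"GCA": a, "GCT": t, "GCG": g, "GCC": c}
        )

    def test_hand_derived_biases(self):
        [p] = pr2_plot([self.counts_with_thirds(a=1, t=3, g=3, c=1)])
        assert p.at_bias == pytest.approx(0.25)
        assert p.gc_bias == pytest.approx(0.75)
        assert p.quadrant == 4

    def test_parity_center(self):
        [p] = pr2_plot([self.counts_with_thirds(a=5, t=5, g=7, c=7)])
        assert (p.at_bias, p.gc_bias) == (0.5, 0.5)

    def test_undefined_point_reported_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            [p] = pr2_plot([CodonCountTable("g", {"AAA": 5, "GCA": 5})])
        assert p is None  # no G/C third positions at all

    def test_quadrant_assignment(self):
        cases = {
            (6, 2, 6, 2): 1,   # A>T, G>C -> top-right
            (6, 2, 2, 6): 2,   # A>T, C>G -> top-left
            (2, 6, 2, 6): 3,
            (2, 6, 6, 2): 4,
        }
        for (a, t, g, c), quadrant in cases.items():
            [p] = pr2_plot([self.counts_with_thirds(a=a, t=t, g=g, c=c)])
            assert p.quadrant == quadrant

    def test_fourfold_only_mode_ignores_twofold_families(self):
        counts = CodonCountTable(
            "g", {"GCA": 4, "GCT": 4, "GCG": 2, "GCC": 2, "AAA": 50}
        )
        [full] = pr2_plot([counts])
        [ff] = pr2_plot([counts], fourfold_only=True)
        assert ff.at_bias == pytest.approx(0.5)      # Ala thirds only
        assert full.at_bias > 0.9                    # AAA dominates


class TestNeutrality:
    @staticmethod
    def profiles_from(xy_pairs):
        # synthesize minimal profiles carrying just GC12/GC3s
        from cubkit.composition import CompositionProfile

        return [
            CompositionProfile(
                gene_id=f"g{i}", a_pct=25, t_pct=25, c_pct=25, g_pct=25,
                gc_pct=50, at_pct=50, gc1_pct=y, gc2_pct=y, gc12_pct=y,
                gc3s_pct=x, a3s_pct=25, t3s_pct=25, c3s_pct=25, g3s_pct=25,
                at3_pct=50,
            )
            for i, (x, y) in enumerate(xy_pairs)
        ]

    def test_mutation_dominated_limit(self):
        fit = neutrality_fit(self.profiles_from([(x, x) for x in (30, 40, 50, 60)]))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.mutation_pct == pytest.approx(100.0)

    def test_selection_dominated_limit(self):
        fit = neutrality_fit(self.profiles_from([(30, 45), (40, 45), (55, 45)]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.selection_pct == pytest.approx(100.0)

    def test_split_sums_to_100(self, study_corpus):
        _, tables, _ = study_corpus
        fit = neutrality_fit([composition_profile(t) for t in tables])
        assert fit.mutation_pct + fit.selection_pct == pytest.approx(100.0)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            neutrality_fit(self.profiles_from([(50, 40), (50, 45), (50, 42)]))
        with pytest.raises(ValueError):
            neutrality_fit(self.profiles_from([(40, 40), (50, 45)]))


class TestCorrespondenceAnalysis:
    HAND_MATRIX = np.array(
        [[12.0, 3.0, 5.0, 1.0], [2.0, 9.0, 4.0, 6.0], [7.0, 2.0, 11.0, 3.0]]
    )

    def test_total_inertia_equals_chi2_over_n(self):
        ca = CorrespondenceAnalysis().fit(self.HAND_MATRIX)
        chi2 = stats.chi2_contingency(self.HAND_MATRIX, correction=False)[0]
        assert ca.total_inertia_ == pytest.approx(
            chi2 / self.HAND_MATRIX.sum(), abs=1e-10
        )
        assert ca.inertia_.sum() == pytest.approx(ca.total_inertia_, abs=1e-10)

    def test_inertia_percentages_sum_to_100_and_descend(self):
        ca = CorrespondenceAnalysis().fit(self.HAND_MATRIX)
        assert ca.inertia_pct_.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(ca.inertia_pct_) <= 1e-12)

    def test_identical_rows_have_zero_inertia_and_no_axes(self):
        X = np.tile([4.0, 2.0, 1.0, 3.0], (5, 1))
        ca = CorrespondenceAnalysis().fit(X)
        assert ca.total_inertia_ == pytest.approx(0.0, abs=1e-12)
        assert ca.inertia_pct_.size == 0

    def test_two_distinct_row_profiles_give_one_axis(self):
        X = np.array([[8.0, 2, 1, 1], [16.0, 4, 2, 2], [1.0, 1, 5, 5]])
        ca = CorrespondenceAnalysis().fit(X)
        assert ca.inertia_pct_[0] == pytest.approx(100.0, abs=1e-9)

    def test_global_scaling_invariance(self):
        a = CorrespondenceAnalysis().fit(self.HAND_MATRIX)
        b = CorrespondenceAnalysis().fit(self.HAND_MATRIX * 7.5)
        assert a.total_inertia_ == pytest.approx(b.total_inertia_, abs=1e-12)
        np.testing.assert_allclose(a.row_coords_, b.row_coords_, atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            CorrespondenceAnalysis().fit(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            CorrespondenceAnalysis().fit(np.array([[1.0, -2.0], [3.0, 4.0]]))

    def test_estimator_params_protocol(self):
        ca = CorrespondenceAnalysis(n_components=2)
        assert ca.get_params()["n_components"] == 2
        ca.set_params(n_components=1)
        assert ca.fit(self.HAND_MATRIX).row_coords_.shape[1] == 1

    def test_rscu_matrix_and_wrapper_on_corpus(self, study_corpus):
        _, tables, _ = study_corpus
        m = rscu_matrix(tables)
        assert m.shape == (30, 59)
        assert "ATG" not in m.columns and "TGG" not in m.columns
        res = correspondence_analysis(m)
        assert res.inertia_pct.sum() == pytest.approx(100.0, abs=1e-6)
        # paralogs vs out-groups separate on the leading axis
        assert res.row_coords.shape[0] == 30
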
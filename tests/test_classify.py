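"""Filters, regression, BH correction, labelling and cross-group consistency."""

import numpy as np
import pytest
from scipy import stats

from psicouple import (
    ClassifiedEvent,
    Thresholds,
    bh_adjust,
    classify_event,
    consistency_report,
    fit_expression_psi,
    label_genes,
    slope_vs_mean_expression,
    variability_filter,
)
from psicouple.classify import (
    DHP, INDETERMINATE, MIXED, NONE, TYPE0, UHP,
    DHP_GENE, TYPE0_GENE, UHP_GENE, FilterDecision, RegressionFit,
)
from psicouple.errors import ValidationError
from psicouple.expression import EventQuant


def _quant(psi, gene, exon=None, event_id="ev"):
    psi = np.asarray(psi, dtype=float)
    gene = np.asarray(gene, dtype=float)
    exon = np.asarray(exon, dtype=float) if exon is not None else psi * gene
    return EventQuant(
        event_id=event_id, gene_id="G",
        sample_ids=[f"s{i}" for i in range(len(psi))],
        psi=psi, exon_expr=exon, gene_expr=gene,
    )


class TestVariabilityFilter:
    def test_constant_expression_fails_on_ratio(self):
        q = _quant([0.5] * 10, [50.0] * 10, exon=[25.0] * 10)
        d = variability_filter(q)
        assert d.expressed_fraction == 1.0
        assert d.mean_expr == 25.0
        assert d.p95_p5_ratio == 1.0
        assert not d.passed

    def test_low_expressed_fraction_fails(self):
        q = _quant([0.5] * 10, [100.0] * 10, exon=[0.0] * 6 + [100.0] * 4)
        d = variability_filter(q)
        assert d.expressed_fraction == pytest.approx(0.4)
        assert not d.passed

    def test_zero_fifth_percentile_is_undefined_and_fails(self):
        exon = [0.0] * 2 + [100.0] * 8
        d = variability_filter(_quant([0.5] * 10, [100.0] * 10, exon=exon))
        assert np.isnan(d.p95_p5_ratio)
        assert not d.passed

    def test_matches_brute_force_on_lognormal_sample(self):
        rng = np.random.default_rng(5)
        exon = rng.lognormal(np.log(30), 0.8, size=100)
        d = variability_filter(_quant([0.5] * 100, exon * 2, exon=exon))
        # independent recomputation of all three criteria
        frac = np.mean(exon >= 1)
        mean = exon.mean()
        p5, p95 = np.percentile(exon, [5, 95])
        assert d.expressed_fraction == pytest.approx(frac)
        assert d.mean_expr == pytest.approx(mean)
        assert d.p95_p5_ratio == pytest.approx(p95 / p5)
        assert d.passed == (frac >= 0.5 and mean >= 20 and p95 / p5 >= 2.0)


class TestFitExpressionPsi:
    def test_exact_line(self):
        fit = fit_expression_psi(_quant([0, 0.5, 1], [0, 1, 2]))
        assert fit.beta1 == pytest.approx(2.0)
        assert fit.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_sign_symmetry(self):
        fit = fit_expression_psi(_quant([0, 0.5, 1], [2, 1, 0]))
        assert fit.beta1 == pytest.approx(-2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_slope_within_analytic_se_band(self):
        rng = np.random.default_rng(17)
        psi = rng.uniform(0, 1, 50)
        y = 10 + 5 * psi + rng.normal(0, 1, 50)
        fit = fit_expression_psi(_quant(psi, y))
        se = 1.0 / np.sqrt(np.sum((psi - psi.mean()) ** 2))  # known sigma=1
        assert abs(fit.beta1 - 5) < 4 * se

    def test_pvalue_matches_permutation_oracle(self):
        # weak effect so the p-value sits mid-range and the Monte-Carlo
        # permutation null is informative
        rng = np.random.default_rng(23)
        psi = rng.uniform(0, 1, 40)
        y = 1.0 + 0.6 * psi + rng.normal(0, 1, 40)
        fit = fit_expression_psi(_quant(psi, y))
        n_perm = 4000
        obs = abs(stats.linregress(psi, y).slope)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(y)
            if abs(stats.linregress(psi, perm).slope) >= obs:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(fit.p_slope - p_perm) < 3 * se + 0.02

    def test_degenerate_inputs_flagged(self):
        assert fit_expression_psi(_quant([0.5, 0.5, 0.5], [1, 2, 3])).degenerate
        assert fit_expression_psi(_quant([0.1, 0.9], [1, 2])).degenerate
        nanpsi = [0.1, np.nan, np.nan, 0.9]
        assert fit_expression_psi(_quant(nanpsi, [1, 2, 3, 4])).degenerate

    def test_constant_response_zero_slope(self):
        fit = fit_expression_psi(_quant([0.1, 0.5, 0.9], [4.0, 4.0, 4.0]))
        assert not fit.degenerate
        assert fit.beta1 == 0.0
        assert fit.p_slope == 1.0


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        adjusted = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(p[perm]), adjusted[perm])

    def test_monotone_in_rank_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


def _fit(beta1, r2=0.6, gene_ratio=3.0, degenerate=False):
    return RegressionFit(
        event_id="ev", beta0=0.0, beta1=beta1, p_slope=0.01, r2=r2,
        n_used=100, gene_p95_p5_ratio=gene_ratio, degenerate=degenerate,
    )


def _decision(passed=True, ratio=3.0):
    return FilterDecision(
        event_id="ev", expressed_fraction=1.0, mean_expr=50.0,
        p95_p5_ratio=ratio, passed=passed,
    )


class TestClassifyEvent:
    def test_positive_slope_significant_is_uhp(self):
        assert classify_event(_fit(+4.0), 0.01, _decision()) == UHP

    def test_negative_slope_significant_is_dhp(self):
        assert classify_event(_fit(-4.0), 0.01, _decision()) == DHP

    def test_high_adjusted_p_is_type0(self):
        assert classify_event(_fit(0.5, r2=0.01), 0.7, _decision(ratio=2.5)) == TYPE0

    def test_mid_p_is_indeterminate(self):
        assert classify_event(_fit(4.0, r2=0.9), 0.2, _decision()) == INDETERMINATE

    def test_degenerate_is_indeterminate(self):
        fit = _fit(0.0, degenerate=True)
        assert classify_event(fit, float("nan"), _decision()) == INDETERMINATE

    def test_gene_ratio_basis_configurable(self):
        th = Thresholds(ratio_basis="gene")
        fit = _fit(4.0, gene_ratio=1.5)
        assert classify_event(fit, 0.01, _decision(ratio=10.0), th) == INDETERMINATE
        assert classify_event(fit, 0.01, _decision(ratio=10.0)) == UHP


def _classified(event_id, gene_id, label, group="g1"):
    return ClassifiedEvent(
        event_id=event_id, gene_id=gene_id, group=group,
        fit=_fit(1.0), adj_p=0.01, label=label,
    )


class TestLabelGenes:
    def test_uhp_with_indeterminate_is_uhp_gene(self):
        events = [_classified("e1", "G", UHP), _classified("e2", "G", INDETERMINATE)]
        assert label_genes(events) == {"G": UHP_GENE}

    def test_mixed_labels(self):
        events = [_classified("e1", "G", UHP), _classified("e2", "G", TYPE0)]
        assert label_genes(events) == {"G": MIXED}

    def test_unlabelled_gene_is_none(self):
        assert label_genes([_classified("e1", "G", INDETERMINATE)]) == {"G": NONE}

    def test_type0_only(self):
        assert label_genes([_classified("e1", "G", TYPE0)]) == {"G": TYPE0_GENE}


class TestConsistency:
    def test_agreeing_groups(self):
        groups = {
            "g1": [_classified("e1", "G", UHP, "g1")],
            "g2": [_classified("e1", "G", UHP, "g2")],
        }
        rep = consistency_report(groups)
        assert rep.n_multi_group == 1
        assert rep.n_conflicts == 0

    def test_conflicting_groups(self):
        groups = {
            "g1": [_classified("e1", "G", UHP, "g1")],
            "g2": [_classified("e1", "G", DHP, "g2")],
        }
        rep = consistency_report(groups)
        assert rep.n_conflicts == 1
        assert rep.conflict_events == ["e1"]

    def test_matches_pairwise_oracle_on_random_labels(self):
        rng = np.random.default_rng(6)
        labels = [UHP, DHP, TYPE0, INDETERMINATE]
        group_names = ["g1", "g2", "g3"]
        events = [f"e{i}" for i in range(30)]
        assignment = {
            (g, e): labels[rng.integers(len(labels))]
            for g in group_names for e in events
        }
        groups = {
            g: [_classified(e, "G", assignment[(g, e)], g) for e in events]
            for g in group_names
        }
        rep = consistency_report(groups)
        # oracle: per event, collect coupled labels over groups
        conflicts = multi = 0
        for e in events:
            coupled = [assignment[(g, e)] for g in group_names
                       if assignment[(g, e)] in (UHP, DHP)]
            if len(coupled) >= 2:
                multi += 1
                if len(set(coupled)) > 1:
                    conflicts += 1
        assert rep.n_multi_group == multi
        assert rep.n_conflicts == conflicts

    def test_crosstab_against_second_result_set(self):
        groups = {
            "g1": [_classified("e1", "G", UHP, "g1"),
                   _classified("e2", "G", TYPE0, "g1")],
            "g2": [_classified("e1", "G", UHP, "g2")],
        }
        other = {"e1": UHP, "e2": DHP}
        rep = consistency_report(groups, other=other)
        assert rep.crosstab.loc[UHP, UHP] == 1
        assert rep.crosstab.loc[TYPE0, DHP] == 1


class TestSlopeVsMean:
    def test_identity_coefficient(self):
        mean = np.array([10.0, 20.0, 40.0, 80.0])
        fit = slope_vs_mean_expression(mean, mean)
        assert fit.coefficient == pytest.approx(1.0)

    def test_double_coefficient(self):
        mean = np.array([10.0, 20.0, 40.0, 80.0])
        fit = slope_vs_mean_expression(2 * mean, mean)
        assert fit.coefficient == pytest.approx(2.0)

    def test_degenerate_constant_mean(self):
        fit = slope_vs_mean_expression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(fit.coefficient)
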
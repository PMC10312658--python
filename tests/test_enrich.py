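"""Delta permutation testing, GO hypergeometrics, psi-marker correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from psicouple import (
    HitMatrix,
    delta_statistic,
    go_hypergeometric,
    motif_screen,
    permutation_pvalue,
    proportion_difference,
    psi_marker_correlation,
)
from psicouple.classify import DHP_GENE, TYPE0_GENE, UHP_GENE
from psicouple.enrich import hypergeom_upper_tail
from psicouple.errors import ValidationError

from conftest import all_label_assignments


def _matrix(hits, labels, factor="F1"):
    units = [f"u{i}" for i in range(len(hits))]
    return HitMatrix(
        hits=pd.DataFrame({factor: hits}, index=units),
        labels=pd.Series(labels, index=units),
    )


FOUR = [UHP_GENE, UHP_GENE, TYPE0_GENE, TYPE0_GENE]


class TestDelta:
    def test_worked_proportion_difference(self):
        assert proportion_difference(32.6, 17.2) == 15.4

    def test_identical_patterns_zero(self):
        m = _matrix([1, 0, 1, 0], FOUR)
        assert delta_statistic(m, "F1", UHP_GENE, TYPE0_GENE) == 0.0

    def test_matches_hand_count_oracle(self):
        rng = np.random.default_rng(2)
        hits = rng.integers(0, 2, size=20)
        labels = [UHP_GENE] * 8 + [TYPE0_GENE] * 12
        m = _matrix(hits, labels)
        expected = 100 * hits[:8].mean() - 100 * hits[8:].mean()
        assert delta_statistic(m, "F1", UHP_GENE, TYPE0_GENE) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        m = _matrix([1, 0], [UHP_GENE, UHP_GENE])
        with pytest.raises(ValidationError):
            delta_statistic(m, "F1", UHP_GENE, TYPE0_GENE)


def exhaustive_oracle(hits, labels, focus, baseline):
    """Independent full enumeration over distinct label assignments."""
    hits = np.asarray(hits, dtype=float)
    labels = np.asarray(labels)
    obs = 100 * hits[labels == focus].mean() - 100 * hits[labels == baseline].mean()
    exceed = total = 0
    for perm in all_label_assignments(list(labels)):
        d = 100 * hits[perm == focus].mean() - 100 * hits[perm == baseline].mean()
        total += 1
        if d > obs + 1e-12:
            exceed += 1
    return exceed / total


class TestPermutationPvalue:
    def test_exhaustive_four_units(self):
        m = _matrix([1, 0, 1, 0], FOUR)
        p = permutation_pvalue(m, "F1", UHP_GENE, TYPE0_GENE, exhaustive=True)
        assert p == pytest.approx(1 / 6)

    def test_maximal_statistic_p_zero(self):
        m = _matrix([1, 1, 0, 0], FOUR)
        p = permutation_pvalue(m, "F1", UHP_GENE, TYPE0_GENE, exhaustive=True)
        assert p == 0.0

    def test_monte_carlo_within_binomial_error(self):
        m = _matrix([1, 0, 1, 0], FOUR)
        p = permutation_pvalue(m, "F1", UHP_GENE, TYPE0_GENE,
                               n_perm=10_000, seed=0)
        truth = 1 / 6
        se = math.sqrt(truth * (1 - truth) / 10_000)
        assert abs(p - truth) <= 3 * se

    def test_exhaustive_matches_oracle_three_classes(self):
        rng = np.random.default_rng(7)
        hits = rng.integers(0, 2, size=8).tolist()
        labels = [UHP_GENE] * 3 + [DHP_GENE] * 2 + [TYPE0_GENE] * 3
        m = _matrix(hits, labels)
        got = permutation_pvalue(m, "F1", UHP_GENE, TYPE0_GENE, exhaustive=True)
        assert got == pytest.approx(
            exhaustive_oracle(hits, labels, UHP_GENE, TYPE0_GENE)
        )

    def test_bit_reproducible(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.integers(0, 2, 30).tolist(),
                    [UHP_GENE] * 15 + [TYPE0_GENE] * 15)
        a = permutation_pvalue(m, "F1", n_perm=5000, seed=11)
        b = permutation_pvalue(m, "F1", n_perm=5000, seed=11)
        assert a == b

    def test_exhaustive_size_limit(self):
        m = _matrix([0] * 13, [UHP_GENE] * 6 + [TYPE0_GENE] * 7)
        with pytest.raises(ValidationError):
            permutation_pvalue(m, "F1", exhaustive=True)

    def test_super_uniform_under_null(self):
        # Under label-exchangeable hits the >=-convention permutation p
        # (1 - P(delta' < delta), obtained exactly by enumerating with the
        # classes swapped) is super-uniform: P(p <= alpha) <= alpha.  The
        # reported strict-inequality p is never larger than it.
        rng = np.random.default_rng(19)
        n_rep = 150
        alphas = (0.1, 0.3)
        below = {a: 0 for a in alphas}
        for _ in range(n_rep):
            hits = rng.integers(0, 2, size=10).tolist()
            m = _matrix(hits, [UHP_GENE] * 5 + [TYPE0_GENE] * 5)
            p_gt = permutation_pvalue(m, "F1", UHP_GENE, TYPE0_GENE,
                                      exhaustive=True)
            p_lt = permutation_pvalue(m, "F1", TYPE0_GENE, UHP_GENE,
                                      exhaustive=True)
            p_ge = 1.0 - p_lt
            assert p_gt <= p_ge + 1e-12
            for a in alphas:
                if p_ge <= a:
                    below[a] += 1
        for a in alphas:
            se = math.sqrt(a * (1 - a) / n_rep)
            assert below[a] / n_rep <= a + 3 * se


class TestMotifScreen:
    def test_planted_factor_significant(self):
        rng = np.random.default_rng(5)
        n = 200
        units = [f"u{i}" for i in range(2 * n)]
        labels = pd.Series([UHP_GENE] * n + [TYPE0_GENE] * n, index=units)
        hits = pd.DataFrame(
            {
                "planted": np.concatenate(
                    [rng.random(n) < 0.30, rng.random(n) < 0.15]
                ).astype(int),
                "null": (rng.random(2 * n) < 0.2).astype(int),
            },
            index=units,
        )
        results = motif_screen(HitMatrix(hits=hits, labels=labels),
                               n_perm=20_000, seed=1)
        by_key = {(r.factor_id, r.focus_class): r for r in results}
        planted = by_key[("planted", UHP_GENE)]
        assert planted.p_bonf < 0.05
        assert not planted.excluded
        null = by_key[("null", UHP_GENE)]
        assert null.p_bonf > 0.05

    def test_tiny_effect_excluded(self):
        # delta = 0.3 percentage points -> excluded regardless of p
        hits = np.array([1] * 503 + [0] * 497 + [1] * 500 + [0] * 500)
        units = [f"u{i}" for i in range(2000)]
        m = HitMatrix(
            hits=pd.DataFrame({"F1": hits}, index=units),
            labels=pd.Series([UHP_GENE] * 1000 + [TYPE0_GENE] * 1000, index=units),
        )
        res = motif_screen(m, n_perm=50, seed=0,
                           comparisons=[(UHP_GENE, TYPE0_GENE)])
        assert res[0].delta == pytest.approx(0.3)
        assert res[0].excluded

    def test_bonferroni_counts_performed_tests(self):
        rng = np.random.default_rng(8)
        units = [f"u{i}" for i in range(30)]
        labels = pd.Series([UHP_GENE] * 10 + [DHP_GENE] * 10 + [TYPE0_GENE] * 10,
                           index=units)
        hits = pd.DataFrame(
            {f"F{j}": rng.integers(0, 2, 30) for j in range(3)}, index=units
        )
        results = motif_screen(HitMatrix(hits=hits, labels=labels),
                               n_perm=100, seed=2)
        assert len(results) == 9  # 3 factors x 3 comparisons
        for r in results:
            assert r.p_bonf == pytest.approx(min(1.0, r.p_emp * 9))


def go_oracle(k, N, K, n):
    """Upper-tail hypergeometric by direct factorial arithmetic."""
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


class TestGoHypergeometric:
    def test_worked_example_6_of_252(self):
        assert hypergeom_upper_tail(4, 10, 4, 5) == pytest.approx(6 / 252)
        classes = {f"i{j}": "UHP" for j in range(4)}
        classes.update({f"i{j}": "TYPE0" for j in range(4, 10)})
        ann = {f"i{j}": ["GO:1"] for j in range(5)}
        out = go_hypergeometric(ann, classes, min_uhp=1)
        assert len(out) == 1
        assert out[0].k_uhp == 4
        assert out[0].n_term == 5
        assert out[0].p == pytest.approx(6 / 252)
        assert out[0].coverage == pytest.approx(0.8)

    def test_min_uhp_filter_skips_sparse_terms(self):
        classes = {f"i{j}": ("UHP" if j < 3 else "TYPE0") for j in range(10)}
        ann = {f"i{j}": ["GO:1"] for j in range(10)}
        assert go_hypergeometric(ann, classes) == []  # only 3 UHP members < 5

    def test_matches_factorial_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            N = int(rng.integers(8, 31))
            K = int(rng.integers(1, N))
            classes = {
                f"i{j}": ("UHP" if j < K else "TYPE0") for j in range(N)
            }
            n = int(rng.integers(2, N + 1))
            members = rng.choice(N, size=n, replace=False)
            ann = {f"i{j}": ["GO:x"] for j in members}
            out = go_hypergeometric(ann, classes, min_uhp=0)
            k = int(sum(1 for j in members if j < K))
            assert len(out) == 1
            assert abs(out[0].p - go_oracle(k, N, K, n)) < 1e-10

    def test_unclassed_isoforms_ignored(self):
        classes = {f"i{j}": "UHP" for j in range(6)}
        ann = {f"i{j}": ["GO:1"] for j in range(6)}
        ann["stranger"] = ["GO:1"]
        out = go_hypergeometric(ann, classes, min_uhp=1)
        assert out[0].n_term == 6

    def test_bonferroni_and_sorting(self):
        classes = {f"i{j}": ("UHP" if j < 10 else "TYPE0") for j in range(30)}
        ann = {}
        for j in range(10):
            ann.setdefault(f"i{j}", []).append("GO:strong")
        for j in range(0, 30, 2):
            ann.setdefault(f"i{j}", []).append("GO:weak")
        out = go_hypergeometric(ann, classes, min_uhp=5)
        assert [r.go_id for r in out] == ["GO:strong", "GO:weak"]
        for r in out:
            assert r.adj_p == pytest.approx(min(1.0, r.p * len(out)))


class TestPsiMarkerCorrelation:
    def test_proportional_is_one(self):
        marker = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        psi = pd.DataFrame([0.1 * marker.to_numpy()], index=["e1"],
                           columns=list("abcd"))
        out = psi_marker_correlation(psi, marker)
        assert out["e1"] == pytest.approx(1.0)

    def test_anti_proportional_is_minus_one(self):
        marker = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        psi = pd.DataFrame([(-marker + 5).to_numpy()],
                           index=["e1"], columns=list("abcd"))
        out = psi_marker_correlation(psi, marker)
        assert out["e1"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(size=50)
        m = rng.uniform(size=50)
        psi = pd.DataFrame([x], index=["e1"], columns=[f"s{i}" for i in range(50)])
        marker = pd.Series(m, index=psi.columns)
        r = psi_marker_correlation(psi, marker)["e1"]
        expected = ((x - x.mean()) * (m - m.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((m - m.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_undefined_with_constant_or_missing(self):
        marker = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        psi = pd.DataFrame(
            [[0.5, 0.5, 0.5], [0.1, np.nan, np.nan]],
            index=["const", "sparse"], columns=list("abc"),
        )
        out = psi_marker_correlation(psi, marker)
        assert np.isnan(out["const"])
        assert np.isnan(out["sparse"])
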
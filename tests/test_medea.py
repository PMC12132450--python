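"""Medea model: expected fractions, estimators, pooling, allele scan.

The expected-affected-fraction oracle enumerates offspring genotypes at the
two unlinked loci directly from parental gametes, then applies the per-locus
damage probabilities -- independent of the closed forms in the module.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from crossworm.medea import (MedeaModel, MedeaPenetranceModel, agresti_caffo_ci,
                             allele_frequency_scan, classify_and_pool,
                             cross_class, cross_classes, difference_estimator,
                             estimate_penetrance, expected_affected_fraction,
                             expected_difference, make_progeny_table,
                             pool_backcross_f2, simulate_progeny_counts,
                             solve_equal_penetrance, solve_one_full_penetrance)


def _gametes(gt):
    return [gt[0], gt[1]]


def _oracle_fraction(mother, father, beta_i, beta_iii, rule, mode="medea"):
    """Exhaustive enumeration over the 4x4 parental gamete combinations."""
    acting, other = (mother, father) if mode == "medea" else (father, mother)
    total = 0.0
    p_each = 1.0 / 16.0
    for gi_m, gi_f in itertools.product(_gametes(mother[0]), _gametes(father[0])):
        for g3_m, g3_f in itertools.product(_gametes(mother[1]), _gametes(father[1])):
            hom_i = {gi_m, gi_f} == {"A"} and acting[0] == "AB"
            hom_iii = {g3_m, g3_f} == {"A"} and acting[1] == "AB"
            if rule == "survival":
                p = 1 - (1 - beta_i * hom_i) * (1 - beta_iii * hom_iii)
            else:
                p = (beta_i * hom_i * (not hom_iii) + beta_iii * hom_iii * (not hom_i)
                     + beta_i * beta_iii * hom_i * hom_iii)
            total += p_each * p
    return total


class TestExpectedFraction:
    @pytest.mark.parametrize("rule", ["survival", "product"])
    @pytest.mark.parametrize("betas", [(1.0, 1.0), (0.8, 0.6), (0.3, 0.0)])
    def test_matches_enumeration_all_16_classes(self, rule, betas):
        m = MedeaModel(*betas, rule=rule)
        for c in cross_classes():
            want = _oracle_fraction((c.mother.chrom_i, c.mother.chrom_iii),
                                    (c.father.chrom_i, c.father.chrom_iii),
                                    m.beta_i, m.beta_iii, rule)
            assert expected_affected_fraction(c, m) == pytest.approx(want, abs=1e-12)

    def test_backcross_full_penetrance_three_quarters(self):
        # F1 mother x susceptible-homozygote father, both loci fully penetrant
        c = next(c for c in cross_classes()
                 if c.mother.name == "F1_AB" and c.father.name == "A")
        assert expected_affected_fraction(c, MedeaModel(1, 1)) == pytest.approx(0.75)

    def test_f1xf1_full_penetrance_seven_sixteenths(self):
        c = next(c for c in cross_classes()
                 if c.mother.name == "F1_AB" and c.father.name == "F1_AB")
        assert expected_affected_fraction(c, MedeaModel(1, 1)) == pytest.approx(7 / 16)

    def test_homozygous_mother_never_affected(self):
        m = MedeaModel(1, 1)
        for c in cross_classes():
            if c.mother.name in ("A", "B"):
                assert expected_affected_fraction(c, m) == 0.0

    def test_peel_swaps_parents(self):
        m = MedeaModel(1, 1, mode="peel")
        for c in cross_classes():
            if c.father.name in ("A", "B"):
                assert expected_affected_fraction(c, m) == 0.0
        c = next(c for c in cross_classes()
                 if c.father.name == "F1_AB" and c.mother.name == "A")
        assert expected_affected_fraction(c, m) == pytest.approx(0.75)


class TestDifferenceEstimator:
    def test_printed_counts(self):
        e = difference_estimator(517, 827, 644, 1544)
        assert e.d == pytest.approx(0.2081, abs=5e-4)
        hw = (e.d_ci[1] - e.d_ci[0]) / 2
        assert hw == pytest.approx(0.0411, abs=1e-3)

    def test_equal_proportions_symmetric(self):
        e = difference_estimator(50, 100, 50, 100)
        assert e.d == 0.0
        assert e.d_ci[0] == pytest.approx(-e.d_ci[1])

    def test_extreme_difference_clamped(self):
        e = difference_estimator(100, 100, 0, 100)
        assert e.d == 1.0
        assert e.d_ci[1] <= 1.0

    def test_agresti_caffo_closed_form(self):
        # hand-computed: p1~=101/102? no: (100+1)/(100+2), (0+1)/(100+2)
        d, ci = agresti_caffo_ci(100, 100, 0, 100)
        p1, p2 = 101 / 102, 1 / 102
        se = np.sqrt(p1 * (1 - p1) / 102 + p2 * (1 - p2) / 102)
        assert ci[0] == pytest.approx((p1 - p2) - 1.959964 * se, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            difference_estimator(0, 0, 1, 10)


class TestSolvers:
    def test_equal_penetrance_printed_value(self):
        beta, _ = solve_equal_penetrance(517 / 827 - 644 / 1544)
        assert round(beta, 2) == 0.77

    def test_single_penetrance_printed_value(self):
        beta, _ = solve_one_full_penetrance(517 / 827 - 644 / 1544)
        assert beta == pytest.approx(0.5822, abs=5e-4)

    @pytest.mark.parametrize("d,expect", [(0.0, 0.0), (5 / 16, 1.0)])
    def test_equal_boundaries(self, d, expect):
        assert solve_equal_penetrance(d)[0] == pytest.approx(expect)

    @pytest.mark.parametrize("d,expect", [(1 / 16, 0.0), (5 / 16, 1.0)])
    def test_single_boundaries(self, d, expect):
        assert solve_one_full_penetrance(d)[0] == pytest.approx(expect)

    def test_round_trip_exact_on_grid(self):
        for beta in np.linspace(0, 1, 21):
            d = expected_difference(beta, beta)
            got, _ = solve_equal_penetrance(d)
            assert got == pytest.approx(beta, abs=1e-12)

    def test_negative_difference_warns_to_zero(self):
        with pytest.warns(UserWarning):
            beta, _ = solve_equal_penetrance(-0.1)
        assert beta == 0.0

    def test_ci_halfwidths_printed(self):
        e = estimate_penetrance(517, 827, 644, 1544)
        assert (e.beta_equal_ci[1] - e.beta_equal_ci[0]) / 2 == pytest.approx(0.10, abs=0.01)
        assert (e.beta_single_ci[1] - e.beta_single_ci[0]) / 2 == pytest.approx(0.16, abs=0.01)


def _row(cls, embryos=10, unhatched=4, deformed=1, adults=5, larvae=0):
    return {"plate": 0, "embryos": embryos, "unhatched": unhatched,
            "deformed": deformed, "adult_females": adults, "adult_males": 0,
            "l4_females": 0, "l4_males": 0, "larvae": larvae,
            "mother": "F1_AB", "father": "A", "cross_class": cls}


class TestPooling:
    def test_single_row_default(self):
        pooled = classify_and_pool(make_progeny_table([_row(1)]))
        assert (pooled.loc[1, "affected"], pooled.loc[1, "total"]) == (5, 10)

    def test_two_rows_sum(self):
        pooled = classify_and_pool(make_progeny_table([_row(3), _row(3)]))
        assert (pooled.loc[3, "affected"], pooled.loc[3, "total"]) == (10, 20)

    def test_delayed_toggle_differs_by_larvae(self):
        t = make_progeny_table([_row(2, larvae=3, adults=2)])
        with_d = classify_and_pool(t, include_delayed=True)
        without = classify_and_pool(t, include_delayed=False)
        assert with_d.loc[2, "affected"] - without.loc[2, "affected"] == 3

    def test_proportions_sum_to_one(self):
        t = make_progeny_table([_row(5, embryos=20, unhatched=3, deformed=2,
                                     adults=10, larvae=1)])
        pooled = classify_and_pool(t)
        props = pooled.loc[5, ["prop_affected", "prop_wildtype", "prop_missing"]]
        assert props.sum() == pytest.approx(1.0)

    def test_pool_backcross_f2_class_selection(self):
        rows = [_row(c.class_id) for c in cross_classes()]
        pooled = classify_and_pool(make_progeny_table(rows))
        a_bc, n_bc, a_f2, n_f2 = pool_backcross_f2(pooled)
        # two het-mother x A-father classes, four F1 x F1 classes
        assert (n_bc, n_f2) == (20, 40)


class TestSimulation:
    def test_no_effect_no_mortality_all_wildtype(self, rng):
        c = cross_class(9)
        row = simulate_progeny_counts(c, MedeaModel(0, 0), 500, rng=rng)
        assert row["unhatched"] == row["deformed"] == row["larvae"] == 0
        assert (row["adult_females"] + row["adult_males"]
                + row["l4_females"] + row["l4_males"]) == 500

    def test_large_n_matches_expectation(self):
        c = next(c for c in cross_classes()
                 if c.mother.name == "F1_AB" and c.father.name == "A")
        m = MedeaModel(1, 1)
        row = simulate_progeny_counts(c, m, 100_000, rng=np.random.default_rng(0))
        affected = row["unhatched"] + row["deformed"] + row["larvae"]
        assert affected / 100_000 == pytest.approx(0.75, abs=0.01)

    def test_seed_determinism(self):
        c = cross_class(13)
        m = MedeaModel(0.5, 0.5)
        r1 = simulate_progeny_counts(c, m, 1000, rng=np.random.default_rng(42))
        r2 = simulate_progeny_counts(c, m, 1000, rng=np.random.default_rng(42))
        assert r1 == r2

    def test_estimator_consistency_under_product_rule(self):
        """Estimating from a large simulated table recovers the true penetrance."""
        m = MedeaModel(0.8, 0.8, rule="product")
        rows = [simulate_progeny_counts(c, m, 50_000, rng=np.random.default_rng(c.class_id))
                for c in cross_classes()]
        res = MedeaPenetranceModel.from_progeny_table(make_progeny_table(rows)).fit()
        assert res.estimate.beta_equal == pytest.approx(0.8, abs=0.03)


class TestAlleleScan:
    @pytest.mark.parametrize("calls,expect", [
        ([["AB", "AB", "AB"]], 0.5),
        ([["BB", "BB", "BB"]], 1.0),
        ([["AA", "BB", "AB"]], 0.5),
    ])
    def test_frequencies(self, calls, expect):
        out = allele_frequency_scan(pd.DataFrame(calls))
        assert out["freq_B"].iloc[0] == pytest.approx(expect)

    def test_all_missing_reports_nan(self):
        out = allele_frequency_scan(pd.DataFrame([[None, None]]))
        assert np.isnan(out["freq_B"].iloc[0])
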
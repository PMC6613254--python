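import math

import numpy as np
import pytest

from leqate import (
    ScoreContingencyTable,
    SimulationScenario,
    bootstrap_p,
    conditional_lrt,
    expected_counts,
    fit_cml,
    gamma_from_thresholds,
    goodman_kruskal_gamma,
    parametric_bootstrap_tables,
    person_misfit_test,
    run_fit_tests,
    simulate_misfit_table,
)


def naive_g2(table, fit):
    exp = expected_counts(fit, table.total_margin)
    total = 0.0
    for x in range(table.counts.shape[0]):
        for y in range(table.counts.shape[1]):
            o = table.counts[x, y]
            if o > 0:
                total += 2 * o * math.log(o / exp[x, y])
    return total


def naive_gamma(counts):
    """Pair-by-pair concordance count (quadratic oracle)."""
    c = np.asarray(counts)
    concordant = discordant = 0
    cells = [
        (x, y, c[x, y]) for x in range(c.shape[0]) for y in range(c.shape[1]) if c[x, y]
    ]
    for i, (x1, y1, n1) in enumerate(cells):
        for x2, y2, n2 in cells[i + 1 :]:
            if (x1 - x2) * (y1 - y2) > 0:
                concordant += n1 * n2
            elif (x1 - x2) * (y1 - y2) < 0:
                discordant += n1 * n2
    if concordant + discordant == 0:
        return math.nan
    return (concordant - discordant) / (concordant + discordant)


class TestConditionalLrt:
    def test_zero_when_observed_equals_expected(self):
        table = ScoreContingencyTable(np.array([[0, 1], [1, 0]]))
        fit = fit_cml(table)
        assert conditional_lrt(table, fit) == pytest.approx(0.0, abs=1e-12)

    def test_zero_on_forced_splits(self):
        # every observed total admits a single split: expectation = observation
        table = ScoreContingencyTable(np.array([[7, 0], [0, 5]]))
        fit = fit_cml(table)
        assert conditional_lrt(table, fit) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_loop(self, medium_table, medium_fit):
        assert conditional_lrt(medium_table, medium_fit) == pytest.approx(
            naive_g2(medium_table, medium_fit), abs=1e-10
        )

    def test_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            counts = rng.integers(0, 9, size=(4, 4))
            if counts.sum() == 0:
                continue
            table = ScoreContingencyTable(counts)
            fit = fit_cml(table)
            g2 = conditional_lrt(table, fit)
            assert g2 >= -1e-10
            assert g2 == pytest.approx(naive_g2(table, fit), abs=1e-10)


class TestGoodmanKruskalGamma:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[10, 0], [0, 10]], 1.0),
            ([[0, 10], [10, 0]], -1.0),
            ([[10, 10], [10, 10]], 0.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert goodman_kruskal_gamma(np.array(counts)) == pytest.approx(expected)

    def test_all_ties_undefined(self):
        assert math.isnan(goodman_kruskal_gamma(np.array([[5]])))

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            counts = rng.integers(0, 7, size=(4, 5))
            if counts.sum() < 2:
                continue
            assert goodman_kruskal_gamma(counts) == pytest.approx(
                naive_gamma(counts), abs=1e-12
            )


class TestParametricBootstrap:
    def test_empty_stream(self, medium_fit, medium_table):
        assert (
            list(parametric_bootstrap_tables(medium_fit, medium_table.total_margin, 0))
            == []
        )

    def test_preserves_total_score_margin(self, medium_fit, medium_table):
        for boot in parametric_bootstrap_tables(
            medium_fit, medium_table.total_margin, 5, seed=1
        ):
            np.testing.assert_array_equal(
                boot.total_margin, medium_table.total_margin
            )

    def test_seed_reproducibility(self, medium_fit, medium_table):
        t1 = [
            t.counts
            for t in parametric_bootstrap_tables(
                medium_fit, medium_table.total_margin, 3, seed=99
            )
        ]
        t2 = [
            t.counts
            for t in parametric_bootstrap_tables(
                medium_fit, medium_table.total_margin, 3, seed=99
            )
        ]
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a, b)


class TestBootstrapP:
    def test_bounds(self):
        boots = np.arange(999, dtype=float)
        assert bootstrap_p(2000.0, boots) == pytest.approx(1 / 1000)
        assert bootstrap_p(-5.0, boots) == pytest.approx(1.0)

    def test_median_is_half(self):
        boots = np.arange(999, dtype=float)
        assert bootstrap_p(499.0, boots) == pytest.approx(0.5, abs=0.01)

    def test_two_sided_symmetric(self):
        boots = np.concatenate([-np.arange(500.0), np.arange(500.0)])
        p_hi = bootstrap_p(450.0, boots, "two_sided")
        p_lo = bootstrap_p(-450.0, boots, "two_sided")
        assert p_hi == pytest.approx(p_lo, abs=1e-12)


class TestPersonMisfit:
    def test_forced_splits_never_flagged(self):
        table = ScoreContingencyTable(np.array([[7, 0], [0, 5]]))
        fit = fit_cml(table)
        result = person_misfit_test(table, fit)
        assert result.count == 0
        assert result.p == 1.0

    def test_null_flag_rate_near_level(self, medium_table, medium_fit):
        result = person_misfit_test(medium_table, medium_fit)
        assert 0.01 < result.proportion < 0.10
        assert result.ci_low < result.proportion < result.ci_high

    def test_exact_method_is_more_conservative(self, medium_table, medium_fit):
        midp = person_misfit_test(medium_table, medium_fit, method="midp")
        strict = person_misfit_test(medium_table, medium_fit, method="exact")
        assert strict.count <= midp.count

    def test_careless_responders_raise_flagged_count(self):
        """A careless subgroup produces more improbable splits than the model
        implies; the bootstrap-calibrated count test in the report sees it."""
        scenario = SimulationScenario(
            gamma_a=gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3),
            gamma_b=gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2),
            n=5_000,
            careless_rate=0.05,
            seed=404,
        )
        table = simulate_misfit_table(scenario)
        fit = fit_cml(table)
        result = person_misfit_test(table, fit)
        assert result.proportion > result.null_proportion
        report = run_fit_tests(table, fit, n_bootstrap=199, seed=9)
        assert report.misfit_p < 0.5  # count sees the excess, if less sharply
        assert report.verdict == "strong_evidence_against"


class TestRunFitTests:
    def test_report_fields_and_reproducibility(self, medium_table, medium_fit):
        rep1 = run_fit_tests(medium_table, medium_fit, n_bootstrap=99, seed=5)
        rep2 = run_fit_tests(medium_table, medium_fit, n_bootstrap=99, seed=5)
        assert rep1 == rep2
        assert 0 < rep1.lrt_p <= 1
        assert 0 < rep1.gamma_p <= 1
        assert rep1.verdict in {"fit", "moderate_evidence", "strong_evidence_against"}
        assert -1 <= rep1.gamma_observed <= 1
        d = rep1.to_dict()
        assert d["misfit_ci"] == list(rep1.misfit_ci)

    def test_gamma_expected_inside_bootstrap_band(self, medium_table, medium_fit):
        """Under the model the expected-table gamma sits centrally among
        bootstrap gammas."""
        boots = [
            goodman_kruskal_gamma(t.counts)
            for t in parametric_bootstrap_tables(
                medium_fit, medium_table.total_margin, 199, seed=17
            )
        ]
        lo, hi = np.quantile(boots, [0.025, 0.975])
        exp_gamma = goodman_kruskal_gamma(
            expected_counts(medium_fit, medium_table.total_margin)
        )
        assert lo < exp_gamma < hi

    def test_local_dependence_yields_strong_evidence(self):
        """Scores copied between scales (shared items) violate the conditional
        product form and are flagged decisively."""
        scenario = SimulationScenario(
            gamma_a=gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3),
            gamma_b=gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2),
            n=2_000,
            copy_rate=0.4,
            seed=2_024,
        )
        table = simulate_misfit_table(scenario)
        report = run_fit_tests(table, n_bootstrap=199, seed=6)
        assert report.verdict == "strong_evidence_against"
        assert report.lrt_p <= 0.01

    def test_trait_divergence_is_absorbed_by_conditional_model(self):
        """Bivariate-normal trait divergence stays inside the quasi-independence
        family the conditional model spans, so no test fires: a documented
        limitation of purely conditional checks."""
        scenario = SimulationScenario(
            gamma_a=gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3),
            gamma_b=gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2),
            n=2_000,
            trait_correlation=0.3,
            seed=2_024,
        )
        table = simulate_misfit_table(scenario)
        report = run_fit_tests(table, n_bootstrap=199, seed=6)
        assert report.verdict != "strong_evidence_against"
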
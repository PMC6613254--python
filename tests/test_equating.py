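import math

import numpy as np
import pandas as pd
import pytest

from leqate import (
    ScoreContingencyTable,
    SimulationScenario,
    EquatingTable,
    equate_direct,
    equate_indirect,
    equate_indirect_from_tables,
    fit_cml,
    gamma_from_thresholds,
    round_expected,
    see_bootstrap,
    see_bootstrap_indirect,
    see_from_error_distribution,
    simulate_scores,
    simulate_table,
    weighted_see_mean,
)
from conftest import make_fit


class TestRoundExpected:
    @pytest.mark.parametrize(
        "value, expected",
        [(1.9, 2), (4.4, 4), (2.5, 3), (0.49, 0), (0.0, 0), (-2.5, -3), (11.5, 12)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_expected(value) == expected


class TestSeeArithmetic:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ({0: 1.0}, 0.0),
            ({-1: 0.05, 0: 0.9, 1: 0.05}, math.sqrt(0.10)),
            ({-2: 0.025, -1: 0.225, 0: 0.5, 1: 0.225, 2: 0.025}, math.sqrt(0.65)),
            # frequencies 3 x 0.317 + 2 x 0.025 sum to 1.001 (rounded thirds);
            # after normalization the SEE still prints as 0.91
            ({-2: 0.025, -1: 0.317, 0: 0.317, 1: 0.317, 2: 0.025}, 0.913),
        ],
    )
    def test_error_distribution_see(self, freqs, expected):
        assert see_from_error_distribution(freqs) == pytest.approx(expected, abs=5e-4)

    def test_invalid_frequencies(self):
        with pytest.raises(ValueError):
            see_from_error_distribution({0: -0.5, 1: 1.5})

    def test_small_sample_correction(self):
        freqs = {-1: 0.05, 0: 0.9, 1: 0.05}
        plain = see_from_error_distribution(freqs)
        corrected = see_from_error_distribution(freqs, n_samples=1000)
        assert corrected == pytest.approx(plain * math.sqrt(1000 / 999))


class TestWeightedSeeMean:
    def test_all_zero_is_acceptable(self):
        mean, ok = weighted_see_mean(np.zeros(3), np.ones(3))
        assert mean == 0.0 and ok

    def test_strict_bound(self):
        mean, ok = weighted_see_mean(np.array([0.91]), np.array([1.0]))
        assert mean == pytest.approx(0.91) and not ok

    def test_hand_arithmetic(self):
        mean, ok = weighted_see_mean(np.array([1.0, 0.0]), np.array([1.0, 3.0]))
        assert mean == pytest.approx(0.25) and ok

    def test_zero_weights_error(self):
        with pytest.raises(ValueError):
            weighted_see_mean(np.array([1.0]), np.array([0.0]))


class TestEquateDirect:
    def test_identical_scales_give_identity(self):
        fit = make_fit([1, 2, 2, 1], [1, 2, 2, 1])
        table = equate_direct(fit, "A").table
        np.testing.assert_array_equal(
            table["equated_target"], table["source_score"]
        )
        np.testing.assert_allclose(
            table["expected_target"], table["source_score"], atol=1e-8
        )

    def test_endpoints_map_to_observed_extremes(self, medium_fit):
        for source in medium_fit.scale_names:
            tab = equate_direct(medium_fit, source).table
            tgt = medium_fit.params(
                [s for s in medium_fit.scale_names if s != source][0]
            )
            assert tab.iloc[0]["expected_target"] == tgt.min_support
            assert tab.iloc[-1]["expected_target"] == tgt.max_support
            assert tab.iloc[0]["theta"] == -math.inf
            assert tab.iloc[-1]["theta"] == math.inf

    def test_monotone_in_source_score(self, medium_fit):
        for source in medium_fit.scale_names:
            tab = equate_direct(medium_fit, source).table
            assert tab["expected_target"].is_monotonic_increasing
            assert tab["equated_target"].is_monotonic_increasing

    def test_rows_cover_observed_scores_only(self, medium_fit):
        tab = equate_direct(medium_fit, "A").table
        np.testing.assert_array_equal(
            tab["source_score"], medium_fit.observed_scores_a
        )

    def test_near_inverse_composition(self, medium_fit):
        """A->B then B->A returns each interior A score within one point."""
        ab = equate_direct(medium_fit, "A").table
        ba = equate_direct(medium_fit, "B").table
        back = np.interp(
            ab["expected_target"], ba["source_score"], ba["expected_target"]
        )
        interior = slice(1, -1)
        assert np.all(np.abs(back[interior] - ab["source_score"][interior]) <= 1.0)


@pytest.fixture(scope="module")
def boot_result(medium_table):
    return see_bootstrap(medium_table, source="A", S=60, seed=11)


class TestSeeBootstrap:
    def test_reproducible(self, medium_table, boot_result):
        eq2, _ = see_bootstrap(medium_table, source="A", S=60, seed=11)
        pd.testing.assert_frame_equal(boot_result[0].table, eq2.table)

    def test_see_consistent_with_error_distribution(self, boot_result):
        eq, dist = boot_result
        for _, row in eq.table.iterrows():
            s = int(row["source_score"])
            if not math.isnan(row["see"]) and dist.errors[s]:
                assert dist.see(s) == pytest.approx(row["see"], abs=1e-9)

    def test_error_frequencies_sum_to_one(self, boot_result):
        _, dist = boot_result
        disp = dist.display()
        np.testing.assert_allclose(
            disp.drop(columns="source_score").sum(axis=1), 1.0, atol=1e-12
        )

    def test_summary_metadata(self, boot_result):
        eq, _ = boot_result
        summary = eq.summary()
        assert summary["S"] == 60 and summary["seed"] == 11
        assert summary["weighted_see_mean"] == pytest.approx(eq.weighted_see_mean)

    def test_degenerate_table_has_zero_see(self):
        table = ScoreContingencyTable(np.diag([30, 40, 30]))
        eq, _ = see_bootstrap(table, source="A", S=30, seed=3)
        np.testing.assert_allclose(eq.table["see"].dropna(), 0.0, atol=1e-12)


class TestIndirect:
    def test_fig_style_midpoint_interpolation(self):
        """B=6 with expected A 4.5; expected C at A=4,5 of 3.5 and 5.3 gives
        expected C 4.4, equated 4."""
        tab_ba = EquatingTable(
            source="B",
            target="A",
            table=pd.DataFrame(
                {
                    "source_score": [6],
                    "theta": [0.0],
                    "expected_target": [4.5],
                    "equated_target": [4],
                    "see": [math.nan],
                    "weight": [1.0],
                }
            ),
        )
        tab_ac = EquatingTable(
            source="A",
            target="C",
            table=pd.DataFrame(
                {
                    "source_score": [4, 5],
                    "theta": [0.0, 0.1],
                    "expected_target": [3.5, 5.3],
                    "equated_target": [4, 5],
                    "see": [math.nan] * 2,
                    "weight": [0.5, 0.5],
                }
            ),
        )
        out = equate_indirect_from_tables(tab_ba, tab_ac).table
        assert out["expected_target"].iloc[0] == pytest.approx(4.4)
        assert out["equated_target"].iloc[0] == 4

    def test_integer_expected_score_hits_grid_value(self, medium_fit):
        ba = equate_direct(medium_fit, "B")
        ac = equate_direct(medium_fit, "A")
        # force an exactly integer expected A score
        ba.table.loc[ba.table.index[1], "expected_target"] = 3.0
        out = equate_indirect_from_tables(ba, ac).table
        grid_value = ac.table.loc[
            ac.table["source_score"] == 3, "expected_target"
        ].iloc[0]
        assert out["expected_target"].iloc[1] == pytest.approx(grid_value)

    def test_identity_link_reproduces_direct(self):
        """Indirect equating through a copy of the source scale equals the
        direct table."""
        scenario = SimulationScenario(
            gamma_a=gamma_from_thresholds([[-1.0, 0.0, 1.0]] * 2),
            gamma_b=gamma_from_thresholds([[-0.8, 0.8]] * 2),
            n=4_000,
            seed=77,
        )
        table = simulate_table(scenario)
        fit = fit_cml(table)
        direct = equate_direct(fit, "A").table
        indirect = equate_indirect_from_tables(
            EquatingTable(source="A", target="A", table=_identity_table(fit)),
            equate_direct(fit, "A"),
        ).table
        np.testing.assert_allclose(
            indirect["expected_target"], direct["expected_target"], atol=1e-9
        )

    def test_chain_mismatch_raises(self, medium_fit):
        with pytest.raises(ValueError):
            equate_indirect_from_tables(
                equate_direct(medium_fit, "A"), equate_direct(medium_fit, "A")
            )

    def test_equate_indirect_from_fits_monotone(self):
        df = _triplet_scores(seed=5)
        t_ba = ScoreContingencyTable.from_scores(
            df["B"], df["A"], 8, 12, scale_names=("B", "A")
        )
        t_ac = ScoreContingencyTable.from_scores(
            df["A"], df["C"], 12, 10, scale_names=("A", "C")
        )
        out = equate_indirect(fit_cml(t_ba), fit_cml(t_ac))
        assert out.source == "B" and out.target == "C"
        assert out.table["expected_target"].is_monotonic_increasing

    def test_see_bootstrap_indirect_reproducible(self):
        df = _triplet_scores(seed=6)
        t_ba = ScoreContingencyTable.from_scores(
            df["B"], df["A"], 8, 12, scale_names=("B", "A")
        )
        t_ac = ScoreContingencyTable.from_scores(
            df["A"], df["C"], 12, 10, scale_names=("A", "C")
        )
        eq1, _ = see_bootstrap_indirect(t_ba, t_ac, S=30, seed=2)
        eq2, _ = see_bootstrap_indirect(t_ba, t_ac, S=30, seed=2)
        pd.testing.assert_frame_equal(eq1.table, eq2.table)
        assert (eq1.table["see"].dropna() >= 0).all()


def _identity_table(fit) -> pd.DataFrame:
    scores = fit.observed_scores_a
    return pd.DataFrame(
        {
            "source_score": scores,
            "theta": np.zeros(scores.size),
            "expected_target": scores.astype(float),
            "equated_target": scores,
            "see": np.full(scores.size, math.nan),
            "weight": fit.margin_a[scores] / fit.margin_a.sum(),
        }
    )


def _triplet_scores(seed):
    scenario = SimulationScenario(
        gamma_a=gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3),  # A: 0-12
        gamma_b=gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2),  # B: 0-8
        gamma_c=gamma_from_thresholds([[-1.0, 0.0, 1.0]] * 2 + [[-0.5, 0.5]] * 2),  # C: 0-10
        n=1_500,
        seed=seed,
    )
    return simulate_scores(scenario)
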
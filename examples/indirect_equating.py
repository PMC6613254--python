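"""Indirect (common-scale) equating: B to C through A.

Two independent samples are simulated: sample 1 answers scales B and A,
sample 2 answers A and C.  B is equated to C by chaining the two direct
equatings through A (with linear interpolation between integer A scores),
and the SEE is bootstrapped by resampling both samples.  For comparison,
the same B -> C equating is done directly on a single common-person sample:
the indirect route accumulates two sources of estimation error, so its
weighted SEE mean is larger.
"""

from leqate import (
    ScoreContingencyTable,
    SimulationScenario,
    gamma_from_thresholds,
    see_bootstrap,
    see_bootstrap_indirect,
    simulate_scores,
)

gamma_a = gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3)  # A: 0-12 (link)
gamma_b = gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2)  # B: 0-8
gamma_c = gamma_from_thresholds([[-1.0, 0.0, 1.0]] * 2 + [[-0.5, 0.5]] * 2)  # C: 0-10

sample1 = simulate_scores(SimulationScenario(
    gamma_a=gamma_a, gamma_b=gamma_b, gamma_c=gamma_c, n=722, seed=301))
sample2 = simulate_scores(SimulationScenario(
    gamma_a=gamma_a, gamma_b=gamma_b, gamma_c=gamma_c, n=722, seed=302))

table_ba = ScoreContingencyTable.from_scores(
    sample1["B"], sample1["A"], 8, 12, scale_names=("B", "A"))
table_ac = ScoreContingencyTable.from_scores(
    sample2["A"], sample2["C"], 12, 10, scale_names=("A", "C"))

indirect, _ = see_bootstrap_indirect(table_ba, table_ac, S=199, seed=71)
print("indirect B -> C via A:")
print(indirect.table.round(2).to_string(index=False))
print(f"weighted SEE mean (indirect): {indirect.weighted_see_mean:.2f}")

table_bc = ScoreContingencyTable.from_scores(
    sample1["B"], sample1["C"], 8, 10, scale_names=("B", "C"))
direct, _ = see_bootstrap(table_bc, source="B", S=199, seed=72)
print(f"weighted SEE mean (direct, common persons): {direct.weighted_see_mean:.2f}")
print("the indirect route is less precise: it chains two estimated equatings.")
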
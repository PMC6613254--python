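import numpy as np
import pytest

from leqate import (
    LeunbachFit,
    ScoreParameterVector,
    SimulationScenario,
    fit_cml,
    gamma_from_thresholds,
    omega_convolution,
    simulate_table,
)


def make_fit(gamma_a, gamma_b, margin_a=None, margin_b=None, total_margin=None,
             scale_names=("A", "B")) -> LeunbachFit:
    """Assemble a LeunbachFit directly from known parameters (no estimation)."""
    pa = ScoreParameterVector(np.asarray(gamma_a, dtype=float))
    pb = ScoreParameterVector(np.asarray(gamma_b, dtype=float))
    ma = np.ones(pa.gamma.size) if margin_a is None else np.asarray(margin_a)
    mb = np.ones(pb.gamma.size) if margin_b is None else np.asarray(margin_b)
    tm = (
        np.ones(pa.max_score + pb.max_score + 1)
        if total_margin is None
        else np.asarray(total_margin)
    )
    return LeunbachFit(
        params_a=pa,
        params_b=pb,
        omega=omega_convolution(pa, pb),
        scale_names=tuple(scale_names),
        margin_a=ma,
        margin_b=mb,
        total_margin=tm,
        normalization={"constraint": "as constructed"},
        converged=True,
        identifiable=True,
        iterations=0,
        max_change=0.0,
    )


@pytest.fixture(scope="session")
def medium_scenario():
    """Two well-behaved scales (ranges 0-12 and 0-8), a plausible cohort size."""
    return SimulationScenario(
        gamma_a=gamma_from_thresholds([[-1.5, -0.5, 0.5, 1.5]] * 3),
        gamma_b=gamma_from_thresholds([[-1.2, -0.4, 0.4, 1.2]] * 2),
        n=722,
        seed=20_260_925,
    )


@pytest.fixture(scope="session")
def medium_table(medium_scenario):
    return simulate_table(medium_scenario)


@pytest.fixture(scope="session")
def medium_fit(medium_table):
    fit = fit_cml(medium_table)
    assert fit.converged
    return fit
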
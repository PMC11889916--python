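import numpy as np
import pytest

from morphoscreen.design import (
    Factor,
    LayoutConfig,
    assign_plate_layout,
    enumerate_full_factorial,
)
from morphoscreen.profiling import aggregate_wells, fit_pca, mad_normalize
from morphoscreen.synthetic import SyntheticConfig, TreatmentEffect, simulate_screen


def make_factors(k: int) -> list[Factor]:
    return [Factor(f"GF{i}", 0.0, 10.0 * (i + 1)) for i in range(k)]


@pytest.fixture(scope="session")
def small_design():
    """2^4 = 16 formulations: fits one plate at the default well budget."""
    return enumerate_full_factorial(make_factors(4))


@pytest.fixture(scope="session")
def small_layouts(small_design):
    return assign_plate_layout(small_design, LayoutConfig(), seed=11)


@pytest.fixture(scope="session")
def planted_screen(small_design, small_layouts):
    """One simulated plate with two strong planted hits among 14 nulls."""
    effects = {fid: TreatmentEffect() for fid in small_design.formulation_ids}
    effects["T03"] = TreatmentEffect(m=2.0, delta=6.0)
    effects["T11"] = TreatmentEffect(m=2.2, delta=6.0)
    config = SyntheticConfig(
        seed=7, n_features=60, n_latent=6, baseline_cells_per_well=60.0,
        effects=effects,
    )
    cells, truth = simulate_screen(config, small_layouts)
    return config, cells, truth


@pytest.fixture(scope="session")
def planted_profiles(planted_screen, small_layouts):
    _, cells, _ = planted_screen
    return aggregate_wells(cells, small_layouts)


@pytest.fixture(scope="session")
def planted_normalized(planted_profiles):
    normalized, params = mad_normalize(planted_profiles)
    return normalized, params


@pytest.fixture(scope="session")
def planted_scores(planted_normalized):
    normalized, _ = planted_normalized
    model, scores = fit_pca(normalized)
    pcs = [f"PC{i + 1}" for i in range(model.n_retained)]
    meta = [c for c in scores.columns if not c.startswith("PC")]
    return model, scores[meta + pcs]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
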
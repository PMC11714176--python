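import numpy as np
import pytest

from tmescore.synthetic import StudyParams, emulate_reference_cohort, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A light synthetic study (6 tumors, CD3+CD8 panels) for pipeline tests."""
    params = StudyParams(
        n_tumors=6, cores_per_region=2, panels=("CD3", "CD8"),
        tumor_parent_intensity=15.0, tumor_offspring_mean=12.0,
        tcell_intensity=120.0, other_intensity=60.0, seed=7,
    )
    return simulate_study(params)


@pytest.fixture(scope="session")
def reference_cohort():
    return emulate_reference_cohort(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pattern(rng, n_cells=120, radius=500.0, phenotypes=("tumor", "T_CD3")):
    """Uniform random pattern in the disc, mixed phenotypes (test helper)."""
    from tmescore.spatial import CellRecord, CorePattern

    r = radius * np.sqrt(rng.uniform(size=n_cells))
    th = rng.uniform(0, 2 * np.pi, size=n_cells)
    phen = rng.choice(phenotypes, size=n_cells)
    cells = tuple(
        CellRecord(float(x), float(y), str(p))
        for x, y, p in zip(r * np.cos(th), r * np.sin(th), phen)
    )
    return CorePattern("rand", (0.0, 0.0), radius, cells)
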
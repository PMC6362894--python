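import pandas as pd
import pytest

from cohortengine.panel import PopulationPanel
from cohortengine.synthetic import ScenarioSpec, generate_panel


def make_panel(rows):
    """Panel from (area, race, sex, age, year, value) tuples."""
    return PopulationPanel(
        pd.DataFrame(rows, columns=["area", "race", "sex", "age", "year", "value"])
    )


@pytest.fixture
def toy_panel():
    """The printed single-cohort example: 100 aged 5-9 at t-5, 125 aged 10-14
    and 90 aged 5-9 at t (area 01001, race 1, male)."""
    return make_panel(
        [
            ("01001", 1, 1, 2, 1995, 100.0),
            ("01001", 1, 1, 3, 1995, 0.0),
            ("01001", 1, 1, 2, 2000, 90.0),
            ("01001", 1, 1, 3, 2000, 125.0),
        ]
    )


@pytest.fixture(scope="session")
def ccr_fixture():
    """Noise-free default panel evolved under constant CCRs (declining)."""
    spec = ScenarioSpec(dynamics="CCR", seed=7)
    panel, truth = generate_panel(spec)
    return spec, panel, truth


@pytest.fixture(scope="session")
def ccd_fixture():
    """Noise-free default panel evolved under constant positive CCDs (growing)."""
    spec = ScenarioSpec(dynamics="CCD", seed=11)
    panel, truth = generate_panel(spec)
    return spec, panel, truth


def uniform_panel(value=100.0, years=(1995, 2000), areas=("01001",), races=(1,),
                  srb=1.0):
    """Identical cells at every census: exactly stationary under the
    projection operators.  Every measured ratio reproduces its own cell, the
    85+ ratio halves the doubled 80+ pool, and the child-woman ratio
    regenerates the 0-4 total, whose sex split is built srb-consistent so
    the birth split also reproduces it."""
    male_share = srb / (1.0 + srb)
    rows = []
    for a in areas:
        for r in races:
            for s in (1, 2):
                for g in range(1, 19):
                    if g == 1:
                        v = 2 * value * (male_share if s == 1 else 1 - male_share)
                    else:
                        v = value
                    rows.extend((a, r, s, g, y, v) for y in years)
    return make_panel(rows)
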
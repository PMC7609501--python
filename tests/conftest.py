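import numpy as np
import pytest

from bfikit import design, simulate


@pytest.fixture(scope="session")
def panel():
    return simulate.load_panel()


@pytest.fixture(scope="session")
def panel_db(panel):
    return [(s.compound_name, s.formula) for s in panel]


@pytest.fixture(scope="session")
def menus():
    return design.load_menu_plans()


@pytest.fixture(scope="session")
def full_panel_sim(panel, menus):
    """Full-panel study-2 simulation: 12 participants, 3 weeks, all markers."""
    base = simulate.STUDY_PROFILES["study2"]
    profile = simulate.CohortProfile(
        n=12, female_fraction=base.female_fraction, age=base.age,
        weight_kg=base.weight_kg, height_cm=base.height_cm, waist_cm=base.waist_cm,
    )
    cohort = simulate.generate_cohort(profile, seed=2)
    assignments = design.randomize_study2(cohort.ids, seed=2)
    exposures = simulate.simulate_exposures(cohort, assignments, menus, seed=2)
    matrix, truth = simulate.simulate_fingerprints(
        exposures, panel, assignments, seed=2
    )
    return matrix, truth, exposures
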
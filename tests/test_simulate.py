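"""Cohort, exposure and fingerprint generation."""

import numpy as np
import pandas as pd
import pytest

from bfikit import design, simulate
from bfikit.chem import ChemicalFormula, RULES_BY_LABEL
from bfikit.design import compliance_fraction
from bfikit.simulate import (
    BackgroundSpec,
    BiomarkerSpec,
    CohortProfile,
    ComplianceProfile,
    TraitProfile,
    ZERO_COMPLIANCE,
    generate_cohort,
    marker_bin_map,
    simulate_exposures,
    simulate_fingerprints,
    spike_multiplier,
    two_class_spike_scenario,
)


class TestCohort:
    def test_default_profile_reproduces_recruitment(self):
        cohort = generate_cohort(seed=0)
        assert len(cohort) == 51
        assert cohort.female_count == 29  # 57% female by deterministic rounding

    def test_single_participant(self):
        cohort = generate_cohort(CohortProfile(n=1), seed=0)
        assert len(cohort) == 1
        p = cohort.participants[0]
        assert 19 <= p.age <= 77 and p.bmi > 0

    def test_mean_age_matches_profile_over_seeds(self):
        ages = np.concatenate(
            [[p.age for p in generate_cohort(seed=s).participants] for s in range(10)]
        )
        se = 17.5 / np.sqrt(ages.size)
        # truncation to 19-77 shifts the mean by ~+0.6 y; well inside 3 SE
        assert abs(ages.mean() - 46.3) <= 3 * se

    def test_traits_respect_bounds(self):
        cohort = generate_cohort(seed=3)
        for p in cohort.participants:
            assert 19 <= p.age <= 77

    @pytest.mark.parametrize(
        "profile_kwargs",
        [dict(n=0), dict(female_fraction=1.5)],
    )
    def test_infeasible_profile_rejected(self, profile_kwargs):
        with pytest.raises(ValueError):
            CohortProfile(**profile_kwargs)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            TraitProfile(46.3, -1.0, 19.0, 77.0)


@pytest.fixture(scope="module")
def small_study(menus):
    cohort = generate_cohort(CohortProfile(n=6), seed=1)
    assignments = design.randomize_study2(cohort.ids, seed=1)
    return cohort, assignments


class TestExposures:
    def test_deterministic_for_fixed_seed(self, small_study, menus):
        cohort, assignments = small_study
        e1 = simulate_exposures(cohort, assignments, menus, seed=9)
        e2 = simulate_exposures(cohort, assignments, menus, seed=9)
        assert e1 == e2

    def test_zero_compliance_profile(self, small_study, menus):
        cohort, assignments = small_study
        events = simulate_exposures(
            cohort, assignments, menus, compliance=ZERO_COMPLIANCE, seed=0
        )
        assert all(e.consumed_fraction == 0.0 for e in events)

    def test_default_compliance_above_eighty_percent(self, small_study, menus):
        cohort, assignments = small_study
        events = simulate_exposures(cohort, assignments, menus, seed=0)
        records = simulate.compliance_records_from_events(events)
        _, overall = compliance_fraction(records)
        assert overall > 0.80

    def test_missing_menu_plan_rejected(self, small_study, menus):
        cohort, assignments = small_study
        partial = {k: v for k, v in menus.items() if k != 5}
        with pytest.raises(ValueError, match="menu plan 5"):
            simulate_exposures(cohort, assignments, partial, seed=0)

    def test_meal_ends_inside_windows(self, small_study, menus):
        cohort, assignments = small_study
        for e in simulate_exposures(cohort, assignments, menus, seed=2):
            w0, w1 = design.MEAL_WINDOWS[e.slot]
            assert e.day * 24 + w0 <= e.meal_end_h <= e.day * 24 + w1

    def test_compliance_probabilities_validated(self):
        with pytest.raises(ValueError):
            ComplianceProfile({100: 0.5, 75: 0.2, 50: 0.1, 25: 0.1, 0: 0.05})


class TestSpikeKinetics:
    def test_unit_magnitude_never_changes_signal(self):
        spec = simulate.shared_legume_marker(fold=1.0)
        for t in np.linspace(0, 48, 97):
            assert spike_multiplier(spec, t, 19.0, 1.0) == 1.0

    def test_peak_multiplier_and_decay(self):
        spec = simulate.shared_legume_marker(fold=5.0)
        peak = spike_multiplier(spec, 19.0 + spec.appearance_lag_h, 19.0, 1.0)
        assert peak == pytest.approx(5.0)
        one_halflife = spike_multiplier(
            spec, 19.0 + spec.appearance_lag_h + spec.decay_halflife_h, 19.0, 1.0
        )
        assert one_halflife == pytest.approx(3.0)  # 1 + 4/2

    def test_no_effect_before_lag(self):
        spec = simulate.shared_legume_marker(fold=5.0)
        assert spike_multiplier(spec, 19.2, 19.0, 1.0) == 1.0


@pytest.fixture(scope="module")
def noise_free(panel, menus):
    cohort = generate_cohort(CohortProfile(n=4), seed=5)
    assignments = design.randomize_study2(cohort.ids, seed=5)
    exposures = simulate_exposures(cohort, assignments, menus, seed=5)
    kwargs = dict(
        background=BackgroundSpec(n_features=200), bin_width=0.01, seed=5,
    )
    diluted, truth = simulate_fingerprints(
        exposures, panel, assignments, noise_cv=0.0, dilution_cv=0.3, **kwargs
    )
    undiluted, _ = simulate_fingerprints(
        exposures, panel, assignments, noise_cv=0.0, dilution_cv=0.0, **kwargs
    )
    return diluted, undiluted, truth


class TestFingerprints:
    def test_dilution_conservation(self, noise_free):
        """Dividing by the recorded dilution factor recovers pre-dilution
        intensities exactly when the noise CV is zero."""
        from bfikit.processing import normalize_dilution

        diluted, undiluted, _ = noise_free
        recovered = normalize_dilution(diluted)
        assert np.allclose(
            recovered.intensities, undiluted.intensities, rtol=1e-12, atol=0
        )

    def test_truth_table_covers_every_sample_and_food(self, noise_free, menus):
        diluted, _, truth = noise_free
        assert set(truth["sample_id"]) == set(diluted.sample_ids())
        foods = {
            item.name for p in (4, 5, 6) for items in menus[p].meals.values()
            for item in items
        }
        assert {f"food:{f}" for f in foods} <= set(truth.columns)
        assert any(c.startswith("group:") for c in truth.columns)

    def test_marker_bins_elevated_after_exposure(self, noise_free, panel):
        diluted, undiluted, truth = noise_free
        bins = marker_bin_map(panel)
        j = undiluted.bin_index(bins["acesulfame potassium"][0])
        flag = dict(zip(truth["sample_id"], truth["food:low-calorie beverage"]))
        exposed = [i for i, m in enumerate(undiluted.sample_meta)
                   if flag[m.sample_id] and m.urine_type == "bed_time"]
        baseline = [i for i, m in enumerate(undiluted.sample_meta)
                    if flag[m.sample_id] == 0 and m.urine_type == "FMV"]
        assert exposed and baseline
        assert (
            np.median(undiluted.intensities[exposed, j])
            > 2 * np.median(undiluted.intensities[baseline, j])
        )

    def test_bin_collision_rejected_naming_pair(self):
        a = BiomarkerSpec(
            compound_name="compound A", formula=ChemicalFormula.parse("C6H6O6S"),
            ionization_products=(RULES_BY_LABEL["[M-H]1-"],),
            food_sources="x", source_groups=("g1",), msi_evidence=("class_only",),
            appearance_lag_h=0, decay_halflife_h=1, spike_magnitude=2,
        )
        b = BiomarkerSpec(
            compound_name="compound B", formula=ChemicalFormula.parse("C6H6O6S"),
            ionization_products=(RULES_BY_LABEL["[M-H]1-"],),
            food_sources="y", source_groups=("g2",), msi_evidence=("class_only",),
            appearance_lag_h=0, decay_halflife_h=1, spike_magnitude=2,
        )
        with pytest.raises(ValueError, match="compound A.*compound B"):
            marker_bin_map([a, b])

    def test_packaged_panel_has_no_bin_collisions(self, panel):
        bins = marker_bin_map(panel)
        all_centers = [c for centers in bins.values() for c in centers]
        assert len(all_centers) == len(set(all_centers))


class TestTwoClassScenario:
    def test_shapes_and_balance(self):
        X, labels, j = two_class_spike_scenario(
            n_per_class=10, n_features=50, seed=0
        )
        assert X.shape == (20, 50)
        assert (labels == "exposed").sum() == 10
        assert 0 <= j < 50

    def test_spiked_feature_separates_classes(self):
        X, labels, j = two_class_spike_scenario(
            n_per_class=30, n_features=50, fold=5.0, seed=1
        )
        assert (
            X[labels == "exposed", j].mean() - X[labels == "baseline", j].mean()
            > 0.5
        )

    def test_null_scenario_classifier_near_chance(self):
        """With no spiked signal the RF stays near-chance (AUC <= 0.6 on
        out-of-bag votes, averaged over 10 seeds)."""
        from bfikit.discovery import RFParams, classify_urine_classes

        aucs = []
        for seed in range(10):
            X, labels, _ = two_class_spike_scenario(
                fold=1.0, n_features=200, seed=seed
            )
            metrics, _ = classify_urine_classes(
                X, labels, positive_class="exposed",
                params=RFParams(n_trees=200), seed=seed,
            )
            aucs.append(metrics.auc)
        assert np.mean(aucs) <= 0.6
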
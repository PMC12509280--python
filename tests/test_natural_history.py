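import numpy as np
import pytest

from capscreen import (
    CalibrationTargets,
    LifeTable,
    NaturalHistoryModel,
    NaturalHistoryParams,
    generate_default_params,
    simulate_cohort,
    simulate_life_history,
)
from capscreen.natural_history import CalibrationError

from _oracle import simulate_discrete


def _zero_onset(params):
    return NaturalHistoryParams(
        onset_bands=np.zeros(10),
        rate_small_to_medium=params.rate_small_to_medium,
        rate_medium_to_large=params.rate_medium_to_large,
        rate_large_to_malignant=params.rate_large_to_malignant,
        stage_progression=params.stage_progression,
        stage_detection=params.stage_detection,
        segment_distribution=params.segment_distribution,
        stage_survival_mean=params.stage_survival_mean,
    )


# ----------------------------------------------------------------------
class TestDefaults:
    def test_default_params_satisfy_invariants(self):
        p = generate_default_params(1)
        assert np.all(p.onset_bands >= 0)
        assert np.isclose(p.segment_distribution.sum(), 1.0)
        assert np.all(np.diff(p.stage_survival_mean) <= 0)

    def test_default_params_deterministic_per_seed(self):
        a, b = generate_default_params(1), generate_default_params(1)
        assert np.array_equal(a.onset_bands, b.onset_bands)
        assert a.rate_small_to_medium == b.rate_small_to_medium
        c = generate_default_params(2)
        assert not np.array_equal(a.onset_bands, c.onset_bands)

    def test_uncalibrated_incidence_in_starting_band(self, life_table):
        p = generate_default_params(1)
        s = simulate_cohort(p, life_table, 100_000, seed=1).summary()
        assert 40 <= s["crc_cases_per_1000"] <= 120

    def test_yaml_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.yaml"
        default_params.to_yaml(path)
        p2 = NaturalHistoryParams.from_yaml(path)
        assert np.allclose(default_params.onset_bands, p2.onset_bands)
        assert np.allclose(default_params.stage_survival_mean, p2.stage_survival_mean)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("rate_small_to_medium", -0.1),
            ("stage_survival_mean", np.array([1.0, 2.0, 3.0, 4.0])),  # wrong ordering
            ("segment_distribution", np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.5])),
        ],
    )
    def test_invalid_params_rejected(self, default_params, field, value):
        d = default_params.to_dict()
        d[field] = value
        with pytest.raises(ValueError):
            NaturalHistoryParams.from_dict(d)


# ----------------------------------------------------------------------
class TestCohortSimulation:
    def test_zero_onset_means_no_disease(self, default_params, life_table):
        coh = simulate_cohort(_zero_onset(default_params), life_table, 1000, seed=1)
        out = coh.no_screening_outcomes()
        assert coh.n_lesions == 0
        assert np.all(out.dx_mode == 0)
        assert np.all(out.death_cause == 0)

    def test_zero_detection_means_no_clinical_diagnoses(self, default_params, life_table):
        p = default_params.to_dict()
        p["stage_detection"] = [0.0, 0.0, 0.0, 0.0]
        coh = simulate_cohort(NaturalHistoryParams.from_dict(p), life_table, 5000, seed=1)
        assert np.all(np.isinf(coh.clin_age))
        out = coh.no_screening_outcomes()
        assert np.all(out.dx_mode == 0)

    def test_summary_deterministic_per_seed(self, default_params, life_table):
        s1 = simulate_cohort(default_params, life_table, 20_000, seed=9).summary()
        s2 = simulate_cohort(default_params, life_table, 20_000, seed=9).summary()
        assert s1 == s2

    def test_partition_invariance(self, default_params, life_table):
        """Person i's history does not depend on cohort chunking."""
        whole = simulate_cohort(default_params, life_table, 4000, seed=2)
        part1 = simulate_cohort(default_params, life_table, 2500, seed=2)
        part2 = simulate_cohort(default_params, life_table, 1500, seed=2, person_offset=2500)
        assert np.allclose(
            whole.other_death_age, np.concatenate([part1.other_death_age, part2.other_death_age])
        )
        assert whole.n_lesions == part1.n_lesions + part2.n_lesions
        assert np.allclose(whole.clin_age, np.concatenate([part1.clin_age, part2.clin_age]))

    def test_rejects_empty_cohort(self, default_params, life_table):
        with pytest.raises(ValueError):
            simulate_cohort(default_params, life_table, 0, seed=1)

    def test_cases_always_at_least_deaths(self, cohort):
        out = cohort.no_screening_outcomes()
        s = out.summary_per_1000()
        assert s["crc_cases_per_1000"] >= s["crc_deaths_per_1000"]
        # every CRC death carries a prior diagnosis
        crc_deaths = out.death_cause == 1
        assert np.all(out.dx_mode[crc_deaths] > 0)
        assert np.all(out.dx_age[crc_deaths] <= out.death_age[crc_deaths])

    def test_lesion_state_entry_ages_ordered(self, cohort):
        assert np.all(cohort.age_medium > cohort.onset_age)
        assert np.all(cohort.age_large > cohort.age_medium)
        assert np.all(cohort.age_malignant > cohort.age_large)
        assert np.all(cohort.e2 > cohort.age_malignant)
        assert np.all(cohort.clin_age > cohort.age_malignant)

    def test_death_age_capped_at_max(self, cohort):
        out = cohort.no_screening_outcomes()
        assert np.all(out.death_age <= cohort.params.max_age)

    def test_life_expectancy_without_disease_matches_table(self, default_params, life_table):
        coh = simulate_cohort(_zero_onset(default_params), life_table, 150_000, seed=4)
        out = coh.no_screening_outcomes()
        assert abs(out.death_age.mean() - life_table.life_expectancy()) < 0.2


class TestSinglePerson:
    def test_life_history_object_view(self, calibrated_params, life_table):
        found = 0
        for pid in range(300):
            lh = simulate_life_history(calibrated_params, life_table, seed=5, person_id=pid)
            assert 1938 <= lh.birth_year <= 1957
            assert lh.death[0] <= 100.0
            if lh.crc_diagnosis:
                assert 1 <= lh.crc_diagnosis["stage"] <= 4
                found += 1
            for lesion in lh.lesions:
                ages = list(lesion.state_entry_ages.values())
                assert all(b > a for a, b in zip(ages, ages[1:]))
        assert found > 0

    def test_crc_death_requires_diagnosis(self, calibrated_params, life_table):
        for pid in range(200):
            lh = simulate_life_history(calibrated_params, life_table, seed=8, person_id=pid)
            if lh.death[1] == "crc":
                assert lh.crc_diagnosis is not None


# ----------------------------------------------------------------------
class TestInterventionReplay:
    def test_removing_diagnosing_lesion_averts_or_delays_cancer(self, cohort):
        out = cohort.no_screening_outcomes()
        dxed = np.flatnonzero(out.dx_mode == 1)[:2000]
        lesions = cohort.argmin_clin_lesion(dxed, cohort.clin_age)
        removed = np.zeros(cohort.n_lesions, bool)
        removed[lesions] = True
        out2 = cohort.outcomes_given(removed=removed)
        # the removed lesion can no longer cause that diagnosis
        still = out2.dx_mode[dxed] > 0
        assert np.all(out2.dx_age[dxed][still] > out.dx_age[dxed][still])
        assert np.count_nonzero(~still) > 0  # most cancers are averted outright

    def test_removing_all_lesions_eliminates_all_cancer(self, cohort):
        removed = np.ones(cohort.n_lesions, bool)
        out = cohort.outcomes_given(removed=removed)
        assert np.all(out.dx_mode == 0)
        assert np.all(out.death_cause == 0)


# ----------------------------------------------------------------------
class TestOracleAgreement:
    def test_lifetime_rates_match_discrete_time_oracle(self, default_params, life_table):
        """Continuous-time simulator agrees with a monthly brute-force walk."""
        n_oracle = 6000
        oracle = simulate_discrete(default_params, life_table, n_oracle, seed=42)
        big = simulate_cohort(default_params, life_table, 150_000, seed=10).summary()
        for key in ("crc_cases_per_1000", "crc_deaths_per_1000"):
            p = big[key] / 1000.0
            se = 1000.0 * np.sqrt(p * (1 - p) / n_oracle)
            assert abs(oracle[key] - big[key]) < 3.5 * se, key

    def test_two_transition_chain_matches_closed_form(self, life_table):
        """Time from onset to large adenoma is hypoexponential(l1, l2)."""
        p = generate_default_params(1)
        coh = simulate_cohort(p, life_table, 100_000, seed=6)
        l1, l2 = p.rate_small_to_medium, p.rate_medium_to_large
        t = 15.0
        analytic = 1.0 - (l2 * np.exp(-l1 * t) - l1 * np.exp(-l2 * t)) / (l2 - l1)
        empirical = np.mean((coh.age_large - coh.onset_age) <= t)
        se = np.sqrt(analytic * (1 - analytic) / coh.n_lesions)
        assert abs(empirical - analytic) < 4 * se


# ----------------------------------------------------------------------
class TestCalibration:
    def test_targets_validated(self):
        with pytest.raises(ValueError):
            CalibrationTargets(lifetime_crc_incidence_per_1000=30, lifetime_crc_mortality_per_1000=40)

    def test_fixed_point_returns_unit_scales(self, calibration, life_table):
        """Re-fitting from already calibrated parameters changes nothing
        (tolerance wide enough to absorb the evaluation's Monte-Carlo noise)."""
        model = NaturalHistoryModel(
            targets=CalibrationTargets(tolerance=0.05),
            life_table=life_table,
            params0=calibration.params,
        )
        res = model.fit(sim_size=60_000, seed=3)
        assert res.converged
        assert res.n_iter == 1
        assert res.onset_scale == 1.0 and res.fatality_scale == 1.0

    def test_calibration_reaches_targets(self, calibration):
        """Achieved aggregates sit within tolerance, allowing the
        Monte-Carlo error of the reporting evaluation."""
        t = calibration.targets
        assert calibration.converged
        assert abs(calibration.achieved_incidence - t.lifetime_crc_incidence_per_1000) <= (
            t.tolerance * t.lifetime_crc_incidence_per_1000
            + 2 * calibration.mc_se_per_1000(calibration.achieved_incidence)
        )
        assert abs(calibration.achieved_mortality - t.lifetime_crc_mortality_per_1000) <= (
            t.tolerance * t.lifetime_crc_mortality_per_1000
            + 2 * calibration.mc_se_per_1000(calibration.achieved_mortality)
        )

    def test_onset_scale_increases_with_incidence_target(self, life_table):
        scales = []
        for target in (50.0, 100.0):
            res = NaturalHistoryModel(
                targets=CalibrationTargets(
                    lifetime_crc_incidence_per_1000=target,
                    lifetime_crc_mortality_per_1000=target * 36 / 79,
                    tolerance=0.03,
                ),
                life_table=life_table,
            ).fit(sim_size=40_000, seed=3)
            scales.append(res.onset_scale)
        assert scales[1] > scales[0]

    def test_non_convergence_raises_with_trace(self, life_table):
        with pytest.raises(CalibrationError) as err:
            NaturalHistoryModel(life_table=life_table).fit(
                sim_size=5000, seed=1, max_iter=1
            )
        assert len(err.value.trace) == 1

    def test_summary_mentions_targets(self, calibration):
        text = calibration.summary()
        assert "79.0" in text and "36.0" in text and "converged" in text
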
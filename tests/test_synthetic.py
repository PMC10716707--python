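"""Synthetic cohort generator: determinism, prevalence calibration,
effect-size recovery, information content."""

import numpy as np
import pytest
from scipy.special import expit

from cxrfuse.clinical import kbest_select, stratified_split
from cxrfuse.synthetic import (CohortSimParams, generate_clinical_table,
                               generate_cohort, generate_multilabel_images,
                               lung_fields, write_cohort)


class TestParams:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortSimParams(n_patients=1)
        with pytest.raises(ValueError):
            CohortSimParams(image_size=16)
        with pytest.raises(ValueError):
            CohortSimParams(label_prevalences=1.5)
        with pytest.raises(ValueError):
            CohortSimParams(clinical_effect_sizes={"not_a_column": 1.0})
        with pytest.raises(ValueError):
            CohortSimParams(clinical_effect_sizes={"radiological_score": 1.0})


class TestImages:
    def test_null_prevalence_gives_lungs_only(self):
        params = CohortSimParams(n_patients=4, label_prevalences=0.0,
                                 noise_sd=0.0, seed=0)
        images, labels = generate_multilabel_images(params)
        assert labels.sum() == 0
        base = 0.08 + 0.5 * lung_fields(params.image_size, soft=True)
        for img in images:
            np.testing.assert_allclose(img, np.clip(base, 0, 1), atol=1e-12)

    def test_seeded_determinism(self):
        params = CohortSimParams(n_patients=6, seed=11)
        a = generate_multilabel_images(params)
        b = generate_multilabel_images(params)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_intensity_range(self):
        images, _ = generate_multilabel_images(CohortSimParams(n_patients=5, seed=2))
        assert images.min() >= 0.0 and images.max() <= 1.0

    def test_empirical_prevalence_within_binomial_ci(self):
        # Oracle: per-label prevalence within 3 binomial SDs of the target.
        n, p = 500, 0.3
        params = CohortSimParams(n_patients=n, label_prevalences=p, seed=3)
        _, labels = generate_multilabel_images(params)
        sd = np.sqrt(p * (1 - p) / n)
        emp = labels.mean(axis=0)
        assert (np.abs(emp - p) < 3 * sd).all()


class TestClinicalTable:
    def test_null_effects_give_no_association(self):
        # Null-simulation oracle: with all effect sizes zero, every
        # feature's point-biserial correlation with the label is small.
        params = CohortSimParams(n_patients=1000, clinical_effect_sizes={},
                                 seed=0)
        table, y = generate_clinical_table(params)
        for col in ("cs_amount", "igm_quant", "age", "erv_abs", "pneumonia"):
            x = table[col].astype(float)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(r) < 0.1, col

    def test_strong_effect_ranks_first_in_kbest(self):
        from cxrfuse.clinical import assemble_final_features

        hits = 0
        for rep in range(40):
            params = CohortSimParams(
                n_patients=500, seed=500 + rep,
                clinical_effect_sizes={"ko_rdw": 5.0})
            table, y = generate_clinical_table(params)
            feats = assemble_final_features(table).frame.reset_index(drop=True)
            ranked = kbest_select(feats, y, k=1)
            hits += ranked.iloc[0]["feature"] == "ko_rdw"
        assert hits >= 38  # >= 95% of replicates

    def test_no_missing_markers_when_rate_zero(self):
        table, _ = generate_clinical_table(
            CohortSimParams(n_patients=50, missing_rate=0.0, seed=5))
        for col in ("dyspnea", "cough", "fatigue"):
            assert set(table[col]) <= {"yes", "no"}

    def test_bmi_consistent_with_weight_height(self):
        table, _ = generate_clinical_table(CohortSimParams(n_patients=30, seed=6))
        bmi = table["weight_kg"] / (table["height_cm"] / 100) ** 2
        np.testing.assert_allclose(table["bmi"], bmi, atol=0.5)

    def test_effect_size_recovery_by_logistic_fit(self):
        # A logistic fit on a large table recovers the planted log-odds
        # within 3 standard errors.
        import statsmodels.api as sm

        beta = 0.8
        params = CohortSimParams(n_patients=4000, seed=7,
                                 clinical_effect_sizes={"ko_rdw": beta})
        table, y = generate_clinical_table(params)
        x = table["ko_rdw"].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std()
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        est, se = fit.params[1], fit.bse[1]
        assert abs(est - beta) < 3 * se


class TestCohort:
    def test_composition_and_determinism(self):
        params = CohortSimParams(n_patients=40, seed=8)
        a = generate_cohort(params)
        b = generate_cohort(params)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.benefit_labels, b.benefit_labels)
        assert a.clinical.equals(b.clinical)
        assert len(a.images) == len(a.masks) == len(a.clinical) == 40

    def test_273_cohort_splits_218_55(self):
        cohort = generate_cohort(CohortSimParams(n_patients=273, seed=9))
        train, test = stratified_split(cohort.benefit_labels, seed=0)
        assert (len(train), len(test)) == (218, 55)

    def test_benefit_positive_images_carry_opacity(self):
        params = CohortSimParams(n_patients=120, seed=10, image_effect=0.3,
                                 label_prevalences=0.0, noise_sd=0.0)
        c = generate_cohort(params)
        pos = c.images[c.benefit_labels == 1].mean()
        neg = c.images[c.benefit_labels == 0].mean()
        assert pos > neg + 0.01

    def test_benefit_prevalence_matches_target(self):
        c = generate_cohort(CohortSimParams(n_patients=2000, seed=12))
        target = c.truth.benefit_prevalence
        sd = np.sqrt(target * (1 - target) / 2000)
        assert abs(c.benefit_labels.mean() - target) < 4 * sd


def test_write_cohort_round_trip(tmp_path):
    cohort = generate_cohort(CohortSimParams(n_patients=3, seed=13))
    write_cohort(cohort, tmp_path)
    assert (tmp_path / "clinical.csv").exists()
    assert (tmp_path / "truth.json").exists()
    assert len(list((tmp_path / "images").glob("*.png"))) == 3

    from cxrfuse.clinical import load_clinical_table

    table = load_clinical_table(tmp_path / "clinical.csv")
    assert len(table) == 3
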
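"""Generator contracts: cohort arithmetic, determinism, dose monotonicity,
dependency-selective responses and proteomics ground truth."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from albh3 import ProteomicsSimConfig, SimConfig, apply_exclusion_filters
from albh3.config import ConfigError
from albh3.simulate import (
    PatientLatent,
    apply_treatment_shift,
    drug_death_fraction,
    release_probability,
    simulate_bh3_plate,
    simulate_chemo_plate,
    simulate_cohort,
    simulate_proteomics,
)


class TestSimulateCohort:
    def test_full_accrual_fixed_counts(self):
        manifest, latents = simulate_cohort(SimConfig.full_cohort(seed=1))
        assert len(manifest) == 88 and len(latents) == 88
        included, summary = apply_exclusion_filters(manifest)
        assert summary.n_insufficient == 8
        assert summary.n_no_predominance == 22
        assert summary.n_included == 58

    def test_empty_cohort(self):
        manifest, latents = simulate_cohort(SimConfig(n_patients=0, n_naive=0))
        assert len(manifest) == 0 and latents == []

    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig.full_cohort(seed=9)
        m1, l1 = simulate_cohort(cfg)
        m2, l2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(m1.records, m2.records)
        assert l1 == l2

    def test_naive_group_more_primed_by_configured_gap(self):
        cfg = SimConfig(seed=3, n_patients=400, n_naive=200)
        _, latents = simulate_cohort(cfg)
        theta = pd.Series({l.patient_id: l.priming_theta for l in latents})
        status = pd.Series({l.patient_id: l.treatment_status for l in latents})
        gap = theta[status == "naive"].mean() - theta[status == "relapsed"].mean()
        assert gap == pytest.approx(cfg.priming_gap, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_patients=-1)
        with pytest.raises(ConfigError):
            SimConfig(n_patients=4, n_insufficient=3, n_no_predominance=3)


class TestReleaseModel:
    def test_monotone_in_dose_priming_and_dependency(self, latent):
        doses = [0.01, 0.1, 1.0, 10.0, 100.0]
        for pep in ("BIM", "BID", "PUMA", "BAD", "HRK", "MS1"):
            probs = [release_probability(latent, pep, d) for d in doses]
            assert np.all(np.diff(probs) >= 0), pep
        thetas = np.linspace(0, 1, 11)
        probs = [
            release_probability(
                dataclasses.replace(latent, priming_theta=t), "BIM", 1.0
            )
            for t in thetas
        ]
        assert np.all(np.diff(probs) >= 0)
        deps = np.linspace(0, 1, 11)
        probs = [
            release_probability(dataclasses.replace(latent, dep_mcl1=w), "MS1", 10.0)
            for w in deps
        ]
        assert np.all(np.diff(probs) >= 0)

    def test_zero_priming_yields_background_only(self, latent):
        flat = dataclasses.replace(latent, priming_theta=0.0)
        for pep in ("BIM", "BAD", "MS1"):
            assert release_probability(flat, pep, 10.0) == pytest.approx(0.05)

    def test_saturating_priming_approaches_positive_control(self, latent):
        hot = dataclasses.replace(latent, priming_theta=1.0)
        top = release_probability(hot, "BIM", 10.0)
        assert release_probability(hot, "alamethicin", 0.0) == 1.0
        assert top > 0.98

    def test_mcl1_dependent_patient_prefers_ms1_over_bad(self):
        # Monte-Carlo across simulated plates, several seeds
        lat = PatientLatent("P", 0.8, dep_bcl2=0.1, dep_bclxl=0.05, dep_mcl1=0.9)
        cfg = SimConfig(events_per_well=500)
        ms1, bad = [], []
        for seed in range(10):
            ev = simulate_bh3_plate(lat, events_per_well=500, seed=seed, config=cfg)
            for name, acc in (("MS1", ms1), ("BAD", bad)):
                well = ev[(ev.condition == name) & (ev.dose == 10.0)]
                acc.append((well["cytc"] < 100).mean())
        assert np.mean(ms1) > np.mean(bad)


class TestBH3Plate:
    def test_missing_controls_named(self, latent):
        from albh3.simulate import _panel_conditions

        with pytest.raises(ConfigError, match="negative-control"):
            _panel_conditions([("BIM", (1.0,)), ("alamethicin", ())])
        with pytest.raises(ConfigError, match="alamethicin"):
            _panel_conditions([("BIM", (1.0,)), ("DMSO", ())])

    def test_plate_determinism_and_bimodality(self, latent, small_config):
        ev1 = simulate_bh3_plate(latent, events_per_well=800, seed=5, config=small_config)
        ev2 = simulate_bh3_plate(latent, events_per_well=800, seed=5, config=small_config)
        pd.testing.assert_frame_equal(ev1, ev2)
        pos = ev1[ev1.control_type == "positive_alamethicin"]
        neg = ev1[ev1.control_type == "negative_dmso"]
        assert pos["cytc"].median() < neg["cytc"].median()


class TestChemoPlate:
    def test_no_dependency_tracks_dmso(self):
        lat = PatientLatent("P", 0.9, dep_bcl2=0.0, dep_bclxl=0.0, dep_mcl1=0.5)
        for dose in (1.0, 100.0, 1000.0):
            assert drug_death_fraction(lat, "ABT-199", dose) == 0.0
        wells = simulate_chemo_plate(lat, drugs=[("ABT-199", (10.0, 1000.0))], seed=1)
        abt = wells[wells.drug_a == "ABT-199"]["pct_annexin_pos_in_cd138"]
        dmso = wells[wells.drug_a == "DMSO"]["pct_annexin_pos_in_cd138"]
        assert abs(abt.mean() - dmso.mean()) < 5.0

    def test_full_dependency_strictly_increasing_expectation(self):
        lat = PatientLatent("P", 1.0, dep_bcl2=1.0, dep_bclxl=0.0, dep_mcl1=0.0)
        deaths = [drug_death_fraction(lat, "ABT-199", d) for d in (1, 10, 100, 1000)]
        assert np.all(np.diff(deaths) > 0)
        # Monte-Carlo: observed Annexin means follow the same ordering
        means = []
        for seed in range(5):
            w = simulate_chemo_plate(lat, drugs=[("ABT-199", (10.0, 100.0, 1000.0))], seed=seed)
            w = w[w.drug_a == "ABT-199"].groupby("dose_a")["pct_annexin_pos_in_cd138"].mean()
            means.append(w.to_numpy())
        assert np.all(np.diff(np.mean(means, axis=0)) > 0)

    def test_unknown_drug_lists_recognized(self, latent):
        with pytest.raises(ConfigError, match="recognized drugs"):
            simulate_chemo_plate(latent, drugs=[("nonsense", (1.0,))])

    def test_determinism(self, latent):
        w1 = simulate_chemo_plate(latent, seed=3)
        w2 = simulate_chemo_plate(latent, seed=3)
        pd.testing.assert_frame_equal(w1, w2)


class TestTreatmentShift:
    def test_shift_arithmetic(self, latent):
        shifted = apply_treatment_shift(
            dataclasses.replace(latent, dep_bcl2=0.4, dep_mcl1=0.8), 0.3
        )
        assert shifted.dep_bcl2 == pytest.approx(0.7)
        assert shifted.dep_mcl1 == pytest.approx(0.5)
        assert shifted.treatment_status == "on_bortezomib"

    def test_zero_shift_identity_except_status(self, latent):
        shifted = apply_treatment_shift(latent, 0.0)
        assert shifted == dataclasses.replace(latent, treatment_status="on_bortezomib")

    def test_clipping_and_input_untouched(self, latent):
        hot = dataclasses.replace(latent, dep_bcl2=0.9, dep_mcl1=0.1)
        shifted = apply_treatment_shift(hot, 0.3)
        assert shifted.dep_bcl2 == 1.0 and shifted.dep_mcl1 == 0.0
        assert hot.dep_bcl2 == 0.9  # frozen input unchanged

    def test_negative_shift_rejected(self, latent):
        with pytest.raises(ConfigError):
            apply_treatment_shift(latent, -0.1)


class TestProteomicsSim:
    def test_determinism_and_truth_shape(self):
        cfg = ProteomicsSimConfig(n_proteins=50)
        m1, t1 = simulate_proteomics(cfg, seed=2)
        m2, t2 = simulate_proteomics(cfg, seed=2)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)
        assert m1.values.shape == (50, 10)

    def test_exact_nonnull_fraction(self):
        cfg = ProteomicsSimConfig(n_proteins=40, fraction_nonnull=0.25)
        _, truth = simulate_proteomics(cfg, seed=0)
        assert truth["nonnull"].sum() == 10
        null = truth[~truth["nonnull"]]
        assert (null[["b1", "b2", "b3"]] == 0).all().all()

    def test_config_contracts(self):
        with pytest.raises(ConfigError):
            ProteomicsSimConfig(n_proteins=0).validate()
        with pytest.raises(ConfigError):
            ProteomicsSimConfig(timepoints=(0.0,)).validate()
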
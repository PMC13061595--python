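"""Composite risk scores, flags, fitness categorization, patient ranking."""

import numpy as np
import pandas as pd
import pytest

from epifit.errors import AlignmentError, DegenerateScaleError
from epifit.risk import (RiskTable, ThresholdConfig, categorize_fitness, compute_direct_risk,
                         compute_indirect_risk, compute_risk_scores, rank_high_risk_patients)


def hazard_table(rows):
    return pd.DataFrame(rows, columns=["disease", "protein_id", "log_hr"])


def idx(n):
    return pd.Index([f"S{i}" for i in range(n)], name="sample_id")


class TestDirectRisk:
    def test_null_weights_give_zero(self, rng):
        episc = pd.DataFrame(rng.normal(size=(4, 2)), index=idx(4), columns=["P1", "P2"])
        hz = hazard_table([("d1", "P1", 0.0), ("d1", "P2", 0.0)])
        assert (compute_direct_risk(episc, hz) == 0).all().all()

    def test_identity_weight_returns_episcore(self, rng):
        episc = pd.DataFrame(rng.normal(size=(4, 1)), index=idx(4), columns=["P1"])
        hz = hazard_table([("d1", "P1", 1.0)])
        np.testing.assert_allclose(compute_direct_risk(episc, hz)["d1"], episc["P1"])

    def test_hand_computed_two_protein_sum(self):
        episc = pd.DataFrame({"P1": [1.0], "P2": [2.0]}, index=idx(1))
        hz = hazard_table([("d1", "P1", 0.3), ("d1", "P2", -0.2)])
        assert compute_direct_risk(episc, hz).iloc[0, 0] == pytest.approx(-0.1, abs=1e-12)

    def test_missing_protein_skipped_with_warning(self, rng, caplog):
        episc = pd.DataFrame(rng.normal(size=(4, 1)), index=idx(4), columns=["P1"])
        hz = hazard_table([("d1", "P1", 0.5), ("d1", "P9", 0.5), ("d2", "P9", 0.1)])
        with caplog.at_level("WARNING"):
            out = compute_direct_risk(episc, hz)
        np.testing.assert_allclose(out["d1"], 0.5 * episc["P1"])
        assert (out["d2"] == 0).all()
        assert "absent" in caplog.text


def brute_force_indirect(fitness_z, sig, hz):
    """Oracle: explicit loop over every (trait, protein, disease) chain."""
    diseases = list(dict.fromkeys(hz["disease"]))
    out = pd.DataFrame(0.0, index=fitness_z.index, columns=diseases)
    for s in fitness_z.index:
        for _, arow in sig.iterrows():
            for _, hrow in hz.iterrows():
                if hrow["protein_id"] == arow["protein_id"]:
                    out.loc[s, hrow["disease"]] += (
                        arow["beta"] * hrow["log_hr"] * fitness_z.loc[s, arow["fitness_trait"]]
                    )
    return out


class TestIndirectRisk:
    def test_empty_chain_is_zero(self, rng, caplog):
        fit = pd.DataFrame(rng.normal(size=(3, 1)), index=idx(3), columns=["BMI"])
        sig = pd.DataFrame(columns=["fitness_trait", "protein_id", "beta"])
        hz = hazard_table([("d1", "P1", 0.2)])
        with caplog.at_level("WARNING"):
            out = compute_indirect_risk(fit, sig, hz)
        assert (out == 0).all().all()

    def test_single_chain_hand_product(self):
        fit = pd.DataFrame({"BMI": [2.0]}, index=idx(1))
        sig = pd.DataFrame([("BMI", "P1", 0.5)],
                           columns=["fitness_trait", "protein_id", "beta"])
        hz = hazard_table([("d1", "P1", 0.2)])
        out = compute_indirect_risk(fit, sig, hz)
        assert out.iloc[0, 0] == pytest.approx(0.2, abs=1e-12)

    def test_two_chains_sum_additively(self):
        fit = pd.DataFrame({"BMI": [1.5]}, index=idx(1))
        hz = hazard_table([("d1", "P1", 0.2), ("d1", "P2", -0.3)])
        sig1 = pd.DataFrame([("BMI", "P1", 0.5)],
                            columns=["fitness_trait", "protein_id", "beta"])
        sig2 = pd.DataFrame([("BMI", "P2", 0.4)],
                            columns=["fitness_trait", "protein_id", "beta"])
        both = pd.concat([sig1, sig2], ignore_index=True)
        combined = compute_indirect_risk(fit, both, hz)
        separate = compute_indirect_risk(fit, sig1, hz) + compute_indirect_risk(fit, sig2, hz)
        pd.testing.assert_frame_equal(combined, separate, atol=1e-12, rtol=0)

    def test_matches_brute_force_enumeration(self, rng):
        traits = ["VO2max", "BMI", "Cognition"]
        fit = pd.DataFrame(rng.normal(size=(6, 3)), index=idx(6), columns=traits)
        sig = pd.DataFrame(
            [(traits[int(rng.integers(3))], f"P{int(rng.integers(4))}", rng.normal())
             for _ in range(8)],
            columns=["fitness_trait", "protein_id", "beta"])
        hz = hazard_table([(f"d{j}", f"P{i}", rng.normal() * 0.3)
                           for j in range(3) for i in range(4)])
        fast = compute_indirect_risk(fit, sig, hz)
        oracle = brute_force_indirect(fit, sig, hz)
        pd.testing.assert_frame_equal(fast, oracle[fast.columns], atol=1e-12, rtol=0)


class TestComputeRiskScores:
    def test_three_patient_hand_calculation(self):
        direct = pd.DataFrame({"d1": [1.0, 2.0, 3.0]}, index=idx(3))
        indirect = pd.DataFrame({"d1": [0.0, 0.0, 0.0]}, index=idx(3))
        risk = compute_risk_scores(direct, indirect)
        np.testing.assert_allclose(risk.z["d1"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert not risk.high_risk["d1"].any()  # max z = 1.0 < 1.28

    def test_raw_is_sum_of_terms(self, rng):
        direct = pd.DataFrame({"d1": rng.normal(size=5)}, index=idx(5))
        indirect = pd.DataFrame({"d1": rng.normal(size=5)}, index=idx(5))
        risk = compute_risk_scores(direct, indirect)
        pd.testing.assert_frame_equal(risk.raw, direct + indirect)

    def test_z_columns_mean_zero_sd_one(self, rng):
        direct = pd.DataFrame(rng.normal(size=(50, 3)), index=idx(50),
                              columns=["d1", "d2", "d3"])
        risk = compute_risk_scores(direct, direct * 0.0)
        assert (risk.z.mean().abs() < 1e-9).all()
        assert ((risk.z.std(ddof=1) - 1).abs() < 1e-9).all()
        # flags are exactly the strict exceedances
        assert (risk.high_risk == (risk.z > 1.28)).all().all()

    def test_identical_patients_raise(self):
        direct = pd.DataFrame({"d1": [1.0, 1.0, 1.0]}, index=idx(3))
        with pytest.raises(DegenerateScaleError):
            compute_risk_scores(direct, direct * 0.0)

    def test_misaligned_tables_raise(self, rng):
        direct = pd.DataFrame({"d1": rng.normal(size=3)}, index=idx(3))
        indirect = pd.DataFrame({"d2": rng.normal(size=3)}, index=idx(3))
        with pytest.raises(AlignmentError):
            compute_risk_scores(direct, indirect)


class TestCategorizeFitness:
    def _cohort(self, rng, n=400):
        cov = pd.DataFrame({"age": rng.uniform(40, 80, n),
                            "sex": rng.integers(0, 2, n)}, index=idx(n))
        fitness = pd.DataFrame({
            "VO2max": rng.normal(35, 7, n),
            "GripStrength": rng.normal(0.55, 0.1, n),
            "JumpMax": rng.normal(0.22, 0.05, n),
            "BMI": rng.normal(26, 4, n),
            "Cognition": rng.normal(6, 1.5, n),
        }, index=cov.index)
        return fitness, cov

    def test_value_at_stratum_mean_is_normal(self, rng):
        fitness, cov = self._cohort(rng)
        cats = categorize_fitness(fitness, cov)
        # the sample closest to its stratum mean must be "normal"
        group = cats["group_id"]
        mean = fitness["BMI"].groupby(group).transform("mean")
        closest = (fitness["BMI"] - mean).abs().idxmin()
        assert cats.loc[closest, "BMI"] == "normal"

    def test_every_sample_categorized_for_every_trait(self, rng):
        fitness, cov = self._cohort(rng)
        cats = categorize_fitness(fitness, cov)
        for trait in fitness.columns:
            assert cats[trait].isin(["low", "normal", "high"]).all()

    def test_cognition_percentile_boundaries_on_ten_values(self):
        """With values 1..10 the 10th/90th percentiles (linear interpolation)
        are 1.9 and 9.1: the boundary value is 'normal', strictly outside is
        'low'/'high'."""
        n = 10
        cov = pd.DataFrame({"age": np.full(n, 55.0), "sex": np.zeros(n, dtype=int)},
                           index=idx(n))
        fitness = pd.DataFrame({"Cognition": np.arange(1.0, 11.0)}, index=cov.index)
        cats = categorize_fitness(fitness, cov)
        values = fitness["Cognition"]
        assert (cats.loc[values < 1.9, "Cognition"] == "low").all()
        assert (cats.loc[values > 9.1, "Cognition"] == "high").all()
        assert (cats.loc[(values >= 1.9) & (values <= 9.1), "Cognition"] == "normal").all()
        # exactly at the boundary -> normal
        fitness.loc[fitness.index[0], "Cognition"] = np.percentile(np.arange(1.0, 11.0), 90)
        cats2 = categorize_fitness(fitness, cov)
        assert cats2.loc[fitness.index[0], "Cognition"] == "normal"

    def test_small_stratum_falls_back_to_cohort(self, rng, caplog):
        cov = pd.DataFrame({"age": [45.0, 45.0, 45.0, 85.0],
                            "sex": [0, 0, 0, 1]}, index=idx(4))
        fitness = pd.DataFrame({"BMI": [24.0, 26.0, 28.0, 40.0]}, index=cov.index)
        with caplog.at_level("WARNING"):
            cats = categorize_fitness(fitness, cov)
        assert "fall back" in caplog.text
        assert cats.loc["S3", "BMI"] == "high"  # cohort-wide band excludes 40

    def test_normal_band_covers_about_80_percent(self):
        rng = np.random.default_rng(0)
        n = 20000
        cov = pd.DataFrame({"age": np.full(n, 55.0), "sex": np.zeros(n, dtype=int)},
                           index=idx(n))
        fitness = pd.DataFrame({"BMI": rng.normal(26, 4, n)}, index=cov.index)
        cats = categorize_fitness(fitness, cov)
        assert (cats["BMI"] == "normal").mean() == pytest.approx(0.7994, abs=0.02)


class TestRankHighRisk:
    def _risk(self, z: pd.DataFrame) -> RiskTable:
        return RiskTable(raw=z, z=z, high_risk=z > 1.28)

    def test_five_patient_toy_matches_hand_ordering(self):
        z = pd.DataFrame({
            "d1": [2.0, 2.0, 0.0, 2.0, 0.0],
            "d2": [2.0, 0.0, 0.0, 2.0, 0.0],
            "d3": [2.0, 0.0, 0.0, 1.5, 0.0],
        }, index=idx(5))
        # flags: S0 -> 3, S3 -> 3, S1 -> 1, S2/S4 -> 0
        # tie S0 vs S3 broken by z-sum (6.0 vs 5.5); S2 vs S4 by sample_id
        report = rank_high_risk_patients(self._risk(z), k=5)
        assert list(report["sample_id"]) == ["S0", "S3", "S1", "S2", "S4"]
        assert list(report["n_flagged"]) == [3, 3, 1, 0, 0]
        assert report.loc[0, "flagged_diseases"] == "d1;d2;d3"

    def test_more_flags_outranks_regardless_of_magnitude(self):
        z = pd.DataFrame({
            "d1": [9.0, 1.5], "d2": [0.0, 1.5], "d3": [0.0, 1.5],
        }, index=idx(2))
        report = rank_high_risk_patients(self._risk(z), k=2)
        assert list(report["sample_id"]) == ["S1", "S0"]

    def test_all_zero_flags_rank_by_tiebreakers(self):
        z = pd.DataFrame({"d1": [0.5, 1.0, -0.5]}, index=idx(3))
        report = rank_high_risk_patients(self._risk(z), k=3)
        assert (report["n_flagged"] == 0).all()
        assert list(report["sample_id"]) == ["S1", "S0", "S2"]  # by z-sum

    def test_k_larger_than_cohort_warns_and_returns_all(self, caplog):
        z = pd.DataFrame({"d1": [0.5, 1.0]}, index=idx(2))
        with caplog.at_level("WARNING"):
            report = rank_high_risk_patients(self._risk(z), k=10)
        assert len(report) == 2
        assert "exceeds" in caplog.text
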
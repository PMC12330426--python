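"""Brain-age gaps and the covariate-adjusted association suite."""

import numpy as np
import pandas as pd
import pytest

import connage as ca
from connage.bag import GLMDesign, correct_bag_bias
from connage.errors import InvalidInputError
from connage.features import sfnc_features


def synth_population(n=150, seed=0, bag_sd=7.0, slope=0.0, noise_sd=11.13,
                     n_sites=3):
    """Direct phenotype + BAG simulation (no imaging): the GLM's own oracle.

    With slope -0.5, bag_sd 7 and noise_sd 11.13 the planted partial
    correlation between BAG and outcome given the covariates is -0.30.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(39.0, 80.0, n)
    sex = rng.choice(["F", "M"], n)
    site = rng.choice([f"site{i}" for i in range(1, n_sites + 1)], n)
    diagnosis = rng.integers(0, 2, n)
    bag = rng.normal(0.0, bag_sd, n)
    outcome = (slope * bag + 0.05 * (age - 60) + 0.3 * diagnosis
               + noise_sd * rng.standard_normal(n))
    phen = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "age": age, "sex": sex, "site": site, "diagnosis": diagnosis,
        "attention": outcome, "working_memory": outcome,
    })
    bag_table = pd.DataFrame({
        "subject_id": phen["subject_id"], "chronological_age": age,
        "predicted_age": age + bag, "bag": bag,
        "scope": "wide", "modality": "sfnc",
    })
    return bag_table, phen


class TestComputeBag:
    def test_simple_difference(self):
        pred = pd.DataFrame({"subject_id": ["a"], "predicted_age": [50.0]})
        phen = pd.DataFrame({"subject_id": ["a"], "age": [45.0]})
        out = ca.compute_bag(pred, phen)
        assert out["bag"].iloc[0] == pytest.approx(5.0)

    def test_perfect_predictions_give_zero_bags(self):
        phen = pd.DataFrame({"subject_id": list("abc"), "age": [30.0, 40, 50]})
        pred = phen.rename(columns={"age": "predicted_age"})
        out = ca.compute_bag(pred, phen)
        assert np.all(out["bag"] == 0.0)
        assert len(out) == 3

    def test_unmatched_subjects_listed(self):
        pred = pd.DataFrame({"subject_id": ["a", "zz"], "predicted_age": [1.0, 2.0]})
        phen = pd.DataFrame({"subject_id": ["a"], "age": [45.0]})
        with pytest.raises(InvalidInputError, match="zz"):
            ca.compute_bag(pred, phen)

    def test_bias_correction_removes_age_slope(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(30, 80, 200)
        table = pd.DataFrame({"chronological_age": age,
                              "bag": -0.3 * (age - 55) + rng.normal(0, 1, 200)})
        out = correct_bag_bias(table)
        assert abs(np.polyfit(age, out["bag"], 1)[0]) < 1e-10


class TestAssociationGLM:
    def test_exact_linear_case(self):
        bag_table, phen = synth_population(seed=1)
        phen = phen.assign(attention=2.0 * bag_table["bag"].to_numpy()
                           + 1e-8 * np.random.default_rng(1).standard_normal(len(phen)))
        res = ca.fit_association_glm(bag_table, phen, "attention")
        assert res.beta == pytest.approx(2.0, abs=1e-4)
        assert res.p < 1e-12
        assert res.partial_r > 0.999

    def test_result_internal_consistency(self):
        bag_table, phen = synth_population(seed=2, slope=-0.5)
        res = ca.fit_association_glm(bag_table, phen, "attention")
        # CI reconstructable from beta and se; partial r shares beta's sign
        from scipy import stats
        tcrit = stats.t.ppf(0.975, res.df)
        assert res.ci95[0] == pytest.approx(res.beta - tcrit * res.se)
        assert res.ci95[1] == pytest.approx(res.beta + tcrit * res.se)
        assert np.sign(res.partial_r) == np.sign(res.beta)
        assert res.partial_r == pytest.approx(
            res.t / np.sqrt(res.t**2 + res.df)
        )

    def test_age_filter_applied(self):
        bag_table, phen = synth_population(seed=3)
        phen.loc[:19, "age"] = 25.0
        bag_table.loc[:19, "chronological_age"] = 25.0
        res = ca.fit_association_glm(bag_table, phen, "attention",
                                     GLMDesign(age_filter_min=38.0))
        assert res.n == 130

    def test_rank_deficient_design_names_columns(self):
        bag_table, phen = synth_population(seed=4)
        phen["diagnosis"] = 0  # constant column -> collinear with intercept
        with pytest.raises(InvalidInputError, match="diagnosis"):
            ca.fit_association_glm(bag_table, phen, "attention")

    def test_type_i_error_calibrated(self):
        # outcome independent of BAG: rejection rate at alpha = .05 within
        # the binomial band [0.02, 0.09] over 200 replicates
        rejections = 0
        reps = 200
        for seed in range(reps):
            bag_table, phen = synth_population(seed=seed, slope=0.0)
            res = ca.fit_association_glm(bag_table, phen, "attention")
            rejections += res.p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_planted_partial_r_recovered(self):
        # planted partial r = -0.30 at n = 150: the mean recovered value
        # lies within +/-0.1 and the sign is negative in >= 95% of replicates
        rs = []
        for seed in range(100):
            bag_table, phen = synth_population(seed=1000 + seed, slope=-0.5)
            rs.append(ca.fit_association_glm(bag_table, phen, "attention").partial_r)
        rs = np.array(rs)
        assert abs(rs.mean() - (-0.30)) < 0.1
        assert np.mean(rs < 0) >= 0.95


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ca.fdr_correct([0.037]), [0.037])

    def test_hand_applied_step_up_rule(self):
        np.testing.assert_allclose(
            ca.fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(ca.fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 15))
            # oracle: sort, multiply by m/rank, running minimum from the top
            order = np.argsort(p)
            m = len(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(scaled[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(adj, 1.0)
            np.testing.assert_allclose(ca.fdr_correct(p), oracle, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.random(30)
        assert np.all(ca.fdr_correct(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ca.fdr_correct([0.5, 1.2])


class TestAssociationSuite:
    def _bag_tables(self, phen, scopes, modalities, seed=0):
        rng = np.random.default_rng(seed)
        tables = []
        for scope in scopes:
            for modality in modalities:
                bag = rng.normal(0, 5, len(phen))
                tables.append(pd.DataFrame({
                    "subject_id": phen["subject_id"],
                    "chronological_age": phen["age"],
                    "predicted_age": phen["age"] + bag, "bag": bag,
                    "scope": scope, "modality": modality,
                }))
        return tables

    def test_seven_networks_two_modalities_fourteen_tests(self, atlas53):
        _, phen = synth_population(n=200, seed=7)
        tables = self._bag_tables(phen, atlas53.networks, ("sfnc", "dfnc"))
        res = ca.run_association_suite(tables, phen)
        for outcome in ("attention", "working_memory"):
            assert (res["outcome"] == outcome).sum() == 14
        assert np.all(res["p_fdr"] >= res["p"] - 1e-15)

    def test_single_test_family_fdr_equals_raw(self):
        _, phen = synth_population(n=200, seed=8)
        tables = self._bag_tables(phen, ["SCN"], ["sfnc"])
        res = ca.run_association_suite(tables, phen, outcomes=("attention",))
        assert res["p_fdr"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_missing_outcome_column_rejected(self):
        _, phen = synth_population(n=150, seed=9)
        tables = self._bag_tables(phen, ["wide"], ["sfnc"])
        with pytest.raises(InvalidInputError, match="iq"):
            ca.run_association_suite(tables, phen, outcomes=("iq",))

    def test_planted_network_survives_fdr_nulls_mostly_do_not(self):
        # signal planted in the subcortical BAG only: over seeded replicates
        # SCN survives FDR while null networks rarely produce false positives
        networks = ("SCN", "AUD", "SMN", "VSN", "CCN", "DMN", "CBN")
        scn_hits, null_false = 0, 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            n = 160
            _, phen = synth_population(n=n, seed=300 + seed)
            scn_bag = rng.normal(0, 7, n)
            phen["attention"] = -0.5 * scn_bag + 11.13 * rng.standard_normal(n)
            phen["working_memory"] = phen["attention"]
            tables = []
            for net in networks:
                for modality in ("sfnc", "dfnc"):
                    bag = scn_bag if net == "SCN" else rng.normal(0, 7, n)
                    tables.append(pd.DataFrame({
                        "subject_id": phen["subject_id"],
                        "chronological_age": phen["age"],
                        "predicted_age": phen["age"] + bag, "bag": bag,
                        "scope": net, "modality": modality,
                    }))
            res = ca.run_association_suite(tables, phen, outcomes=("attention",))
            scn = res[res["scope"] == "SCN"]
            scn_hits += bool(scn["significant"].all())
            null_false += bool(res[res["scope"] != "SCN"]["significant"].any())
        assert scn_hits >= 0.9 * reps
        assert null_false <= 0.25 * reps


@pytest.fixture(scope="module")
def recovered():
    """Full chain: simulate -> prep -> connectivity -> train -> BAG -> GLM."""
    runs = []
    for seed in range(3):
        cfg = ca.CohortConfig(
            n_subjects=400, n_components=20, n_frames=450,
            aging_edge_fraction=0.2, aging_slope=0.006,
            accel_sd=7.0, cognition_noise_sd=11.1,
            diagnosis_fraction=0.35, psd_repair_tol=1.5, seed=seed,
        )
        cohort = ca.generate_cohort(cfg)
        prepped = [ca.prepare_timecourses(t) for t in cohort.timecourses]
        fncs = [ca.static_fnc(t) for t in prepped]
        seqs_raw = [ca.dynamic_fnc(t, ca.WindowSpec(stride_tr=4))
                    for t in prepped]
        from connage.features import dfnc_sequences
        seqs = dfnc_sequences(seqs_raw)
        ages = cohort.phenotypes["age"].to_numpy()
        controls = cohort.phenotypes["diagnosis"].to_numpy() == 0
        bags = []
        for modality, X in (
            ("sfnc", sfnc_features(fncs)),
            ("dfnc", np.concatenate([seqs.mean(axis=1), seqs.std(axis=1)],
                                    axis=1)),
        ):
            est = ca.RidgeBrainAge(alpha=1000.0).fit(X[controls],
                                                     ages[controls])
            pred = pd.DataFrame({
                "subject_id": cohort.phenotypes["subject_id"],
                "predicted_age": est.predict(X),
            })
            bags.append(ca.compute_bag(pred, cohort.phenotypes, "wide",
                                       modality))
        res = ca.run_association_suite(bags, cohort.phenotypes)
        runs.append((cohort, bags, res))
    return runs


class TestEndToEndRecovery:
    def test_wide_brain_associations_negative_and_fdr_significant(self, recovered):
        for _, _, res in recovered:
            assert np.all(res["partial_r"] < 0)
            assert res["significant"].all()

    def test_diagnosis_shift_recovered_in_bags(self):
        # a lightly regularized model preserves the +7 y planted shift scale
        shifts = []
        for seed in range(5):
            cfg = ca.CohortConfig(
                n_subjects=400, n_components=20, n_frames=450,
                aging_edge_fraction=0.2, aging_slope=0.006,
                accel_sd=7.0, cognition_noise_sd=11.1,
                diagnosis_fraction=0.35, psd_repair_tol=1.5, seed=seed,
            )
            cohort = ca.generate_cohort(cfg)
            fncs = [ca.static_fnc(ca.prepare_timecourses(t))
                    for t in cohort.timecourses]
            X = sfnc_features(fncs)
            ages = cohort.phenotypes["age"].to_numpy()
            controls = cohort.phenotypes["diagnosis"].to_numpy() == 0
            est = ca.RidgeBrainAge(alpha=100.0).fit(X[controls], ages[controls])
            bag = est.predict(X) - ages
            diag = cohort.phenotypes["diagnosis"].to_numpy() == 1
            shifts.append(bag[diag].mean() - bag[~diag].mean())
        assert np.mean(shifts) == pytest.approx(7.0, abs=1.5)

    def test_null_cohort_produces_no_findings(self):
        # zero cognition coupling: FDR-significant families must be rare
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            _, phen = synth_population(n=160, seed=500 + seed, slope=0.0)
            tables = []
            for modality in ("sfnc", "dfnc"):
                bag = rng.normal(0, 7, len(phen))
                tables.append(pd.DataFrame({
                    "subject_id": phen["subject_id"],
                    "chronological_age": phen["age"],
                    "predicted_age": phen["age"] + bag, "bag": bag,
                    "scope": "wide", "modality": modality,
                }))
            res = ca.run_association_suite(tables, phen,
                                           outcomes=("attention",))
            hits += bool(res["significant"].any())
        assert hits / reps <= 0.15
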
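import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumordiv import outcomes, synthetic


class TestRescale595:
    def test_endpoints_map_to_zero_and_one(self):
        v = np.arange(101, dtype=float)  # p5 = 5, p95 = 95
        out = outcomes.rescale_5_95(v)
        assert out[5] == pytest.approx(0.0, abs=1e-12)
        assert out[95] == pytest.approx(1.0, abs=1e-12)
        assert out[50] == pytest.approx(0.5, abs=1e-12)  # midpoint of p5, p95
        assert out[0] < 0 and out[100] > 1  # values outside the band map outside [0, 1]

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            outcomes.rescale_5_95(np.ones(50))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=20, max_size=60, unique=True))
    def test_affine_preserves_order_and_difference_ratios(self, vals):
        v = np.array(vals)
        out = outcomes.rescale_5_95(v)
        order = np.argsort(v)
        assert (np.diff(out[order]) >= 0).all()  # order preserved
        d_in = v[1] - v[0]
        d_in2 = v[2] - v[0]
        if abs(d_in2) > 1e-6 and abs(d_in) > 1e-6:
            assert (out[1] - out[0]) / (out[2] - out[0]) == pytest.approx(
                d_in / d_in2, rel=1e-5
            )


class TestPrepareCovariates:
    @pytest.fixture
    def metrics(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "lossness": rng.uniform(0.01, 0.6, 90),
            "spearman": rng.uniform(0, 1.5, 90),
            "isup": rng.choice([1, 2, 3, 4, 5], 90),
        })

    def test_lossness_log_transformed(self, metrics):
        spec = outcomes.CovariateSpec("lossness", transform="log")
        mm = outcomes.prepare_covariates(metrics, [spec], rescale=False)
        np.testing.assert_allclose(mm["lossness"], np.log(metrics["lossness"]))

    def test_spearman_upper_tertile_split(self, metrics):
        spec = outcomes.CovariateSpec("spearman", kind="binary", split="upper-tertile")
        mm = outcomes.prepare_covariates(metrics, [spec])
        frac_high = mm["spearman"].mean()
        assert frac_high == pytest.approx(1 / 3, abs=0.05)
        cut = np.quantile(metrics["spearman"], 2 / 3)
        assert ((metrics["spearman"] >= cut) == (mm["spearman"] == 1)).all()

    def test_median_split_ties_to_lower_group(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 2.0, 3.0, 4.0]})
        spec = outcomes.CovariateSpec("x", kind="binary", split="median")
        mm = outcomes.prepare_covariates(df, [spec])
        assert mm["x"].tolist() == [0, 0, 0, 1, 1]

    def test_isup_reference_level_omitted(self, metrics):
        spec = outcomes.CovariateSpec("isup", kind="categorical", reference="5")
        mm = outcomes.prepare_covariates(metrics, [spec])
        assert "isup_5" not in mm.columns
        assert {"isup_1", "isup_2", "isup_3", "isup_4"} <= set(mm.columns)


class TestUnivariateScreen:
    def test_null_metric_admitted_near_ten_percent(self):
        """P<0.1 screen admits a null continuous metric at ~10% over replicates."""
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 120
        for i in range(n_rep):
            df = pd.DataFrame({"m": rng.normal(1, 0.3, 80)})
            surv = synthetic.simulate_survival_cohort(df, beta={"m": 0.0},
                                                      censor_rate=0.2, seed=1000 + i)
            out = outcomes.univariate_screen(surv, ["m"], transforms={"m": "identity"})
            row = out[(out["metric"] == "m") & (out["form"] == "continuous")]
            hits += bool(row["qualifies"].iloc[0])
        rate = hits / n_rep
        assert 0.03 <= rate <= 0.20  # ~0.10 within binomial noise

    def test_continuous_preferred_when_both_qualify(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"m": rng.normal(1, 0.4, 300)})
        surv = synthetic.simulate_survival_cohort(df, beta={"m": 1.5},
                                                  censor_rate=0.0, seed=5)
        out = outcomes.univariate_screen(surv, ["m"], transforms={"m": "identity"})
        assert out["qualifies"].all()
        sel = out[out["selected"]]
        assert len(sel) == 1
        assert sel.iloc[0]["form"] == "continuous"

    def test_no_qualifier_leaves_empty_selection(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"m": rng.normal(0, 1, 60),
                           "time": rng.exponential(5, 60),
                           "event": np.ones(60, dtype=int)})
        # decouple covariate from survival entirely; may rarely qualify by chance
        out = outcomes.univariate_screen(df, ["m"], transforms={"m": "identity"})
        sel = out[out["selected"]]
        assert set(sel["form"]) <= {"continuous", "binary"}


class TestMultivariateCox:
    def test_binary_log_hr_recovery(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.binomial(1, 0.5, 500).astype(float)})
        surv = synthetic.simulate_survival_cohort(df, beta={"x": 1.0},
                                                  censor_rate=0.0, seed=6)
        res = outcomes.multivariate_cph(surv[["x", "time", "event"]])
        coef = res.set_index("covariate").loc["x", "coef"]
        assert coef == pytest.approx(1.0, abs=0.2)

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(5)
        covered = 0
        n_rep = 60
        for i in range(n_rep):
            df = pd.DataFrame({"x": rng.normal(0, 1, 120)})
            surv = synthetic.simulate_survival_cohort(df, beta={"x": 0.0},
                                                      censor_rate=0.0, seed=2000 + i)
            res = outcomes.multivariate_cph(surv[["x", "time", "event"]])
            row = res.set_index("covariate").loc["x"]
            covered += bool(row["hr_lo"] <= 1.0 <= row["hr_hi"])
        assert covered / n_rep >= 0.85  # ~95% nominal

    def test_duplicated_covariate_surfaces_error(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(0, 1, 100)})
        surv = synthetic.simulate_survival_cohort(df, beta={"x": 0.5},
                                                  censor_rate=0.0, seed=7)
        surv["x_copy"] = surv["x"]
        with pytest.raises(Exception, match="(?i)singular|collinear|converg|variance"):
            outcomes.multivariate_cph(surv[["x", "x_copy", "time", "event"]])


class TestKMLogrank:
    def test_identical_groups_null_statistic(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 100)
        df = pd.DataFrame({"time": np.r_[t, t], "event": 1,
                           "grp": np.r_[np.zeros(100), np.ones(100)]})
        out = outcomes.km_logrank(df, "grp")
        assert out["chi2"] == pytest.approx(0.0, abs=1e-8)
        assert out["df"] == 1

    def test_power_at_hr2(self):
        rng = np.random.default_rng(8)
        sig = 0
        n_rep = 40
        for i in range(n_rep):
            grp = rng.binomial(1, 0.5, 300).astype(float)
            df = pd.DataFrame({"grp": grp})
            surv = synthetic.simulate_survival_cohort(df, beta={"grp": np.log(2)},
                                                      censor_rate=0.2, seed=3000 + i)
            out = outcomes.km_logrank(surv, "grp")
            sig += out["p"] < 0.05
        assert sig / n_rep >= 0.8

    def test_all_censored_group_median_not_reached(self):
        df = pd.DataFrame({
            "time": [5, 6, 7, 8, 1, 2, 3],
            "event": [0, 0, 0, 0, 1, 1, 1],
            "grp": [0, 0, 0, 0, 1, 1, 1],
        })
        out = outcomes.km_logrank(df, "grp")
        assert np.isinf(out["median_survival"][0])


class TestMixedAssociation:
    def test_gradient_recovery(self):
        rng = np.random.default_rng(9)
        n_part, per = 100, 5
        part = np.repeat(np.arange(n_part), per)
        u = rng.normal(0, 0.05, n_part)[part]
        x = rng.binomial(1, 0.5, n_part * per).astype(float)
        y = 0.07 * x + u + rng.normal(0, 0.05, n_part * per)
        df = pd.DataFrame({"y": y, "x": x, "participant": part})
        res = outcomes.mixed_association(df, "y", "x")
        assert res["estimate"] == pytest.approx(0.07, abs=0.03)
        assert res["p"] < 0.05

    def test_constant_predictor_refused(self):
        df = pd.DataFrame({"y": np.random.default_rng(0).normal(size=30),
                           "x": np.ones(30), "participant": np.arange(30) % 5})
        with pytest.raises(ValueError, match="singular"):
            outcomes.mixed_association(df, "y", "x")


class TestArmAssociationScan:
    def _table(self, n_loss, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(60):
            status = "loss" if i < n_loss else "neutral"
            rows.append(dict(participant=i // 3, arm="1p", status=status,
                             cg=3.5 + (0.3 if status == "loss" else 0.0)
                             + rng.normal(0, 0.1)))
        return pd.DataFrame(rows)

    def test_too_few_observations_suppresses_model(self):
        out = outcomes.arm_association_scan(self._table(9), dependent="cg")
        assert len(out) == 0

    def test_sufficient_observations_emit_model_with_bh(self):
        out = outcomes.arm_association_scan(self._table(25), dependent="cg")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["direction"] == "loss"
        assert row["estimate"] == pytest.approx(0.3, abs=0.1)
        assert row["q"] >= row["p"] - 1e-12


class TestBHWithinDependent:
    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(10)
        rows = []
        for arm in range(6):
            for i in range(40):
                status = "gain" if i < 20 else "neutral"
                rows.append(dict(participant=i % 10, arm=f"a{arm}", status=status,
                                 dep=rng.normal(0, 1)))
        df = pd.DataFrame(rows)
        out = outcomes.arm_association_scan(df, dependent="dep")
        out = out.sort_values("p")
        assert (np.diff(out["q"]) >= -1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()
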
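import numpy as np
import pandas as pd
import pytest

from oracles import closed_form_sem, random_recursive_model, simulate_recursive
from rhizonet import sem

FIG5_SPEC = """
# richness path model (reconstruction)
RW ~ NN + AN
BC ~ NN + Na + RW
FC ~ Na + RW
"""


class TestParse:
    def test_direct_construction(self):
        model = sem.parse_model("BD ~ RW + NN")
        assert model.paths == [("RW", "BD"), ("NN", "BD")]
        assert model.endogenous == ["BD"]
        assert sorted(model.exogenous) == ["NN", "RW"]

    def test_arrow_syntax_and_comments(self):
        model = sem.parse_model("# comment\nY <- X1 + X2  # trailing\n")
        assert model.paths == [("X1", "Y"), ("X2", "Y")]

    def test_cycle_listed(self):
        with pytest.raises(ValueError, match="cycle"):
            sem.parse_model("X ~ Y\nY ~ X")

    def test_empty_spec_saturated_exogenous(self):
        model = sem.parse_model("", variables=["A", "B", "C"])
        assert model.paths == []
        assert model.df == 0
        assert model.n_free_params == 6

    def test_df_arithmetic_on_parsed_models(self, rng):
        for _ in range(20):
            variables, paths, _ = random_recursive_model(rng)
            text = "\n".join(
                f"{e} ~ " + " + ".join(c for c, ee in paths if ee == e)
                for e in {e for _, e in paths}
            )
            model = sem.parse_model(text, variables=variables)
            p = model.p
            assert model.df == p * (p + 1) // 2 - model.n_free_params

    def test_unknown_data_variable_named(self):
        model = sem.parse_model("Y ~ X")
        data = pd.DataFrame({"Y": [1.0, 2, 3, 4, 5], "Z": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="X"):
            sem.fit_from_data(model, data)


class TestImpliedCovariance:
    def test_no_paths_identity(self):
        model = sem.parse_model("", variables=["A", "B"])
        # theta: var(A), var(B), cov(A,B)
        sigma = sem.implied_covariance(model, [2.0, 3.0, 0.5])
        np.testing.assert_allclose(sigma, [[2.0, 0.5], [0.5, 3.0]])

    def test_single_path_hand_algebra(self):
        model = sem.parse_model("Y ~ X")
        b, psi = 0.7, 0.4
        sigma = sem.implied_covariance(model, [b, 1.0, psi])
        idx = {v: i for i, v in enumerate(model.variables)}
        assert sigma[idx["Y"], idx["Y"]] == pytest.approx(b**2 + psi)
        assert sigma[idx["X"], idx["Y"]] == pytest.approx(b)

    def test_symmetric_positive_definite_for_admissible_theta(self, rng):
        model = sem.parse_model(FIG5_SPEC)
        for _ in range(10):
            theta = np.concatenate(
                [
                    rng.uniform(-0.8, 0.8, size=7),  # paths
                    rng.uniform(0.5, 2.0, size=3),  # exo variances
                    rng.uniform(-0.2, 0.2, size=3),  # exo covariances
                    rng.uniform(0.3, 1.5, size=3),  # disturbances
                ]
            )
            sigma = sem.implied_covariance(model, theta)
            np.testing.assert_allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > 0


class TestFit:
    def test_saturated_model_perfect_fit(self, rng):
        model = sem.parse_model("", variables=["A", "B", "C"])
        data = pd.DataFrame(rng.normal(size=(50, 3)), columns=["A", "B", "C"])
        fit = sem.fit_from_data(model, data)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        assert fit.rmsea == 0.0 and fit.cfi == 1.0

    def test_noiseless_data_recovered_exactly(self):
        x = np.linspace(-2, 2, 20)
        data = pd.DataFrame({"X": x, "Y": 0.5 * x})
        fit = sem.fit_from_data(sem.parse_model("Y ~ X"), data)
        assert fit.estimates["X->Y"] == pytest.approx(0.5, abs=1e-6)
        assert fit.converged
        assert fit.chi2 == pytest.approx(0.0)

    def test_general_singular_s_rejected(self):
        # singular S the model cannot reproduce: Y depends exactly on Z
        # too, but the model routes Y only through X (and cov(X, Z) = 0)
        x = np.linspace(-2, 2, 21)
        z = x**2
        data = pd.DataFrame({"X": x, "Y": 0.5 * x + z, "Z": z})
        model = sem.parse_model("Y ~ X", variables=["Z"])
        with pytest.raises(ValueError, match="positive-definite"):
            sem.fit_from_data(model, data)

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(42)
        truth = {
            ("NN", "RW"): -0.40, ("AN", "RW"): 0.25,
            ("NN", "BC"): -0.30, ("Na", "BC"): -0.35, ("RW", "BC"): 0.40,
            ("Na", "FC"): -0.30, ("RW", "FC"): 0.35,
        }
        data = pd.DataFrame(
            simulate_recursive(["NN", "AN", "Na", "RW", "BC", "FC"], truth, 5000, rng)
        )
        fit = sem.fit_from_data(sem.parse_model(FIG5_SPEC), data)
        for (c, e), b in truth.items():
            assert fit.estimates[f"{c}->{e}"] == pytest.approx(b, abs=0.05)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            variables, paths, coefs = random_recursive_model(rng)
            data = pd.DataFrame(simulate_recursive(variables, coefs, 300, rng))
            endo = {e for _, e in paths}
            text = "\n".join(
                f"{e} ~ " + " + ".join(c for c, ee in paths if ee == e)
                for e in endo
            )
            model = sem.parse_model(text, variables=variables)
            S = data[model.variables].cov()
            fit = sem.fit_ml(model, S, N=300)
            ref = closed_form_sem(
                model.variables, model.paths, S.to_numpy(), 300
            )
            assert fit.df == ref["df"]
            assert fit.chi2 == pytest.approx(ref["chi2"], abs=1e-4)
            assert fit.cfi == pytest.approx(ref["cfi"], abs=1e-4)
            assert fit.rmsea == pytest.approx(ref["rmsea"], abs=1e-4)
            for (c, e), b in ref["estimates"].items():
                assert fit.estimates[f"{c}->{e}"] == pytest.approx(b, abs=1e-4)

    def test_needs_more_samples_than_variables(self):
        model = sem.parse_model("Y ~ X")
        with pytest.raises(ValueError, match="N > p"):
            sem.fit_ml(model, np.eye(2), N=2)


class TestIndicesAndStandardization:
    def test_gfi_one_when_model_reproduces_s(self, rng):
        model = sem.parse_model("", variables=["A", "B"])
        data = pd.DataFrame(rng.normal(size=(40, 2)), columns=["A", "B"])
        fit = sem.fit_from_data(model, data)
        assert fit.gfi == pytest.approx(1.0, abs=1e-8)

    def test_indices_hand_computed_three_variable_example(self):
        # X -> Y, Z independent; covariance chosen by hand
        model = sem.parse_model("Y ~ X", variables=["Z"])
        S = pd.DataFrame(
            [[1.0, 0.5, 0.1], [0.5, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=["X", "Y", "Z"], columns=["X", "Y", "Z"],
        )
        N = 101
        fit = sem.fit_ml(model, S, N=N)
        ref = closed_form_sem(model.variables, model.paths, S.to_numpy(), N)
        assert fit.chi2 == pytest.approx(ref["chi2"], abs=1e-8)
        assert fit.cfi == pytest.approx(ref["cfi"], abs=1e-8)
        assert fit.rmsea == pytest.approx(ref["rmsea"], abs=1e-8)
        # GFI from its definition, recomputed here longhand
        sigma = fit.implied.to_numpy()
        W = np.linalg.inv(sigma) @ S.to_numpy()
        gfi = 1 - np.trace((W - np.eye(3)) @ (W - np.eye(3))) / np.trace(W @ W)
        assert fit.gfi == pytest.approx(gfi, abs=1e-8)

    def test_standardized_coefficient_hand_algebra(self):
        model = sem.parse_model("Y ~ X")
        b, psi, var_x = 0.6, 0.5, 4.0
        theta = np.array([b, var_x, psi])
        std = sem.standardize(model, theta)
        expected = 2 * b / np.sqrt(4 * b**2 + psi)
        assert std["X->Y"] == pytest.approx(expected)

    def test_unit_variance_standardized_equals_unstandardized(self):
        model = sem.parse_model("Y ~ X")
        b = 0.6
        theta = np.array([b, 1.0, 1.0 - b**2])  # implied var(Y) = 1
        std = sem.standardize(model, theta)
        assert std["X->Y"] == pytest.approx(b)

    def test_single_parent_standardized_bounded(self, rng):
        model = sem.parse_model("Y ~ X")
        for _ in range(20):
            theta = np.array(
                [rng.uniform(-3, 3), rng.uniform(0.2, 4), rng.uniform(0.01, 4)]
            )
            std = sem.standardize(model, theta)
            assert abs(std["X->Y"]) <= 1.0

    def test_forced_indices_when_chi2_below_df(self, rng):
        truth = {("X", "Y"): 0.5}
        data = pd.DataFrame(simulate_recursive(["X", "Z", "Y"], truth, 400, rng))
        model = sem.parse_model("Y ~ X", variables=["Z"])
        fit = sem.fit_from_data(model, data)
        if fit.chi2 <= fit.df:
            assert fit.rmsea == 0.0 and fit.cfi == 1.0
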
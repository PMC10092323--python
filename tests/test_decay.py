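import numpy as np
import pandas as pd
import pytest

from decayscreen.decay import (
    DecayModel,
    FitError,
    FitOptions,
    fit_all,
    fit_decay,
    fit_log_linear,
    holdout_validate,
    residuals,
    residuals_all,
    summarize_residuals,
)


def make_og(t, scores, states=None, p_miss=None):
    """Build (og_scores, traits) frames for one orthogroup."""
    n = len(t)
    species = [f"s{i:02d}" for i in range(n)]
    og = pd.DataFrame(
        {"og_id": "OG1", "species_id": pd.array(species, dtype="string"), "bitscore": scores}
    )
    traits = pd.DataFrame(
        {
            "species_id": pd.array(species, dtype="string"),
            "bristle_state": pd.array(states or ["present"] * n, dtype="string"),
            "p_miss": p_miss if p_miss is not None else [0.0] * n,
            "dist_to_focal": t,
        }
    )
    return og, traits


class TestLogLinear:
    def test_exact_on_noiseless_log_line(self):
        t = np.linspace(0.1, 0.6, 8)
        s = 500.0 * np.exp(-2.0 * t)
        L0, R0 = fit_log_linear(t, s)
        assert L0 == pytest.approx(500.0, abs=1e-9)
        assert R0 == pytest.approx(2.0, abs=1e-9)

    def test_single_distance_is_degenerate(self):
        with pytest.raises(FitError):
            fit_log_linear([0.3, 0.3, 0.3], [100, 110, 90])

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(FitError):
            fit_log_linear([0.1, 0.2], [100.0, 0.0])

    def test_matches_weighted_normal_equations(self, rng):
        t = rng.uniform(0.05, 0.7, 15)
        s = 300 * np.exp(-1.5 * t) * np.exp(0.1 * rng.standard_normal(15))
        w = rng.uniform(0.3, 1.0, 15)
        L0, R0 = fit_log_linear(t, s, w)
        # closed-form WLS oracle on (1, t) design
        x = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(x.T @ np.diag(w) @ x, x.T @ np.diag(w) @ np.log(s))
        assert L0 == pytest.approx(np.exp(beta[0]), rel=1e-10)
        assert R0 == pytest.approx(-beta[1], rel=1e-10)


class TestFitDecay:
    def test_exact_recovery_on_noiseless_data(self):
        t = np.linspace(0.05, 0.65, 10)
        og, traits = make_og(t, 800.0 * np.exp(-1.2 * t))
        fit = fit_decay(og, traits, og_id="OG1")
        assert fit.converged and not fit.spurious
        assert fit.model.L == pytest.approx(800.0, rel=1e-6)
        assert fit.model.R == pytest.approx(1.2, rel=1e-6)

    def test_fewer_than_min_species_skipped(self):
        t = np.array([0.1, 0.2, 0.3, 0.4])
        og, traits = make_og(t, 500 * np.exp(-t))
        fit = fit_decay(og, traits, FitOptions(min_species=5))
        assert not fit.converged
        assert "too-few-species" in fit.skip_reason

    def test_non_reference_species_excluded_from_fit(self):
        t = np.linspace(0.05, 0.65, 12)
        s = 800.0 * np.exp(-1.2 * t)
        states = ["present"] * 8 + ["absent"] * 4
        s[8:] = 5.0  # wildly off-model scores in the non-reference state
        og, traits = make_og(t, s, states=states)
        fit = fit_decay(og, traits)
        assert fit.n_used == 8
        assert fit.model.L == pytest.approx(800.0, rel=1e-6)

    def test_sse_beats_grid_oracle(self, rng):
        """Fitted SSE never exceeds the best point of a 400x400 (L, R) grid."""
        L_true, R_true = 600.0, 1.8
        t = rng.uniform(0.05, 0.7, 20)
        model = DecayModel(L_true, R_true)
        s = model.predict(t) + model.sigma(t) * rng.standard_normal(20)
        s = np.clip(s, 1.0, None)
        og, traits = make_og(t, s)
        fit = fit_decay(og, traits)
        sse_fit = np.sum((s - fit.model.predict(t)) ** 2)
        Ls = np.linspace(0.5 * L_true, 1.5 * L_true, 400)
        Rs = np.linspace(0.5 * R_true, 1.5 * R_true, 400)
        pred = Ls[:, None, None] * np.exp(-Rs[None, :, None] * t[None, None, :])
        sse_grid = ((s - pred) ** 2).sum(axis=2).min()
        assert sse_fit <= sse_grid + 1e-9

    def test_inverted_decay_flagged_spurious(self, rng):
        flagged = 0
        for i in range(40):
            r = np.random.default_rng(i)
            t = r.uniform(0.05, 0.7, 12)
            s = 200.0 * np.exp(+0.8 * t) * np.exp(0.05 * r.standard_normal(12))
            og, traits = make_og(t, s)
            fit = fit_decay(og, traits)
            flagged += fit.spurious
        assert flagged >= 38  # >= 95%

    def test_constant_weights_match_unweighted_fit(self, rng):
        t = rng.uniform(0.05, 0.7, 15)
        model = DecayModel(400.0, 2.2)
        s = np.clip(model.predict(t) + model.sigma(t) * rng.standard_normal(15), 1, None)
        og, traits = make_og(t, s, p_miss=[0.4] * 15)
        fw = fit_decay(og, traits, FitOptions(weighted=True))
        fu = fit_decay(og, traits, FitOptions(weighted=False))
        assert fw.model.L == pytest.approx(fu.model.L, rel=1e-6)
        assert fw.model.R == pytest.approx(fu.model.R, rel=1e-6)

    def test_near_zero_distances_unidentifiable(self):
        t = np.full(8, 0.01) + np.arange(8) * 1e-4
        og, traits = make_og(t, 500 * np.exp(-t))
        fit = fit_decay(og, traits)
        assert not fit.converged
        assert "unidentifiable" in fit.skip_reason

    def test_parameter_recovery_under_noise_model(self):
        """Median relative errors over 200 noisy OGs: R < 10%, L < 5%."""
        rng = np.random.default_rng(77)
        rel_L, rel_R = [], []
        t = rng.uniform(0.05, 0.7, 30)
        for _ in range(200):
            L = float(np.exp(rng.uniform(np.log(100), np.log(2000))))
            R = float(np.exp(rng.uniform(np.log(0.3), np.log(5.0))))
            model = DecayModel(L, R)
            s = np.clip(model.predict(t) + model.sigma(t) * rng.standard_normal(30), 0.5, None)
            og, traits = make_og(t, s)
            fit = fit_decay(og, traits)
            if fit.converged and not fit.spurious:
                rel_L.append(abs(fit.model.L - L) / L)
                rel_R.append(abs(fit.model.R - R) / R)
        assert len(rel_L) > 180
        assert np.median(rel_L) < 0.05
        assert np.median(rel_R) < 0.10


class TestResiduals:
    def _fit(self):
        t = np.linspace(0.05, 0.65, 10)
        og, traits = make_og(t, 800.0 * np.exp(-1.2 * t))
        return fit_decay(og, traits, og_id="OG1"), traits

    def test_zero_residual_when_observed_equals_predicted(self):
        fit, _ = self._fit()
        held = pd.DataFrame(
            {
                "species_id": ["x"],
                "dist_to_focal": [0.4],
                "bitscore": [fit.model.predict(0.4)],
            }
        )
        rows = residuals(fit, held)
        assert rows["residual"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_species_beyond_tmax_excluded(self):
        fit, _ = self._fit()
        held = pd.DataFrame(
            {"species_id": ["x", "y"], "dist_to_focal": [0.75, 0.4], "bitscore": [10.0, 20.0]}
        )
        rows = residuals(fit, held)
        assert list(rows["species_id"]) == ["y"]

    def test_negative_means_less_similar_than_expected(self):
        fit, _ = self._fit()
        pred = fit.model.predict(0.3)
        held = pd.DataFrame(
            {"species_id": ["lo", "hi"], "dist_to_focal": [0.3, 0.3], "bitscore": [pred - 50, pred + 50]}
        )
        rows = residuals(fit, held).set_index("species_id")
        assert rows.loc["lo", "residual"] < 0 < rows.loc["hi", "residual"]

    def test_spurious_fit_rejected(self):
        fit, _ = self._fit()
        fit.spurious = True
        with pytest.raises(FitError):
            residuals(fit, pd.DataFrame({"species_id": [], "dist_to_focal": [], "bitscore": []}))

    def test_absent_state_residuals_negative_under_simulated_effect(
        self, small_tree, small_traits, small_config, small_scores
    ):
        scores, ann, _ = small_scores
        fits = fit_all(scores, small_traits, FitOptions())
        resid = residuals_all(fits, scores, small_traits)
        summ = summarize_residuals(resid, small_traits).merge(ann, on="og_id")
        testis = summ[summ["category"] == "testis"]
        med = testis.groupby("bristle_state", observed=True)["median_residual"].mean()
        if "absent" in med.index:
            assert med["absent"] < med["present"]


class TestSummaries:
    def test_odd_count_median(self):
        rows = pd.DataFrame(
            {"og_id": ["OG1"] * 3, "species_id": ["a", "b", "c"], "t": [0.1] * 3,
             "residual": [-3.0, 0.0, 5.0]}
        )
        traits = pd.DataFrame(
            {"species_id": pd.array(["a", "b", "c"], dtype="string"),
             "bristle_state": pd.array(["present"] * 3, dtype="string")}
        )
        out = summarize_residuals(rows, traits)
        assert out["median_residual"].iloc[0] == 0.0

    def test_unrepresented_state_missing_not_zero(self):
        rows = pd.DataFrame(
            {"og_id": ["OG1"] * 2, "species_id": ["a", "b"], "t": [0.1] * 2,
             "residual": [1.0, 2.0]}
        )
        traits = pd.DataFrame(
            {"species_id": pd.array(["a", "b"], dtype="string"),
             "bristle_state": pd.array(["present", "present"], dtype="string")}
        )
        out = summarize_residuals(rows, traits)
        assert set(out["bristle_state"]) == {"present"}

    def test_medians_match_sort_oracle(self, rng):
        n = 60
        species = [f"s{i}" for i in range(n)]
        states = rng.choice(["present", "reduced", "absent"], n)
        resid = rng.standard_normal(n) * 10
        rows = pd.DataFrame(
            {"og_id": ["OG1"] * n, "species_id": species, "t": [0.3] * n, "residual": resid}
        )
        traits = pd.DataFrame(
            {"species_id": pd.array(species, dtype="string"),
             "bristle_state": pd.array(states, dtype="string")}
        )
        out = summarize_residuals(rows, traits).set_index("bristle_state")
        for st in np.unique(states):
            vals = np.sort(resid[states == st])
            k = len(vals)
            oracle = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
            assert out.loc[st, "median_residual"] == pytest.approx(oracle)


class TestHoldout:
    def _data(self, seed=0, n=24):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0.05, 0.68, n)
        model = DecayModel(500.0, 1.5)
        s = np.clip(model.predict(t) + model.sigma(t) * rng.standard_normal(n), 1, None)
        return make_og(t, s)

    def test_zero_fraction_reduces_to_plain_fit(self):
        og, traits = self._data()
        out = holdout_validate(og, traits, holdout_fraction=0.0, seed=1)
        assert len(out) == 0

    def test_same_seed_same_split(self):
        og, traits = self._data()
        a = holdout_validate(og, traits, holdout_fraction=0.25, seed=3)
        b = holdout_validate(og, traits, holdout_fraction=0.25, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_heldout_residuals_unbiased_without_trait_effect(self):
        meds = []
        for seed in range(40):
            og, traits = self._data(seed=seed)
            out = holdout_validate(og, traits, holdout_fraction=0.25, seed=seed)
            if len(out):
                meds.append(out["residual"].median())
        grand = np.median(meds)
        boot = np.random.default_rng(1).choice(meds, size=(500, len(meds)))
        se = np.median(boot, axis=1).std()
        assert abs(grand) < 2 * se + 1e-9

    def test_infeasible_holdout_rejected(self):
        og, traits = self._data(n=6)
        with pytest.raises(FitError):
            holdout_validate(og, traits, holdout_fraction=0.9, seed=0)
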
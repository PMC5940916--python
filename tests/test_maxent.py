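"""The presence-background maximum-entropy estimator: feature expansion,
convex fitting, clamped projection and replicate runs."""

import numpy as np
import pandas as pd
import pytest

from grainsdm.landscape import sample_presences
from grainsdm.maxent import (MaxEnt, extract_point_values, load_model,
                             mean_map, predict_map, run_replicates,
                             save_model)
from grainsdm.occurrences import clean_and_rarefy, sample_background
from grainsdm.variables import build_variable_sets


def binary_fit(p_mean=0.8, bg_share=0.5, n=20, **kw):
    n_pres = n // 2
    n_bg = n - n_pres
    f = [1.0] * int(p_mean * n_pres) + [0.0] * (n_pres - int(p_mean * n_pres))
    f += [1.0] * int(bg_share * n_bg) + [0.0] * (n_bg - int(bg_share * n_bg))
    X = pd.DataFrame({"f": f})
    y = [1] * n_pres + [0] * n_bg
    defaults = dict(quadratic=False, standardize=False, reg_beta=0.0,
                    tol=1e-14, max_iter=5000)
    defaults.update(kw)
    return MaxEnt(**defaults).fit(X, y)


@pytest.fixture(scope="module")
def fitted(bundle80, truth80):
    """A replicate-style fit on the 80x80 landscape at native grain."""
    vs = build_variable_sets(bundle80, aspect_mode="northness")["VS-3"]
    occ = sample_presences(truth80, 120, seed=4)
    rarefied = clean_and_rarefy(occ, vs.ref_grid())
    bg = sample_background(vs, n=1500, seed=5)
    Xp = extract_point_values(vs, rarefied)
    Xb = vs.extract(bg.points).dropna().reset_index(drop=True)
    X = pd.concat([Xp, Xb], ignore_index=True)
    y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]
    model = MaxEnt(categorical=("landcover",)).fit(X, y)
    return model, vs, Xp, Xb


class TestFeatureExpansion:
    def test_categorical_indicator_vector(self):
        m = MaxEnt(categorical=("lc",))
        X = pd.DataFrame({"lc": [1.0, 2.0, 2.0, 1.0, 1.0, 2.0]})
        m.fit(X, [1, 1, 0, 0, 0, 0])
        F = m._expand(pd.DataFrame({"lc": [2.0]}))
        assert F.loc[0, "lc==1"] == 0.0 and F.loc[0, "lc==2"] == 1.0

    def test_quadratic_is_square_of_raw_value(self):
        m = MaxEnt()
        m._learn_expansion(pd.DataFrame({"v": [0.0]}))
        pts = pd.DataFrame({"v": [-2.0, -0.5, 0.0, 1.5, 3.0]})
        F = m._expand(pts)
        assert np.allclose(F["v^2"], pts["v"] ** 2)

    def test_background_standardisation(self, fitted):
        model, _, _, Xb = fitted
        Z, _ = model._design(Xb, clamp=False)
        cont = [i for i, n in enumerate(model.feature_names_)
                if not n.startswith("landcover==")]
        assert np.allclose(Z[:, cont].mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z[:, cont].std(axis=0), 1, atol=1e-9)

    def test_point_on_nodata_is_error(self, bundle80):
        vs = build_variable_sets(bundle80)["VS-3"]
        with pytest.raises(ValueError, match="offenders"):
            extract_point_values(vs, np.array([[1e6, 1e6]]))


class TestFit:
    def test_constant_feature_gives_uniform_model(self):
        X = pd.DataFrame({"f": [3.0] * 12})
        m = MaxEnt(quadratic=False).fit(X, [1] * 4 + [0] * 8)
        assert m.gain_ == pytest.approx(0.0, abs=1e-12)
        scores = m.predict_logistic(X)
        assert np.allclose(scores, scores[0])

    def test_single_binary_feature_closed_form(self):
        # moment matching: e^l / (e^l + 1) = 0.8  =>  lambda = ln 4
        m = binary_fit()
        assert m.lambdas_["f"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_heavy_regularisation_shrinks_to_uniform(self):
        m = binary_fit(reg_beta=1e6)
        assert abs(m.lambdas_["f"]) < 1e-8

    def test_shrinkage_monotone_in_reg_beta(self):
        norms = [np.abs(binary_fit(reg_beta=b).lambdas_).sum()
                 for b in (0.0, 1.0, 10.0)]
        assert norms[0] >= norms[1] >= norms[2]

    def test_gain_trajectory_non_decreasing(self, fitted):
        model = fitted[0]
        assert np.all(np.diff(model.gain_trajectory_) >= -1e-9)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"a": rng.normal(size=60),
                              "b": rng.normal(size=60)})
            y = [1] * 20 + [0] * 40
            m = MaxEnt(reg_beta=0.5).fit(X, y)
            assert np.all(np.diff(m.gain_trajectory_) >= -1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="presence"):
            MaxEnt().fit(pd.DataFrame({"f": [1.0, 0.0, 1.0]}), [1, 0, 0])
        with pytest.raises(ValueError, match="background"):
            MaxEnt().fit(pd.DataFrame({"f": [1.0, 0.0, 1.0]}), [1, 1, 0])
        with pytest.raises(ValueError, match="finite"):
            MaxEnt().fit(pd.DataFrame({"f": [1.0, np.nan, 0.0, 0.5]}),
                         [1, 1, 0, 0])

    def test_sklearn_param_interface(self):
        m = MaxEnt(reg_beta=2.0)
        assert m.get_params()["reg_beta"] == 2.0
        m.set_params(reg_beta=0.5, tol=1e-8)
        assert m.reg_beta == 0.5 and m.tol == 1e-8
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


class TestPredict:
    def test_raw_sums_to_one(self, fitted):
        model, vs, _, _ = fitted
        smap = predict_map(model, vs)
        assert smap.raw.values[smap.raw.mask()].sum() == pytest.approx(1.0, abs=1e-9)

    def test_training_area_identical_under_any_clamp_mode(self, fitted):
        """Projection onto the training area clamps nothing, so all clamp
        modes agree wherever features stay inside the training range."""
        model, vs, _, _ = fitted
        none = predict_map(model, vs, clamp_mode="none")
        clamp = predict_map(model, vs, clamp_mode="clamp")
        fade = predict_map(model, vs, clamp_mode="fade")
        inside = clamp.clamp_flag.values == 0
        assert np.allclose(none.logistic.values[inside],
                           clamp.logistic.values[inside])
        assert np.allclose(none.logistic.values[inside],
                           fade.logistic.values[inside])

    def test_fade_not_above_clamp_outside_training_range(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"v": np.r_[rng.uniform(0, 1, 30),
                                     rng.uniform(0, 1, 60)]})
        y = [1] * 30 + [0] * 60
        m = MaxEnt(quadratic=False).fit(X, y)
        far = pd.DataFrame({"v": [5.0, -4.0, 0.5]})
        lc = m.predict_logistic(far, clamp_mode="clamp")
        lf = m.predict_logistic(far, clamp_mode="fade")
        assert np.all(lf <= lc + 1e-12)
        assert lf[2] == pytest.approx(lc[2])

    def test_missing_variable_is_error(self, fitted):
        model, vs, _, _ = fitted
        smaller = vs.subset([n for n in vs.names() if n != "slope"])
        with pytest.raises(ValueError, match="slope"):
            predict_map(model, smaller)


class TestRunReplicates:
    def test_replicate_count_and_metric_spread(self, bundle80, truth80):
        vs = build_variable_sets(bundle80, aspect_mode="northness")["VS-3"]
        occ = sample_presences(truth80, 80, seed=9)
        rarefied = clean_and_rarefy(occ, vs.ref_grid())
        reps = run_replicates(vs, rarefied, n_rep=4, n_background=500,
                              master_seed=3)
        assert len(reps.metrics) == 4
        assert len(reps.models) == 4
        assert reps.metrics["auc_test"].std(ddof=0) >= 0
        assert reps.metrics["converged"].all()

    def test_single_replicate_mean_map_is_that_map(self, bundle80, truth80):
        vs = build_variable_sets(bundle80, aspect_mode="northness")["VS-3"]
        occ = sample_presences(truth80, 80, seed=9)
        rarefied = clean_and_rarefy(occ, vs.ref_grid())
        reps = run_replicates(vs, rarefied, n_rep=1, n_background=500,
                              master_seed=3)
        single = predict_map(reps.models[0], vs)
        assert np.allclose(reps.mean_map.logistic.values,
                           single.logistic.values)

    def test_deterministic_under_master_seed(self, bundle80, truth80):
        vs = build_variable_sets(bundle80, aspect_mode="northness")["VS-3"]
        occ = sample_presences(truth80, 80, seed=9)
        rarefied = clean_and_rarefy(occ, vs.ref_grid())
        a = run_replicates(vs, rarefied, n_rep=2, n_background=400,
                           master_seed=8)
        b = run_replicates(vs, rarefied, n_rep=2, n_background=400,
                           master_seed=8)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert np.array_equal(a.mean_map.logistic.values,
                              b.mean_map.logistic.values)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, fitted, tmp_path):
        model, vs, Xp, Xb = fitted
        path = tmp_path / "model.lambdas"
        save_model(model, path)
        back = load_model(path)
        for X in (Xp, Xb):
            assert np.allclose(back.predict_logistic(X, clamp_mode="fade"),
                               model.predict_logistic(X, clamp_mode="fade"))
        assert back.variables_ == model.variables_
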
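import json

import numpy as np
import pytest

from nichecast.grids import InputError
from nichecast.maxent import (
    MaxEnt,
    MaxEntConfig,
    build_features,
    fit_penalized,
)


def _objective(beta, f_pres, f_back, lam):
    """Independent penalised-loss evaluation (uniform background weights)."""
    beta = np.asarray(beta, dtype=float)
    eta_b = f_back @ beta
    return (
        -(f_pres @ beta).mean()
        + np.log(np.mean(np.exp(eta_b)))
        + np.sum(lam * np.abs(beta))
    )


class TestFeatureExpansion:
    def setup_method(self):
        self.back = np.linspace(0.0, 10.0, 21).reshape(-1, 1)
        self.pres = np.array([[2.0], [8.0]])

    def test_linear_feature_at_background_max_is_one(self):
        cfg = MaxEntConfig(feature_classes=("linear",), auto_features=False)
        fs = build_features(np.array([[10.0]]), self.back, ["v"], cfg)
        assert fs.presence[0, 0] == 1.0

    def test_threshold_indicator(self):
        cfg = MaxEntConfig(feature_classes=("threshold",), auto_features=False, n_knots=1)
        fs = build_features(np.array([[4.0]]), self.back, ["v"], cfg)
        knot = fs.defs[0].knot
        assert knot == pytest.approx(0.5)
        assert fs.presence[0, 0] == 0.0  # scaled 0.4 <= knot 0.5

    def test_hinge_endpoints(self):
        cfg = MaxEntConfig(feature_classes=("hinge",), auto_features=False, n_knots=1)
        fs = build_features(np.array([[5.0], [10.0], [0.0]]), self.back, ["v"], cfg)
        fwd = [j for j, d in enumerate(fs.defs) if not d.reverse][0]
        assert fs.presence[0, fwd] == 0.0  # at the knot
        assert fs.presence[1, fwd] == 1.0  # at the max
        rev = [j for j, d in enumerate(fs.defs) if d.reverse][0]
        assert fs.presence[2, rev] == 1.0  # at the min, reverse hinge is 1

    def test_quadratic_and_product(self):
        cfg = MaxEntConfig(feature_classes=("linear", "quadratic", "product"),
                           auto_features=False)
        back = np.column_stack([np.linspace(0, 1, 11), np.linspace(0, 2, 11)])
        fs = build_features(np.array([[0.5, 1.0]]), back, ["a", "b"], cfg)
        labels = [d.label(["a", "b"]) for d in fs.defs]
        assert "a^2" in labels and "a*b" in labels
        q = labels.index("a^2")
        assert fs.presence[0, q] == pytest.approx(0.25)

    def test_constant_variable_warns(self):
        back = np.column_stack([np.linspace(0, 1, 11), np.full(11, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            build_features(np.array([[0.5, 3.0]]), back, ["a", "b"],
                           MaxEntConfig(feature_classes=("linear",), auto_features=False))

    def test_auto_features_respects_presence_count(self):
        cfg = MaxEntConfig()
        assert cfg.active_classes(5) == ("linear",)
        assert "hinge" in cfg.active_classes(20)
        assert "threshold" not in cfg.active_classes(20)
        assert set(cfg.active_classes(100)) == set(cfg.feature_classes)


class TestFitOracle:
    def test_null_data_gives_zero_beta_and_gain(self):
        # presences identical in distribution to the background
        back = np.linspace(0, 1, 10).reshape(-1, 1)
        state = fit_penalized(back, back, None, lam=np.array([0.01]))
        assert np.allclose(state["beta"], 0.0)
        assert state["gain"] == 0.0

    def test_binary_feature_matches_grid_search(self):
        f_back = np.array([[1.0], [1.0], [0.0], [0.0]])
        f_pres = np.array([[1.0], [1.0], [1.0]])
        lam = np.array([0.05])
        state = fit_penalized(f_pres, f_back, None, lam, tol=1e-10)
        grid = np.arange(-10, 10, 1e-3)
        objs = [-(g * 1.0) + np.log(np.mean(np.exp(f_back.ravel() * g))) + lam[0] * abs(g)
                for g in grid]
        best = grid[int(np.argmin(objs))]
        assert abs(state["beta"][0] - best) < 2e-3

    def test_two_feature_instance_matches_grid_search(self, rng):
        f_back = rng.uniform(0, 1, size=(25, 2))
        f_pres = f_back[rng.choice(25, size=8, p=np.exp(2 * f_back[:, 0])
                                   / np.exp(2 * f_back[:, 0]).sum())]
        lam = np.array([0.03, 0.03])
        state = fit_penalized(f_pres, f_back, None, lam, tol=1e-12, max_passes=5000)
        # coarse grid then 1e-3 refinement around the coarse optimum
        coarse = np.arange(-10, 10, 0.05)
        obj = np.array([[_objective([a, b], f_pres, f_back, lam) for b in coarse]
                        for a in coarse])
        ia, ib = np.unravel_index(obj.argmin(), obj.shape)
        fine_a = np.arange(coarse[ia] - 0.06, coarse[ia] + 0.06, 1e-3)
        fine_b = np.arange(coarse[ib] - 0.06, coarse[ib] + 0.06, 1e-3)
        obj2 = np.array([[_objective([a, b], f_pres, f_back, lam) for b in fine_b]
                         for a in fine_a])
        ja, jb = np.unravel_index(obj2.argmin(), obj2.shape)
        assert abs(state["beta"][0] - fine_a[ja]) < 2e-3
        assert abs(state["beta"][1] - fine_b[jb]) < 2e-3

    def test_gain_trace_monotone_nondecreasing(self, niche_fit):
        trace = np.array(niche_fit.gain_trace)
        assert np.all(np.diff(trace) >= -1e-12)
        assert niche_fit.gain >= 0.0

    def test_doubling_rm_never_increases_l1_norm(self, rng):
        for _ in range(30):
            f_back = rng.uniform(0, 1, size=(20, 2))
            f_pres = f_back[rng.choice(20, size=6)]
            base = rng.uniform(0.01, 0.1, size=2)
            b1 = fit_penalized(f_pres, f_back, None, base, tol=1e-9)["beta"]
            b2 = fit_penalized(f_pres, f_back, None, 2 * base, tol=1e-9)["beta"]
            assert np.abs(b2).sum() <= np.abs(b1).sum() + 1e-6


class TestPrediction:
    def test_zero_model_uniform_raw_and_constant_cloglog(self, world):
        model = MaxEnt.from_env_grid(world["grid"], world["occ"],
                                     config=MaxEntConfig(rm=1e6))  # penalty kills all betas
        res = model.fit()
        assert np.allclose(res.params, 0.0)
        raw = res.predict_values(model.background[:50], transform="raw")
        assert np.allclose(raw, raw[0])
        cll = res.predict_values(model.background[:50], transform="cloglog")
        assert np.allclose(cll, cll[0])

    def test_raw_sums_to_one_over_background(self, niche_fit):
        assert abs(niche_fit.raw_on_background().sum() - 1.0) < 1e-8

    def test_clamped_prediction_beyond_training_max(self, niche_fit):
        vmax = niche_fit.features.var_max.copy()
        inside = niche_fit.presence_means.copy()
        beyond = inside.copy()
        beyond[0] = vmax[0] + 100.0
        at_max = inside.copy()
        at_max[0] = vmax[0]
        assert niche_fit.predict_values(beyond[None, :], clamp=True) \
            == pytest.approx(niche_fit.predict_values(at_max[None, :], clamp=True))

    def test_background_order_permutation_invariance(self, rng):
        back = rng.uniform(0, 10, size=(200, 2))
        pres = rng.uniform(4, 6, size=(30, 2))
        cfg = MaxEntConfig(feature_classes=("linear", "quadratic"), auto_features=False,
                           tol=1e-9)
        r1 = MaxEnt(pres, back, ["a", "b"], config=cfg).fit()
        perm = rng.permutation(200)
        r2 = MaxEnt(pres, back[perm], ["a", "b"], config=cfg).fit()
        x = rng.uniform(0, 10, size=(20, 2))
        assert np.max(np.abs(r1.predict_values(x) - r2.predict_values(x))) < 1e-10

    def test_transform_values_in_unit_interval(self, niche_fit, world):
        smap = niche_fit.predict_grid(world["grid"])
        v = smap.valid_values()
        assert v.min() >= 0.0 and v.max() <= 1.0


class TestContributionAndReporting:
    def test_single_variable_model_contributes_everything(self, world):
        model = MaxEnt.from_env_grid(world["grid"], world["occ"],
                                     variables=["temp_cold_q"])
        res = model.fit()
        assert res.percent_contribution()["temp_cold_q"] == pytest.approx(100.0)

    def test_contributions_sum_to_100(self, niche_fit):
        assert niche_fit.percent_contribution().sum() == pytest.approx(100.0, abs=0.1)

    def test_equally_informative_duplicates_split_contribution(self, rng):
        # two variables with identical, equally informative marginals
        n = 1500
        back = rng.uniform(0, 1, size=(n, 2))
        w = np.exp(3 * back[:, 0] + 3 * back[:, 1])
        pres = back[rng.choice(n, size=150, p=w / w.sum())]
        cfg = MaxEntConfig(feature_classes=("linear",), auto_features=False)
        res = MaxEnt(pres, back, ["a", "b"], config=cfg).fit()
        pct = res.percent_contribution()
        assert abs(pct["a"] - 50.0) < 10.0

    def test_summary_mentions_key_quantities(self, niche_fit):
        text = niche_fit.summary()
        assert "regularized gain" in text
        assert "temp_cold_q" in text

    def test_json_round_trip_is_complete(self, niche_fit, tmp_path):
        path = tmp_path / "model.json"
        niche_fit.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["var_names"] == ["temp_cold_q", "prec_wet_m", "prec_dry_m"]
        assert len(doc["beta"]) == len(doc["features"])
        assert doc["gain"] == pytest.approx(niche_fit.gain)


class TestValidation:
    def test_rm_must_be_positive(self):
        with pytest.raises(InputError):
            MaxEntConfig(rm=0.0)

    def test_needs_presences_and_background(self):
        with pytest.raises(InputError):
            MaxEnt(np.empty((0, 1)), np.ones((5, 1)))
        with pytest.raises(InputError):
            MaxEnt(np.ones((2, 1)), np.ones((1, 1)))

    def test_missing_variable_on_predict(self, niche_fit, world):
        grid = world["grid"].subset(["temp_cold_q", "prec_wet_m"])
        with pytest.raises(InputError):
            niche_fit.predict_grid(grid)
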
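"""FIML likelihood, model specs, estimation, and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trackace import (
    CholeskyACE,
    FitResult,
    GenerativeConfig,
    ModelSpec,
    PairTable,
    aic,
    delta_ci,
    fit_model,
    likelihood_ratio_test,
    neg2_loglik,
    simulate_pairs,
    standardize_components,
    variance_components,
)
from trackace.fiml_engine import (
    GLOBAL_ROLES,
    STATUS_ROLES,
    _n2ll_and_grad,
    _Prepared,
    _SpecIndex,
    moment_start,
)
from trackace.pair_data import RELATEDNESS

from conftest import two_status_config, univariate_config


def oracle_neg2ll(params: dict, spec: ModelSpec, table: PairTable) -> float:
    """Independent -2LL oracle: factor-loading Gram construction per pair
    plus scipy's multivariate-normal density, summed over observed blocks."""
    total = 0.0
    for pair in table.pairs():
        r = RELATEDNESS[pair.zygosity]
        # latent factors: A_x1 A_x2 C_x E_x1 E_x2 A_y1 A_y2 C_y E_y1 E_y2
        phi = np.eye(10)
        phi[0, 1] = phi[1, 0] = r
        phi[5, 6] = phi[6, 5] = r
        L = np.zeros((4, 10))
        mu = np.zeros(4)
        yob_mean = table.birth_year_mean
        for t, twin in enumerate((pair.twin1, pair.twin2)):
            status = twin.tracking
            x = twin.performance_centered if np.isfinite(twin.performance_centered) else 0.0
            v = lambda role: spec.value(params, status, role)
            g = lambda role: spec.global_value(params, role)
            L[2 * t, [t, 2, 3 + t]] = [v("a_xx"), v("c_xx"), v("e_xx")]
            L[2 * t + 1, [t, 2, 3 + t]] = [
                v("a_yx") + v("ap_yx") * x,
                v("c_yx") + v("cp_yx") * x,
                v("e_yx") + v("ep_yx") * x,
            ]
            L[2 * t + 1, [5 + t, 7, 8 + t]] = [
                v("a_yy") + v("ap_yy") * x,
                v("c_yy") + v("cp_yy") * x,
                v("e_yy") + v("ep_yy") * x,
            ]
            yob_c = twin.birth_year - yob_mean
            mu[2 * t] = v("mu_x") + g("b_male_x") * twin.male + g("b_yob_x") * yob_c
            mu[2 * t + 1] = (v("mu_y") + g("b_male_y") * twin.male
                             + g("b_yob_y") * yob_c + v("b_mod_y") * x)
        sigma = L @ phi @ L.T
        data = np.array([
            pair.twin1.performance_centered, pair.twin1.attainment,
            pair.twin2.performance_centered, pair.twin2.attainment,
        ])
        obs = np.isfinite(data)
        obs[1] &= obs[0]   # moderator missing drops the attainment term
        obs[3] &= obs[2]
        if not obs.any():
            continue
        total += -2.0 * stats.multivariate_normal.logpdf(
            data[obs], mean=mu[obs], cov=sigma[np.ix_(obs, obs)]
        )
    return total


def example_params(spec: ModelSpec) -> dict:
    cfg = GenerativeConfig.default(n_mz=10, n_dz=10)
    vals = {}
    for status in spec.statuses:
        ps, ms = cfg.paths[status], cfg.means[status]
        for role in STATUS_ROLES:
            key = spec.status_map[(status, role)]
            if isinstance(key, str):
                if role in ("mu_x", "mu_y"):
                    vals[key] = {"mu_x": ms.mu_x, "mu_y": ms.mu_y}[role]
                else:
                    vals[key] = getattr(ps, role, 0.0)
    for role in GLOBAL_ROLES:
        vals[spec.global_map[role]] = {"b_male_x": 0.6, "b_male_y": 0.06,
                                       "b_yob_x": 0.05, "b_yob_y": 0.005}[role]
    return vals


class TestLikelihood:
    def test_matches_multivariate_normal_oracle_complete_data(self, complete_table):
        spec = ModelSpec.model_1b(("immediate", "delayed"))
        params = example_params(spec)
        ours = neg2_loglik(params, spec, complete_table)
        ref = oracle_neg2ll(params, spec, complete_table)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_matches_oracle_with_missingness_and_moderation(self):
        cfg = GenerativeConfig.default(n_mz=80, n_dz=70, seed=17)
        table = simulate_pairs(cfg)
        spec = ModelSpec.model_2()
        params = example_params(spec)
        for s in spec.statuses:
            params[f"ap_yx@{s}"] = 0.01
            params[f"cp_yy@{s}"] = -0.005
        ours = neg2_loglik(params, spec, table)
        ref = oracle_neg2ll(params, spec, table)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_single_variable_pairs_reduce_to_univariate_densities(self, complete_table):
        df = complete_table.df.copy()
        df[["attainment_1", "attainment_2", "performance_2"]] = np.nan
        df["tracking_2"] = "missing"
        table = PairTable(df, performance_mean=complete_table.performance_mean)
        spec = ModelSpec.model_1a(("immediate", "delayed", "missing"))
        params = example_params(spec)
        ours = neg2_loglik(params, spec, table)
        x = table.df["performance_centered_1"].to_numpy()
        male = table.df["male_1"].to_numpy()
        yob_c = table.df["birth_year_1"].to_numpy() - table.birth_year_mean
        mu = params["mu_x"] + params["b_male_x"] * male + params["b_yob_x"] * yob_c
        var = params["a_xx"] ** 2 + params["c_xx"] ** 2 + params["e_xx"] ** 2
        ref = float(np.sum(-2.0 * stats.norm.logpdf(x, mu, np.sqrt(var))))
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_duplicating_pairs_doubles_neg2ll(self, complete_table):
        spec = ModelSpec.model_1b(("immediate", "delayed"))
        params = example_params(spec)
        base = neg2_loglik(params, spec, complete_table)
        df2 = pd.concat([complete_table.df, complete_table.df], ignore_index=True)
        df2["pair_id"] = [f"q{i}" for i in range(len(df2))]
        doubled = PairTable(df2, performance_mean=complete_table.performance_mean,
                            birth_year_mean=complete_table.birth_year_mean)
        assert neg2_loglik(params, spec, doubled) == pytest.approx(2 * base, rel=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, complete_table):
        spec = ModelSpec.model_2(("immediate", "delayed"))
        prep = _Prepared.from_table(complete_table, spec.statuses)
        sx = _SpecIndex(spec)
        start = moment_start(spec, complete_table)
        rng = np.random.default_rng(1)
        th = np.array([start[n] for n in spec.free_names])
        th = th * (1 + 0.05 * rng.standard_normal(len(th))) + 0.01 * rng.standard_normal(len(th))
        _, g = _n2ll_and_grad(th, spec, prep, sx, want_grad=True)
        for i in rng.choice(len(th), size=12, replace=False):
            h = 1e-6 * max(1.0, abs(th[i]))
            up, dn = th.copy(), th.copy()
            up[i] += h
            dn[i] -= h
            fd = (_n2ll_and_grad(up, spec, prep, sx)
                  - _n2ll_and_grad(dn, spec, prep, sx)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)

    def test_singular_covariance_penalized_not_crashed(self, complete_table):
        spec = ModelSpec.model_1a(("immediate", "delayed"))
        params = {n: 0.0 for n in spec.free_names}
        with pytest.warns(RuntimeWarning):
            value = neg2_loglik(params, spec, complete_table)
        assert np.isfinite(value) and value > 1e7


class TestSpecAccounting:
    def test_free_parameter_counts(self):
        assert ModelSpec.model_1a().n_free == 15
        assert ModelSpec.model_1b().n_free == 37
        assert ModelSpec.model_2().n_free == 55

    def test_lrt_dfs_match_study_accounting(self):
        # freeing per-status sets adds 22; freeing moderation adds 18
        assert ModelSpec.model_1b().n_free - ModelSpec.model_1a().n_free == 22
        assert ModelSpec.model_2().n_free - ModelSpec.model_1b().n_free == 18

    def test_two_status_accounting(self):
        assert ModelSpec.model_1b(("immediate", "delayed")).n_free - \
            ModelSpec.model_1a(("immediate", "delayed")).n_free == 11

    def test_moderator_mean_option_recorded_and_counted(self):
        spec = ModelSpec.model_2(moderator_mean=True)
        assert spec.n_free == 58
        assert spec.moderator_mean

    def test_yaml_round_trip(self, tmp_path):
        spec = ModelSpec.model_2(("immediate", "delayed"))
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        again = ModelSpec.from_yaml(path)
        assert again == spec

    def test_unknown_model_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_name("3")


@pytest.fixture(scope="module")
def fitted(complete_table):
    return fit_model("1a", complete_table, n_restarts=1, seed=0)


class TestFit:
    def test_converged_with_finite_ses(self, fitted):
        assert fitted.converged
        assert all(np.isfinite(v) for v in fitted.se.values())

    def test_canonical_signs(self, fitted):
        for role in ("a_xx", "c_xx", "e_xx", "a_yy", "e_yy"):
            assert fitted.estimates[role] >= 0

    def test_start_invariance_of_optimum(self, complete_table):
        a = fit_model("1a", complete_table, n_restarts=1, seed=0, compute_se=False)
        bumped = {k: v * 1.25 + 0.05 for k, v in moment_start(
            ModelSpec.model_1a(("immediate", "delayed")), complete_table).items()}
        b = fit_model("1a", complete_table, starts=bumped, n_restarts=1, seed=0,
                      compute_se=False)
        assert abs(a.neg2_loglik - b.neg2_loglik) < 1e-4

    def test_nested_monotonicity(self, complete_table, fitted):
        warm = dict(fitted.estimates)
        warm.update({f"{k}@{s}": v for k, v in fitted.estimates.items()
                     for s in ("immediate", "delayed")})
        full = fit_model("1b", complete_table, starts=warm, n_restarts=1,
                         compute_se=False)
        assert full.neg2_loglik <= fitted.neg2_loglik + 1e-3

    def test_c_zero_data_gives_near_zero_c_estimate(self):
        cfg = univariate_config(a2=0.7, c2=0.0, e2=0.3, n_mz=3000, n_dz=3000, seed=21)
        table = simulate_pairs(cfg)
        spec = ModelSpec.model_1a(("immediate",))
        free = fit_model(spec, table, n_restarts=1, compute_se=False)
        c_share = free.estimates["c_xx"] ** 2 / (
            free.estimates["a_xx"] ** 2 + free.estimates["c_xx"] ** 2
            + free.estimates["e_xx"] ** 2)
        assert c_share < 0.06
        smap = dict(spec.status_map)
        for role in ("c_xx", "c_yx", "c_yy"):
            smap[("immediate", role)] = 0.0
        fixed_spec = ModelSpec("1a-noC", ("immediate",), smap, spec.global_map)
        fixed = fit_model(fixed_spec, table, n_restarts=1, compute_se=False)
        assert fixed.neg2_loglik - free.neg2_loglik < 8.0  # ~chi2(3) range
        assert fixed.neg2_loglik >= free.neg2_loglik - 1e-3

    def test_estimator_is_sklearn_compatible(self, complete_table):
        est = CholeskyACE(model="1a", n_restarts=1, compute_se=False)
        assert est.get_params()["model"] == "1a"
        est.set_params(seed=3)
        est.fit(complete_table)
        assert hasattr(est, "params_") and hasattr(est, "neg2_loglik_")
        assert est.score(complete_table) == pytest.approx(
            -0.5 * est.neg2_loglik_ / complete_table.n_pairs)

    def test_fit_result_json_round_trip(self, fitted, tmp_path):
        path = tmp_path / "fit.json"
        fitted.to_json(path)
        again = FitResult.from_json(path)
        assert again.neg2_loglik == pytest.approx(fitted.neg2_loglik)
        assert again.estimates == pytest.approx(fitted.estimates)
        assert again.spec == fitted.spec

    def test_tsv_export_layout(self, fitted, tmp_path):
        df = fitted.to_tsv(tmp_path / "fit.tsv")
        assert set(df.columns) == {"group", "parameter", "estimate", "se"}
        assert (tmp_path / "fit.tsv").exists()


class TestModelComparison:
    def make_fit(self, name, n2ll, k):
        spec = {"1a": ModelSpec.model_1a, "1b": ModelSpec.model_1b,
                "2": ModelSpec.model_2}[name]()
        return FitResult(
            spec=spec, estimates={}, se={}, cov=None, neg2_loglik=n2ll,
            n_free=k, n_obs_stats=14426, n_pairs=4941, group_sizes={},
            converged=True, grad_norm=0.0, n_restarts=1, seed=0,
        )

    def test_printed_lrt_shared_vs_split(self):
        lrt = likelihood_ratio_test(self.make_fit("1a", 73003.2, 15),
                                    self.make_fit("1b", 72691.1, 37))
        assert lrt.statistic == pytest.approx(312.1, abs=1e-6)
        assert lrt.df == 22
        assert lrt.p_value < 0.001

    def test_printed_lrt_split_vs_moderated(self):
        lrt = likelihood_ratio_test(self.make_fit("1b", 72691.1, 37),
                                    self.make_fit("2", 72386.9, 55))
        assert lrt.statistic == pytest.approx(304.2, abs=1e-6)
        assert lrt.df == 18

    def test_identical_fits_give_zero_statistic(self):
        lrt = likelihood_ratio_test(self.make_fit("1a", 500.0, 15),
                                    self.make_fit("1b", 500.0, 37))
        assert lrt.statistic == 0.0
        assert lrt.p_value == pytest.approx(1.0)

    def test_negative_statistic_warns(self):
        with pytest.warns(UserWarning, match="refit|worse"):
            likelihood_ratio_test(self.make_fit("1a", 500.0, 15),
                                  self.make_fit("1b", 510.0, 37))

    def test_aic_conventions(self):
        fit = self.make_fit("1a", 100.0, 5)
        out = aic(fit)
        assert out["aic"] == pytest.approx(110.0)
        assert out["aic_mx"] == pytest.approx(100.0 - 2 * (14426 - 5))

    def test_printed_mx_aics_reproduced(self):
        # observed statistics: 8847 performance + 5579 attainment scores
        for n2ll, k, printed in [(73003.2, 15, 44181.2), (72691.1, 37, 43913.1),
                                 (72386.9, 55, 43644.9)]:
            assert self.make_fit("1a", n2ll, k).aic_mx == pytest.approx(printed)

    def test_delta_aic_identity(self):
        f1 = self.make_fit("1a", 73003.2, 15)
        f2 = self.make_fit("1b", 72691.1, 37)
        lrt = likelihood_ratio_test(f1, f2)
        assert f1.aic - f2.aic == pytest.approx(lrt.statistic - 2 * lrt.df)


class TestDeltaCI:
    def test_identity_transform_matches_wald_interval(self, fitted):
        lo, hi, est, se = delta_ci(fitted, lambda p: p["a_xx"])
        assert est == pytest.approx(fitted.estimates["a_xx"])
        assert se == pytest.approx(fitted.se["a_xx"], rel=1e-3)
        assert hi - lo == pytest.approx(2 * 1.959963984540054 * se, rel=1e-6)

    def test_constant_transform_zero_width(self, fitted):
        lo, hi, est, se = delta_ci(fitted, lambda p: 3.14)
        assert se == 0.0 and lo == hi == est == pytest.approx(3.14)

    def test_unavailable_without_covariance(self, fitted):
        import dataclasses

        broken = dataclasses.replace(fitted, cov=None)
        with pytest.raises(ValueError, match="unavailable"):
            delta_ci(broken, lambda p: p["a_xx"])

    def test_standardized_heritability_interval_covers_truth(self):
        """Scaled-down coverage check for the standardized genetic share."""

        def a_share(p):
            from trackace.ace_structure import ModeratedPathSet
            ps = ModeratedPathSet(
                a_xx=p["a_xx"], c_xx=p["c_xx"], e_xx=p["e_xx"],
                a_yx=p["a_yx"], c_yx=p["c_yx"], e_yx=p["e_yx"],
                a_yy=p["a_yy"], c_yy=p["c_yy"], e_yy=p["e_yy"],
            )
            return standardize_components(variance_components(ps))["a_x"]

        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            table = simulate_pairs(two_status_config(n_mz=220, n_dz=180,
                                                     seed=5000 + rep))
            fit = fit_model("1a", table, n_restarts=1, compute_se=True)
            lo, hi, est, _ = delta_ci(fit, a_share)
            truth = 7.08**2 / (7.08**2 + 2.74**2 + 3.69**2)
            covered += lo <= truth <= hi
        # binomial(30, 0.95): >= 24 successes covers all but ~1e-3 of mass
        assert covered >= 24
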
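import json

import numpy as np
import pytest

from selmeta.inference import (
    FitOptions,
    FitResult,
    contrast_probability,
    corrected_estimates,
    derive_reporting_probability,
    exclusion_protocol,
    fit,
    model_table,
    reporting_probability,
)
from selmeta.likelihood import StudyResult, combined_loglik, MarkerParams
from selmeta.models import build_model
from tests.conftest import make_corpus, toy_marker


class TestClosedFormFits:
    def test_fixed_effect_unbiased_is_inverse_variance_mean(self):
        studies = toy_marker([0.4, 0.1], [0.2, 0.4])
        res = fit(studies, build_model("unbiased", "fixed"))
        w = np.array([1 / 0.2**2, 1 / 0.4**2])
        want = float(w @ [0.4, 0.1] / w.sum())
        assert res.delta[0] == pytest.approx(want, abs=1e-7)
        assert res.converged

    def test_refit_from_optimum_does_not_improve(self, small_corpus):
        spec = build_model("model1")
        res = fit(small_corpus, spec)
        kept = [s for s in small_corpus if s.marker_id in set(res.marker_ids)]
        params = {mid: MarkerParams(res.delta[i], res.tau2[i])
                  for i, mid in enumerate(res.marker_ids)}
        direct = combined_loglik(kept, params, res.theta_w, spec)
        assert direct == pytest.approx(res.loglik, abs=1e-8)


class TestGridOracle:
    """On tiny problems the joint BFGS optimum must match a dense grid
    search over all free parameters."""

    def corpus(self):
        return toy_marker([0.55, -0.1, 0.32, 0.15, 0.9],
                          [0.3, 0.25, 0.35, 0.2, 0.45])

    def test_model1_random_effects_three_parameters(self):
        # a lone marker's unrestricted likelihood is unbounded at
        # tau2 -> -min sigma_i^2, so the grid comparison uses the
        # nonnegative-variance mode where the optimum is well defined
        corpus = self.corpus()
        spec = build_model("model1")
        res = fit(corpus, spec, FitOptions(variance_floor=True))
        deltas = np.linspace(-0.5, 1.0, 61)
        tau2s = np.linspace(0.0, 0.4, 41)
        lws = np.linspace(-2.0, 1.0, 31)
        best = (-np.inf, None)
        for d in deltas:
            for t in tau2s:
                for lw in lws:
                    ll = combined_loglik(corpus, {"M1": MarkerParams(d, t)},
                                         [lw], spec)
                    if ll > best[0]:
                        best = (ll, (d, t, lw))
        assert res.loglik >= best[0] - 1e-6
        d, t, lw = best[1]
        assert abs(res.delta[0] - d) <= (deltas[1] - deltas[0])
        assert abs(res.tau2[0] - t) <= (tau2s[1] - tau2s[0])
        assert abs(res.theta_w[0] - lw) <= (lws[1] - lws[0])

    def test_model1_fixed_effects_two_parameters(self):
        corpus = self.corpus()
        spec = build_model("model1", "fixed")
        res = fit(corpus, spec)
        deltas = np.linspace(-0.5, 1.0, 151)
        lws = np.linspace(-2.0, 1.0, 121)
        best = (-np.inf, None)
        for d in deltas:
            for lw in lws:
                ll = combined_loglik(corpus, {"M1": MarkerParams(d, 0.0)},
                                     [lw], spec)
                if ll > best[0]:
                    best = (ll, (d, lw))
        assert res.loglik >= best[0] - 1e-6
        d, lw = best[1]
        assert abs(res.delta[0] - d) <= (deltas[1] - deltas[0])
        assert abs(res.theta_w[0] - lw) <= (lws[1] - lws[0])


class TestDerivedQuantities:
    def test_point_and_interval_from_log_weight(self):
        eff = reporting_probability(-0.33, 0.11)
        assert eff.point == pytest.approx(0.7189, abs=5e-4)
        assert eff.ci_low == pytest.approx(0.5795, abs=5e-4)
        assert eff.ci_high == pytest.approx(0.8919, abs=5e-4)

    def test_zero_log_weight_zero_se_is_exactly_one(self):
        eff = reporting_probability(0.0, 0.0)
        assert (eff.point, eff.ci_low, eff.ci_high) == (1.0, 1.0, 1.0)

    def test_contrast_uses_covariance(self):
        # var1 + var2 - 2 cov = 0.14^2 with a 0.32 difference
        eff = contrast_probability(est1=-0.11, est2=-0.43,
                                   var1=0.17**2, var2=0.17**2,
                                   cov=(2 * 0.17**2 - 0.14**2) / 2)
        assert eff.se == pytest.approx(0.14, abs=1e-12)
        assert eff.point == pytest.approx(0.7261, abs=5e-4)
        assert eff.ci_low == pytest.approx(0.5519, abs=5e-4)
        assert eff.ci_high == pytest.approx(0.9554, abs=5e-4)

    def test_interval_ordering_invariant(self):
        eff = reporting_probability(-0.8, 0.25)
        assert 0 < eff.ci_low <= eff.point <= eff.ci_high

    def test_from_fit_result(self, nested_fits):
        res = nested_fits["model1"]
        eff = derive_reporting_probability(res, "log_w_S")
        assert eff.point == pytest.approx(np.exp(res.theta_w[0]))
        with pytest.raises(KeyError, match="log_w_I"):
            derive_reporting_probability(res, "log_w_I")

    def test_contrast_from_fit_result(self, nested_fits):
        res = nested_fits["proteus"]
        eff = derive_reporting_probability(res, ("log_w_E1", "log_w_E2"))
        i, j = res.param_index("log_w_E1"), res.param_index("log_w_E2")
        want_se = np.sqrt(res.cov_w[i, i] + res.cov_w[j, j] - 2 * res.cov_w[i, j])
        assert eff.se == pytest.approx(want_se)
        assert eff.point == pytest.approx(
            np.exp(-(res.theta_w[i] - res.theta_w[j])))


def _dummy_fit(name, loglik, marker_ids=("A", "B"), n_free=0, theta=(),
               effects_mode="random"):
    spec = build_model(name, effects_mode)
    p = spec.n_free_weight_params
    m = len(marker_ids)
    return FitResult(
        model_name=name, effects_mode=effects_mode, spec=spec,
        param_names=spec.param_names, theta_w=np.asarray(theta, float),
        se_w=np.full(p, 0.1), cov_w=np.eye(p) * 0.01,
        marker_ids=tuple(marker_ids), delta=np.zeros(m), tau2=np.zeros(m),
        se_delta=np.full(m, 0.1), se_tau2=np.full(m, 0.1),
        loglik=loglik, aic=2 * (p + 2 * m) - 2 * loglik,
        n_parameters=p + 2 * m, converged=True, excluded_markers=(),
        optimizer_diag={}, n_studies=10,
    )


class TestModelTable:
    def test_reported_aic_difference(self):
        base = _dummy_fit("unbiased", loglik=-100.0)
        m1 = _dummy_fit("model1", loglik=-95.6, theta=(-0.33,))
        table = model_table([base, m1], base)
        assert table.loc["model1", "delta_loglik"] == pytest.approx(4.4)
        assert table.loc["model1", "delta_aic"] == pytest.approx(-6.8)

    def test_baseline_against_itself_is_zero(self):
        base = _dummy_fit("unbiased", loglik=-42.0)
        table = model_table([base], base)
        assert table.loc["unbiased", "delta_loglik"] == 0.0
        assert table.loc["unbiased", "delta_aic"] == 0.0

    def test_equal_k_models_differ_by_twice_delta_loglik(self):
        base = _dummy_fit("unbiased", loglik=-100.0)
        m3 = _dummy_fit("model3", loglik=-88.6, theta=(-0.8, -0.3, -0.2, -0.1))
        pr = _dummy_fit("proteus", loglik=-86.1, theta=(-0.8, -0.1, -0.4, -0.1))
        table = model_table([base, m3, pr], base)
        diff = table.loc["proteus", "delta_aic"] - table.loc["model3", "delta_aic"]
        assert diff == pytest.approx(-2 * (pr.loglik - m3.loglik))
        assert table.loc["proteus", "best"]

    def test_mismatched_marker_sets_rejected(self):
        base = _dummy_fit("unbiased", loglik=-10.0, marker_ids=("A", "B"))
        other = _dummy_fit("model1", loglik=-9.0, marker_ids=("A", "C"),
                           theta=(-0.1,))
        with pytest.raises(ValueError, match="marker set"):
            model_table([base, other], base)


class TestExclusionProtocol:
    def degenerate_corpus(self):
        """Three healthy markers plus one whose studies are all identical
        (its unrestricted between-study variance diverges)."""
        rng = np.random.default_rng(2)
        corpus = []
        for mid in ("A", "B", "C"):
            xs = rng.normal(0.1, 0.25, 6)
            corpus.extend(toy_marker(xs, [0.25] * 6, marker_id=mid))
        corpus.extend(toy_marker([0.3] * 6, [0.2] * 6, marker_id="DEG"))
        return corpus

    def test_degenerate_marker_flagged_and_shared(self):
        corpus = self.degenerate_corpus()
        specs = [build_model("unbiased"), build_model("model1")]
        excluded, per_model, fits = exclusion_protocol(corpus, specs)
        assert "DEG" in excluded
        for res in fits.values():
            assert res.excluded_markers == ()
            assert "DEG" not in res.marker_ids

    def test_no_failures_is_identity(self):
        corpus = self.degenerate_corpus()
        corpus = [s for s in corpus if s.marker_id != "DEG"]
        excluded, _, _ = exclusion_protocol(corpus, [build_model("unbiased")])
        assert excluded == set()

    def test_final_fits_share_one_marker_set(self, small_corpus):
        specs = [build_model(n) for n in ("unbiased", "model1")]
        excluded, per_model, fits = exclusion_protocol(small_corpus, specs)
        assert excluded == set().union(*per_model.values())
        sets = [set(res.marker_ids) for res in fits.values()]
        assert all(s == sets[0] for s in sets)
        assert sets[0].isdisjoint(excluded)


class TestInvariances:
    def test_rescaling_one_marker_rescales_only_its_parameters(self):
        corpus = make_corpus(n_markers=12, seed=4)
        res1 = fit(corpus, build_model("model2"))
        target = res1.marker_ids[0]
        c = 3.0
        scaled = [
            StudyResult(s.x * c if s.marker_id == target else s.x,
                        s.sigma * c if s.marker_id == target else s.sigma,
                        s.marker_id, s.pub_id, s.year, s.category, s.sign_agrees)
            for s in corpus
        ]
        res2 = fit(scaled, build_model("model2"))
        assert set(res1.marker_ids) == set(res2.marker_ids)
        np.testing.assert_allclose(res2.theta_w, res1.theta_w, atol=2e-4)
        i1 = res1.marker_ids.index(target)
        i2 = res2.marker_ids.index(target)
        assert res2.delta[i2] == pytest.approx(c * res1.delta[i1], abs=1e-4)
        assert np.sqrt(res2.tau2[i2]) == pytest.approx(
            c * np.sqrt(res1.tau2[i1]), abs=1e-4)


class TestCorrectedEstimates:
    def test_no_selection_corrected_matches_uncorrected(self):
        corpus = make_corpus(model="unbiased", log_weights=(), n_markers=25,
                             seed=6)
        unb = fit(corpus, build_model("unbiased"))
        kept = [s for s in corpus if s.marker_id in set(unb.marker_ids)]
        sel = fit(kept, build_model("model1"))
        unb2 = fit(kept, build_model("unbiased"))
        if set(sel.marker_ids) != set(unb2.marker_ids):
            common = set(sel.marker_ids) & set(unb2.marker_ids)
            kept = [s for s in kept if s.marker_id in common]
            sel = fit(kept, build_model("model1"))
            unb2 = fit(kept, build_model("unbiased"))
        table, summary = corrected_estimates(sel, unb2)
        np.testing.assert_allclose(table["delta_corrected"],
                                    table["delta_uncorrected"], atol=0.02)

    def test_selection_shrinks_mean_absolute_effect(self, nested_fits,
                                                    small_corpus):
        sel, unb = nested_fits["model2"], nested_fits["unbiased"]
        common = set(sel.marker_ids) & set(unb.marker_ids)
        kept = [s for s in small_corpus if s.marker_id in common]
        sel2 = fit(kept, build_model("model2"))
        unb2 = fit(kept, build_model("unbiased"))
        table, summary = corrected_estimates(sel2, unb2)
        assert summary["abs_effect_shrunk"]
        assert summary["tau2_shrunk"]


class TestCovariance:
    def test_full_covariance_assembles_all_blocks(self, nested_fits):
        from selmeta.models import count_parameters

        res = nested_fits["model2"]
        cov = res.full_covariance()
        p, m = len(res.param_names), len(res.marker_ids)
        assert cov.shape == (p + 2 * m, p + 2 * m)
        np.testing.assert_allclose(cov, cov.T)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)[:p]), res.se_w)
        np.testing.assert_allclose(np.sqrt(cov[p, p]), res.se_delta[0])
        # eigenvalues of a covariance are nonnegative (tiny FD noise allowed)
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_parameter_count_matches_aic_bookkeeping(self, nested_fits,
                                                     small_corpus):
        from selmeta.models import count_parameters

        res = nested_fits["model2"]
        kept = [s for s in small_corpus if s.marker_id in set(res.marker_ids)]
        assert res.n_parameters == count_parameters(res.spec, kept)
        assert res.aic == pytest.approx(2 * res.n_parameters - 2 * res.loglik)


class TestSerialization:
    def test_fit_result_json_round_trip(self, nested_fits, tmp_path):
        res = nested_fits["model2"]
        path = tmp_path / "fit.json"
        res.to_json(path)
        with open(path) as fh:
            d = json.load(fh)
        assert d["model_name"] == "model2"
        np.testing.assert_allclose(d["theta_w"], res.theta_w)
        assert d["loglik"] == pytest.approx(res.loglik)
        assert list(d["marker_ids"]) == list(res.marker_ids)
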
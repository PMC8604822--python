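"""Laplace engine: conditional density, quadrature oracles, OFV, EBEs, fits."""
import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import ordlink as o
from ordlink.data import ValidationError
from ordlink.estimate import (
    compile_bundle,
    re_layout,
    _ParamView,
    _cond_ll,
    _newton_modes,
)

from conftest import subject_records


def brute_force_conditional(records, params, eta, variances):
    """Term-by-term re-implementation of the subject conditional log density.

    Pure loops and explicit formulas: cumulative logits from the cutpoint
    cascade, logistic differencing, diagonal-normal prior.  Amounts-variant
    pleasantness and the two driver endpoints only.
    """
    total = 0.0
    for r in records:
        prefix = {"sweetness": "S", "creaminess": "C", "pleasantness": "P"}[r.endpoint]
        base = [params[f"alpha_{prefix}1"]]
        for x in range(2, 9):
            base.append(base[-1] + params[f"alpha_{prefix}{x}_{x + 1}"])
        sugar, fat = r.solution.sugar, r.solution.fat
        if r.endpoint == "sweetness":
            smax_i = params["Smax_Sugar"] * np.exp(eta["eta_Smax"])
            g = [sugar * smax_i / (sugar + params["SSugar50"]) + params["SL_S_Fat"] * fat] * 8
            shift = eta["eta_S_base"]
        elif r.endpoint == "creaminess":
            g = [params["SL_C_Fat"] * fat + params["SL_C_Sugar"] * sugar] * 8
            shift = eta["eta_C_base"]
        else:
            fa = sugar * params["Pmax_Sugar"] / (sugar + params["PSugar50"])
            fb = fat * params["Pmax_Fat"] / (fat + params["PFat50"])
            inter = params["IP_Sugar_Fat"] * (params["wIP_Sugar"] * sugar / 20.0 + fat / 37.5)
            b5 = params["beta_Sugar5"]
            b3, b4, b7 = params["beta_Fat3"], params["beta_Fat4"], params["beta_Fat7"]
            ba = [1, 1, 1, b5, b5, b5, b5, b5]
            bb = [1, b3, b3 * b4, b3 * b4, b3 * b4, b3 * b4 * b7, b3 * b4 * b7, b3 * b4 * b7]
            g = [fa * ba[i] + fb * bb[i] + inter for i in range(8)]
            shift = eta["eta_P_base"]
        L = [base[i] + g[i] + shift for i in range(8)]
        cum = [1.0] + [expit(v) for v in L] + [0.0]
        p = [cum[i] - cum[i + 1] for i in range(9)]
        # the model's smooth floor: 0.5*(p + floor + sqrt((p - floor)^2 + w^2))
        smooth = [0.5 * (q + 1e-10 + np.sqrt((q - 1e-10) ** 2 + 1e-4 ** 2)) for q in p]
        total += np.log(smooth[r.score - 1] / sum(smooth))
    for name, var in variances.items():
        total += norm.logpdf(eta[name], scale=np.sqrt(var))
    return total


class TestConditionalLoglik:
    def test_matches_brute_force_term_sum(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        eta = {"eta_S_base": 0.4, "eta_Smax": -0.3, "eta_C_base": 1.1, "eta_P_base": -0.7}
        variances = {"eta_S_base": 1.34, "eta_Smax": 0.207, "eta_C_base": 4.21, "eta_P_base": 4.21}
        for sid in (1, 3, 6):
            recs = subject_records(dataset, sid)
            got = o.subject_conditional_loglik(recs, ref_amounts, spec, eta)
            want = brute_force_conditional(recs, ref_amounts, eta, variances)
            assert got == pytest.approx(want, abs=1e-9)

    def test_zero_records_is_just_the_prior(self, ref_amounts):
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        got = o.subject_conditional_loglik(
            [o.ScoreRecord(subject_id=1, occasion=1, solution=o.Solution(fat=0, sugar=0),
                           endpoint="pleasantness", score=5)],
            ref_amounts, spec, {"eta_P_base": 0.9})
        # subtracting the single observation term leaves the normal density
        L = o.cumulative_logits(ref_amounts, "pleasantness",
                                o.pleasantness_g_vector((0.0, 0.0), ref_amounts, "amounts"),
                                eta_base=0.9)
        obs = float(o.observation_loglik(5, o.category_probabilities(L).p))
        assert got - obs == pytest.approx(norm.logpdf(0.9, scale=np.sqrt(4.21)), abs=1e-9)

    def test_dimension_mismatch_rejected(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        with pytest.raises(ValidationError):
            o.subject_conditional_loglik(subject_records(dataset, 1), ref_amounts, spec,
                                         np.zeros(2))


class TestLaplaceVsQuadrature:
    def test_agq_one_node_equals_laplace(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        recs = subject_records(dataset, 2, {"pleasantness"})
        lap = o.laplace_marginal_loglik(recs, ref_amounts, spec)
        assert o.agq_marginal_loglik(recs, ref_amounts, spec, 1) == pytest.approx(lap, abs=1e-9)

    def test_laplace_error_bounded_one_dim(self, small_amounts_study, ref_amounts):
        """At the study design the expected-information Laplace value sits
        within ~0.1 of the (quad-validated) AGQ oracle per subject; assert
        the documented bound."""
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        for sid in range(1, 7):
            recs = subject_records(dataset, sid, {"pleasantness"})
            lap = o.laplace_marginal_loglik(recs, ref_amounts, spec)
            agq = o.agq_marginal_loglik(recs, ref_amounts, spec, 41)
            assert lap == pytest.approx(agq, abs=0.2)

    def test_agq_node_convergence(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        recs = subject_records(dataset, 4, {"pleasantness"})
        a11 = o.agq_marginal_loglik(recs, ref_amounts, spec, 11)
        a41 = o.agq_marginal_loglik(recs, ref_amounts, spec, 41)
        assert a11 == pytest.approx(a41, abs=1e-6)

    def test_laplace_close_to_tensor_agq_two_dim(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("sweetness",), variant="amounts")
        for sid in (1, 5):
            recs = subject_records(dataset, sid, {"sweetness"})
            lap = o.laplace_marginal_loglik(recs, ref_amounts, spec)
            agq = o.agq_marginal_loglik(recs, ref_amounts, spec, 21)
            assert lap == pytest.approx(agq, abs=0.2)

    def test_degenerate_prior_reduces_to_conditional_at_zero(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        frozen = ref_amounts.replace(omega2_P=0.0)
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        recs = subject_records(dataset, 3, {"pleasantness"})
        lap = o.laplace_marginal_loglik(recs, frozen, spec)
        agq = o.agq_marginal_loglik(recs, frozen, spec, 11)
        cond = o.subject_conditional_loglik(recs, frozen, spec, np.zeros(0))
        assert lap == pytest.approx(cond, abs=1e-12)
        assert agq == pytest.approx(cond, abs=1e-12)

    def test_high_dimension_rejected(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        with pytest.raises(ValidationError):
            o.agq_marginal_loglik(subject_records(dataset, 1), ref_amounts, spec, 11)


class TestTotalOFV:
    def test_single_subject_and_additivity(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        subsets = {}
        for ids in [(1, 2, 3), (4, 5, 6)]:
            recs = [r for r in dataset.records if r.subject_id in ids]
            subs = [s for s in dataset.subjects if s.id in ids]
            subsets[ids] = o.SFPTDataset(subjects=subs, records=recs)
        whole = o.total_ofv(dataset, ref_amounts, spec)
        parts = sum(o.total_ofv(ds, ref_amounts, spec) for ds in subsets.values())
        assert whole == pytest.approx(parts, abs=1e-6)

        one = o.SFPTDataset(subjects=[dataset.subjects[0]],
                            records=[r for r in dataset.records if r.subject_id == 1])
        lap = o.laplace_marginal_loglik(subject_records(dataset, 1), ref_amounts, spec)
        assert o.total_ofv(one, ref_amounts, spec) == pytest.approx(-2 * lap, abs=1e-6)

    def test_matches_quadrature_oracle_sum(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        ofv = o.total_ofv(dataset, ref_amounts, spec)
        # exact consistency with the per-subject Laplace values
        lap_sum = -2 * sum(
            o.laplace_marginal_loglik(subject_records(dataset, s.id, {"pleasantness"}),
                                      ref_amounts, spec)
            for s in dataset.subjects)
        assert ofv == pytest.approx(lap_sum, abs=1e-8)
        # and within the accumulated genuine Laplace error of the AGQ oracle
        oracle = -2 * sum(
            o.agq_marginal_loglik(subject_records(dataset, s.id, {"pleasantness"}),
                                  ref_amounts, spec, 41)
            for s in dataset.subjects)
        assert ofv == pytest.approx(oracle, abs=6 * 4e-2)

    def test_record_order_invariance(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        shuffled = o.SFPTDataset(subjects=dataset.subjects, records=dataset.records[::-1])
        assert o.total_ofv(shuffled, ref_amounts, spec) == \
            pytest.approx(o.total_ofv(dataset, ref_amounts, spec), abs=1e-9)


class TestEBEs:
    def test_matches_dense_grid_argmax(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        ebes = o.compute_ebes(dataset, ref_amounts, spec)
        bundle = compile_bundle(dataset, spec)
        layout = re_layout(spec, ref_amounts, 2)
        pv = _ParamView(ref_amounts, spec, layout)
        omega = np.sqrt(ref_amounts["omega2_P"])
        for i in (0, 2, 5):
            one = o.SFPTDataset(subjects=[dataset.subjects[i]],
                                records=subject_records(dataset, dataset.subjects[i].id,
                                                        {"pleasantness"}))
            b1 = compile_bundle(one, spec)
            grid = np.linspace(-6 * omega, 6 * omega, 24001)[:, None]
            vals = _cond_ll(b1, pv, grid)
            assert ebes[i].eta["eta_P_base"] == pytest.approx(float(grid[np.argmax(vals), 0]),
                                                              abs=1e-3)

    def test_all_nines_push_baseline_up(self, ref_odds):
        sols = [o.Solution(fat=f, sugar=s) for f in (0.0, 37.5) for s in (0.0, 20.0)]
        recs = [o.ScoreRecord(subject_id=1, occasion=1, solution=sol,
                              endpoint="sweetness", score=9) for sol in sols]
        ds = o.SFPTDataset(subjects=[o.Subject(id=1)], records=recs)
        spec = o.ModelSpec(endpoints=("sweetness",))
        ebes = o.compute_ebes(ds, ref_odds, spec)
        assert ebes[0].eta["eta_S_base"] > 0

    def test_tiny_variance_shrinks_ebe_to_zero(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        tight = ref_amounts.replace(omega2_P=1e-8)
        spec = o.ModelSpec(endpoints=("pleasantness",), variant="amounts")
        ebes = o.compute_ebes(dataset, tight, spec)
        assert all(abs(e.eta["eta_P_base"]) < 1e-3 for e in ebes)

    def test_curvature_positive_definite(self, small_linked_study, ref_odds):
        _, dataset, _ = small_linked_study
        spec = o.ModelSpec(variant="linked")
        for e in o.compute_ebes(dataset, ref_odds, spec):
            assert np.all(np.linalg.eigvalsh(e.curvature) > 0)


class TestFit:
    def test_all_fixed_returns_start_unchanged(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(variant="amounts")
        res = o.fit(dataset, spec, ref_amounts, free=[])
        assert res.params.values == ref_amounts.values
        assert res.n_params == 0
        assert res.aic == res.ofv
        assert res.converged

    def test_single_parameter_refit_moves_toward_optimum(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("creaminess",), variant="amounts")
        start = ref_amounts.replace(SL_C_Fat=0.10)
        res = o.fit(dataset, spec, start, free=["SL_C_Fat"], compute_se=True)
        assert res.converged
        assert res.ofv <= o.total_ofv(dataset, start, spec) + 1e-6
        assert res.n_params == 1
        assert res.aic == pytest.approx(res.ofv + 2)
        assert res.se is not None and res.se["SL_C_Fat"] > 0
        assert res.rse_percent["SL_C_Fat"] == pytest.approx(
            100 * res.se["SL_C_Fat"] / abs(res.params["SL_C_Fat"]))

    def test_freeing_a_parameter_never_hurts_the_ofv(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        spec = o.ModelSpec(endpoints=("creaminess",), variant="amounts")
        narrow = o.fit(dataset, spec, ref_amounts, free=["SL_C_Fat"], compute_se=False)
        wide = o.fit(dataset, spec, ref_amounts, free=["SL_C_Fat", "SL_C_Sugar"],
                     compute_se=False)
        assert wide.ofv <= narrow.ofv + 1e-4


class TestCompareModels:
    def _fit_pair(self, dataset, ref_amounts):
        spec = o.ModelSpec(endpoints=("creaminess",), variant="amounts")
        a = o.fit(dataset, spec, ref_amounts, free=[], compute_se=False)
        return a

    def test_identical_fits(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        a = self._fit_pair(dataset, ref_amounts)
        rep = o.compare_models(a, a)
        assert rep["delta_ofv"] == 0
        assert rep["lrt_p"] == 1.0
        assert rep["equal_params_note"] == "AIC comparison = OFV comparison"

    def test_chi_square_critical_value(self, small_amounts_study, ref_amounts):
        _, dataset, _ = small_amounts_study
        a = self._fit_pair(dataset, ref_amounts)
        import dataclasses
        b = dataclasses.replace(a, ofv=a.ofv - 6.63, n_params=a.n_params + 1)
        rep = o.compare_models(a, b)
        assert rep["lrt_df"] == 1
        assert rep["lrt_p"] == pytest.approx(0.0100, abs=2e-4)
        # 6.63 sits marginally above the exact 0.01 critical value (6.635)
        assert rep["significant"] == (rep["lrt_p"] < rep["alpha"])

    def test_different_datasets_rejected(self, small_amounts_study, small_linked_study,
                                         ref_amounts, ref_odds):
        _, ds_a, _ = small_amounts_study
        _, ds_b, _ = small_linked_study
        spec = o.ModelSpec(endpoints=("creaminess",), variant="amounts")
        a = o.fit(ds_a, spec, ref_amounts, free=[], compute_se=False)
        b = o.fit(ds_b, spec, ref_odds.with_variant("amounts"), free=[], compute_se=False)
        with pytest.raises(ValidationError):
            o.compare_models(a, b)
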
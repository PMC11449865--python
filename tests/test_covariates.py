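"""Covariate screening, likelihood-ratio thresholds and the stepwise
search.  Search-decision logic is additionally exercised against a stubbed
likelihood so boundary semantics are tested exactly."""

import numpy as np
import pandas as pd
import pytest

import pyropk.covariates as cov_mod
from pyropk.cohort import CohortDesign, generate_cohort
from pyropk.covariates import (
    backward_step,
    clinical_relevance,
    forward_step,
    lrt_threshold,
    prescreen_covariates,
    stepwise_search,
)
from pyropk.datatypes import (
    CovariateTerm,
    DosingEvent,
    ModelSpec,
    Observation,
    ResidualErrorSpec,
    SubjectRecord,
    base_model,
    final_model,
)


class TestLrtThreshold:
    def test_published_thresholds(self):
        assert lrt_threshold(0.05) == pytest.approx(3.84, abs=0.005)
        assert lrt_threshold(0.001) == pytest.approx(10.83, abs=0.005)

    def test_vanishes_as_alpha_approaches_one(self):
        assert lrt_threshold(0.9999) < 1e-4

    def test_df_and_domain(self):
        assert lrt_threshold(0.05, df=2) > lrt_threshold(0.05, df=1)
        with pytest.raises(ValueError):
            lrt_threshold(0.0)


class TestPrescreen:
    def make_subjects(self, cov: pd.DataFrame):
        return [
            SubjectRecord(str(i), [DosingEvent(0, 400)], [],
                          cov.iloc[i].to_dict())
            for i in range(len(cov))
        ]

    def test_perfectly_correlated_pair_keeps_one(self, rng):
        wt = rng.normal(60, 8, 40)
        df = pd.DataFrame({"WT": wt, "BMI": 0.4 * wt - 1.0})
        report = prescreen_covariates(self.make_subjects(df))
        assert report.retained == ["WT"]
        assert "BMI" in report.dropped

    def test_synthetic_cohort_screening_fires(self, final_spec):
        # generator induces corr(WT, BMI) > 0.7, so BMI must fall to WT
        sim = generate_cohort(CohortDesign(n_subjects=200), final_spec, seed=3)
        report = prescreen_covariates(sim.subjects)
        assert report.correlation.loc["WT", "BMI"] > 0.7
        assert "WT" in report.retained and "BMI" in report.dropped
        assert "TP" in report.retained
        assert "ALT" in report.dropped and "AST" in report.retained
        assert "DBIL" in report.dropped and "TBIL" in report.retained

    def test_rare_category_rule(self, rng):
        n = 50
        base_cols = {"AGE": rng.normal(55, 8, n), "WT": rng.normal(60, 8, n)}
        df = pd.DataFrame({**base_cols,
                           "MP": (np.arange(n) < 9).astype(float),    # 18 %
                           "LC": (np.arange(n) < 4).astype(float)})   # 8 %
        report = prescreen_covariates(self.make_subjects(df))
        assert "MP" in report.retained
        assert "LC" in report.dropped

    def test_missingness_rule(self, rng):
        n = 50
        tp = rng.normal(67, 5, n)
        tp[:11] = np.nan  # 22 % missing
        df = pd.DataFrame({"TP": tp, "WT": rng.normal(60, 8, n)})
        report = prescreen_covariates(self.make_subjects(df))
        assert "TP" in report.dropped
        assert "22" in report.dropped["TP"]

    def test_constant_covariate_warns_and_is_retained(self, rng):
        df = pd.DataFrame({"AGE": np.full(30, 55.0),
                           "WT": rng.normal(60, 8, 30)})
        with pytest.warns(UserWarning, match="constant"):
            report = prescreen_covariates(self.make_subjects(df))
        assert "AGE" in report.retained

    def test_every_drop_has_reason(self, final_spec):
        sim = generate_cohort(CohortDesign(n_subjects=100), final_spec, seed=5)
        report = prescreen_covariates(sim.subjects)
        all_names = set(sim.subjects[0].covariates)
        assert set(report.retained) | set(report.dropped) == all_names
        assert all(report.dropped.values())


class _StubFit:
    def __init__(self, ofv, spec):
        self.ofv = ofv
        self.spec = spec
        self.converged = True


def _stub_fit_factory(ofv_by_terms):
    """fit_foce replacement mapping frozenset of (param, cov) -> OFV."""

    def fake_fit(subjects, spec, maxiter=None, **kw):
        key = frozenset((t.parameter, t.covariate) for t in spec.covariate_terms)
        return _StubFit(ofv_by_terms[key], spec)

    return fake_fit


@pytest.fixture
def stub_subjects():
    return [
        SubjectRecord(f"S{i}", [DosingEvent(0, 400)],
                      [Observation(4.0, 50.0)], {"TP": 60.0 + i, "HT": 158.0})
        for i in range(4)
    ]


class TestSearchDecisionLogic:
    def test_forward_accepts_largest_significant_drop(self, monkeypatch,
                                                      stub_subjects):
        base = base_model()
        ofvs = {
            frozenset(): -837.585,
            frozenset({("CL", "TP")}): -849.969,  # drop 12.384 > 3.84
            frozenset({("V", "HT")}): -840.0,     # drop 2.415 < 3.84
        }
        monkeypatch.setattr(cov_mod, "fit_foce", _stub_fit_factory(ofvs))
        spec, ofv, accepted, rows = forward_step(
            stub_subjects, base, -837.585,
            [("CL", "TP", "exponential"), ("V", "HT", "exponential")],
        )
        assert accepted == ("CL", "TP", "exponential")
        assert ofv == pytest.approx(-849.969)

    def test_forward_boundary_equality_not_accepted(self, monkeypatch,
                                                    stub_subjects):
        base = base_model()
        thr = lrt_threshold(0.05)
        ofvs = {frozenset(): 0.0, frozenset({("CL", "TP")}): -thr}
        monkeypatch.setattr(cov_mod, "fit_foce", _stub_fit_factory(ofvs))
        _, _, accepted, _ = forward_step(
            stub_subjects, base, 0.0, [("CL", "TP", "exponential")]
        )
        assert accepted is None  # strict inequality at the threshold

    def test_backward_boundary_equality_removes_term(self, monkeypatch,
                                                     stub_subjects):
        thr = lrt_threshold(0.001)
        full = base_model()
        full.covariate_terms = [CovariateTerm("CL", "TP", "exponential", 0.3, 67.2)]
        ofvs = {frozenset({("CL", "TP")}): -thr, frozenset(): 0.0}
        monkeypatch.setattr(cov_mod, "fit_foce", _stub_fit_factory(ofvs))
        spec, ofv, rows = backward_step(stub_subjects, full, -thr)
        assert spec.covariate_terms == []  # rise of exactly 10.83 → removed

    def test_backward_retains_strongly_supported_term(self, monkeypatch,
                                                      stub_subjects):
        full = base_model()
        full.covariate_terms = [CovariateTerm("CL", "TP", "exponential", 0.3, 67.2)]
        ofvs = {frozenset({("CL", "TP")}): -850.0, frozenset(): -837.0}
        monkeypatch.setattr(cov_mod, "fit_foce", _stub_fit_factory(ofvs))
        spec, _, _ = backward_step(stub_subjects, full, -850.0)
        assert len(spec.covariate_terms) == 1

    def test_backward_without_terms_is_noop(self, stub_subjects):
        spec, ofv, rows = backward_step(stub_subjects, base_model(), -100.0)
        assert spec.covariate_terms == [] and rows == []

    def test_empty_candidate_set_yields_base_only_trace(self, monkeypatch,
                                                        stub_subjects):
        ofvs = {frozenset(): -837.585}
        monkeypatch.setattr(cov_mod, "fit_foce", _stub_fit_factory(ofvs))
        trace = stepwise_search(stub_subjects, base_model(), [])
        df = trace.to_frame()
        assert list(df["direction"]) == ["base", "final"]
        assert trace.final_spec.covariate_terms == []


@pytest.fixture(scope="module")
def cohort_with_drh_effect():
    """Cohort with a strong true covariate signal: clearance doubled in
    subjects with diarrhea (a detectable effect at this cohort size, unlike
    the subtle total-protein relation, whose interval estimate spans zero
    even in the source study)."""
    design = CohortDesign(
        n_subjects=60, samples_per_subject=4, total_observations=240,
        dose_levels=(400.0,), dose_proportions=(1.0,), n_days=14,
        dose_reduction_fraction=0.0,
    )
    gen = base_model(cl=88.8, v=3940.0, omega_cl=0.515, omega_v=0.965,
                     sigma_p=0.27)
    gen.covariate_terms = [CovariateTerm("CL", "DRH", "categorical", 2.0)]
    return generate_cohort(design, gen, seed=101).subjects


class TestSearchOnSyntheticData:
    def test_true_effect_enters_and_survives(self, cohort_with_drh_effect):
        candidates = [("CL", "DRH", "categorical"), ("V", "HT", "exponential"),
                      ("CL", "HT", "exponential")]
        trace = stepwise_search(
            cohort_with_drh_effect, base_model(), candidates, maxiter=250
        )
        final_terms = {(t.parameter, t.covariate)
                       for t in trace.final_spec.covariate_terms}
        assert ("CL", "DRH") in final_terms
        assert ("V", "HT") not in final_terms and ("CL", "HT") not in final_terms
        coef = trace.final_spec.covariate_terms[0].theta2
        assert coef == pytest.approx(2.0, rel=0.25)

    def test_forward_trace_ofv_monotone(self, cohort_with_drh_effect):
        candidates = [("CL", "DRH", "categorical"), ("CL", "HT", "exponential")]
        trace = stepwise_search(
            cohort_with_drh_effect, base_model(), candidates, maxiter=250
        )
        df = trace.to_frame()
        accepted = df[df["decision"].isin(["start", "accepted"])]
        ofvs = accepted["ofv"].to_numpy()
        assert np.all(np.diff(ofvs) <= 1e-6)

    def test_full_model_strategy_reaches_same_conclusion(self,
                                                         cohort_with_drh_effect):
        candidates = [("CL", "DRH", "categorical"), ("CL", "HT", "exponential")]
        trace = stepwise_search(
            cohort_with_drh_effect, base_model(), candidates, maxiter=250,
            strategy="full-model",
        )
        final_terms = {(t.parameter, t.covariate)
                       for t in trace.final_spec.covariate_terms}
        assert ("CL", "DRH") in final_terms
        assert ("CL", "HT") not in final_terms


class TestClinicalRelevance:
    def _subjects_with_tp_range(self):
        tps = [49.0, 60.0, 67.2, 75.0, 80.7]
        return [SubjectRecord(str(i), [DosingEvent(0, 400)], [], {"TP": tp})
                for i, tp in enumerate(tps)]

    def test_tp_term_not_clinically_relevant(self):
        spec = final_model()
        table = clinical_relevance(spec, self._subjects_with_tp_range())
        row = table.iloc[0]
        assert row["change_at_min_percent"] == pytest.approx(-9.7, abs=0.1)
        assert row["change_at_max_percent"] == pytest.approx(7.8, abs=0.1)
        assert not row["clinically_relevant"]

    def test_zero_coefficient_gives_zero_change(self):
        spec = final_model(tp_coefficient=0.0)
        table = clinical_relevance(spec, self._subjects_with_tp_range())
        assert table.iloc[0]["max_abs_change_percent"] == pytest.approx(0.0)

    def test_categorical_term_25_percent_is_relevant(self):
        spec = base_model()
        spec.covariate_terms = [CovariateTerm("CL", "DRH", "categorical", 1.25)]
        subjects = [SubjectRecord(str(i), [DosingEvent(0, 400)], [],
                                  {"DRH": float(i % 2)}) for i in range(10)]
        row = clinical_relevance(spec, subjects).iloc[0]
        assert row["max_abs_change_percent"] == pytest.approx(25.0)
        assert row["clinically_relevant"]

    def test_model_without_terms_raises(self):
        with pytest.raises(ValueError):
            clinical_relevance(base_model(), self._subjects_with_tp_range())
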
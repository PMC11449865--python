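"""scikit-learn style estimators wrapping the FOCE-I engine.

:class:`PopPKModel` is the package's central object: configure the model
structure in the constructor, ``fit`` a NONMEM-style rectangular dataset
(or a list of :class:`~pyropk.datatypes.SubjectRecord`), and read the
estimates off trailing-underscore attributes.  It composes with sklearn
tooling (``get_params``/``set_params``/``clone``); ``predict`` returns
population-level concentration predictions for the observation rows of the
input data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import CovariateTerm, ModelSpec, ResidualErrorSpec, SubjectRecord
from .foce import (
    FitResult,
    PackedDataset,
    _pred_concentrations,
    fit_foce,
    pack_dataset,
    typical_value_arrays,
)


def _coerce_subjects(X) -> list[SubjectRecord]:
    from .io import frame_to_subjects

    if isinstance(X, pd.DataFrame):
        return frame_to_subjects(X)
    if isinstance(X, (list, tuple)) and all(isinstance(s, SubjectRecord) for s in X):
        return list(X)
    raise TypeError(
        "X must be a NONMEM-style DataFrame or a list of SubjectRecord"
    )


class PopPKModel(BaseEstimator):
    """One-compartment oral population-PK model estimated by FOCE-I.

    Parameters
    ----------
    cl, v, ka : float
        Initial typical values for CL/F (L/h), V/F (L) and Ka (1/h).
    fix_ka : bool
        Freeze Ka during estimation (the study fixes Ka = 0.357 h⁻¹ because
        almost no absorption-phase samples exist to support it).
    omega_cl, omega_v : float
        Initial between-subject SDs (lognormal scale).  Set to 0 to remove
        the random effect from that parameter.
    error : {"proportional", "additive", "combined"}
    sigma_p, sigma_a : float
        Initial residual SDs (proportional fraction / additive ng/mL).
    covariate_terms : list of CovariateTerm or (parameter, covariate, form,
        theta2, median) tuples, optional
    compute_se : bool
        Also compute sandwich RSE% (adds a Hessian's worth of likelihood
        evaluations).
    maxiter : int, optional
        Cap on outer optimizer iterations per stage.

    Attributes
    ----------
    theta_ : dict — typical values {CL, V, KA}
    covariate_coefficients_ : dict — fitted θ2 per term, keyed "COV-PARAM"
    omega_ : dict — between-subject SDs
    sigma_ : dict — residual SDs
    ofv_ : float — objective function value (NONMEM convention)
    converged_ : bool
    ebes_ : DataFrame — empirical Bayes η̂ per subject
    pred_, ipred_, cwres_ : arrays over non-excluded observations
    eta_shrinkage_, eps_shrinkage_ : diagnostics (%)
    rse_ : dict or None — RSE% when ``compute_se``
    result_ : FitResult — the full fit object
    """

    def __init__(
        self,
        cl: float = 127.0,
        v: float = 3900.0,
        ka: float = 0.357,
        fix_ka: bool = True,
        omega_cl: float = 0.5,
        omega_v: float = 0.9,
        error: str = "proportional",
        sigma_p: float = 0.3,
        sigma_a: float = 0.0,
        covariate_terms=None,
        compute_se: bool = False,
        maxiter: int | None = None,
    ):
        self.cl = cl
        self.v = v
        self.ka = ka
        self.fix_ka = fix_ka
        self.omega_cl = omega_cl
        self.omega_v = omega_v
        self.error = error
        self.sigma_p = sigma_p
        self.sigma_a = sigma_a
        self.covariate_terms = covariate_terms
        self.compute_se = compute_se
        self.maxiter = maxiter

    # -- model-spec plumbing ------------------------------------------------

    def _terms(self) -> list[CovariateTerm]:
        out = []
        for t in self.covariate_terms or []:
            out.append(t if isinstance(t, CovariateTerm) else CovariateTerm(*t))
        return out

    def build_spec(self) -> ModelSpec:
        """The ModelSpec encoding this estimator's structure and initials."""
        omega = {}
        if self.omega_cl > 0:
            omega["CL"] = self.omega_cl
        if self.omega_v > 0:
            omega["V"] = self.omega_v
        return ModelSpec(
            theta={"CL": self.cl, "V": self.v, "KA": self.ka},
            omega=omega,
            error=ResidualErrorSpec(
                self.error, sigma_p=self.sigma_p, sigma_a=self.sigma_a
            ),
            covariate_terms=self._terms(),
            fixed=frozenset({"KA"}) if self.fix_ka else frozenset(),
        )

    @classmethod
    def from_spec(cls, spec: ModelSpec, **kwargs) -> "PopPKModel":
        return cls(
            cl=spec.theta["CL"],
            v=spec.theta["V"],
            ka=spec.theta["KA"],
            fix_ka="KA" in spec.fixed,
            omega_cl=spec.omega.get("CL", 0.0),
            omega_v=spec.omega.get("V", 0.0),
            error=spec.error.form,
            sigma_p=spec.error.sigma_p,
            sigma_a=spec.error.sigma_a,
            covariate_terms=list(spec.covariate_terms) or None,
            **kwargs,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None) -> "PopPKModel":
        """Estimate the free parameters from a longitudinal dataset.

        ``X`` is a NONMEM-style DataFrame (ID/TIME/AMT/DV/EVID + covariate
        columns) or a list of SubjectRecord; ``y`` is ignored (the response
        lives inside the dataset, as is idiomatic for longitudinal data).
        """
        subjects = _coerce_subjects(X)
        result: FitResult = fit_foce(
            subjects,
            self.build_spec(),
            maxiter=self.maxiter,
            compute_se=self.compute_se,
        )
        self.result_ = result
        self.theta_ = result.theta
        self.covariate_coefficients_ = result.covariate_coefficients
        self.omega_ = result.omega
        self.sigma_ = result.sigma
        self.ofv_ = result.ofv
        self.converged_ = result.converged
        self.ebes_ = pd.DataFrame(
            result.ebes,
            index=result.ids,
            columns=[f"eta_{p}" for p in result.spec.random_effects],
        )
        self.pred_ = result.pred
        self.ipred_ = result.ipred
        self.cwres_ = result.cwres
        self.eta_shrinkage_ = result.eta_shrinkage
        self.eps_shrinkage_ = result.eps_shrinkage
        self.rse_ = result.rse
        self.n_features_in_ = 1
        return self

    @property
    def fitted_spec_(self) -> ModelSpec:
        return self.result_.spec

    def predict(self, X) -> np.ndarray:
        """Population predictions (η = 0) for the observation rows of X."""
        if not hasattr(self, "result_"):
            raise AttributeError("PopPKModel instance is not fitted yet")
        packed = pack_dataset(_coerce_subjects(X))
        cl_t, v_t, ka_t = typical_value_arrays(self.result_.spec, packed)
        return _pred_concentrations(packed, cl_t, v_t, ka_t)[packed.obs_mask]

    def score(self, X, y=None) -> float:
        """Negative OFV on a dataset (higher is better, sklearn convention)."""
        from .foce import foce_ofv

        return -foce_ofv(_coerce_subjects(X), self.result_.spec)

    def parameter_table(self) -> pd.DataFrame:
        return self.result_.parameter_table()
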
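"""One-compartment oral PK model: structural prediction, covariate submodels,
individual-parameter model and residual-error variance.

The structural model is first-order absorption into a single central
compartment with first-order elimination.  For one dose D (mg) given at time
t0, with k = CL/V,

    C(t) = (1000·D)·Ka / (V·(Ka − k)) · (e^{−k·Δt} − e^{−Ka·Δt}),  Δt = t − t0,

in ng/mL (the factor 1000 converts mg to µg; with V in L, µg/L ≡ ng/mL).
The model is linear in dose, so arbitrary dosing histories — including the
real-world 400→320→240 mg reductions — are handled by superposition of this
single-dose solution; no steady-state shortcut is used.  The removable
singularity at Ka = k is replaced by its analytic limit
C(t) = (1000·D)·k·Δt·e^{−k·Δt}/V when |Ka − k| < 1e−8·k.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .datatypes import (
    CovariateTerm,
    DosingEvent,
    ModelSpec,
    ResidualErrorSpec,
    StructuralParams,
)

MG_TO_UG = 1000.0
_KA_DEGENERACY_RTOL = 1e-8


def covariate_effect(
    form: str,
    theta1: float,
    theta2: float,
    cov_value: float,
    cov_median: float = 1.0,
) -> float:
    """Evaluate one covariate–parameter relation.

    linear:       θ1 + θ2·(cov/med)
    power:        θ1·(cov/med)^θ2
    exponential:  θ1·exp(θ2·cov/med)
    categorical:  θ1·θ2^cov          (cov ∈ {0, 1}, raw, no centering)
    """
    if theta1 <= 0:
        raise ValueError("theta1 must be > 0")
    if form == "categorical":
        value = theta1 * theta2**cov_value
    else:
        if cov_median <= 0:
            raise ValueError("cov_median must be > 0 for continuous forms")
        x = cov_value / cov_median
        if form == "linear":
            value = theta1 + theta2 * x
        elif form == "power":
            value = theta1 * x**theta2
        elif form == "exponential":
            value = theta1 * math.exp(theta2 * x)
        else:
            raise ValueError(f"unknown covariate form {form!r}")
    if value <= 0:
        raise ValueError(
            f"covariate relation {form} produced non-positive parameter {value}"
        )
    return value


def typical_parameters(
    spec: ModelSpec, covariates: dict[str, float]
) -> dict[str, float]:
    """Typical (population) parameter values after all covariate terms."""
    values = dict(spec.theta)
    for term in spec.covariate_terms:
        cov = covariates.get(term.covariate, math.nan)
        if cov is None or (isinstance(cov, float) and math.isnan(cov)):
            raise ValueError(
                f"covariate {term.covariate!r} required by the model is missing"
            )
        values[term.parameter] = covariate_effect(
            term.form, values[term.parameter], term.theta2, cov, term.median
        )
    return values


def individual_parameters(
    spec: ModelSpec,
    covariates: dict[str, float],
    eta: dict[str, float] | None = None,
) -> StructuralParams:
    """Individual parameters P_i = P_typical(cov) · e^{η}; parameters without
    a random effect use η = 0."""
    eta = eta or {}
    tv = typical_parameters(spec, covariates)
    out = {
        p.lower(): tv[p] * math.exp(eta.get(p, 0.0)) for p in ("CL", "V", "KA")
    }
    return StructuralParams(**out)


def predict_concentration(
    doses: Sequence[DosingEvent],
    params: StructuralParams,
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Concentration (ng/mL) at ``times`` by superposition over the dosing
    history; 0 before the first dose."""
    t = np.asarray(times, dtype=float)
    dose_t = np.array([d.time for d in doses], dtype=float)
    amt_ug = np.array([d.amount for d in doses], dtype=float) * MG_TO_UG
    dt = t[:, None] - dose_t[None, :]
    return _superpose(dt, amt_ug, params.cl, params.v, params.ka)


def _superpose(
    dt: np.ndarray, amt_ug: np.ndarray, cl: float, v: float, ka: float
) -> np.ndarray:
    k = cl / v
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    if abs(ka - k) < _KA_DEGENERACY_RTOL * k:
        contrib = amt_ug * k * dtp * np.exp(-k * dtp) / v
    else:
        contrib = (
            amt_ug
            * ka
            / (v * (ka - k))
            * (np.exp(-k * dtp) - np.exp(-ka * dtp))
        )
    return np.sum(np.where(active, contrib, 0.0), axis=-1)


def residual_variance(error: ResidualErrorSpec, ipred: float | np.ndarray):
    """Residual-error variance (ng/mL)² at an individual prediction.

    proportional: σ_p²·IPRED²; additive: σ_a²; combined: the sum.
    """
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be >= 0")
    if error.form == "proportional":
        out = error.sigma_p**2 * ipred**2
    elif error.form == "additive":
        out = np.full_like(ipred, error.sigma_a**2)
    else:
        out = error.sigma_p**2 * ipred**2 + error.sigma_a**2
    return out if out.ndim else float(out)


def predict_concentration_two_compartment(
    doses: Sequence[DosingEvent],
    cl: float,
    v1: float,
    q: float,
    v2: float,
    ka: float,
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Two-compartment oral model (triexponential closed form), provided as
    the structural comparator for base-model selection; the one-compartment
    model is the production structure.

    cl: elimination clearance CL/F (L/h); v1: central volume (L);
    q: inter-compartmental clearance (L/h); v2: peripheral volume (L).
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    for pair in ((ka, alpha), (ka, beta), (alpha, beta)):
        if abs(pair[0] - pair[1]) < 1e-10 * max(pair[0], pair[1]):
            raise ValueError("degenerate rate constants in two-compartment form")
    t = np.asarray(times, dtype=float)
    dose_t = np.array([d.time for d in doses], dtype=float)
    amt_ug = np.array([d.amount for d in doses], dtype=float) * MG_TO_UG
    dt = t[:, None] - dose_t[None, :]
    active = dt > 0
    dtp = np.where(active, dt, 0.0)
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    cc = (k21 - ka) / ((alpha - ka) * (beta - ka))
    shape = (
        ca * np.exp(-alpha * dtp)
        + cb * np.exp(-beta * dtp)
        + cc * np.exp(-ka * dtp)
    )
    contrib = amt_ug * ka / v1 * shape
    return np.sum(np.where(active, contrib, 0.0), axis=-1)


def derive_secondary(params: StructuralParams) -> dict[str, float]:
    """Elimination rate constant k = CL/V (1/h) and half-life t½ = ln2/k (h)."""
    k = params.cl / params.v
    return {"k_elim": k, "half_life": math.log(2) / k}
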
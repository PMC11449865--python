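"""Domain containers shared across the package.

Units follow the oral-dosing convention used throughout: dose amounts in mg,
volumes in L, clearances in L/h, times in hours since a subject's first dose,
concentrations in ng/mL (numerically equal to µg/L). Apparent parameters
CL/F and V/F are the native quantities — oral data cannot separate
bioavailability F, so F never appears as its own symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: continuous baseline covariates collected in the study
CONTINUOUS_COVARIATES = (
    "AGE", "HT", "WT", "BMI", "NA", "K", "ALB", "GLB", "TP",
    "AST", "ALT", "TBIL", "DBIL", "IBIL", "SCR",
)
#: dichotomous baseline covariates (0/1)
CATEGORICAL_COVARIATES = ("DRH", "MP", "LC", "ER", "PR")

CovariateForm = Literal["linear", "power", "exponential", "categorical"]
ErrorForm = Literal["proportional", "additive", "combined"]


@dataclass(frozen=True)
class DosingEvent:
    """A single oral dose: ``time`` hours since first dose, ``amount`` mg."""

    time: float
    amount: float
    interval: float | None = None  # repeat interval (h) when part of a schedule

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class Observation:
    """One measured concentration (ng/mL); ``blq`` marks values below LLOQ."""

    time: float
    concentration: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class SubjectRecord:
    """One subject's dosing history, observations and baseline covariates.

    Covariates are stored as a plain mapping; missing values are ``nan`` so
    missingness can be counted for the 20 %-missing exclusion rule.
    """

    id: str
    doses: list[DosingEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.doses and self.observations:
            raise ValueError(f"subject {self.id}: observations without any dose")
        if self.doses and self.observations:
            first_dose = min(d.time for d in self.doses)
            for obs in self.observations:
                if obs.time < first_dose:
                    raise ValueError(
                        f"subject {self.id}: observation at t={obs.time} "
                        f"precedes first dose at t={first_dose}"
                    )


@dataclass(frozen=True)
class StructuralParams:
    """One-compartment oral parameters: CL/F (L/h), V/F (L), Ka (1/h)."""

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual-error model: proportional, additive, or combined.

    ``sigma_p`` is the proportional SD (unitless fraction; 0.27 ~ 27 %CV),
    ``sigma_a`` the additive SD in ng/mL.
    """

    form: ErrorForm = "proportional"
    sigma_p: float = 0.0
    sigma_a: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual error form {self.form!r}")
        if self.sigma_p < 0 or self.sigma_a < 0:
            raise ValueError("error SDs must be >= 0")


@dataclass(frozen=True)
class CovariateTerm:
    """A covariate–parameter relation θ_i = g(θ1, θ2, cov).

    ``form``: linear θ1+θ2·(cov/med); power θ1·(cov/med)^θ2;
    exponential θ1·exp(θ2·cov/med); categorical θ1·θ2^cov (cov ∈ {0,1},
    no centering).
    """

    parameter: Literal["CL", "V", "KA"]
    covariate: str
    form: CovariateForm
    theta2: float
    median: float = 1.0

    def __post_init__(self) -> None:
        if self.form != "categorical" and self.median <= 0:
            raise ValueError("centering median must be > 0 for continuous forms")


@dataclass
class ModelSpec:
    """Full model definition: typical values, random effects, residual error,
    covariate terms, and which fixed effects are frozen during estimation.

    ``omega`` holds between-subject SDs (lognormal scale) keyed by parameter;
    parameters absent from ``omega`` carry no random effect. %CV reporting
    convention: BSV %CV = 100·ω and proportional residual %CV = 100·σ_p.
    """

    theta: dict[str, float]
    omega: dict[str, float] = field(default_factory=dict)
    error: ResidualErrorSpec = field(default_factory=ResidualErrorSpec)
    covariate_terms: list[CovariateTerm] = field(default_factory=list)
    fixed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for p, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega[{p}] must be >= 0")
        seen = set()
        for t in self.covariate_terms:
            key = (t.parameter, t.covariate)
            if key in seen:
                raise ValueError(f"duplicate covariate term for {key}")
            seen.add(key)

    @property
    def random_effects(self) -> tuple[str, ...]:
        return tuple(p for p in ("CL", "V", "KA") if p in self.omega)

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            theta=dict(self.theta),
            omega=dict(self.omega),
            error=self.error,
            covariate_terms=list(self.covariate_terms),
            fixed=self.fixed,
        )


def base_model(
    cl: float = 127.0,
    v: float = 3900.0,
    ka: float = 0.357,
    omega_cl: float = 0.5,
    omega_v: float = 0.9,
    sigma_p: float = 0.3,
) -> ModelSpec:
    """Covariate-free one-compartment model with Ka fixed, BSV on CL and V,
    and proportional residual error."""
    return ModelSpec(
        theta={"CL": cl, "V": v, "KA": ka},
        omega={"CL": omega_cl, "V": omega_v},
        error=ResidualErrorSpec("proportional", sigma_p=sigma_p),
        fixed=frozenset({"KA"}),
    )


def final_model(
    cl: float = 88.8,
    v: float = 3940.0,
    ka: float = 0.357,
    tp_coefficient: float = 0.376,
    tp_median: float = 67.2,
    omega_cl: float = 0.515,
    omega_v: float = 0.965,
    sigma_p: float = 0.270,
) -> ModelSpec:
    """Final pyrotinib model: CL/F = θ1·exp(θ2·TP/67.2), V/F and Ka as in the
    base structure, Ka fixed at 0.357 h⁻¹."""
    return ModelSpec(
        theta={"CL": cl, "V": v, "KA": ka},
        omega={"CL": omega_cl, "V": omega_v},
        error=ResidualErrorSpec("proportional", sigma_p=sigma_p),
        covariate_terms=[
            CovariateTerm("CL", "TP", "exponential", tp_coefficient, tp_median)
        ],
        fixed=frozenset({"KA"}),
    )


def expand_doses(doses: list[DosingEvent], until: float) -> list[DosingEvent]:
    """Unroll scheduled repeats (``interval``) into explicit events up to
    time ``until`` (inclusive)."""
    out: list[DosingEvent] = []
    for d in doses:
        if d.interval is None:
            out.append(d)
        else:
            t = d.time
            while t <= until:
                out.append(DosingEvent(t, d.amount))
                t += d.interval
    return sorted(out, key=lambda d: d.time)
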
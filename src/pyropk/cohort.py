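"""Virtual study cohorts with the statistical structure the analysis assumes.

The clinical dataset behind the model (50 HER2-positive breast-cancer
patients, 158 opportunistic steady-state samples under once-daily oral
240/320/400 mg dosing) is not publicly deposited, so every pipeline stage is
exercised against synthetic cohorts generated here: baseline covariates drawn
from the published summary distributions (median and range, with correlated
blocks and skewed margins), explicit multi-dose histories simulated to steady
state, sparse opportunistic sampling, lognormal between-subject variability
and proportional residual error, and an LLOQ censoring rule at 1 ng/mL.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    DosingEvent,
    ModelSpec,
    Observation,
    SubjectRecord,
)
from .foce import compute_cwres, pack_dataset
from .pkmodel import predict_concentration, individual_parameters

#: median and observed range of each continuous baseline covariate
COVARIATE_SUMMARIES: dict[str, tuple[float, float, float]] = {
    "AGE": (53.0, 34.0, 68.0),
    "HT": (158.0, 150.0, 166.0),
    "WT": (61.5, 52.5, 86.0),
    "BMI": (24.2, 17.0, 31.6),
    "NA": (138.6, 123.2, 145.2),
    "K": (4.1, 2.27, 5.47),
    "ALB": (41.4, 12.2, 51.5),
    "GLB": (26.1, 15.1, 38.1),
    "TP": (67.2, 49.0, 80.7),
    "AST": (19.8, 11.8, 327.1),
    "ALT": (16.7, 6.6, 193.6),
    "TBIL": (8.0, 3.3, 77.0),
    "DBIL": (2.2, 0.1, 49.9),
    "IBIL": (5.3, 0.3, 27.1),
    "SCR": (60.5, 30.8, 419.0),
}

#: right-skewed laboratory covariates drawn log-normally.  AST, TBIL and SCR
#: are skewed in the source cohort; their correlated partners ALT, DBIL and
#: IBIL share ranges spanning >1 decade, so a truncated-normal margin cannot
#: hit both the median and the range and they are drawn log-normally too.
SKEWED_COVARIATES = frozenset({"AST", "ALT", "TBIL", "DBIL", "IBIL", "SCR"})

#: prevalence of each dichotomous covariate
CATEGORICAL_PREVALENCE = {"DRH": 0.48, "MP": 0.18, "LC": 0.30, "ER": 0.56, "PR": 0.50}

#: correlated covariate blocks induced through a Gaussian copula
CORRELATED_PAIRS = {
    ("WT", "BMI"): 0.85,
    ("WT", "HT"): 0.75,
    ("BMI", "HT"): 0.75,
    ("AST", "ALT"): 0.80,
    ("TBIL", "DBIL"): 0.80,
    ("TBIL", "IBIL"): 0.80,
    ("DBIL", "IBIL"): 0.80,
}


@dataclass
class CohortDesign:
    """Study design: cohort size, dosing, sampling scheme, LLOQ.

    With ``samples_per_subject`` unset, per-subject sample counts are
    allocated so the cohort totals exactly ``total_observations`` (158 at
    n=50 ≈ 3.16/subject, the sparse opportunistic scheme); setting it gives
    every subject the same richer schedule.
    """

    n_subjects: int = 50
    total_observations: int = 158
    samples_per_subject: int | None = None
    dose_levels: tuple[float, ...] = (240.0, 320.0, 400.0)
    dose_proportions: tuple[float, ...] = (0.2, 0.3, 0.5)
    dosing_interval: float = 24.0
    n_days: int = 20
    steady_state_day: int = 14        # samples drawn on/after this dose number
    dose_reduction_fraction: float = 0.15
    sample_window: tuple[float, float] = (0.5, 24.0)
    lloq: float = 1.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.dose_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("dose proportions must sum to 1")
        if self.lloq <= 0:
            raise ValueError("LLOQ must be > 0")
        if not set(self.dose_levels) <= {240.0, 320.0, 400.0}:
            warnings.warn("dose levels outside the studied 240/320/400 mg set")
        if self.n_days < self.steady_state_day:
            raise ValueError("n_days must reach the steady-state day")


def recovery_design(n_subjects: int = 200, samples_per_subject: int = 6) -> CohortDesign:
    """Rich design for simulate-then-refit parameter recovery: 400 mg QD to
    steady state, uniform (0.5, 24] h post-dose sampling."""
    return CohortDesign(
        n_subjects=n_subjects,
        samples_per_subject=samples_per_subject,
        total_observations=n_subjects * samples_per_subject,
        dose_levels=(400.0,),
        dose_proportions=(1.0,),
        n_days=14,
        dose_reduction_fraction=0.0,
    )


@dataclass
class SimulatedDataset:
    """Simulated cohort plus the ground truth needed to recompute it."""

    subjects: list[SubjectRecord]
    truth: dict = field(default_factory=dict)
    n_generated: int = 0
    n_blq: int = 0
    n_eps_resampled: int = 0


def _copula_correlation(columns: list[str]) -> np.ndarray:
    n = len(columns)
    R = np.eye(n)
    idx = {c: i for i, c in enumerate(columns)}
    for (a, b), r in CORRELATED_PAIRS.items():
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    vals = np.linalg.eigvalsh(R)
    if vals.min() <= 0:
        warnings.warn("correlation target not PSD; repairing by eigenvalue clipping")
        w, V = np.linalg.eigh(R)
        R = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def generate_covariates(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Baseline covariate table: truncated-normal margins parameterized by
    median (as location) and range (as ±3 SD truncation), log-normal margins
    for the skewed laboratory values, correlated blocks via a Gaussian
    copula, and Bernoulli dichotomous flags at the published prevalences."""
    rng = np.random.default_rng(seed)
    cols = list(CONTINUOUS_COVARIATES)
    R = _copula_correlation(cols)
    z = rng.multivariate_normal(np.zeros(len(cols)), R, size=design.n_subjects,
                                method="cholesky")
    u = stats.norm.cdf(z)
    data = {}
    for j, name in enumerate(cols):
        med, lo, hi = COVARIATE_SUMMARIES[name]
        if name in SKEWED_COVARIATES:
            loc = math.log(med)
            scale = (math.log(hi) - math.log(lo)) / 6.0
            a = (math.log(lo) - loc) / scale
            b = (math.log(hi) - loc) / scale
            data[name] = np.exp(stats.truncnorm.ppf(u[:, j], a, b, loc, scale))
        else:
            scale = (hi - lo) / 6.0
            a = (lo - med) / scale
            b = (hi - med) / scale
            data[name] = stats.truncnorm.ppf(u[:, j], a, b, med, scale)
    for name in CATEGORICAL_COVARIATES:
        p = CATEGORICAL_PREVALENCE[name]
        data[name] = (rng.random(design.n_subjects) < p).astype(float)
    ids = [f"S{i + 1:03d}" for i in range(design.n_subjects)]
    return pd.DataFrame(data, index=ids)


def generate_design(
    design: CohortDesign, seed: int, covariates: pd.DataFrame | None = None
) -> list[SubjectRecord]:
    """Dosing histories and sampling schedules (observations hold placeholder
    zero concentrations until :func:`simulate_dataset` fills them).

    Once-daily dosing is written out explicitly over ``n_days`` so dose
    reductions (400→320→240 mg) are exact; each sample falls a uniform
    (0.5, 24] h after a dose given on or after the steady-state day.
    """
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    if covariates is None:
        covariates = generate_covariates(design, seed)
    # per-subject sample counts
    if design.samples_per_subject is not None:
        counts = np.full(n, design.samples_per_subject, dtype=int)
    else:
        base, extra = divmod(design.total_observations, n)
        counts = np.full(n, base, dtype=int)
        counts[rng.choice(n, size=extra, replace=False)] += 1
    levels = np.asarray(design.dose_levels)
    assigned = rng.choice(len(levels), size=n, p=np.asarray(design.dose_proportions))
    reduce_mask = rng.random(n) < design.dose_reduction_fraction
    subjects = []
    for i in range(n):
        sid = covariates.index[i]
        amount = levels[assigned[i]]
        switch_day = design.n_days + 1
        reduced_amount = amount
        if reduce_mask[i] and amount > levels.min():
            lower = levels[levels < amount]
            reduced_amount = float(lower.max())
            switch_day = int(rng.integers(5, design.n_days - 1))
        doses = [
            DosingEvent(
                time=d * design.dosing_interval,
                amount=float(amount if d < switch_day else reduced_amount),
            )
            for d in range(design.n_days)
        ]
        lo, hi = design.sample_window
        days = rng.integers(design.steady_state_day - 1, design.n_days, size=counts[i])
        tads = rng.uniform(lo, hi, size=counts[i])
        times = np.sort(days * design.dosing_interval + tads)
        obs = [Observation(time=float(t), concentration=0.0) for t in times]
        subjects.append(
            SubjectRecord(
                id=sid, doses=doses, observations=obs,
                covariates=covariates.loc[sid].to_dict(),
            )
        )
    return subjects


def simulate_dataset(
    subjects: list[SubjectRecord],
    spec: ModelSpec,
    seed: int,
    lloq: float = 1.0,
) -> SimulatedDataset:
    """Fill a designed cohort with concentrations simulated from ``spec``.

    η_i ~ N(0, ω²) per random-effect parameter; observations get the
    residual-error model applied (proportional draws below −1, which would
    produce negative concentrations, are resampled and counted); values
    below ``lloq`` are flagged BLQ.
    """
    rng = np.random.default_rng(seed)
    re = spec.random_effects
    err = spec.error
    out_subjects: list[SubjectRecord] = []
    etas: dict[str, dict[str, float]] = {}
    n_gen = n_blq = n_resampled = 0
    for s in subjects:
        eta = {p: rng.normal(0.0, spec.omega[p]) for p in re}
        etas[s.id] = eta
        params = individual_parameters(spec, s.covariates, eta)
        times = [o.time for o in s.observations]
        f = predict_concentration(s.doses, params, times)
        obs = []
        for fij, t in zip(f, times):
            y = fij
            if err.form in ("proportional", "combined"):
                eps = rng.normal(0.0, err.sigma_p)
                while eps < -1.0:
                    n_resampled += 1
                    eps = rng.normal(0.0, err.sigma_p)
                y = fij * (1.0 + eps)
            if err.form in ("additive", "combined"):
                y = y + rng.normal(0.0, err.sigma_a)
            y = max(y, 0.0)
            n_gen += 1
            blq = y < lloq
            n_blq += int(blq)
            obs.append(Observation(time=t, concentration=float(y), blq=blq))
        out_subjects.append(
            SubjectRecord(id=s.id, doses=list(s.doses), observations=obs,
                          covariates=dict(s.covariates))
        )
    truth = {
        "theta": dict(spec.theta),
        "covariate_terms": list(spec.covariate_terms),
        "omega": dict(spec.omega),
        "error": spec.error,
        "eta": etas,
        "seed": seed,
    }
    return SimulatedDataset(
        subjects=out_subjects, truth=truth,
        n_generated=n_gen, n_blq=n_blq, n_eps_resampled=n_resampled,
    )


def generate_cohort(
    design: CohortDesign, spec: ModelSpec, seed: int
) -> SimulatedDataset:
    """Covariates → design → simulation in one deterministic call; the three
    stages draw from decorrelated substreams of ``seed``."""
    covs = generate_covariates(design, seed)
    designed = generate_design(design, seed + 1, covariates=covs)
    return simulate_dataset(designed, spec, seed + 2, lloq=design.lloq)


def apply_data_rules(
    subjects: list[SubjectRecord],
    lloq: float = 1.0,
    fit_spec: ModelSpec | None = None,
    cwres_limit: float = 6.0,
    missing_threshold: float = 0.20,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Apply the study's data-handling rules and log every exclusion.

    Observations below the LLOQ are omitted; when a fitted model is supplied,
    observations with |CWRES| > 6 are flagged as outliers and removed;
    covariates missing in more than 20 % of subjects are dropped.
    """
    log: list[dict] = []
    cleaned: list[SubjectRecord] = []
    for s in subjects:
        kept = []
        for o in s.observations:
            if o.blq or o.concentration < lloq:
                log.append({"subject": s.id, "time": o.time,
                            "value": o.concentration, "reason": "BLQ"})
            else:
                kept.append(o)
        cleaned.append(SubjectRecord(s.id, list(s.doses), kept, dict(s.covariates)))
    if fit_spec is not None:
        with_obs = [s for s in cleaned if s.observations]
        if with_obs:
            cwres = compute_cwres(pack_dataset(with_obs), fit_spec)
            pos = 0
            for s in with_obs:
                kept = []
                for o in s.observations:
                    if abs(cwres[pos]) > cwres_limit:
                        log.append({"subject": s.id, "time": o.time,
                                    "value": o.concentration,
                                    "reason": f"|CWRES|={abs(cwres[pos]):.2f}>{cwres_limit:g}"})
                    else:
                        kept.append(o)
                    pos += 1
                s.observations = kept
    n = len(cleaned)
    if n:
        all_covs = sorted({k for s in cleaned for k in s.covariates})
        for name in all_covs:
            n_missing = sum(
                1 for s in cleaned
                if name not in s.covariates
                or (isinstance(s.covariates.get(name), float)
                    and math.isnan(s.covariates[name]))
            )
            if n_missing / n > missing_threshold:
                for s in cleaned:
                    s.covariates.pop(name, None)
                log.append({"subject": "*", "time": np.nan, "value": np.nan,
                            "reason": f"covariate {name} missing in "
                                      f"{100 * n_missing / n:.0f}% of subjects"})
    log_df = pd.DataFrame(log, columns=["subject", "time", "value", "reason"])
    return cleaned, log_df
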
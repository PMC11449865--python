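"""Covariate pre-screening and stepwise covariate model building.

Screening removes redundant and unusable covariates before any likelihood
work: within each cluster of highly correlated continuous covariates
(|r| > 0.7) one representative is kept; covariates missing in more than
20 % of subjects and dichotomous covariates whose minority class covers
less than 10 % of subjects are dropped.

The formal search is stepwise: forward inclusion adds one covariate–
parameter relation at a time, accepting the candidate with the largest
objective-function drop when that drop exceeds 3.84 (χ²₁, p < 0.05);
backward elimination then deletes terms one at a time, retaining a term
only when its deletion raises the OFV by more than 10.83 (χ²₁, p < 0.001).
Both thresholds are strict inequalities.  Decisions depend on ΔOFV only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    CovariateTerm,
    ModelSpec,
    SubjectRecord,
)
from .foce import FitResult, fit_foce, pack_dataset
from .pkmodel import covariate_effect

#: screening retains these over their correlated partners, mirroring the
#: study's choice of WT over BMI/HT, TBIL over DBIL/IBIL, TP over ALB/GLB,
#: and AST over ALT
DEFAULT_PRIORITY = ("TP", "WT", "TBIL", "AST", "AGE", "SCR")


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """ΔOFV threshold of the likelihood-ratio test: the χ² quantile at
    1 − alpha with ``df`` degrees of freedom (3.84 at p<0.05, 10.83 at
    p<0.001 for df=1; report rounded to 2 decimals)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass
class ScreenReport:
    """Outcome of covariate pre-screening with a reason for every drop."""

    correlation: pd.DataFrame
    retained: list[str]
    dropped: dict[str, str]  # covariate -> reason

    def __post_init__(self) -> None:
        assert not set(self.retained) & set(self.dropped)


def prescreen_covariates(
    subjects: list[SubjectRecord] | pd.DataFrame,
    corr_threshold: float = 0.7,
    missing_threshold: float = 0.20,
    rare_threshold: float = 0.10,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> ScreenReport:
    """Correlation / missingness / rare-category screening.

    Pearson correlations use pairwise-complete observations.  Within each
    connected cluster of pairs with |r| > ``corr_threshold`` exactly one
    covariate is retained — the first by the ``priority`` list, else the
    first in column order.  Constant covariates (undefined correlation) are
    retained with a warning.
    """
    if isinstance(subjects, pd.DataFrame):
        cov = subjects.copy()
    else:
        cov = pd.DataFrame([s.covariates for s in subjects],
                           index=[s.id for s in subjects])
    if cov.shape[1] < 2:
        raise ValueError("screening needs at least 2 covariates")
    dropped: dict[str, str] = {}
    n = len(cov)
    for name in list(cov.columns):
        frac = cov[name].isna().mean()
        if frac > missing_threshold:
            dropped[name] = f"missing in {100 * frac:.0f}% of subjects"
    cat = [c for c in cov.columns if c in CATEGORICAL_COVARIATES and c not in dropped]
    for name in cat:
        vals = cov[name].dropna()
        minority = min(vals.mean(), 1 - vals.mean())
        if minority < rare_threshold:
            dropped[name] = (
                f"minority class {100 * minority:.0f}% < {100 * rare_threshold:.0f}%"
            )
    cont = [c for c in cov.columns
            if c in CONTINUOUS_COVARIATES and c not in dropped]
    corr = cov[cont].corr(method="pearson") if cont else pd.DataFrame()
    for name in cont:
        if cov[name].dropna().nunique() <= 1:
            warnings.warn(f"covariate {name} is constant; correlation undefined")
    # connected components of the |r| > threshold graph
    remaining = set(cont)
    adj = {c: set() for c in cont}
    for i, a in enumerate(cont):
        for b in cont[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > corr_threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    for c in cont:
        if c in seen:
            continue
        stack, cluster = [c], set()
        while stack:
            u = stack.pop()
            if u in cluster:
                continue
            cluster.add(u)
            stack.extend(adj[u] - cluster)
        seen |= cluster
        if len(cluster) > 1:
            ranked = sorted(
                cluster,
                key=lambda x: (priority.index(x) if x in priority else len(priority),
                               cont.index(x)),
            )
            keep = ranked[0]
            for other in ranked[1:]:
                dropped[other] = f"|r|>{corr_threshold:g} with retained {keep}"
                remaining.discard(other)
    retained = [c for c in cov.columns if c not in dropped]
    return ScreenReport(correlation=corr, retained=retained, dropped=dropped)


# ---------------------------------------------------------------------------
# stepwise search
# ---------------------------------------------------------------------------

@dataclass
class StepwiseTrace:
    """Ordered record of the covariate search (one row per candidate fit)."""

    steps: list[dict] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: FitResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["step", "direction", "description", "ofv", "delta_ofv",
                     "threshold", "decision"],
        )


Candidate = tuple[str, str, str]  # (parameter, covariate, form)


def _with_term(spec: ModelSpec, cand: Candidate, median: float) -> ModelSpec:
    param, covname, form = cand
    out = spec.copy()
    theta2 = 1.0 if form == "categorical" else (1.0 if form == "linear" else 0.0)
    out.covariate_terms = list(out.covariate_terms) + [
        CovariateTerm(param, covname, form, theta2, median)
    ]
    return out


def _medians(subjects, candidates):
    cov = pd.DataFrame([s.covariates for s in subjects])
    med = {}
    for _, name, form in candidates:
        med[name] = 1.0 if form == "categorical" else float(cov[name].median())
    return med


def forward_step(
    subjects,
    current: ModelSpec,
    current_ofv: float,
    candidates: list[Candidate],
    alpha: float = 0.05,
    maxiter: int | None = None,
):
    """One forward-inclusion round: fit each single added candidate, accept
    the largest OFV drop if it beats the χ² threshold.  Ties break toward
    fewer added parameters, then candidate order.  Returns
    (best_spec, best_ofv, accepted_candidate_or_None, step_rows)."""
    if not candidates:
        raise ValueError("no candidates")
    packed = pack_dataset(subjects)
    threshold = lrt_threshold(alpha)
    med = _medians(subjects, candidates)
    rows, results = [], []
    for cand in candidates:
        trial = _with_term(current, cand, med[cand[1]])
        desc = f"+{cand[1]}-{cand[0]} ({cand[2]})"
        try:
            fit = fit_foce(packed, trial, maxiter=maxiter)
        except (ValueError, FloatingPointError) as exc:
            rows.append({"direction": "forward", "description": desc,
                         "ofv": np.nan, "delta_ofv": np.nan,
                         "threshold": threshold,
                         "decision": f"skipped ({exc})"})
            continue
        if not fit.converged:
            rows.append({"direction": "forward", "description": desc,
                         "ofv": fit.ofv, "delta_ofv": fit.ofv - current_ofv,
                         "threshold": threshold, "decision": "skipped (no convergence)"})
            continue
        drop = current_ofv - fit.ofv
        rows.append({"direction": "forward", "description": desc,
                     "ofv": fit.ofv, "delta_ofv": fit.ofv - current_ofv,
                     "threshold": threshold,
                     "decision": "candidate" if drop > threshold else "rejected"})
        results.append((drop, len(trial.covariate_terms), cand, fit))
    accepted = None
    best_spec, best_ofv = current, current_ofv
    if results:
        results.sort(key=lambda t: (-t[0], t[1]))
        drop, _, cand, fit = results[0]
        if drop > threshold:  # strict inequality
            accepted = cand
            best_spec, best_ofv = fit.spec, fit.ofv
            for row in rows:
                if row["description"] == f"+{cand[1]}-{cand[0]} ({cand[2]})":
                    row["decision"] = "accepted"
    return best_spec, best_ofv, accepted, rows


def _deletion_compensation(trial: ModelSpec, term: CovariateTerm, subjects):
    """Fold the removed term's average multiplier back into the typical
    value so the reduced model starts in the right likelihood basin (the
    exponential form is not centered to 1 at the median, so θ1 and θ2 ride
    a near-collinear ridge)."""
    cov = pd.Series([s.covariates.get(term.covariate, np.nan) for s in subjects])
    x = cov.dropna().to_numpy() / (term.median if term.form != "categorical" else 1.0)
    if x.size == 0:
        return
    if term.form == "exponential":
        trial.theta[term.parameter] *= float(np.mean(np.exp(term.theta2 * x)))
    elif term.form == "power":
        trial.theta[term.parameter] *= float(np.mean(x**term.theta2))
    elif term.form == "categorical" and term.theta2 > 0:
        trial.theta[term.parameter] *= float(np.mean(term.theta2**x))
    elif term.form == "linear":
        trial.theta[term.parameter] += term.theta2 * float(np.mean(x))
    if trial.theta[term.parameter] <= 0:
        trial.theta[term.parameter] = abs(trial.theta[term.parameter]) or 1.0


def backward_step(
    subjects,
    full: ModelSpec,
    full_ofv: float,
    alpha: float = 0.001,
    maxiter: int | None = None,
):
    """Backward elimination to exhaustion: repeatedly delete the term whose
    removal raises the OFV least, until every remaining term's deletion
    would raise the OFV by more than the χ² threshold (strict)."""
    packed = pack_dataset(subjects)
    threshold = lrt_threshold(alpha)
    spec, ofv = full, full_ofv
    rows = []
    while spec.covariate_terms:
        results = []
        for i, term in enumerate(spec.covariate_terms):
            trial = spec.copy()
            del trial.covariate_terms[i]
            _deletion_compensation(trial, term, subjects)
            desc = f"-{term.covariate}-{term.parameter}"
            try:
                fit = fit_foce(packed, trial, maxiter=maxiter)
            except (ValueError, FloatingPointError) as exc:
                rows.append({"direction": "backward", "description": desc,
                             "ofv": np.nan, "delta_ofv": np.nan,
                             "threshold": threshold,
                             "decision": f"skipped ({exc})"})
                continue
            rise = fit.ofv - ofv
            rows.append({"direction": "backward", "description": desc,
                         "ofv": fit.ofv, "delta_ofv": rise,
                         "threshold": threshold,
                         "decision": "retained" if rise > threshold else "removable"})
            results.append((rise, i, fit))
        if not results:
            break
        results.sort(key=lambda t: (t[0], t[1]))
        rise, i, fit = results[0]
        if rise > threshold:
            break  # every deletion is significant; all terms retained
        removed = spec.covariate_terms[i]
        spec, ofv = fit.spec, fit.ofv
        for row in rows:
            if (row["description"] == f"-{removed.covariate}-{removed.parameter}"
                    and row["decision"] == "removable"):
                row["decision"] = "removed"
    return spec, ofv, rows


def stepwise_search(
    subjects,
    base: ModelSpec,
    candidates: list[Candidate],
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.001,
    maxiter: int | None = None,
    strategy: str = "stepwise",
) -> StepwiseTrace:
    """Full covariate search: forward inclusion to exhaustion, then backward
    elimination (``strategy="stepwise"``), or fit all screened candidates at
    once and only backward-eliminate (``strategy="full-model"``)."""
    packed = pack_dataset(subjects)
    trace = StepwiseTrace()
    base_fit = fit_foce(packed, base, maxiter=maxiter)
    spec, ofv = base_fit.spec, base_fit.ofv
    trace.steps.append({"step": 0, "direction": "base", "description": "base model",
                        "ofv": ofv, "delta_ofv": np.nan, "threshold": np.nan,
                        "decision": "start"})
    step = 0
    if strategy == "full-model":
        med = _medians(subjects, candidates)
        for cand in candidates:
            spec = _with_term(spec, cand, med[cand[1]])
        fit = fit_foce(packed, spec, maxiter=maxiter)
        spec, ofv = fit.spec, fit.ofv
        step += 1
        trace.steps.append({"step": step, "direction": "full",
                            "description": "base + all candidates", "ofv": ofv,
                            "delta_ofv": ofv - base_fit.ofv, "threshold": np.nan,
                            "decision": "full model"})
    elif strategy == "stepwise":
        remaining = list(candidates)
        while remaining:
            spec2, ofv2, accepted, rows = forward_step(
                subjects, spec, ofv, remaining, alpha=forward_alpha, maxiter=maxiter
            )
            step += 1
            for r in rows:
                trace.steps.append({"step": step, **r})
            if accepted is None:
                break
            spec, ofv = spec2, ofv2
            remaining = [c for c in remaining
                         if (c[0], c[1]) != (accepted[0], accepted[1])]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    spec, ofv, rows = backward_step(subjects, spec, ofv, alpha=backward_alpha,
                                    maxiter=maxiter)
    step += 1
    for r in rows:
        trace.steps.append({"step": step, **r})
    trace.final_spec = spec
    trace.final_fit = fit_foce(packed, spec, maxiter=maxiter)
    trace.steps.append({"step": step + 1, "direction": "final",
                        "description": "final model", "ofv": trace.final_fit.ofv,
                        "delta_ofv": trace.final_fit.ofv - base_fit.ofv,
                        "threshold": np.nan, "decision": "final"})
    return trace


def clinical_relevance(
    spec: ModelSpec,
    subjects,
    threshold_percent: float = 20.0,
) -> pd.DataFrame:
    """Percent change of each covariate-adjusted parameter over the observed
    covariate range, relative to its value at the median; terms moving the
    parameter by more than 20 % are flagged clinically relevant."""
    if not spec.covariate_terms:
        raise ValueError("model has no covariate terms")
    cov = pd.DataFrame([s.covariates for s in subjects])
    rows = []
    for term in spec.covariate_terms:
        theta1 = spec.theta[term.parameter]
        if term.form == "categorical":
            ref = covariate_effect(term.form, theta1, term.theta2, 0.0)
            alt = covariate_effect(term.form, theta1, term.theta2, 1.0)
            changes = [100.0 * (alt - ref) / ref]
        else:
            vals = cov[term.covariate].dropna()
            med = float(vals.median())
            ref = covariate_effect(term.form, theta1, term.theta2, med, term.median)
            changes = [
                100.0 * (covariate_effect(term.form, theta1, term.theta2,
                                          float(v), term.median) - ref) / ref
                for v in (vals.min(), vals.max())
            ]
        max_abs = max(abs(c) for c in changes)
        rows.append({
            "parameter": term.parameter,
            "covariate": term.covariate,
            "form": term.form,
            "change_at_min_percent": changes[0],
            "change_at_max_percent": changes[-1],
            "max_abs_change_percent": max_abs,
            "clinically_relevant": max_abs > threshold_percent,
        })
    return pd.DataFrame(rows)


class StepwiseCovariateSelector(BaseEstimator):
    """sklearn-style wrapper around screening + stepwise search.

    Parameters mirror :func:`prescreen_covariates` and
    :func:`stepwise_search`; ``base`` is a :class:`PopPKModel` (unfitted)
    defining the structural base model.  After ``fit``:

    - ``screen_`` — the ScreenReport
    - ``trace_`` — the StepwiseTrace
    - ``model_`` — fitted final-model PopPKModel
    """

    def __init__(
        self,
        base=None,
        parameters: tuple[str, ...] = ("CL", "V"),
        forms: tuple[str, ...] = ("power", "exponential"),
        forward_alpha: float = 0.05,
        backward_alpha: float = 0.001,
        strategy: str = "stepwise",
        maxiter: int | None = None,
    ):
        self.base = base
        self.parameters = parameters
        self.forms = forms
        self.forward_alpha = forward_alpha
        self.backward_alpha = backward_alpha
        self.strategy = strategy
        self.maxiter = maxiter

    def fit(self, X, y=None):
        from .estimators import PopPKModel, _coerce_subjects

        subjects = _coerce_subjects(X)
        base = self.base if self.base is not None else PopPKModel()
        base_spec = base.build_spec()
        self.screen_ = prescreen_covariates(subjects)
        candidates: list[Candidate] = []
        for name in self.screen_.retained:
            if name in CATEGORICAL_COVARIATES:
                candidates.extend((p, name, "categorical") for p in self.parameters)
            else:
                candidates.extend(
                    (p, name, form) for p in self.parameters for form in self.forms
                )
        self.candidates_ = candidates
        self.trace_ = stepwise_search(
            subjects, base_spec, candidates,
            forward_alpha=self.forward_alpha,
            backward_alpha=self.backward_alpha,
            maxiter=self.maxiter, strategy=self.strategy,
        )
        self.model_ = PopPKModel.from_spec(self.trace_.final_spec)
        self.model_.result_ = self.trace_.final_fit
        self.model_.theta_ = self.trace_.final_fit.theta
        return self
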
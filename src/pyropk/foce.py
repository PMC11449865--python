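"""First-order conditional estimation with η–ε interaction (FOCE-I).

The marginal likelihood of a nonlinear mixed-effects model has no closed
form; FOCE-I approximates it by linearizing the model about each subject's
conditional mode η̂ (the empirical Bayes estimate), with the residual-error
variance evaluated at that mode (the "interaction").  For subject i with
observations y_i, model f_i(η), Jacobian G_i = ∂f_i/∂η at η̂_i, residual
covariance R_i = diag(residual variance at IPRED), and random-effect
covariance Ω:

    V_i  = G_i Ω G_iᵀ + R_i
    r_i  = y_i − f_i(η̂_i) + G_i η̂_i
    OFV  = Σ_i [ log det V_i + r_iᵀ V_i⁻¹ r_i ]

The n·log 2π constant is omitted (NONMEM convention), so the OFV can be
negative.  Differences in OFV between nested models are χ²-distributed under
the null, which is what the covariate search consumes.

Subjects are packed into padded arrays and the inner η optimization runs in
compiled per-subject loops (see ``_kernels``), cold-started from η = 0 every
time so the objective is a deterministic, reproducible function of the
population parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._kernels import solve_cohort
from .datatypes import ModelSpec, ResidualErrorSpec, SubjectRecord
from .pkmodel import MG_TO_UG, _KA_DEGENERACY_RTOL

_W_FLOOR = 1e-12  # variance floor guarding σ→0 or IPRED→0 corner cases


# ---------------------------------------------------------------------------
# dataset packing
# ---------------------------------------------------------------------------

@dataclass
class PackedDataset:
    """Cohort packed into padded arrays for vectorized likelihood work."""

    ids: list[str]
    y: np.ndarray          # (S, O) observed concentrations, 0-padded
    obs_mask: np.ndarray   # (S, O) True where a real observation sits
    times: np.ndarray      # (S, O) observation times
    dtp: np.ndarray        # (S, O, D) time since each dose, clamped at 0
    act: np.ndarray        # (S, O, D) True where the dose precedes the obs
    amt_ug: np.ndarray     # (S, D) dose amounts in µg, 0-padded
    covariates: pd.DataFrame  # one row per subject, same order as ids

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())


def pack_dataset(subjects: list[SubjectRecord]) -> PackedDataset:
    if not subjects:
        raise ValueError("empty dataset")
    S = len(subjects)
    O = max(max((len(s.observations) for s in subjects), default=0), 1)
    D = max(max((len(s.doses) for s in subjects), default=0), 1)
    y = np.zeros((S, O))
    m = np.zeros((S, O), dtype=bool)
    t = np.zeros((S, O))
    dt = np.zeros((S, O, D))
    amt = np.zeros((S, D))
    cov_rows = []
    for i, s in enumerate(subjects):
        s.validate()
        n = len(s.observations)
        if n:
            y[i, :n] = [o.concentration for o in s.observations]
            t[i, :n] = [o.time for o in s.observations]
            m[i, :n] = True
        nd = len(s.doses)
        if nd:
            dose_t = np.array([d.time for d in s.doses])
            amt[i, :nd] = [d.amount * MG_TO_UG for d in s.doses]
            dt[i, :, :nd] = t[i][:, None] - dose_t[None, :]
        cov_rows.append(dict(s.covariates))
    cov = pd.DataFrame(cov_rows, index=[s.id for s in subjects])
    act = dt > 0
    dtp = np.where(act, dt, 0.0)
    return PackedDataset([s.id for s in subjects], y, m, t, dtp, act, amt, cov)


def _as_packed(subjects) -> PackedDataset:
    return subjects if isinstance(subjects, PackedDataset) else pack_dataset(subjects)


# ---------------------------------------------------------------------------
# vectorized covariate submodels
# ---------------------------------------------------------------------------

def typical_value_arrays(spec: ModelSpec, packed: PackedDataset):
    """Per-subject typical CL, V, Ka after covariate terms, as (S,) arrays."""
    S = packed.n_subjects
    tv = {p: np.full(S, spec.theta[p], dtype=float) for p in ("CL", "V", "KA")}
    for term in spec.covariate_terms:
        if term.covariate not in packed.covariates.columns:
            raise ValueError(f"covariate {term.covariate!r} absent from dataset")
        cov = packed.covariates[term.covariate].to_numpy(dtype=float)
        if np.any(~np.isfinite(cov)):
            bad = packed.covariates.index[~np.isfinite(cov)].tolist()
            raise ValueError(
                f"covariate {term.covariate!r} missing for subjects {bad}"
            )
        t1 = tv[term.parameter]
        if term.form == "linear":
            t1 = t1 + term.theta2 * cov / term.median
        elif term.form == "power":
            t1 = t1 * (cov / term.median) ** term.theta2
        elif term.form == "exponential":
            t1 = t1 * np.exp(term.theta2 * cov / term.median)
        elif term.form == "categorical":
            t1 = t1 * term.theta2**cov
        else:  # pragma: no cover
            raise ValueError(f"unknown covariate form {term.form!r}")
        tv[term.parameter] = t1
    if any(np.any(v <= 0) for v in tv.values()):
        raise ValueError("covariate model produced non-positive typical values")
    return tv["CL"], tv["V"], tv["KA"]


def _pred_concentrations(packed: PackedDataset, cl, v, ka) -> np.ndarray:
    """Structural predictions (S, O) at per-subject parameters, vectorized."""
    k = cl / v
    kb = k[:, None, None]
    kab = ka[:, None, None] if np.ndim(ka) else np.full_like(kb, ka)
    vb = v[:, None, None]
    a = packed.amt_ug[:, None, :]
    deg = np.abs(kab - kb) < _KA_DEGENERACY_RTOL * kb
    denom = np.where(deg, 1.0, kab - kb)
    E1 = np.exp(-kb * packed.dtp)
    E2 = np.exp(-kab * packed.dtp)
    contrib = np.where(
        deg,
        a * kb * packed.dtp * E1 / vb,
        a * kab / (vb * denom) * (E1 - E2),
    )
    return np.where(packed.act, contrib, 0.0).sum(axis=-1)


# ---------------------------------------------------------------------------
# inner problem / OFV via the compiled kernels
# ---------------------------------------------------------------------------

def _random_effect_layout(spec: ModelSpec):
    """Active random effects (ω > 0) and their kernel codes (0=CL, 1=V)."""
    re = [p for p in spec.random_effects if spec.omega[p] > 0]
    if "KA" in re:
        raise NotImplementedError("random effect on KA is not supported")
    codes = np.array([0 if p == "CL" else 1 for p in re], dtype=np.int64)
    omega2 = np.array([spec.omega[p] ** 2 for p in re])
    return re, codes, omega2


def _solve(packed: PackedDataset, spec: ModelSpec):
    """Inner solve for the whole cohort.

    Returns (re, eta (S,n_eta), f, G (S,O,n_eta), w, ofv_i)."""
    re, codes, omega2 = _random_effect_layout(spec)
    cl_t, v_t, ka_t = typical_value_arrays(spec, packed)
    err = spec.error
    sigp2 = err.sigma_p**2 if err.form in ("proportional", "combined") else 0.0
    siga2 = err.sigma_a**2 if err.form in ("additive", "combined") else 0.0
    eta, f, G, w, ofv_i = solve_cohort(
        codes, cl_t, v_t, ka_t, packed.dtp, packed.act, packed.amt_ug,
        packed.y, packed.obs_mask, omega2, sigp2, siga2,
    )
    n = len(re)
    return re, eta[:, :n], f, G[:, :, :n], w, ofv_i


def estimate_ebes(
    subjects: list[SubjectRecord] | PackedDataset, spec: ModelSpec
) -> np.ndarray:
    """Empirical Bayes η̂ (conditional modes), one row per subject, one
    column per random effect with ω > 0.  Subjects without observations get
    η̂ = 0 (the prior mode)."""
    packed = _as_packed(subjects)
    _, eta, _, _, _, _ = _solve(packed, spec)
    return eta


def foce_ofv(
    subjects: list[SubjectRecord] | PackedDataset, spec: ModelSpec
) -> float:
    """FOCE-I objective function value (NONMEM convention, no n·log 2π).

    When every ω is zero the Ω term drops and the value reduces to the
    naive-pooled objective Σ[log w + (y−f)²/w] at η = 0.
    """
    packed = _as_packed(subjects)
    _, _, _, _, _, ofv_i = _solve(packed, spec)
    if np.any(np.isnan(ofv_i)):
        bad = [packed.ids[i] for i in np.where(np.isnan(ofv_i))[0]]
        raise FloatingPointError(f"singular marginal covariance for subjects {bad}")
    return float(ofv_i.sum())


def compute_cwres(
    subjects: list[SubjectRecord] | PackedDataset, spec: ModelSpec
) -> np.ndarray:
    """Conditional weighted residuals V⁻¹ᐟ²(y − E[y]) under the FOCE-I
    linearization (symmetric square root by eigendecomposition); nominally
    N(0,1) under a correct model.  Returned flat in observation order."""
    packed = _as_packed(subjects)
    re, eta, f, G, w, _ = _solve(packed, spec)
    omega2 = np.array([spec.omega[p] ** 2 for p in re])
    m = packed.obs_mask
    out = []
    for i in range(packed.n_subjects):
        idx = np.where(m[i])[0]
        if idx.size == 0:
            continue
        Gi = G[i][idx]
        Vi = np.diag(w[i][idx])
        if re:
            Vi = Vi + (Gi * omega2) @ Gi.T
        ri = (packed.y[i] - f[i])[idx] + (Gi @ eta[i] if re else 0.0)
        vals, vecs = np.linalg.eigh(Vi)
        if np.any(vals <= 0):
            raise FloatingPointError(
                f"non-PSD marginal covariance for subject {packed.ids[i]}"
            )
        out.append(vecs @ ((vecs.T @ ri) / np.sqrt(vals)))
    return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# outer problem: maximum likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """FOCE-I fit: estimates, objective, diagnostics and EBEs."""

    spec: ModelSpec                    # fitted model (estimates in place)
    theta: dict[str, float]
    covariate_coefficients: dict[str, float]
    omega: dict[str, float]            # SD scale
    sigma: dict[str, float]
    ofv: float
    converged: bool
    n_function_evals: int
    ids: list[str] = field(default_factory=list)
    ebes: np.ndarray | None = None
    pred: np.ndarray | None = None     # population predictions (η = 0), flat
    ipred: np.ndarray | None = None    # individual predictions (η = η̂), flat
    cwres: np.ndarray | None = None
    eta_shrinkage: dict[str, float] = field(default_factory=dict)
    eps_shrinkage: float | None = None
    rse: dict[str, float] | None = None

    def parameter_table(self) -> pd.DataFrame:
        """Estimate / RSE% / shrinkage% table (one row per reported scalar),
        with BSV and proportional error on the %CV convention (100·ω, 100·σ_p)."""
        rows = []
        for p, v in self.theta.items():
            fixed = p in self.spec.fixed
            rows.append({"parameter": p, "estimate": v,
                         "rse_percent": None if fixed or not self.rse else self.rse.get(p),
                         "shrinkage_percent": None, "fixed": fixed})
        for name, v in self.covariate_coefficients.items():
            rows.append({"parameter": name, "estimate": v,
                         "rse_percent": self.rse.get(name) if self.rse else None,
                         "shrinkage_percent": None, "fixed": False})
        for p, wv in self.omega.items():
            rows.append({"parameter": f"BSV-{p} (%CV)", "estimate": 100.0 * wv,
                         "rse_percent": self.rse.get(f"omega_{p}") if self.rse else None,
                         "shrinkage_percent": self.eta_shrinkage.get(p), "fixed": False})
        for name, sv in self.sigma.items():
            label = "ERR-prop (%CV)" if name == "sigma_p" else "ERR-add (ng/mL)"
            rows.append({"parameter": label,
                         "estimate": 100.0 * sv if name == "sigma_p" else sv,
                         "rse_percent": self.rse.get(name) if self.rse else None,
                         "shrinkage_percent": self.eps_shrinkage, "fixed": False})
        return pd.DataFrame(rows)


def _free_parameters(spec: ModelSpec):
    """(name, kind, key) triples for the free parameters, in a fixed order.

    θ and the variance components are log-transformed internally to enforce
    positivity; covariate coefficients θ2 stay on the natural scale."""
    entries = []
    for p in ("CL", "V", "KA"):
        if p not in spec.fixed:
            entries.append((p, "theta", p))
    for i, term in enumerate(spec.covariate_terms):
        entries.append((f"{term.covariate}-{term.parameter}", "covterm", i))
    for p in spec.random_effects:
        entries.append((f"omega_{p}", "omega", p))
    if spec.error.form in ("proportional", "combined"):
        entries.append(("sigma_p", "sigma", "sigma_p"))
    if spec.error.form in ("additive", "combined"):
        entries.append(("sigma_a", "sigma", "sigma_a"))
    return entries


def _pack_x(spec: ModelSpec) -> np.ndarray:
    x = []
    for name, kind, key in _free_parameters(spec):
        if kind == "theta":
            x.append(np.log(spec.theta[key]))
        elif kind == "covterm":
            x.append(spec.covariate_terms[key].theta2)
        elif kind == "omega":
            x.append(np.log(max(spec.omega[key], 1e-6)))
        else:
            x.append(np.log(max(getattr(spec.error, key), 1e-6)))
    return np.array(x)


def _unpack_x(spec: ModelSpec, x: np.ndarray) -> ModelSpec:
    from dataclasses import replace

    out = spec.copy()
    for (name, kind, key), xi in zip(_free_parameters(spec), x):
        if kind == "theta":
            out.theta[key] = float(np.exp(xi))
        elif kind == "covterm":
            out.covariate_terms[key] = replace(out.covariate_terms[key], theta2=float(xi))
        elif kind == "omega":
            out.omega[key] = float(np.exp(xi))
        else:
            err = out.error
            kw = {"form": err.form, "sigma_p": err.sigma_p, "sigma_a": err.sigma_a}
            kw[key] = float(np.exp(xi))
            out.error = ResidualErrorSpec(**kw)
    return out


def fit_foce(
    subjects: list[SubjectRecord] | PackedDataset,
    spec: ModelSpec,
    maxiter: int | None = None,
    compute_se: bool = False,
    xtol: float = 1e-4,
    ftol: float = 1e-6,
) -> FitResult:
    """Maximize the FOCE-I approximate likelihood over the free parameters.

    A derivative-free simplex search is followed by a finite-difference
    quasi-Newton (BFGS) polish; fixed parameters (e.g. Ka = 0.357) are never
    perturbed.  ``spec`` supplies both the model structure and the initial
    values.  On optimizer failure the best-so-far values are returned with
    ``converged=False``.
    """
    packed = _as_packed(subjects)
    if packed.n_subjects < 2:
        raise ValueError("FOCE fit requires at least 2 subjects")
    x0 = _pack_x(spec)
    names = [e[0] for e in _free_parameters(spec)]
    state = {"evals": 0}
    # generous box bounds around the initial values (±4 log-units, i.e. a
    # factor ~55, and ±10 on covariate coefficients): with extreme
    # between-subject variances the linearized objective has spurious
    # degenerate basins far from any plausible parameter region, and an
    # unbounded search can fall into them
    half_width = np.array([
        10.0 if kind == "covterm" else 4.0
        for (_, kind, _) in _free_parameters(spec)
    ])

    def objective(x):
        state["evals"] += 1
        excess = np.abs(np.asarray(x) - x0) - half_width
        if np.any(excess > 0):
            return 1e8 * (1.0 + float(np.sum(np.clip(excess, 0, None) ** 2)))
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                trial = _unpack_x(spec, x)
                _, _, _, _, _, ofv_i = _solve(packed, trial)
            val = float(ofv_i.sum())
            return val if np.isfinite(val) else 1e10
        except (FloatingPointError, ValueError, np.linalg.LinAlgError):
            return 1e10

    converged = True
    if len(x0):
        # coarse adaptive simplex, then a restarted small-simplex polish:
        # near the optimum the surface is flat in units of ΔOFV, where
        # finite-difference gradient methods stall, but a fresh simplex of
        # 2 % steps converges reliably.
        # explicit starting simplex: 10 % steps on the log-scale entries and
        # 0.3 on covariate coefficients (which start at 0, where the default
        # simplex step would be microscopic)
        steps = np.array([
            0.3 if kind == "covterm" else 0.1
            for (_, kind, _) in _free_parameters(spec)
        ])
        start_simplex = x0 + np.vstack([np.zeros_like(x0), np.diag(steps)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nm = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"xatol": 10 * xtol, "fatol": 0.05,
                         "maxiter": maxiter or 150 * len(x0), "adaptive": True,
                         "initial_simplex": start_simplex},
            )
            simplex = nm.x + 0.02 * np.eye(len(x0) + 1, len(x0), k=-1)
            polish = optimize.minimize(
                objective, nm.x, method="Nelder-Mead",
                options={"xatol": xtol, "fatol": ftol * max(1.0, abs(nm.fun)),
                         "maxiter": maxiter or 100 * len(x0),
                         "initial_simplex": simplex},
            )
        xbest = polish.x if polish.fun <= nm.fun else nm.x
        fbest = min(polish.fun, nm.fun)
        converged = bool(polish.success or nm.success) and fbest < 1e9
    else:
        xbest = x0
    fitted = _unpack_x(spec, xbest)

    re, eta, f_ip, G, w_ip, ofv_i = _solve(packed, fitted)
    ofv = float(np.nansum(ofv_i))
    cl_t, v_t, ka_t = typical_value_arrays(fitted, packed)
    f_pred = _pred_concentrations(packed, cl_t, v_t, ka_t)
    m = packed.obs_mask
    cwres = compute_cwres(packed, fitted)

    eta_shr = {}
    for j, p in enumerate(re):
        sd = float(np.std(eta[:, j], ddof=1))
        eta_shr[p] = 100.0 * (1.0 - sd / fitted.omega[p])
    iwres = ((packed.y - f_ip) / np.sqrt(w_ip))[m]
    eps_shr = 100.0 * (1.0 - float(np.std(iwres, ddof=1))) if iwres.size > 1 else None

    sigma = {}
    if fitted.error.form in ("proportional", "combined"):
        sigma["sigma_p"] = fitted.error.sigma_p
    if fitted.error.form in ("additive", "combined"):
        sigma["sigma_a"] = fitted.error.sigma_a
    result = FitResult(
        spec=fitted,
        theta=dict(fitted.theta),
        covariate_coefficients={
            f"{t.covariate}-{t.parameter}": t.theta2 for t in fitted.covariate_terms
        },
        omega=dict(fitted.omega),
        sigma=sigma,
        ofv=ofv,
        converged=converged,
        n_function_evals=state["evals"],
        ids=list(packed.ids),
        ebes=eta,
        pred=f_pred[m],
        ipred=f_ip[m],
        cwres=cwres,
        eta_shrinkage=eta_shr,
        eps_shrinkage=eps_shr,
    )
    if compute_se:
        result.rse = standard_errors(packed, fitted, names)
    return result


def compute_shrinkage(result: FitResult) -> dict[str, float | None]:
    """η- and ε-shrinkage percentages from a fit.

    η-shrinkage = 100·(1 − SD(η̂)/ω); ε-shrinkage = 100·(1 − SD(IWRES)).
    Values near 100 mean the data carry almost no subject-level information.
    """
    out: dict[str, float | None] = {
        f"eta_{p}": v for p, v in result.eta_shrinkage.items()
    }
    out["eps"] = result.eps_shrinkage
    return out


def standard_errors(
    packed: PackedDataset, spec: ModelSpec, names: list[str] | None = None
) -> dict[str, float] | None:
    """Sandwich (robust) RSE%: H⁻¹SH⁻¹ with H the numerical Hessian of
    OFV/2 and S the cross-product of per-subject score vectors, on the
    transformed scale, delta-method back to the natural scale."""
    packed = _as_packed(packed)
    entries = _free_parameters(spec)
    if names is None:
        names = [e[0] for e in entries]
    x0 = _pack_x(spec)
    n = len(x0)

    def components(x):
        trial = _unpack_x(spec, x)
        _, _, _, _, _, ofv_i = _solve(packed, trial)
        return ofv_i

    h = 1e-4
    grads = np.zeros((packed.n_subjects, n))
    for j in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        grads[:, j] = (components(xp) - components(xm)) / (2 * h) / 2.0
    S = grads.T @ grads
    H = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1):
            xpp = x0.copy(); xpp[j] += h; xpp[k] += h
            xpm = x0.copy(); xpm[j] += h; xpm[k] -= h
            xmp = x0.copy(); xmp[j] -= h; xmp[k] += h
            xmm = x0.copy(); xmm[j] -= h; xmm[k] -= h
            H[j, k] = H[k, j] = (
                components(xpp).sum() - components(xpm).sum()
                - components(xmp).sum() + components(xmm).sum()
            ) / (4 * h * h) / 2.0
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not invertible; RSEs unavailable (use bootstrap)")
        return None
    cov = Hinv @ S @ Hinv
    se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rse = {}
    for (name, kind, key), sx, xi in zip(entries, se_x, x0):
        if kind == "covterm":
            est, se = xi, sx
        else:
            est = float(np.exp(xi))
            se = est * sx  # delta method for log-transformed parameters
        rse[name] = 100.0 * se / abs(est) if est != 0 else np.inf
    return rse
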
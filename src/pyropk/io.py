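"""Dataset I/O, run configuration and the pipeline driver.

The interchange format is the rectangular NONMEM-style CSV: one row per
event, columns ID, TIME (h since the subject's first dose), AMT (mg, dose
rows only), DV (ng/mL, observation rows only), EVID (1 = dose, 0 =
observation), MDV, plus baseline covariate columns constant within a
subject.  Decimal '.'-separated UTF-8 CSV with a mandatory header.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    DosingEvent,
    Observation,
    SubjectRecord,
)

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID")
_KNOWN_COVARIATES = set(CONTINUOUS_COVARIATES) | set(CATEGORICAL_COVARIATES)


def subjects_to_frame(subjects: list[SubjectRecord], lloq: float | None = None) -> pd.DataFrame:
    rows = []
    for s in subjects:
        events = [("dose", d.time, d) for d in s.doses] + [
            ("obs", o.time, o) for o in s.observations
        ]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, ev in events:
            row = {"ID": s.id, "TIME": t}
            if kind == "dose":
                row.update(AMT=ev.amount, DV=np.nan, EVID=1, MDV=1)
            else:
                row.update(AMT=np.nan, DV=ev.concentration, EVID=0,
                           MDV=int(ev.blq))
            row.update(s.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_subjects(df: pd.DataFrame, lloq: float = 1.0) -> list[SubjectRecord]:
    """Parse a NONMEM-style frame into SubjectRecords, validating the
    format invariants with row-addressed messages."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad_evid = df.index[~df["EVID"].isin((0, 1))]
    if len(bad_evid):
        raise ValueError(f"EVID must be 0 or 1 (rows {bad_evid.tolist()[:5]})")
    dose_with_dv = df.index[(df["EVID"] == 1) & df["DV"].notna()]
    if len(dose_with_dv):
        raise ValueError(
            f"DV present on dose (EVID=1) rows {dose_with_dv.tolist()[:5]}"
        )
    obs_no_dv = df.index[(df["EVID"] == 0) & df["DV"].isna()]
    if len(obs_no_dv):
        raise ValueError(
            f"DV missing on observation (EVID=0) rows {obs_no_dv.tolist()[:5]}"
        )
    if not pd.api.types.is_numeric_dtype(pd.to_numeric(df["DV"], errors="coerce").dtype):
        raise ValueError("DV must be numeric")
    cov_cols = [c for c in df.columns if c in _KNOWN_COVARIATES]
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            first_bad = grp.index[np.flatnonzero(np.diff(times) < 0)[0] + 1]
            raise ValueError(f"TIME not sorted within ID {sid} (row {first_bad})")
        doses = [
            DosingEvent(float(r.TIME), float(r.AMT))
            for r in grp.itertuples()
            if r.EVID == 1
        ]
        obs = [
            Observation(float(r.TIME), float(r.DV), blq=float(r.DV) < lloq)
            for r in grp.itertuples()
            if r.EVID == 0
        ]
        covariates = {}
        for c in cov_cols:
            vals = grp[c].dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"covariate {c} not constant within ID {sid}")
            covariates[c] = float(vals[0]) if len(vals) else float("nan")
        rec = SubjectRecord(str(sid), doses, obs, covariates)
        rec.validate()
        subjects.append(rec)
    ids = [s.id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject IDs")
    return subjects


def write_dataset(subjects: list[SubjectRecord], path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_dataset(path, lloq: float = 1.0) -> list[SubjectRecord]:
    return frame_to_subjects(pd.read_csv(path), lloq=lloq)


def missingness_report(subjects: list[SubjectRecord]) -> pd.Series:
    """Per-covariate missingness percentage across subjects (feeds the 20 %
    elimination rule)."""
    cov = pd.DataFrame([s.covariates for s in subjects])
    return (cov.isna().mean() * 100.0).round(2)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream: crc32 of the stage name folded
    into the master seed, kept below 2³¹."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute configured stages in order, writing one artifact per stage
    plus a reproducibility manifest (config hash + seed).

    Stages ⊆ {simulate, fit, stepwise, bootstrap, vpc, sensitivity, qc}.
    A stage failure raises after earlier artifacts are on disk.
    """
    from .cohort import CohortDesign, apply_data_rules, generate_cohort
    from .covariates import StepwiseCovariateSelector, clinical_relevance
    from .datatypes import final_model
    from .estimators import PopPKModel
    from .evaluation import bootstrap, gof_tables, ka_sensitivity, vpc

    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate", "fit"])
    if "seed" not in config:
        raise ValueError("config must provide a seed")
    seed = int(config["seed"])
    known = {"simulate", "fit", "stepwise", "bootstrap", "vpc", "sensitivity", "qc"}
    unknown = set(stages) - known
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    if any(st in stages for st in ("fit", "stepwise", "bootstrap", "vpc", "sensitivity")):
        if "model" not in config and "simulate" not in stages:
            raise ValueError("a model block or a simulate stage is required")

    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": stages,
    }

    model_cfg = config.get("model", {})
    spec = final_model(**model_cfg) if model_cfg.get("covariates", True) else None
    if spec is None:
        from .datatypes import base_model

        spec = base_model()

    subjects = None
    if "simulate" in stages:
        design = CohortDesign(**config.get("design", {}))
        sim = generate_cohort(design, spec, stage_seed(seed, "simulate"))
        subjects, log = apply_data_rules(sim.subjects, lloq=design.lloq)
        write_dataset(subjects, out / "dataset.csv")
        log.to_csv(out / "exclusions.csv", index=False)
    elif "data" in config:
        subjects = read_dataset(config["data"])
        subjects, log = apply_data_rules(subjects)
        log.to_csv(out / "exclusions.csv", index=False)

    fitted = None
    maxiter = config.get("maxiter")
    if "fit" in stages:
        est = PopPKModel.from_spec(spec, maxiter=maxiter).fit(subjects)
        fitted = est.result_
        est.parameter_table().to_csv(out / "fit_report.csv", index=False)
        gof_tables(fitted, subjects).to_csv(out / "gof.csv", index=False)
    if "stepwise" in stages:
        sel = StepwiseCovariateSelector(maxiter=maxiter).fit(subjects)
        sel.trace_.to_frame().to_csv(out / "stepwise_trace.csv", index=False)
        fitted = sel.trace_.final_fit
        if sel.trace_.final_spec.covariate_terms:
            clinical_relevance(sel.trace_.final_spec, subjects).to_csv(
                out / "clinical_relevance.csv", index=False
            )
    if "bootstrap" in stages:
        if fitted is None:
            raise ValueError("bootstrap requires a prior fit/stepwise stage")
        bs = bootstrap(subjects, fitted, n=config.get("bootstrap_n", 1000),
                       seed=stage_seed(seed, "bootstrap"), maxiter=maxiter)
        bs.summary.to_csv(out / "bootstrap.csv")
        manifest["bootstrap_converged"] = bs.n_converged
    if "vpc" in stages:
        vspec = fitted.spec if fitted is not None else spec
        v = vpc(subjects, vspec, n_sim=config.get("vpc_n", 1000),
                bins=config.get("vpc_bins", 8), seed=stage_seed(seed, "vpc"))
        v.table.to_csv(out / "vpc.csv", index=False)
    if "sensitivity" in stages:
        sspec = fitted.spec if fitted is not None else spec
        grid = tuple(config.get("ka_grid", (0.10, 0.30, 0.35, 0.357, 0.40, 0.45, 0.50)))
        ka_sensitivity(subjects, sspec, grid=grid, maxiter=maxiter).to_csv(
            out / "ka_sensitivity.csv", index=False
        )
    if "qc" in stages:
        from .qc import ReplicateBatch, stability_table

        qc_df = pd.read_csv(config["qc_replicates"])
        batches = [
            ReplicateBatch(
                nominal=float(g["nominal"].iloc[0]),
                measured=g["measured"].to_numpy(),
                level=str(name),
            )
            for name, g in qc_df.groupby("level", sort=False)
        ]
        stability_table(batches).to_csv(out / "qc_report.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
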
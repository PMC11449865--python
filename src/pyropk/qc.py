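"""Bioanalytical method-validation statistics for a plasma assay.

Covers the statistics a chromatographic assay validation reports: weighted
(1/x²) calibration regression with its acceptance rule (r > 0.99),
back-calculation accuracy windows (±15 %, ±20 % at the LLOQ), replicate
precision (RSD%) and accuracy (% of nominal), matrix factor and
IS-normalized matrix factor, extraction recovery, and the carryover rule
(blank ≤ 20 % of the LLOQ analyte response and ≤ 5 % of the IS response).
Stability batches reuse the same precision/accuracy computation with the
storage condition as a label.

The LLOQ (S/N ≥ 10) and LOD (S/N = 3) definitions are signal-to-noise
criteria of the chromatogram and are carried as metadata only; no peak
processing happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

LLOQ_SN_RATIO = 10.0   # metadata: LLOQ defined at S/N >= 10
LOD_SN_RATIO = 3.0     # metadata: LOD defined at S/N = 3


@dataclass
class ReplicateBatch:
    """Replicate measurements at one nominal QC concentration."""

    nominal: float
    measured: np.ndarray
    level: str = ""    # e.g. LLOQ / LQC / MQC / HQC
    condition: str = ""  # storage condition label for stability batches

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=float)
        if self.nominal <= 0:
            raise ValueError("nominal concentration must be > 0")
        if self.measured.size < 2:
            raise ValueError("need >= 2 replicates for an SD")


class CalibrationCurve(BaseEstimator, RegressorMixin):
    """Weighted linear calibration of response (peak-area ratio) on nominal
    concentration.

    ``weighting``: "1/x^2" (default), "1/x" or "none".  The correlation
    coefficient ``r_`` is the weighted Pearson correlation, consistent with
    the weights used for the fit; ``r_unweighted_`` is also provided.
    Acceptance requires r > 0.99.
    """

    def __init__(self, weighting: str = "1/x^2", r_acceptance: float = 0.99):
        self.weighting = weighting
        self.r_acceptance = r_acceptance

    def _weights(self, x: np.ndarray) -> np.ndarray:
        if self.weighting == "1/x^2":
            return 1.0 / x**2
        if self.weighting == "1/x":
            return 1.0 / x
        if self.weighting in ("none", None):
            return np.ones_like(x)
        raise ValueError(f"unknown weighting {self.weighting!r}")

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("need at least 2 standards")
        if np.any(x <= 0):
            raise ValueError("nominal concentrations must be > 0")
        w = self._weights(x)
        W = w / w.sum()
        xbar = np.sum(W * x)
        ybar = np.sum(W * y)
        sxx = np.sum(W * (x - xbar) ** 2)
        sxy = np.sum(W * (x - xbar) * (y - ybar))
        syy = np.sum(W * (y - ybar) ** 2)
        self.slope_ = sxy / sxx
        self.intercept_ = ybar - self.slope_ * xbar
        self.r_ = sxy / np.sqrt(sxx * syy) if sxx > 0 and syy > 0 else np.nan
        self.r_unweighted_ = float(np.corrcoef(x, y)[0, 1]) if x.size > 1 else np.nan
        self.accepted_ = bool(self.r_ > self.r_acceptance)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.slope_ * x

    def inverse(self, responses) -> np.ndarray:
        """Back-calculate concentrations from responses."""
        if self.slope_ == 0:
            raise ZeroDivisionError("degenerate calibration curve (slope 0)")
        y = np.asarray(responses, dtype=float).ravel()
        return (y - self.intercept_) / self.slope_


def fit_calibration(standards, responses, weighting: str = "1/x^2") -> dict:
    """Functional facade over :class:`CalibrationCurve`; returns slope,
    intercept, weighted r and the r > 0.99 acceptance flag."""
    curve = CalibrationCurve(weighting=weighting).fit(standards, responses)
    return {
        "slope": curve.slope_,
        "intercept": curve.intercept_,
        "r": curve.r_,
        "accepted": curve.accepted_,
        "curve": curve,
    }


def back_calculate(
    curve: CalibrationCurve,
    responses,
    nominals,
    lloq_mask=None,
    tolerance_percent: float = 15.0,
    lloq_tolerance_percent: float = 20.0,
) -> pd.DataFrame:
    """Back-calculated concentrations with per-level acceptance flags:
    within ±15 % of nominal, relaxed to ±20 % at the LLOQ.  By default the
    lowest nominal level is treated as the LLOQ."""
    nominals = np.asarray(nominals, dtype=float).ravel()
    conc = curve.inverse(responses)
    if lloq_mask is None:
        lloq_mask = nominals == nominals.min()
    lloq_mask = np.asarray(lloq_mask, dtype=bool)
    dev = 100.0 * (conc - nominals) / nominals
    limit = np.where(lloq_mask, lloq_tolerance_percent, tolerance_percent)
    return pd.DataFrame({
        "nominal": nominals,
        "back_calculated": conc,
        "deviation_percent": dev,
        "is_lloq": lloq_mask,
        "accepted": np.abs(dev) <= limit,
    })


def batch_precision_accuracy(batch: ReplicateBatch) -> dict:
    """Mean, sample SD (n−1), precision RSD% = 100·SD/mean and accuracy
    % = 100·mean/nominal for one replicate batch."""
    mean = float(np.mean(batch.measured))
    sd = float(np.std(batch.measured, ddof=1))
    return {
        "level": batch.level,
        "condition": batch.condition,
        "nominal": batch.nominal,
        "n": int(batch.measured.size),
        "mean": mean,
        "sd": sd,
        "rsd_percent": 100.0 * sd / mean,
        "accuracy_percent": 100.0 * mean / batch.nominal,
    }


def stability_table(batches: list[ReplicateBatch]) -> pd.DataFrame:
    """Stability assessment: the same precision/accuracy statistics per
    storage condition and QC level (one code path, conditions as labels)."""
    return pd.DataFrame([batch_precision_accuracy(b) for b in batches])


def matrix_factor(
    post_spiked_areas, neat_areas, is_post_spiked, is_neat
) -> dict:
    """Matrix factor per lot: (matrix present)/(matrix absent), for analyte
    and IS; IS-normalized MF = MF_analyte/MF_IS; RSD% across lots."""
    post = np.asarray(post_spiked_areas, dtype=float)
    neat = np.asarray(neat_areas, dtype=float)
    is_post = np.asarray(is_post_spiked, dtype=float)
    is_neat = np.asarray(is_neat, dtype=float)
    if np.any(neat <= 0) or np.any(is_neat <= 0):
        raise ValueError("neat (matrix-free) areas must be > 0")
    mf = post / neat
    mf_is = is_post / is_neat
    norm = mf / mf_is
    return {
        "mf_analyte": mf,
        "mf_is": mf_is,
        "is_normalized_mf": norm,
        "is_normalized_mf_mean": float(np.mean(norm)),
        "rsd_percent": 100.0 * float(np.std(norm, ddof=1) / np.mean(norm)),
    }


def recovery(pre_spiked_areas, post_spiked_areas) -> float:
    """Extraction recovery %: 100·mean(spiked before extraction)/mean(spiked
    after extraction)."""
    pre = np.asarray(pre_spiked_areas, dtype=float)
    post = np.asarray(post_spiked_areas, dtype=float)
    if np.any(post <= 0):
        raise ValueError("post-extraction areas must be > 0")
    return 100.0 * float(np.mean(pre) / np.mean(post))


def carryover_check(
    blank_analyte_area: float,
    lloq_analyte_area: float,
    blank_is_area: float,
    is_area: float,
    lloq_limit_percent: float = 20.0,
    is_limit_percent: float = 5.0,
) -> dict:
    """Carryover rule on a blank injected after the highest standard: the
    blank's analyte response must not exceed 20 % of the LLOQ response nor
    5 % of the IS response."""
    if lloq_analyte_area <= 0 or is_area <= 0:
        raise ValueError("reference areas must be > 0")
    pct_lloq = 100.0 * blank_analyte_area / lloq_analyte_area
    pct_is = 100.0 * blank_is_area / is_area
    return {
        "percent_of_lloq": pct_lloq,
        "percent_of_is": pct_is,
        "passed": pct_lloq <= lloq_limit_percent and pct_is <= is_limit_percent,
    }
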
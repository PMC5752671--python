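"""Dose-response curve fitting and AUC summarisation for viability screens.

A screen measures fraction-of-control viability at (typically eight)
concentrations spanning several logs, in duplicate.  Each drug-sample pair
is summarised by the area under the fitted viability curve over the tested
log10-concentration range, normalised to [0, 1]: AUC 1 means the drug never
reduced viability, AUC 0 means complete kill everywhere.  Lower AUC = more
sensitive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrixio import DrugResponseMatrix

logger = logging.getLogger("mergeprior")

#: parameter bounds for the 4-parameter logistic: (bottom, top, log10 EC50, hill)
_4PL_BOUNDS = ([0.0, 0.0, -14.0, 0.1], [1.0, 1.5, 0.0, 10.0])


def four_param_logistic(logc, bottom, top, log_ec50, hill):
    """Viability at log10 concentration ``logc`` under a 4PL model.

    Decreasing in concentration when ``hill`` > 0; ``bottom`` <= ``top``.
    """
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ec50)))


@dataclass
class DoseResponseCurve:
    """A fitted drug/sample dose-response record."""

    drug_id: str
    sample_id: str
    concentrations: np.ndarray  # molar, strictly increasing
    viabilities: np.ndarray  # mean over replicates, fraction of control
    fit_params: dict = field(default_factory=dict)
    fallback: bool = False  # True if 4PL failed and interpolation was used
    auc: float = float("nan")

    def predict(self, logc):
        """Fitted viability at log10 concentration(s) ``logc``."""
        logc = np.asarray(logc, dtype=float)
        if self.fallback:
            logx = np.log10(self.concentrations)
            return np.interp(logc, logx, self.viabilities)
        p = self.fit_params
        return four_param_logistic(
            logc, p["bottom"], p["top"], p["log_ec50"], p["hill"]
        )

    @property
    def min_fitted_viability(self) -> float:
        grid = np.linspace(
            math.log10(self.concentrations[0]),
            math.log10(self.concentrations[-1]),
            201,
        )
        return float(np.clip(self.predict(grid), 0.0, 1.0).min())

    @property
    def ic50(self) -> float:
        """Molar EC50 from the fit (NaN for flat or fallback curves)."""
        if self.fallback or self.fit_params.get("flat", False):
            return float("nan")
        return 10.0 ** self.fit_params["log_ec50"]


def fit_curve(
    concentrations, viabilities, drug_id: str = "", sample_id: str = ""
) -> DoseResponseCurve:
    """Fit a four-parameter logistic to viability-vs-concentration data.

    ``viabilities`` may be a 1-D vector (one value per concentration) or a
    2-D array (concentrations x replicates); replicates are averaged before
    fitting.  On non-convergence the curve falls back to monotone linear
    interpolation of the mean viability and is flagged.
    """
    conc = np.asarray(concentrations, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if viab.ndim == 2:
        viab = np.nanmean(viab, axis=1)
    if conc.size < 4 or np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(np.diff(conc) <= 0):
        order = np.argsort(conc)
        conc, viab = conc[order], viab[order]
    if np.any(viab < 0):
        raise ValueError("viabilities must be non-negative")

    logc = np.log10(conc)
    curve = DoseResponseCurve(drug_id, sample_id, conc, viab)

    if np.ptp(viab) < 1e-12:
        # flat response: top == bottom, EC50/hill meaningless
        v = float(np.clip(viab[0], 0.0, 1.5))
        curve.fit_params = {
            "bottom": min(v, 1.0),
            "top": v,
            "log_ec50": float(logc.mean()),
            "hill": 1.0,
            "flat": True,
        }
        curve.auc = compute_auc(curve)
        return curve

    # fit (bottom, span, log_ec50, hill) with span >= 0 so bottom <= top holds
    def _4pl_span(x, bottom, span, log_ec50, hill):
        return four_param_logistic(x, bottom, bottom + span, log_ec50, hill)

    p0 = [
        float(np.clip(viab.min(), 0.0, 1.0)),
        float(np.clip(np.ptp(viab), 0.0, 1.5)),
        float(logc.mean()),
        1.0,
    ]
    span_bounds = ([0.0, 0.0, -14.0, 0.1], [1.0, 1.5, 0.0, 10.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _4pl_span,
                logc,
                viab,
                p0=p0,
                bounds=span_bounds,
                maxfev=20000,
            )
        bottom, span, log_ec50, hill = map(float, popt)
        top = bottom + span
        curve.fit_params = {
            "bottom": bottom,
            "top": top,
            "log_ec50": log_ec50,
            "hill": hill,
            "flat": False,
        }
    except (RuntimeError, ValueError):
        logger.warning(
            "4PL fit failed for %s/%s; falling back to interpolation",
            drug_id,
            sample_id,
        )
        curve.fallback = True
    curve.auc = compute_auc(curve)
    return curve


def compute_auc(curve: DoseResponseCurve, n_grid: int = 512) -> float:
    """Normalised area under the fitted viability curve.

    Trapezoidal mean of the fitted viability (clipped to [0, 1]) over the
    tested log10-concentration range, divided by the range width so values
    are comparable across drugs with different ranges.  Returns a value in
    [0, 1].
    """
    lo = math.log10(curve.concentrations[0])
    hi = math.log10(curve.concentrations[-1])
    grid = np.linspace(lo, hi, n_grid)
    v = np.clip(curve.predict(grid), 0.0, 1.0)
    return float(np.trapezoid(v, grid) / (hi - lo))


def activity_filter(
    min_viability: pd.DataFrame,
    threshold: float = 0.5,
    sample_fraction: float = 0.5,
) -> set[str]:
    """Drugs active (viability <= ``threshold``) in enough samples.

    Parameters
    ----------
    min_viability : DataFrame, drugs x samples
        Minimum fitted viability per drug-sample pair over the tested range.
    threshold : float
        Viability at or below which a drug counts as active in a sample.
    sample_fraction : float
        A drug is retained when active in at least
        ``ceil(sample_fraction * n_samples)`` samples.
    """
    if min_viability.size == 0:
        return set()
    n = min_viability.shape[1]
    need = math.ceil(sample_fraction * n)
    active_counts = (min_viability <= threshold).sum(axis=1)
    return set(min_viability.index[active_counts >= need])


def replicate_consistency(auc_rep1, auc_rep2):
    """Pearson correlation between replicate AUC vectors (QC statistic).

    Returns ``(r, p)``; ``(nan, nan)`` with a warning if either vector has
    zero variance.
    """
    a = np.asarray(auc_rep1, dtype=float)
    b = np.asarray(auc_rep2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if np.ptp(a) < 1e-15 or np.ptp(b) < 1e-15:
        warnings.warn("zero variance in a replicate vector; r undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def screen_to_auc_matrix(
    screen: pd.DataFrame, filter_active: bool = False
) -> tuple[DrugResponseMatrix, pd.DataFrame]:
    """Process a long-format raw screen into a drugs x samples AUC matrix.

    ``screen`` columns: drug_id, sample_id, concentration_M, replicate,
    viability_fraction.  Replicates are averaged per concentration before
    fitting.  Returns the AUC matrix plus a QC frame (per drug-sample:
    auc, min fitted viability, fallback flag).
    """
    required = {
        "drug_id",
        "sample_id",
        "concentration_M",
        "replicate",
        "viability_fraction",
    }
    missing = required - set(screen.columns)
    if missing:
        raise ValueError(f"raw screen missing columns: {sorted(missing)}")

    records = []
    for (drug, sample), grp in screen.groupby(["drug_id", "sample_id"], sort=True):
        mean_v = grp.groupby("concentration_M")["viability_fraction"].mean()
        curve = fit_curve(
            mean_v.index.to_numpy(), mean_v.to_numpy(), str(drug), str(sample)
        )
        records.append(
            {
                "drug_id": str(drug),
                "sample_id": str(sample),
                "auc": curve.auc,
                "min_viability": curve.min_fitted_viability,
                "fallback": curve.fallback,
            }
        )
    qc = pd.DataFrame.from_records(records)
    auc_wide = qc.pivot(index="drug_id", columns="sample_id", values="auc")
    if filter_active:
        minv = qc.pivot(
            index="drug_id", columns="sample_id", values="min_viability"
        )
        keep = sorted(activity_filter(minv))
        auc_wide = auc_wide.loc[keep]
    matrix = DrugResponseMatrix(
        list(auc_wide.index), list(auc_wide.columns), auc_wide.to_numpy()
    )
    return matrix, qc
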
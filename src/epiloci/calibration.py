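"""Significance calibration: permutation P-values, the AUC to -log10 P map,
multiple-testing thresholds, FDR, rank agreement, and the liability-threshold
conversion between AUC and heritability.

The significance of a SNP group scored by cross-validated AUC is estimated by
permutation: labels are shuffled within each subsample (preserving
case/control counts and the population structure the meta-analysis conditions
on), the full cross-validation is re-run, and the empirical P-value is the
add-one fraction of null AUCs at least as large as the observed one.  Because
-log10 P is close to linear in AUC above ~0.51, a linear calibration fitted on
permutation-derived points extrapolates significance to AUC values whose
direct permutation estimate would need astronomically many shuffles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .collective import CVConfig, cross_validate, shuffle_labels

__all__ = [
    "CalibrationModel",
    "LiabilityModel",
    "permutation_pvalue",
    "fit_auc_logp_regression",
    "predict_logp",
    "auc_threshold_for_alpha",
    "bonferroni_threshold",
    "fdr_qvalues",
    "kendall_tau",
    "auc_from_h2",
    "h2_from_auc",
]


# ---------------------------------------------------------------------------
# Permutation P-values
# ---------------------------------------------------------------------------

def permutation_pvalue(
    tables,
    snpset,
    config: CVConfig,
    n_perm: int = 99,
    seed: int = 0,
    return_null: bool = False,
):
    """Empirical P-value of a SNP group's cross-validated AUC.

    Labels are shuffled within each subsample; ``cross_validate`` is re-run
    per permutation with the AUC maximum over the epsilon grid as the
    statistic.  P = (#{null AUC >= observed} + 1) / (n_perm + 1), the add-one
    estimator (valid and never zero; the plain fraction is recovered as
    n_perm grows).
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    observed = cross_validate(tables, snpset, config).auc_max
    rng = np.random.default_rng(int(seed) % (2**31))
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = shuffle_labels(tables, rng)
        null[b] = cross_validate(shuffled, snpset, config).auc_max
    p = (float((null >= observed).sum()) + 1.0) / (n_perm + 1.0)
    if return_null:
        return observed, p, null
    return observed, p


# ---------------------------------------------------------------------------
# AUC -> -log10 P calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Linear map -log10 P = intercept + slope * AUC, valid above ``auc_min``."""

    slope: float
    intercept: float
    r_squared: float
    auc_min: float = 0.51
    auc_max_fitted: float = 1.0
    n_points: int = 0


def fit_auc_logp_regression(points, auc_min: float = 0.51) -> CalibrationModel:
    """OLS of -log10 P on AUC over permutation points with AUC above ``auc_min``.

    ``points`` is a sequence of (AUC, empirical P) pairs; points with P = 1
    or AUC <= auc_min are excluded.  At least 3 usable points are required.
    """
    pts = [(a, p) for a, p in points if a > auc_min and 0.0 < p < 1.0]
    if len(pts) < 3:
        raise ValueError(
            f"need >=3 points with AUC > {auc_min} and P < 1 (got {len(pts)})"
        )
    aucs = np.array([a for a, _ in pts])
    logp = -np.log10([p for _, p in pts])
    fit = stats.linregress(aucs, logp)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        auc_min=auc_min,
        auc_max_fitted=float(aucs.max()),
        n_points=len(pts),
    )


def predict_logp(model: CalibrationModel, auc: float) -> float:
    """P-value implied by the calibration line at the given AUC.

    AUC below the validity bound is an error; extrapolation beyond the
    largest calibrated AUC is allowed but flagged with a warning.
    """
    if auc < model.auc_min:
        raise ValueError(f"AUC {auc} below calibration validity bound {model.auc_min}")
    if auc > model.auc_max_fitted:
        warnings.warn(
            f"AUC {auc:.3f} beyond largest calibrated AUC "
            f"{model.auc_max_fitted:.3f}; extrapolating"
        )
    return float(10.0 ** -(model.intercept + model.slope * auc))


def auc_threshold_for_alpha(model: CalibrationModel, alpha: float) -> float:
    """AUC at which the calibration line crosses P = alpha (inverse map)."""
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return float((-math.log10(alpha) - model.intercept) / model.slope)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def fdr_qvalues(pvals, method: str = "bh") -> np.ndarray:
    """False-discovery-rate q-values, input order preserved.

    ``bh``: Benjamini-Hochberg step-up (default).  ``storey``: Storey's
    q-values with pi0 estimated at lambda = 0.5.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must lie in (0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, (p > 0.5).mean() / 0.5) if p.size else 1.0
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def kendall_tau(ranking_a, ranking_b):
    """Kendall's tau-b with two-sided normal-approximation P-value."""
    a = np.asarray(ranking_a, dtype=float)
    b = np.asarray(ranking_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("rankings must share >=2 items")
    res = stats.kendalltau(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Liability-threshold AUC <-> heritability
# ---------------------------------------------------------------------------

@dataclass
class LiabilityModel:
    """Liability-threshold quantities at population prevalence ``K``.

    Disease occurs when a standard-normal latent liability exceeds the
    upper-K quantile T; ``i_case``/``i_ctrl`` are the mean liabilities of
    affected and unaffected individuals.
    """

    prevalence: float

    def __post_init__(self):
        K = self.prevalence
        if not 0 < K < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        self.threshold = float(stats.norm.isf(K))
        z = float(stats.norm.pdf(self.threshold))
        self.i_case = z / K
        self.i_ctrl = -z / (1.0 - K)


def auc_from_h2(h2: float, prevalence: float) -> float:
    """AUC achieved by a risk score explaining ``h2`` of liability variance.

    Under the liability-threshold model the score separates cases and
    controls by (i_case - i_ctrl) h2 with group variances
    h2 (1 - h2 i (i - T)); the AUC is the normal probability of a case
    outscoring a control.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if h2 == 0:
        return 0.5
    lm = LiabilityModel(prevalence)
    T, ic, iu = lm.threshold, lm.i_case, lm.i_ctrl
    num = h2 * (ic - iu)
    var = h2 * (1.0 - h2 * ic * (ic - T)) + h2 * (1.0 - h2 * iu * (iu - T))
    if var <= 0:
        return 1.0
    return float(stats.norm.cdf(num / math.sqrt(var)))


def h2_from_auc(auc: float, prevalence: float, tol: float = 1e-10) -> float:
    """Liability-scale variance explained implied by an AUC (numerical inverse).

    The forward map is strictly increasing in h2 for fixed prevalence, so the
    inverse is found by bisection to ``tol``.  AUC below 0.5, or so large that
    no h2 <= 1 attains it, is an error.
    """
    if auc < 0.5:
        raise ValueError("AUC below 0.5 has no liability-model interpretation")
    if auc == 0.5:
        return 0.0
    if auc >= auc_from_h2(1.0, prevalence):
        raise ValueError("AUC unattainable for any h2 <= 1 at this prevalence")
    return float(
        optimize.brentq(
            lambda h: auc_from_h2(h, prevalence) - auc, 0.0, 1.0, xtol=tol
        )
    )
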
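"""Genotype distribution models for case/control discrimination.

Case and control genotype distributions are modeled per subsample as discrete
exponential-family (Potts-like) distributions over coded genotype levels:

    P(a_1..a_m) proportional to exp( sum_i h_i(a_i) + sum_{i<j} J_ij(a_i, a_j) )

The independent-loci (IL) limit has all couplings zero and closed-form field
estimates; the interacting model is fit by L2-penalized pseudo-likelihood
(per-site multinomial conditionals), with the penalty controlled by a
regularization parameter epsilon in [0, 1]: epsilon=0 recovers IL exactly and
epsilon=1 is the (numerically stabilized) unpenalized limit.  Disease risk
scores are the log-likelihood ratios of the two fitted distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import xlogy
from scipy.stats import chi2

from .geno_io import MISSING, GenotypeTable
from .params import CODING_LEVELS, PottsParams

#: 1-df chi-square median, denominator of the genomic inflation factor
CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, 1))

#: numerical ridge keeping the unpenalized (epsilon=1) objective bounded
#: (negligible against the per-individual log-likelihood, but it caps the
#: coupling magnitudes under quasi-separation)
RIDGE_FLOOR = 1e-5

__all__ = [
    "CHI2_1DF_MEDIAN",
    "ConvergenceError",
    "DDAModel",
    "ILResult",
    "encode",
    "fit_il",
    "il_meta",
    "il_scan",
    "genomic_inflation",
    "fit_dda",
    "score",
    "lambda_from_epsilon",
]


class ConvergenceError(RuntimeError):
    """Pseudo-likelihood optimizer failed to reach the gradient tolerance."""

    def __init__(self, msg: str, grad_norm: float):
        super().__init__(f"{msg} (grad inf-norm {grad_norm:.3g})")
        self.grad_norm = grad_norm


def encode(dosage: np.ndarray, coding: str) -> np.ndarray:
    """Map minor-allele dosages to model levels.

    genotypic: identity on {0,1,2}; dominant: 1{dosage>=1}; recessive:
    1{dosage==2}.  The missing sentinel is preserved.
    """
    dosage = np.asarray(dosage)
    ok = (dosage == MISSING) | ((dosage >= 0) & (dosage <= 2))
    if not ok.all():
        raise ValueError("dosage outside {0,1,2,missing}")
    miss = dosage == MISSING
    if coding == "genotypic":
        out = dosage.astype(np.int8)
    elif coding == "dominant":
        out = (dosage >= 1).astype(np.int8)
    elif coding == "recessive":
        out = (dosage == 2).astype(np.int8)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    out[miss] = MISSING
    return out


# ---------------------------------------------------------------------------
# Independent loci
# ---------------------------------------------------------------------------

def _level_counts(levels: np.ndarray, L: int) -> np.ndarray:
    """Counts per (level, SNP), ignoring missing entries.  Shape (L, m)."""
    counts = np.empty((L, levels.shape[1]))
    for a in range(L):
        counts[a] = (levels == a).sum(axis=0)
    return counts


def fit_il(levels: np.ndarray, L: int, kappa: float = 0.5) -> np.ndarray:
    """Closed-form independent-loci fields from one group's level matrix.

    h_i(a) = ln( (n_i(a) + kappa) / (n_i(0) + kappa) ), so h_i(0) = 0.
    The pseudocount ``kappa`` guards empty genotype cells.
    """
    if levels.shape[0] < 1:
        raise ValueError("need at least one individual")
    counts = _level_counts(levels, L)
    h = np.log((counts + kappa) / (counts[0] + kappa)).T
    return h


def il_meta(
    case_levels: Sequence[np.ndarray],
    control_levels: Sequence[np.ndarray],
    L: int,
):
    """Meta-analytic per-SNP likelihood-ratio (G) tests across subsamples.

    For each subsample the G statistic of the group-by-level contingency table
    is computed per SNP; statistics add over subsamples and the combined
    statistic is referred to chi-square with (L-1) * n_subsamples degrees of
    freedom.  Monomorphic SNPs contribute q_s = 0 but the df is still counted.

    Returns ``(q, df, p)`` arrays over SNPs.
    """
    if len(case_levels) != len(control_levels) or not case_levels:
        raise ValueError("need matched case/control matrices per subsample")
    m = case_levels[0].shape[1]
    q = np.zeros(m)
    for ca, ct in zip(case_levels, control_levels):
        n_ca = _level_counts(ca, L)
        n_ct = _level_counts(ct, L)
        n_all = n_ca + n_ct
        tot_ca, tot_ct = n_ca.sum(axis=0), n_ct.sum(axis=0)
        tot = tot_ca + tot_ct
        q_s = 2.0 * (
            xlogy(n_ca, n_ca).sum(axis=0)
            + xlogy(n_ct, n_ct).sum(axis=0)
            - xlogy(n_all, n_all).sum(axis=0)
            - xlogy(tot_ca, tot_ca)
            - xlogy(tot_ct, tot_ct)
            + xlogy(tot, tot)
        )
        q += np.maximum(q_s, 0.0)
    q[q < 1e-9] = 0.0  # cancellation noise from the xlogy sums
    df = (L - 1) * len(case_levels)
    p = chi2.sf(q, df)
    return q, np.full(m, df), np.clip(p, np.finfo(float).tiny, 1.0)


def genomic_inflation(pvals) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    observed P-values divided by the null median 0.4549."""
    pvals = np.asarray(pvals, dtype=float)
    stats = chi2.isf(pvals, 1)
    return float(np.median(stats) / CHI2_1DF_MEDIAN)


@dataclass
class ILResult:
    """Per-SNP independent-loci scan: statistics, P-values, inflation factor."""

    snp_ids: list
    q: np.ndarray
    df: np.ndarray
    p: np.ndarray
    lambda_g: float

    def to_frame(self, snp_meta=None):
        import pandas as pd

        df = pd.DataFrame({"snp": self.snp_ids, "q": self.q, "df": self.df, "p": self.p})
        if snp_meta is not None:
            df = df.merge(
                snp_meta[["id", "chrom", "pos"]], left_on="snp", right_on="id"
            ).drop(columns="id")[["snp", "chrom", "pos", "q", "df", "p"]]
        return df


def il_scan(tables: Sequence[GenotypeTable], coding: str = "genotypic") -> ILResult:
    """Run the meta IL test on every SNP of a multi-subsample cohort."""
    L = CODING_LEVELS[coding]
    cases, controls = [], []
    for t in tables:
        lv = encode(t.genotypes, coding)
        cases.append(lv[t.labels])
        controls.append(lv[~t.labels])
    q, df, p = il_meta(cases, controls, L)
    return ILResult(tables[0].snp_ids, q, df, p, genomic_inflation(p))


# ---------------------------------------------------------------------------
# Pseudo-likelihood fitting of the interacting model
# ---------------------------------------------------------------------------

def lambda_from_epsilon(epsilon: float, lam0: float = 0.01) -> float:
    """Coupling penalty weight: lambda(eps) = lam0 * (1/eps - 1).

    eps -> 0 sends the penalty to infinity (IL limit, handled in closed form);
    eps = 1 is the unpenalized limit (a tiny numerical ridge remains).  The
    scale ``lam0`` is set so that shrinkage of couplings sweeps from near-total
    to negligible as eps crosses the default grid: per-individual Fisher
    information per coupling parameter is of order 0.1 for common variants,
    so lam0 = 0.01 puts the half-shrinkage point at eps ~ 0.2 rather than
    compressing all interaction recovery into eps ~ 1.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon == 0.0:
        return np.inf
    return lam0 * (1.0 / epsilon - 1.0) + RIDGE_FLOOR


def _one_hot(levels: np.ndarray, L: int) -> np.ndarray:
    """Indicators of non-reference levels: (n, m) -> (n, m*(L-1)) float."""
    n, m = levels.shape
    F = np.zeros((n, m, L - 1))
    for a in range(1, L):
        F[:, :, a - 1] = levels == a
    return F.reshape(n, m * (L - 1))


def _pl_objective(theta, F, Y, m, L, lam_J, lam_h, self_mask):
    """Joint negative pseudo-log-likelihood (per individual) and gradient.

    The objective is separable over sites; fitting all per-site multinomial
    conditionals in one optimization is algebraically identical to fitting
    them one site at a time.
    """
    n, d = F.shape
    K = L - 1
    b = theta[: m * K]
    W = theta[m * K :].reshape(m * K, d)
    W = W * self_mask
    Z = F @ W.T + b  # (n, m*K) logits vs the zero reference level
    Zr = Z.reshape(n, m, K)
    zmax = np.maximum(Zr.max(axis=2), 0.0)
    ez = np.exp(Zr - zmax[:, :, None])
    denom = np.exp(-zmax) + ez.sum(axis=2)
    lse = zmax + np.log(denom)
    nll = (lse.sum() - (Z * Y).sum()) / n
    P = (ez / denom[:, :, None]).reshape(n, m * K)
    G = (P - Y) / n
    grad_b = G.sum(axis=0) + 2.0 * lam_h * b
    grad_W = (G.T @ F + 2.0 * lam_J * W) * self_mask
    f = nll + lam_J * (W * W).sum() + lam_h * (b * b).sum()
    return f, np.concatenate([grad_b, grad_W.ravel()])


def _fit_pl(
    levels: np.ndarray,
    L: int,
    lam_J: float,
    lam_h: float,
    theta0: np.ndarray | None = None,
    tol: float = 1e-6,
    maxiter: int = 500,
):
    """Fit all per-site multinomial conditionals jointly by L-BFGS.

    Returns ``(h, J, theta)`` where ``J`` is the symmetrized coupling tensor
    and ``theta`` the raw parameter vector (for warm starts along an
    epsilon grid).
    """
    n, m = levels.shape
    K = L - 1
    d = m * K
    F = _one_hot(levels, L)
    Y = F.copy()
    self_mask = np.ones((d, d))
    for i in range(m):
        self_mask[i * K : (i + 1) * K, i * K : (i + 1) * K] = 0.0
    if theta0 is None:
        # start fields at the IL solution, couplings at zero
        theta0 = np.concatenate(
            [fit_il(levels, L)[:, 1:].ravel(), np.zeros(d * d)]
        )
    res = optimize.minimize(
        _pl_objective,
        theta0,
        args=(F, Y, m, L, lam_J, lam_h, self_mask),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-12, "maxcor": 20},
    )
    grad_norm = float(np.abs(res.jac).max())
    if not res.success and grad_norm > max(100 * tol, 1e-3):
        raise ConvergenceError("pseudo-likelihood fit did not converge", grad_norm)
    if not res.success:
        warnings.warn(
            f"pseudo-likelihood fit stopped early (grad inf-norm {grad_norm:.2g})"
        )
    b = res.x[:d]
    W = (res.x[d:].reshape(d, d)) * self_mask
    h = np.zeros((m, L))
    h[:, 1:] = b.reshape(m, K)
    Wr = W.reshape(m, K, m, K)
    J = np.zeros((m, m, L, L))
    J[:, :, 1:, 1:] = (Wr.transpose(0, 2, 1, 3) + Wr.transpose(2, 0, 3, 1)) / 2.0
    return h, J, res.x


def fit_dda(
    levels_by_subsample: Mapping[str, np.ndarray],
    epsilon: float,
    coding: str = "genotypic",
    lam0: float = 0.01,
    kappa: float = 0.5,
    tol: float = 1e-6,
    maxiter: int = 500,
    warm: Mapping[str, np.ndarray] | None = None,
):
    """Fit one group's genotype distribution per subsample.

    At ``epsilon = 0`` the exact closed-form IL solution is returned (all
    couplings zero, no optimization).  Otherwise each subsample's model is fit
    independently by penalized pseudo-likelihood with coupling penalty
    ``lambda(epsilon)`` and a weak Gaussian prior on fields equivalent to the
    IL pseudocount.

    Returns ``(params_by_subsample, warm_states)``; pass ``warm_states`` back
    in as ``warm`` when sweeping an epsilon grid.
    """
    L = CODING_LEVELS[coding]
    out, states = {}, {}
    for s, levels in levels_by_subsample.items():
        if (levels == MISSING).any():
            raise ValueError("fit_dda requires complete (imputed) genotypes")
        if epsilon == 0.0:
            out[s] = PottsParams(coding, fit_il(levels, L, kappa))
            states[s] = None
            continue
        n = levels.shape[0]
        lam_J = lambda_from_epsilon(epsilon, lam0)
        lam_h = kappa / max(n, 1)
        theta0 = warm.get(s) if warm else None
        h, J, theta = _fit_pl(levels, L, lam_J, lam_h, theta0, tol, maxiter)
        out[s] = PottsParams(coding, h, J)
        states[s] = theta
    return out, states


# ---------------------------------------------------------------------------
# Risk scores
# ---------------------------------------------------------------------------

def _energy(params: PottsParams, levels: np.ndarray) -> np.ndarray:
    """Unnormalized log-probability of each individual's genotype vector."""
    F = _one_hot(levels, params.n_levels)
    e = F @ params.field_vector()
    if np.any(params.J):
        Jmat = params.coupling_dense()
        e = e + 0.5 * ((F @ Jmat) * F).sum(axis=1)
    return e


def score(
    case_params: PottsParams,
    control_params: PottsParams,
    levels: np.ndarray,
    center: float = 0.0,
) -> np.ndarray:
    """Disease risk score: log-likelihood ratio of case vs control models,
    shifted by the per-subsample centering constant ``center``."""
    if case_params.coding != control_params.coding:
        raise ValueError("case and control models must share the coding")
    return _energy(case_params, levels) - _energy(control_params, levels) - center


@dataclass
class DDAModel:
    """Fitted case/control distributions per subsample, plus score centering.

    ``centers[s]`` is the mean raw score of the training controls of
    subsample ``s``; subtracting it makes scores comparable across
    subsamples when pooled.
    """

    coding: str
    epsilon: float
    snp_ids: list
    case: dict
    control: dict
    centers: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.case) != set(self.control):
            raise ValueError("case/control subsample sets differ")
        if not self.centers:
            self.centers = {s: 0.0 for s in self.case}

    def score(self, levels: np.ndarray, subsample: str) -> np.ndarray:
        if subsample not in self.case:
            raise KeyError(f"unknown subsample {subsample!r}")
        return score(
            self.case[subsample],
            self.control[subsample],
            levels,
            self.centers[subsample],
        )

    # -- serialization (versioned JSON; couplings stored sparsely) ----------
    def to_json(self) -> str:
        def pack(p: PottsParams):
            nz = np.argwhere(p.J != 0.0)
            return {
                "h": p.h.tolist(),
                "J": [[*map(int, idx), float(p.J[tuple(idx)])] for idx in nz],
            }

        return json.dumps(
            {
                "format": "epiloci-dda-1",
                "coding": self.coding,
                "epsilon": self.epsilon,
                "snp_ids": self.snp_ids,
                "subsamples": {
                    s: {
                        "case": pack(self.case[s]),
                        "control": pack(self.control[s]),
                        "center": self.centers[s],
                    }
                    for s in self.case
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DDAModel":
        obj = json.loads(text)
        if obj.get("format") != "epiloci-dda-1":
            raise ValueError("unrecognized model format")
        coding = obj["coding"]
        L = CODING_LEVELS[coding]
        m = len(obj["snp_ids"])

        def unpack(d):
            J = np.zeros((m, m, L, L))
            for i, j, a, b, v in d["J"]:
                J[i, j, a, b] = v
            return PottsParams(coding, np.array(d["h"]), J)

        case, control, centers = {}, {}, {}
        for s, d in obj["subsamples"].items():
            case[s] = unpack(d["case"])
            control[s] = unpack(d["control"])
            centers[s] = d["center"]
        return cls(coding, obj["epsilon"], obj["snp_ids"], case, control, centers)
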
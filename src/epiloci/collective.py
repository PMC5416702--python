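"""Cross-validated AUC scoring of SNP groups with epsilon optimization.

A SNP group (gene, pathway, or genome-wide selection) is scored by fitting
case and control genotype-distribution models on training folds and measuring
the area under the ROC curve of the resulting risk scores on held-out test
folds, for each value of the interaction-regularization parameter epsilon.
Folds are stratified by subsample and case/control status; all test scores
are pooled (after per-subsample training-control centering) into a single
AUC per epsilon.  No statistic computed on test individuals ever enters SNP
selection, imputation, model fitting, or centering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import dda
from .geno_io import GenotypeTable, SNPSet, impute_missing
from .params import CODING_LEVELS

DEFAULT_EPSILON_GRID = (0.0, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0)

__all__ = [
    "DEFAULT_EPSILON_GRID",
    "CVConfig",
    "CVResult",
    "auc",
    "auc_ci95",
    "fold_assignments",
    "cross_validate",
    "leakage_probe",
    "downsample",
    "shuffle_labels",
]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2 (midranks).

    Equals the probability that a random case outscores a random control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires at least one case and one control")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_placements(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    case, ctl = scores[labels], scores[~labels]
    n1, n0 = case.size, ctl.size
    tx = rankdata(scores)
    t1 = rankdata(case)
    t0 = rankdata(ctl)
    v10 = (tx[labels] - t1) / n0  # placement of each case among controls
    v01 = 1.0 - (tx[~labels] - t0) / n1  # placement of each control among cases
    return v10, v01


def auc_ci95(scores, labels) -> float:
    """Half-width of the DeLong 95% confidence interval for the AUC."""
    v10, v01 = _delong_placements(scores, labels)
    n1, n0 = v10.size, v01.size
    if n1 < 2 or n0 < 2:
        raise ValueError("DeLong variance requires >=2 per class")
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    return float(1.96 * math.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Configuration and folds
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Cross-validation settings.

    ``epsilon_grid`` must contain 0 (the IL limit).  When
    ``selection_p_cutoff`` is set, genome-wide SNP selection by training-fold
    meta IL P-value is performed inside each fold.
    """

    k_folds: int = 5
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID
    selection_p_cutoff: float | None = None
    coding: str = "genotypic"
    seed: int = 0
    lam0: float = 0.01
    kappa: float = 0.5
    tol: float = 1e-6
    maxiter: int = 500

    def __post_init__(self):
        grid = tuple(float(e) for e in self.epsilon_grid)
        if 0.0 not in grid:
            raise ValueError("epsilon grid must include 0 (the IL limit)")
        if any(e < 0 or e > 1 for e in grid):
            raise ValueError("epsilon values must lie in [0, 1]")
        if self.selection_p_cutoff is not None and not (0 < self.selection_p_cutoff <= 1):
            raise ValueError("selection cutoff must lie in (0, 1]")
        if self.coding not in CODING_LEVELS:
            raise ValueError(f"unknown coding {self.coding!r}")
        self.epsilon_grid = grid


def fold_assignments(table: GenotypeTable, k: int, seed: int) -> np.ndarray:
    """Stratified fold ids per individual; a pure function of (seed, ids).

    Cases and controls are shuffled separately with a generator seeded from
    the run seed and a hash of the individual-id list, then dealt round-robin,
    so every fold has both groups and test folds partition the sample.
    """
    import zlib

    digest = zlib.crc32("\x00".join(table.individual_ids).encode())
    rng = np.random.default_rng([int(seed) % (2**31), digest])
    folds = np.empty(table.n_individuals, dtype=int)
    for group in (True, False):
        idx = np.where(table.labels == group)[0]
        if idx.size < k:
            raise ValueError(
                f"subsample {table.subsample_id}: fewer than k={k} "
                f"{'cases' if group else 'controls'}"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return folds


@dataclass
class CVResult:
    """AUC(epsilon) curve and summary from one cross-validated scoring run."""

    auc_by_epsilon: dict
    auc_max: float
    epsilon_star: float
    ci95: float
    mean_selected_m: float
    per_fold: list = field(default_factory=list)
    n_test: int = 0


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _check_shared_panel(tables):
    ids0 = tables[0].snp_ids
    for t in tables[1:]:
        if t.snp_ids != ids0:
            raise ValueError("all subsamples must share one SNP panel")
    return ids0


def _selection_ids(tables, train_rows, coding, cutoff):
    """Meta IL P-values from training rows only; ids passing the cutoff."""
    L = CODING_LEVELS[coding]
    cases, controls = [], []
    for t, rows in zip(tables, train_rows):
        lv = dda.encode(t.genotypes[rows], coding)
        lab = t.labels[rows]
        cases.append(lv[lab])
        controls.append(lv[~lab])
    _, _, p = dda.il_meta(cases, controls, L)
    ids = tables[0].snp_ids
    return [s for s, pv in zip(ids, p) if pv < cutoff]


def cross_validate(
    tables: Sequence[GenotypeTable],
    snpset: SNPSet | Sequence[str] | None,
    config: CVConfig,
) -> CVResult:
    """Cross-validated AUC(epsilon) for one SNP group.

    ``snpset`` fixes the SNP panel; passing ``None`` requires
    ``config.selection_p_cutoff`` and selects SNPs genome-wide within each
    training fold by meta IL P-value (the only supported selection mode —
    whole-sample pre-CV selection is deliberately not an option here).
    """
    tables = list(tables)
    _check_shared_panel(tables)
    if snpset is None and config.selection_p_cutoff is None:
        raise ValueError("either a SNP set or a selection cutoff is required")
    fixed_ids = None
    if snpset is not None:
        fixed_ids = list(snpset.snp_ids) if isinstance(snpset, SNPSet) else list(snpset)

    grid = sorted(set(config.epsilon_grid))
    folds = [fold_assignments(t, config.k_folds, config.seed) for t in tables]
    scores_by_eps = {e: [] for e in grid}
    labels_all = []
    per_fold = []

    for f in range(config.k_folds):
        train_rows = [np.where(fa != f)[0] for fa in folds]
        test_rows = [np.where(fa == f)[0] for fa in folds]
        for t, rows in zip(tables, train_rows):
            if t.labels[rows].sum() == 0 or (~t.labels[rows]).sum() == 0:
                raise ValueError("fold stratification produced an empty group")

        if fixed_ids is not None:
            panel = fixed_ids
        else:
            panel = _selection_ids(
                tables, train_rows, config.coding, config.selection_p_cutoff
            )
        per_fold.append({"fold": f, "m": len(panel)})

        n_test_fold = 0
        for t, rows in zip(tables, test_rows):
            labels_all.append(t.labels[rows])
            n_test_fold += rows.size
        if not panel:
            warnings.warn(f"fold {f}: no SNPs selected; recording uninformative scores")
            for e in grid:
                scores_by_eps[e].append(np.zeros(n_test_fold))
            continue

        sub_tables = [t.subset_snps(panel) for t in tables]
        sub_tables = [
            impute_missing(t, rows) for t, rows in zip(sub_tables, train_rows)
        ]
        levels = [dda.encode(t.genotypes, config.coding) for t in sub_tables]

        train_case = {}
        train_ctl = {}
        test_levels = {}
        for t, lv, tr, te in zip(sub_tables, levels, train_rows, test_rows):
            lab = t.labels
            train_case[t.subsample_id] = lv[tr][lab[tr]]
            train_ctl[t.subsample_id] = lv[tr][~lab[tr]]
            test_levels[t.subsample_id] = lv[te]

        warm_case = warm_ctl = None
        for e in grid:
            case_params, warm_case = dda.fit_dda(
                train_case, e, config.coding, config.lam0, config.kappa,
                config.tol, config.maxiter, warm=warm_case,
            )
            ctl_params, warm_ctl = dda.fit_dda(
                train_ctl, e, config.coding, config.lam0, config.kappa,
                config.tol, config.maxiter, warm=warm_ctl,
            )
            fold_scores = []
            for t in sub_tables:
                s = t.subsample_id
                center = float(
                    dda.score(case_params[s], ctl_params[s], train_ctl[s]).mean()
                )
                fold_scores.append(
                    dda.score(case_params[s], ctl_params[s], test_levels[s], center)
                )
            scores_by_eps[e].append(np.concatenate(fold_scores))

    labels_pooled = np.concatenate(labels_all)
    auc_by_eps = {}
    pooled = {}
    for e in grid:
        pooled[e] = np.concatenate(scores_by_eps[e])
        auc_by_eps[e] = auc(pooled[e], labels_pooled)
    eps_star = max(grid, key=lambda e: (auc_by_eps[e], -e))
    auc_max = auc_by_eps[eps_star]
    try:
        ci95 = auc_ci95(pooled[eps_star], labels_pooled)
    except ValueError:  # pragma: no cover - tiny cohorts
        ci95 = float("nan")
    return CVResult(
        auc_by_epsilon=auc_by_eps,
        auc_max=auc_max,
        epsilon_star=eps_star,
        ci95=ci95,
        mean_selected_m=float(np.mean([d["m"] for d in per_fold])),
        per_fold=per_fold,
        n_test=labels_pooled.size,
    )


def leakage_probe(tables, config: CVConfig, cutoff: float | None = None):
    """Contrast clean within-fold SNP selection with whole-sample selection.

    Returns ``(clean, leaked)`` CVResults.  The leaked arm selects SNPs by
    meta IL P-value computed on the *entire* sample before cross-validation —
    exactly the malpractice that inflates test AUCs — and is provided only as
    a diagnostic.
    """
    cutoff = cutoff if cutoff is not None else config.selection_p_cutoff
    if cutoff is None:
        raise ValueError("leakage probe requires a selection cutoff")
    clean_cfg = CVConfig(**{**config.__dict__, "selection_p_cutoff": cutoff})
    clean = cross_validate(tables, None, clean_cfg)

    all_rows = [np.arange(t.n_individuals) for t in tables]
    leaked_ids = _selection_ids(tables, all_rows, config.coding, cutoff)
    fixed_cfg = CVConfig(**{**config.__dict__, "selection_p_cutoff": None})
    if not leaked_ids:
        warnings.warn("whole-sample selection chose no SNPs; leaked AUC is 0.5")
        leaked = CVResult({0.0: 0.5}, 0.5, 0.0, float("nan"), 0.0, [], 0)
    else:
        leaked = cross_validate(tables, leaked_ids, fixed_cfg)
    return clean, leaked


def downsample(tables, fraction: float, seed: int = 0) -> list:
    """Keep ``floor(fraction * n)`` cases and controls per subsample, uniformly."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(tables)
    rng = np.random.default_rng(int(seed) % (2**31))
    out = []
    for t in tables:
        keep = []
        for group in (False, True):
            idx = np.where(t.labels == group)[0]
            k = int(math.floor(fraction * idx.size))
            if k < 2:
                raise ValueError("down-sampling left fewer than 2 per group")
            keep.append(rng.choice(idx, size=k, replace=False))
        out.append(t.subset_individuals(np.sort(np.concatenate(keep))))
    return out


def shuffle_labels(tables, rng) -> list:
    """Permute case/control labels within each subsample (counts preserved)."""
    from dataclasses import replace

    out = []
    for t in tables:
        out.append(replace(t, labels=rng.permutation(t.labels)))
    return out
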
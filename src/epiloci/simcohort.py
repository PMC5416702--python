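"""Synthetic multi-subpopulation case/control cohorts with known truth.

The generator emulates the statistical structure of multi-ancestry
case/control genotype panels: several subpopulations whose allele frequencies
diverge around shared ancestral frequencies (Balding-Nichols Beta model with
divergence Fst), Hardy-Weinberg equilibrium within each subpopulation, and
optionally planted causal SNP groups.  Three truth models are supported:

* ``null`` - no causal SNPs; case and control distributions are identical.
* ``additive`` - causal SNPs have shifted allele frequencies in cases (an
  ordinary marginal effect that independent-loci tests detect).
* ``epistatic`` - causal SNP pairs carry a coupling in the case distribution
  whose fields are solved numerically so that the per-SNP marginals of cases
  and controls match exactly; the signal exists only in the pairwise joint
  distribution and is invisible to single-SNP tests by construction.

Planted (causal) groups share their parameters across subpopulations; only
null SNPs carry Balding-Nichols divergence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeTable, write_tped, write_tsv
from .params import CODING_LEVELS, PottsParams

#: largest state-space size enumerated exactly (3^12)
MAX_ENUM_STATES = 531_441

__all__ = [
    "AncestralSpec",
    "SimTruth",
    "draw_subpop_freqs",
    "sample_null_genotypes",
    "enumerate_potts",
    "sample_potts_genotypes",
    "plant_pure_epistasis",
    "hwe_marginals",
    "truth_null",
    "truth_additive",
    "truth_epistatic",
    "simulate_tables",
    "generate_cohort",
]


@dataclass
class AncestralSpec:
    """Cohort-level design: panel size, ancestral frequencies, structure, sizes.

    ``fst`` may be a scalar (shared divergence) or one value per
    subpopulation; ``n_cases``/``n_controls`` are per-subpopulation counts.
    """

    n_snps: int
    ancestral_freqs: np.ndarray
    fst: float | Sequence[float]
    n_subpops: int
    n_cases: Sequence[int]
    n_controls: Sequence[int]

    def __post_init__(self):
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if self.ancestral_freqs.shape != (self.n_snps,):
            raise ValueError("ancestral_freqs must have one entry per SNP")
        if np.any(self.ancestral_freqs <= 0) or np.any(self.ancestral_freqs >= 1):
            raise ValueError("ancestral frequencies must lie strictly inside (0, 1)")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_subpops,))
        if np.any(fst < 0) or np.any(fst >= 1):
            raise ValueError("fst must lie in [0, 1)")
        self.fst = fst.copy()
        self.n_cases = [int(x) for x in self.n_cases]
        self.n_controls = [int(x) for x in self.n_controls]
        if len(self.n_cases) != self.n_subpops or len(self.n_controls) != self.n_subpops:
            raise ValueError("need one case and control count per subpopulation")
        if min(self.n_cases) < 1 or min(self.n_controls) < 1:
            raise ValueError("all group sizes must be >= 1")

    @classmethod
    def uniform(
        cls,
        n_snps: int,
        n_subpops: int = 1,
        n_cases: int | Sequence[int] = 1000,
        n_controls: int | Sequence[int] = 1000,
        fst: float = 0.05,
        freq_range=(0.1, 0.4),
        seed: int = 0,
    ) -> "AncestralSpec":
        """Ancestral minor-allele frequencies drawn uniformly in ``freq_range``."""
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(*freq_range, size=n_snps)
        if np.isscalar(n_cases):
            n_cases = [int(n_cases)] * n_subpops
        if np.isscalar(n_controls):
            n_controls = [int(n_controls)] * n_subpops
        return cls(n_snps, freqs, fst, n_subpops, n_cases, n_controls)


@dataclass
class SimTruth:
    """Record of planted effects enabling recovery and power tests.

    ``case_params``/``control_params`` are defined over the causal SNPs only
    (genotypic coding when used for cohort generation); ``blocks`` lists the
    independently sampled index groups (pairs for epistatic truth, singletons
    for additive) as indices into ``causal_snps``.
    """

    model_kind: str
    causal_snps: list
    case_params: PottsParams | None
    control_params: PottsParams | None
    seed: int = 0
    blocks: list = field(default_factory=list)

    def __post_init__(self):
        if self.model_kind not in {"null", "additive", "epistatic"}:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.model_kind == "null":
            if self.causal_snps:
                raise ValueError("null truth cannot have causal SNPs")
        else:
            covered = sorted(i for b in self.blocks for i in b)
            if covered != list(range(len(self.causal_snps))):
                raise ValueError("blocks must partition the causal SNPs")


def draw_subpop_freqs(ancestral_freqs, fst, n_subpops, seed) -> np.ndarray:
    """Balding-Nichols subpopulation allele frequencies.

    Each subpopulation frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F); the degenerate F=0 limit returns the
    ancestral frequencies unchanged.  Returns shape (n_subpops, n_snps).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    fst = np.broadcast_to(np.asarray(fst, dtype=float), (n_subpops,))
    if np.any(fst < 0) or np.any(fst >= 1):
        raise ValueError("fst must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((n_subpops, p.size))
    for s in range(n_subpops):
        F = fst[s]
        if F == 0.0:
            out[s] = p
        else:
            scale = (1.0 - F) / F
            out[s] = rng.beta(p * scale, (1.0 - p) * scale)
            # keep frequencies usable for downstream Bernoulli draws
            out[s] = np.clip(out[s], 1e-12, 1.0 - 1e-12)
    return out


def sample_null_genotypes(freqs, n_individuals, seed) -> np.ndarray:
    """Independent Hardy-Weinberg genotypes: dosage ~ Binomial(2, p) per SNP."""
    p = np.asarray(freqs, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, p, size=(int(n_individuals), p.size)).astype(np.int8)


# ---------------------------------------------------------------------------
# Potts oracle and samplers
# ---------------------------------------------------------------------------

def _all_states(m: int, L: int) -> np.ndarray:
    return np.array(list(itertools.product(range(L), repeat=m)), dtype=np.int8)


def enumerate_potts(params: PottsParams):
    """Exact probability table over all genotype vectors (small m only).

    Returns ``(states, probs)``: states shape (L^m, m), probs sum to 1.
    """
    m, L = params.n_snps, params.n_levels
    if L**m > MAX_ENUM_STATES:
        raise ValueError(f"state space {L}^{m} too large to enumerate")
    S = _all_states(m, L)
    E = params.h[np.arange(m), S].sum(axis=1)
    for i in range(m):
        for j in range(i + 1, m):
            E += params.J[i, j, S[:, i], S[:, j]]
    E -= E.max()
    p = np.exp(E)
    p /= p.sum()
    return S, p


def _gibbs_sample(params: PottsParams, n: int, rng, burn_in: int = 500) -> np.ndarray:
    """n independent single-site Gibbs chains, vectorized over chains."""
    m, L = params.n_snps, params.n_levels
    cur = rng.integers(0, L, size=(n, m), dtype=np.int8)
    for _ in range(burn_in):
        for i in range(m):
            # logits[n, a] = h[i, a] + sum_j J[i, j, a, cur[n, j]]
            gathered = params.J[i].transpose(0, 2, 1)[
                np.arange(m)[None, :], cur, :
            ]  # (n, m, L)
            logits = params.h[i] + gathered.sum(axis=1)
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            cur[:, i] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return cur


def sample_potts_genotypes(params: PottsParams, n: int, seed, burn_in: int = 500) -> np.ndarray:
    """Sample genotype vectors from a Potts model.

    Small systems are sampled exactly via enumeration; larger ones fall back
    to parallel Gibbs chains with ``burn_in`` full sweeps each.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, L = params.n_snps, params.n_levels
    if L**m <= MAX_ENUM_STATES:
        states, probs = enumerate_potts(params)
        idx = rng.choice(states.shape[0], size=int(n), p=probs)
        return states[idx].astype(np.int8)
    return _gibbs_sample(params, int(n), rng, burn_in)


def hwe_marginals(freq: float, coding: str = "genotypic") -> np.ndarray:
    """Level probabilities of a single SNP under HWE for the given coding."""
    q = 1.0 - freq
    if coding == "genotypic":
        return np.array([q * q, 2 * freq * q, freq * freq])
    if coding == "dominant":
        return np.array([q * q, 1.0 - q * q])
    if coding == "recessive":
        return np.array([1.0 - freq * freq, freq * freq])
    raise ValueError(f"unknown coding {coding!r}")


class MarginalSolveError(RuntimeError):
    """Newton solve for marginal-matched case fields failed."""


def _marginals_and_cov(params: PottsParams):
    """Per-SNP non-reference marginals and their indicator covariance."""
    m, L = params.n_snps, params.n_levels
    S, p = enumerate_potts(params)
    K = L - 1
    ind = np.zeros((S.shape[0], m * K))
    for i in range(m):
        for a in range(1, L):
            ind[:, i * K + (a - 1)] = S[:, i] == a
    mu = p @ ind
    cov = (ind * p[:, None]).T @ ind - np.outer(mu, mu)
    return mu, cov


def plant_pure_epistasis(
    control_freqs_for_pair: Sequence[float],
    J_strength: float,
    coding: str = "genotypic",
    tol: float = 1e-10,
    max_iter: int = 200,
):
    """Case/control parameter pair with interaction-only case signal.

    The control model is a pair of independent HWE SNPs.  The case model adds
    a coupling ``J(a, b) = J_strength`` for all non-reference level pairs and
    solves for fields (Newton iteration on the enumerated table) such that the
    case per-SNP marginals equal the control marginals to ``tol``.  The
    association signal then lives purely in the pairwise joint distribution.
    """
    if not np.isfinite(J_strength):
        raise ValueError("J_strength must be finite")
    p1, p2 = control_freqs_for_pair
    L = CODING_LEVELS[coding]
    probs = np.vstack([hwe_marginals(p1, coding), hwe_marginals(p2, coding)])
    control = PottsParams.from_marginals(probs, coding)
    if J_strength == 0.0:
        return PottsParams(coding, control.h.copy()), control

    J = np.zeros((2, 2, L, L))
    J[0, 1, 1:, 1:] = J_strength
    J[1, 0, 1:, 1:] = J_strength
    target = probs[:, 1:].ravel()
    K = L - 1

    def residual(x):
        h = np.zeros((2, L))
        h[:, 1:] = x.reshape(2, K)
        case = PottsParams(coding, h, J)
        mu, cov = _marginals_and_cov(case)
        return case, mu - target, cov

    x = control.h[:, 1:].ravel().copy()
    case, r, cov = residual(x)
    for _ in range(max_iter):
        if np.abs(r).max() < tol:
            return case, control
        try:
            step = np.linalg.solve(cov + 1e-12 * np.eye(cov.shape[0]), r)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise MarginalSolveError(f"singular Jacobian: {e}")
        # damped Newton: backtrack until the residual norm decreases
        t = 1.0
        for _ in range(40):
            case_new, r_new, cov_new = residual(x - t * step)
            if np.linalg.norm(r_new) < np.linalg.norm(r):
                break
            t /= 2.0
        else:
            raise MarginalSolveError(
                f"line search stalled at residual {np.abs(r).max():.3g}"
            )
        x = x - t * step
        case, r, cov = case_new, r_new, cov_new
    raise MarginalSolveError(
        f"Newton failed: residual {np.abs(r).max():.3g} after {max_iter} iterations"
    )


# ---------------------------------------------------------------------------
# Truth builders
# ---------------------------------------------------------------------------

def truth_null(seed: int = 0) -> SimTruth:
    return SimTruth("null", [], None, None, seed, [])


def _block_diag_params(blocks_params, coding: str) -> PottsParams:
    m = sum(p.n_snps for p in blocks_params)
    L = CODING_LEVELS[coding]
    h = np.zeros((m, L))
    J = np.zeros((m, m, L, L))
    off = 0
    for p in blocks_params:
        k = p.n_snps
        h[off : off + k] = p.h
        J[off : off + k, off : off + k] = p.J
        off += k
    return PottsParams(coding, h, J)


def truth_additive(
    causal_snps: Sequence[int],
    control_freqs: Sequence[float],
    case_freqs: Sequence[float],
    coding: str = "genotypic",
    seed: int = 0,
) -> SimTruth:
    """Planted marginal effects: cases draw causal SNPs at shifted frequencies."""
    ctl = PottsParams.from_marginals(
        np.vstack([hwe_marginals(p, coding) for p in control_freqs]), coding
    )
    cas = PottsParams.from_marginals(
        np.vstack([hwe_marginals(p, coding) for p in case_freqs]), coding
    )
    blocks = [(i,) for i in range(len(causal_snps))]
    return SimTruth("additive", list(causal_snps), cas, ctl, seed, blocks)


def truth_epistatic(
    causal_snps: Sequence[int],
    control_freqs: Sequence[float],
    J_strength: float = 1.0,
    coding: str = "genotypic",
    seed: int = 0,
) -> SimTruth:
    """Planted marginal-matched interacting pairs (consecutive SNPs paired)."""
    if len(causal_snps) % 2 or len(control_freqs) != len(causal_snps):
        raise ValueError("need an even number of causal SNPs with matching freqs")
    case_blocks, ctl_blocks, blocks = [], [], []
    for k in range(0, len(causal_snps), 2):
        cas, ctl = plant_pure_epistasis(control_freqs[k : k + 2], J_strength, coding)
        case_blocks.append(cas)
        ctl_blocks.append(ctl)
        blocks.append((k, k + 1))
    return SimTruth(
        "epistatic",
        list(causal_snps),
        _block_diag_params(case_blocks, coding),
        _block_diag_params(ctl_blocks, coding),
        seed,
        blocks,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _default_meta(n_snps: int, spacing: int = 5000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1 + spacing * np.arange(n_snps),
            "id": [f"snp{i:06d}" for i in range(n_snps)],
            "ref": "A",
            "alt": "B",
        }
    )


def _sample_causal(truth: SimTruth, group: str, n: int, rng) -> np.ndarray:
    params = truth.case_params if group == "case" else truth.control_params
    out = np.empty((n, len(truth.causal_snps)), dtype=np.int8)
    for block in truth.blocks:
        idx = list(block)
        sub_h = params.h[idx]
        sub_J = params.J[np.ix_(idx, idx)]
        sub = PottsParams(params.coding, sub_h, sub_J)
        out[:, idx] = sample_potts_genotypes(sub, n, rng)
    return out


def simulate_tables(
    spec: AncestralSpec,
    truth: SimTruth,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> list:
    """Draw one :class:`GenotypeTable` per subpopulation.

    Null SNPs: Balding-Nichols subpopulation frequencies, HWE within
    subpopulation, identical for cases and controls.  Causal SNPs: sampled
    from the truth's case/control Potts blocks (genotypic coding), shared
    across subpopulations.  Deterministic given ``(spec, truth, seed)``.
    """
    if truth.model_kind != "null" and truth.case_params.coding != "genotypic":
        raise ValueError("cohort generation requires genotypic-coded truth params")
    causal = list(truth.causal_snps)
    if any(i < 0 or i >= spec.n_snps for i in causal):
        raise ValueError("causal SNP index out of range")
    null_idx = np.setdiff1d(np.arange(spec.n_snps), causal)
    rng = np.random.default_rng([int(seed) % (2**31), truth.seed % (2**31)])
    sub_freqs = draw_subpop_freqs(
        spec.ancestral_freqs[null_idx], spec.fst, spec.n_subpops, rng
    )
    meta = _default_meta(spec.n_snps)
    tables = []
    for s in range(spec.n_subpops):
        n_ca, n_ct = spec.n_cases[s], spec.n_controls[s]
        g = np.empty((n_ca + n_ct, spec.n_snps), dtype=np.int8)
        g[:n_ct, null_idx] = sample_null_genotypes(sub_freqs[s], n_ct, rng)
        g[n_ct:, null_idx] = sample_null_genotypes(sub_freqs[s], n_ca, rng)
        if causal:
            g[:n_ct, causal] = _sample_causal(truth, "control", n_ct, rng)
            g[n_ct:, causal] = _sample_causal(truth, "case", n_ca, rng)
        labels = np.r_[np.zeros(n_ct, bool), np.ones(n_ca, bool)]
        if missing_rate > 0:
            mask = rng.random(g.shape) < missing_rate
            g[mask] = MISSING
        ids = [f"sub{s}_ind{k:05d}" for k in range(n_ca + n_ct)]
        tables.append(GenotypeTable(f"sub{s}", g, labels, meta.copy(), ids))
    return tables


def _toy_annotation(meta: pd.DataFrame, snps_per_gene: int = 5) -> pd.DataFrame:
    """Tile consecutive SNPs into toy genes spanning their positions."""
    rows = []
    for k in range(0, len(meta), snps_per_gene):
        chunk = meta.iloc[k : k + snps_per_gene]
        rows.append(
            (
                chunk["chrom"].iloc[0],
                int(chunk["pos"].min()),
                int(chunk["pos"].max()),
                f"gene{k // snps_per_gene:04d}",
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def generate_cohort(
    spec: AncestralSpec,
    truth: SimTruth,
    output_dir: str | Path,
    seed: int = 0,
    fmt: str = "tped",
    missing_rate: float = 0.0,
    snps_per_gene: int = 5,
) -> dict:
    """Simulate a cohort and write it to disk.

    Writes per-subpopulation genotype files (``.tped``/``.tfam`` or the TSV
    dialect), a SNP map TSV, a toy gene annotation TSV, a GMT file with a
    ``causal_set`` pathway (plus tiling null pathways), and a key-value truth
    manifest.  Returns a dict of written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = simulate_tables(spec, truth, seed, missing_rate)
    paths = {"subsamples": {}}
    for t in tables:
        prefix = out / t.subsample_id
        if fmt == "tped":
            write_tped(t, prefix)
            paths["subsamples"][t.subsample_id] = {
                "tped": str(prefix) + ".tped",
                "tfam": str(prefix) + ".tfam",
            }
        elif fmt == "tsv":
            write_tsv(t, prefix)
            paths["subsamples"][t.subsample_id] = {
                "geno": str(prefix) + ".geno.tsv",
                "pheno": str(prefix) + ".pheno.tsv",
                "snp_map": str(prefix) + ".snps.tsv",
            }
        else:
            raise ValueError(f"unknown format {fmt!r}")
    meta = tables[0].snp_meta
    meta.to_csv(out / "snps.tsv", sep="\t", index=False)
    paths["snp_map"] = str(out / "snps.tsv")

    anno = _toy_annotation(meta, snps_per_gene)
    anno.to_csv(out / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(out / "genes.tsv")

    causal_genes = sorted(
        {f"gene{i // snps_per_gene:04d}" for i in truth.causal_snps}
    )
    with open(out / "pathways.gmt", "w") as fh:
        if causal_genes:
            fh.write("causal_set\tplanted\t" + "\t".join(causal_genes) + "\n")
        genes = list(anno["gene"])
        for k in range(0, len(genes), 4):
            fh.write(
                f"tiling_set_{k // 4:03d}\ttiling\t" + "\t".join(genes[k : k + 4]) + "\n"
            )
    paths["gmt"] = str(out / "pathways.gmt")

    with open(out / "truth.manifest", "w") as fh:
        fh.write(f"model_kind\t{truth.model_kind}\n")
        fh.write(f"seed\t{seed}\n")
        fh.write(f"format\t{fmt}\n")
        fh.write(f"n_snps\t{spec.n_snps}\n")
        fh.write(f"n_subpops\t{spec.n_subpops}\n")
        fh.write("fst\t" + ",".join(f"{f:g}" for f in spec.fst) + "\n")
        fh.write(
            "causal_snps\t" + ",".join(meta["id"].iloc[i] for i in truth.causal_snps) + "\n"
        )
    paths["truth"] = str(out / "truth.manifest")
    return paths
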
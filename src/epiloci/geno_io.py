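"""Genotype I/O, quality control, and gene/pathway SNP-set construction.

Genotypes are stored as minor-allele dosage counts (0/1/2) per individual and
SNP, with ``-1`` as the missing sentinel.  Two plain-text dialects are
supported: PLINK transposed text (``.tped``/``.tfam``) and a simple
SNP-by-individual TSV (genotype matrix plus a phenotype TSV and a SNP map).
Each subsample (subpopulation / study stratum) is one :class:`GenotypeTable`;
a multi-subsample cohort is a list of tables sharing one SNP panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SNPSet",
    "QCReport",
    "GenotypeParseError",
    "EmptyPanelError",
    "read_genotypes",
    "read_tped",
    "read_tsv",
    "write_tped",
    "write_tsv",
    "read_gene_annotation",
    "read_gmt",
    "hwe_exact_pvalue",
    "apply_qc",
    "impute_missing",
    "map_snps_to_genes",
    "build_pathway_snpsets",
    "ld_prune",
]


class GenotypeParseError(ValueError):
    """Raised on malformed genotype files; carries the offending line number."""


class EmptyPanelError(ValueError):
    """Raised when QC removes every SNP."""


@dataclass
class GenotypeTable:
    """Per-subsample case/control genotype matrix with SNP metadata.

    Attributes
    ----------
    subsample_id : str
        Label for the subpopulation / study stratum.
    genotypes : ndarray, shape (n_individuals, n_snps), int8
        Minor-allele dosages 0/1/2; ``-1`` marks missing calls.
    labels : ndarray of bool, shape (n_individuals,)
        ``True`` for cases, ``False`` for controls.
    snp_meta : DataFrame with columns (chrom, pos, id, ref, alt)
        Positions are 1-based base pairs; ``alt`` is the counted (minor) allele.
    individual_ids : list of str
    """

    subsample_id: str
    genotypes: np.ndarray
    labels: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        n, m = self.genotypes.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must match individual count")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta rows must match SNP count")
        if not self.individual_ids:
            self.individual_ids = [f"{self.subsample_id}_{i}" for i in range(n)]
        ids = self.snp_meta["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate SNP ids within a table")
        if (self.snp_meta["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive")
        if self.labels.sum() < 1 or (~self.labels).sum() < 1:
            raise ValueError("need at least one case and one control")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list:
        return list(self.snp_meta["id"])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeTable":
        """Return a table restricted to ``snp_ids`` (in the given order)."""
        idx = self.snp_index(snp_ids)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, row_idx: np.ndarray) -> "GenotypeTable":
        row_idx = np.asarray(row_idx)
        return replace(
            self,
            genotypes=self.genotypes[row_idx],
            labels=self.labels[row_idx],
            individual_ids=[self.individual_ids[i] for i in row_idx],
        )

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_meta["id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"SNP {e.args[0]!r} not in table {self.subsample_id}")


@dataclass
class SNPSet:
    """A named, ordered, duplicate-free group of SNP ids (gene or pathway)."""

    name: str
    snp_ids: list
    provenance: str = "pathway"

    def __post_init__(self):
        if not self.snp_ids:
            raise ValueError(f"SNP set {self.name!r} is empty")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"SNP set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class QCReport:
    """Counts of SNPs removed by each filter (first applicable filter wins)."""

    n_input: int
    removed_maf: int
    removed_call_rate: int
    removed_hwe: int
    removed_other_subsample: int = 0

    @property
    def retained(self) -> int:
        return (
            self.n_input
            - self.removed_maf
            - self.removed_call_rate
            - self.removed_hwe
            - self.removed_other_subsample
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _recode_minor(dosage: np.ndarray, labels: np.ndarray, meta: pd.DataFrame):
    """Flip dosage so it counts the control-minor allele (per subsample)."""
    controls = dosage[~labels]
    valid = controls != MISSING
    with np.errstate(invalid="ignore"):
        counted = np.where(valid, controls, 0).sum(axis=0)
        denom = 2.0 * valid.sum(axis=0)
        freq = np.divide(counted, denom, out=np.full(dosage.shape[1], 0.0), where=denom > 0)
    flip = freq > 0.5
    if flip.any():
        dosage = dosage.copy()
        cols = np.where(flip)[0]
        block = dosage[:, cols]
        block = np.where(block == MISSING, MISSING, 2 - block).astype(np.int8)
        dosage[:, cols] = block
        meta = meta.copy()
        meta.loc[meta.index[cols], ["ref", "alt"]] = meta.loc[
            meta.index[cols], ["alt", "ref"]
        ].values
    return dosage, meta


def read_tped(tped: str | Path, tfam: str | Path, subsample_id: str = "s0") -> GenotypeTable:
    """Read PLINK transposed text files into a :class:`GenotypeTable`.

    Dosages count the minor allele as determined from controls; ``0 0``
    allele pairs are treated as missing.
    """
    fam_rows = []
    for k, line in enumerate(Path(tfam).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise GenotypeParseError(f"{tfam}: line {k}: expected 6 fields")
        fam_rows.append((parts[1], parts[5]))
    if not fam_rows:
        raise GenotypeParseError(f"{tfam}: no individuals")
    ind_ids = [r[0] for r in fam_rows]
    labels = np.array([r[1] == "2" for r in fam_rows])
    n = len(ind_ids)

    meta_rows, geno_rows = [], []
    for k, line in enumerate(Path(tped).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4 + 2 * n:
            raise GenotypeParseError(
                f"{tped}: line {k}: expected {4 + 2 * n} fields, got {len(parts)}"
            )
        chrom, snp_id, _cm, pos = parts[:4]
        alleles = parts[4:]
        a1 = np.array(alleles[0::2])
        a2 = np.array(alleles[1::2])
        observed = sorted(set(a1) | set(a2) - {"0"} - {"0"})
        observed = [a for a in observed if a != "0"]
        if len(observed) > 2:
            raise GenotypeParseError(f"{tped}: line {k}: more than two alleles")
        ref = observed[0] if observed else "A"
        missing = (a1 == "0") | (a2 == "0")
        if len(observed) > 1:
            alt = observed[1]
            dos = (a1 == alt).astype(np.int8) + (a2 == alt).astype(np.int8)
        else:
            alt = ref
            dos = np.zeros(n, dtype=np.int8)
        dos[missing] = MISSING
        geno_rows.append(dos)
        meta_rows.append((chrom, int(pos), snp_id, ref, alt))

    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosage = np.array(geno_rows, dtype=np.int8).T if geno_rows else np.zeros((n, 0), np.int8)
    dosage, meta = _recode_minor(dosage, labels, meta)
    return GenotypeTable(subsample_id, dosage, labels, meta, ind_ids)


def read_tsv(
    geno: str | Path,
    pheno: str | Path,
    snp_map: str | Path,
    subsample_id: str = "s0",
) -> GenotypeTable:
    """Read the SNP-by-individual TSV dialect.

    ``geno``: header row of individual ids; each row ``snp_id\\t0/1/2/NA...``.
    ``pheno``: TSV with columns (individual, phenotype) where phenotype is
    1=control, 2=case.  ``snp_map``: TSV (chrom, pos, id, ref, alt).
    """
    ph = pd.read_csv(pheno, sep="\t", dtype=str)
    ind_ids = list(ph.iloc[:, 0])
    labels = np.array([v == "2" for v in ph.iloc[:, 1]])

    lines = Path(geno).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{geno}: empty file")
    header = lines[0].split("\t")[1:]
    if header != ind_ids:
        raise GenotypeParseError(f"{geno}: header individuals do not match {pheno}")
    n = len(ind_ids)
    snp_ids, rows = [], []
    for k, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n + 1:
            raise GenotypeParseError(f"{geno}: line {k}: expected {n + 1} fields")
        snp_ids.append(parts[0])
        row = np.array(
            [MISSING if v in ("NA", "") else int(v) for v in parts[1:]], dtype=np.int8
        )
        if ((row < 0) & (row != MISSING)).any() or (row > 2).any():
            raise GenotypeParseError(f"{geno}: line {k}: dosage outside 0/1/2/NA")
        rows.append(row)

    meta = pd.read_csv(snp_map, sep="\t", dtype={"chrom": str})
    meta = meta.set_index("id").loc[snp_ids].reset_index()
    meta = meta[["chrom", "pos", "id", "ref", "alt"]]
    dosage = np.array(rows, dtype=np.int8).T if rows else np.zeros((n, 0), np.int8)
    dosage, meta = _recode_minor(dosage, labels, meta)
    return GenotypeTable(subsample_id, dosage, labels, meta, ind_ids)


def read_genotypes(paths: Mapping[str, Mapping[str, str]], fmt: str) -> list:
    """Read one :class:`GenotypeTable` per subsample.

    ``paths`` maps subsample id to a dict of file paths: for ``fmt='tped'``
    keys (tped, tfam); for ``fmt='tsv'`` keys (geno, pheno, snp_map).
    """
    tables = []
    for sid, p in paths.items():
        if fmt == "tped":
            tables.append(read_tped(p["tped"], p["tfam"], sid))
        elif fmt == "tsv":
            tables.append(read_tsv(p["geno"], p["pheno"], p["snp_map"], sid))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return tables


def write_tped(table: GenotypeTable, prefix: str | Path) -> None:
    """Write ``<prefix>.tped`` / ``<prefix>.tfam`` (phenotype 1=control, 2=case)."""
    prefix = Path(prefix)
    with open(f"{prefix}.tfam", "w") as fh:
        for iid, lab in zip(table.individual_ids, table.labels):
            fh.write(f"F{iid} {iid} 0 0 0 {2 if lab else 1}\n")
    with open(f"{prefix}.tped", "w") as fh:
        for j, row in table.snp_meta.iterrows():
            dos = table.genotypes[:, j]
            pairs = []
            for d in dos:
                if d == MISSING:
                    pairs.append("0 0")
                elif d == 0:
                    pairs.append(f"{row['ref']} {row['ref']}")
                elif d == 1:
                    pairs.append(f"{row['ref']} {row['alt']}")
                else:
                    pairs.append(f"{row['alt']} {row['alt']}")
            fh.write(
                f"{row['chrom']} {row['id']} 0 {row['pos']} " + " ".join(pairs) + "\n"
            )


def write_tsv(table: GenotypeTable, prefix: str | Path) -> None:
    """Write ``<prefix>.geno.tsv``, ``<prefix>.pheno.tsv``, ``<prefix>.snps.tsv``."""
    prefix = Path(prefix)
    with open(f"{prefix}.pheno.tsv", "w") as fh:
        fh.write("individual\tphenotype\n")
        for iid, lab in zip(table.individual_ids, table.labels):
            fh.write(f"{iid}\t{2 if lab else 1}\n")
    with open(f"{prefix}.geno.tsv", "w") as fh:
        fh.write("snp\t" + "\t".join(table.individual_ids) + "\n")
        for j, sid in enumerate(table.snp_meta["id"]):
            vals = [
                "NA" if d == MISSING else str(int(d)) for d in table.genotypes[:, j]
            ]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")
    table.snp_meta.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read BED-like gene annotation TSV (chrom, start, end, gene), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = ["chrom", "start", "end", "gene"][: len(df.columns)]
    if (df["start"] > df["end"]).any():
        raise ValueError("gene annotation has start > end")
    return df


def read_gmt(path: str | Path) -> dict:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    out = {}
    for k, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise GenotypeParseError(f"{path}: line {k}: expected >=3 fields")
        out[parts[0]] = [g for g in parts[2:] if g]
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test P-value.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    one (Wigginton-style exact test).  Monomorphic sites return 1.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("total count must be >= 1")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log P(het = h | allele counts) up to a constant, h same parity as n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = np.where(hets == n_het)[0][0]
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def _snp_stats(table: GenotypeTable):
    g = table.genotypes
    valid = g != MISSING
    call_rate = valid.mean(axis=0)
    with np.errstate(invalid="ignore"):
        counted = np.where(valid, g, 0).sum(axis=0)
        denom = 2.0 * valid.sum(axis=0)
        freq = np.divide(counted, denom, out=np.zeros(g.shape[1]), where=denom > 0)
    maf = np.minimum(freq, 1.0 - freq)
    return call_rate, maf


def apply_qc(
    tables,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
):
    """Apply MAF / call-rate / HWE filters; keep SNPs passing in *all* subsamples.

    MAF uses cases+controls pooled; HWE uses controls only (disease association
    can distort HWE in cases).  A single table may be passed instead of a list.
    Returns ``(filtered_tables, reports)`` with the same single/list shape.
    """
    single = isinstance(tables, GenotypeTable)
    tlist = [tables] if single else list(tables)
    m = tlist[0].n_snps
    for t in tlist:
        if t.snp_ids != tlist[0].snp_ids:
            raise ValueError("subsamples must share one SNP panel for joint QC")

    pass_all = np.ones(m, dtype=bool)
    fail_maf = np.zeros(m, dtype=bool)
    fail_cr = np.zeros(m, dtype=bool)
    fail_hwe = np.zeros(m, dtype=bool)
    for t in tlist:
        call_rate, maf = _snp_stats(t)
        ctl = t.genotypes[~t.labels]
        hwe_p = np.ones(m)
        for j in range(m):
            col = ctl[:, j]
            col = col[col != MISSING]
            if col.size:
                c = np.bincount(col, minlength=3)
                hwe_p[j] = hwe_exact_pvalue(c[0], c[1], c[2])
        fail_maf |= ~(maf > maf_min)
        fail_cr |= ~fail_maf & ~(call_rate > call_rate_min)
        fail_hwe |= ~fail_maf & ~fail_cr & ~(hwe_p > hwe_p_min)
    pass_all = ~(fail_maf | fail_cr | fail_hwe)
    if not pass_all.any():
        raise EmptyPanelError("QC removed every SNP")
    keep_ids = [s for s, k in zip(tlist[0].snp_ids, pass_all) if k]
    out = [t.subset_snps(keep_ids) for t in tlist]
    report = QCReport(
        n_input=m,
        removed_maf=int(fail_maf.sum()),
        removed_call_rate=int(fail_cr.sum()),
        removed_hwe=int(fail_hwe.sum()),
    )
    if single:
        return out[0], report
    return out, report


def impute_missing(table: GenotypeTable, training_index=None) -> GenotypeTable:
    """Replace missing calls by the per-SNP modal genotype of training individuals.

    Training pools both groups; ties pick the lower genotype level.  Determinstic.
    """
    g = table.genotypes
    if not (g == MISSING).any():
        return table
    if training_index is None:
        training_index = np.arange(table.n_individuals)
    train = g[np.asarray(training_index)]
    out = g.copy()
    for j in range(table.n_snps):
        col = out[:, j]
        if not (col == MISSING).any():
            continue
        tcol = train[:, j]
        tcol = tcol[tcol != MISSING]
        if tcol.size == 0:
            raise ValueError(
                f"SNP {table.snp_meta['id'].iloc[j]!r} entirely missing in training"
            )
        counts = np.bincount(tcol, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the lowest level on ties
        col[col == MISSING] = mode
    return replace(table, genotypes=out)


# ---------------------------------------------------------------------------
# Gene / pathway SNP sets
# ---------------------------------------------------------------------------

def map_snps_to_genes(
    snp_meta: pd.DataFrame, gene_annotation: pd.DataFrame, window: int = 50_000
) -> dict:
    """Assign SNPs to genes within ``window`` bp of the coding region.

    A SNP belongs to a gene iff it is on the same chromosome and
    ``start - window <= pos <= end + window`` (all coordinates 1-based
    inclusive).  Returns ``{gene: [snp ids in position order]}``; genes on
    chromosomes absent from the SNP panel are skipped with a warning.
    """
    known_chroms = set(snp_meta["chrom"].astype(str))
    mapping = {}
    by_chrom = {
        c: df.sort_values("pos") for c, df in snp_meta.groupby(snp_meta["chrom"].astype(str))
    }
    skipped = 0
    for row in gene_annotation.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in known_chroms:
            skipped += 1
            continue
        df = by_chrom[chrom]
        lo, hi = row.start - window, row.end + window
        hit = df[(df["pos"] >= lo) & (df["pos"] <= hi)]
        mapping[row.gene] = list(hit["id"])
    if skipped:
        warnings.warn(f"skipped {skipped} annotation rows on unknown chromosomes")
    return mapping


def build_pathway_snpsets(
    gmt: Mapping[str, Sequence[str]], gene_to_snps: Mapping[str, Sequence[str]],
    snp_meta: pd.DataFrame,
) -> list:
    """Union member genes' SNPs per pathway, ordered by (chrom, pos).

    Genes absent from the annotation mapping are ignored (count logged);
    pathways with no mapped SNPs are excluded with a warning.
    """
    order = {
        s: k
        for k, s in enumerate(
            snp_meta.sort_values(["chrom", "pos"])["id"]
        )
    }
    out = []
    n_missing_genes = 0
    for name, genes in gmt.items():
        snps = set()
        for g in genes:
            if g in gene_to_snps:
                snps.update(gene_to_snps[g])
            else:
                n_missing_genes += 1
        if not snps:
            warnings.warn(f"pathway {name!r} has no mapped SNPs; excluded")
            continue
        out.append(SNPSet(name, sorted(snps, key=order.__getitem__), "pathway"))
    if n_missing_genes:
        warnings.warn(f"{n_missing_genes} pathway genes absent from annotation")
    return out


def ld_prune(table: GenotypeTable, r2_max: float, window: int = 500) -> list:
    """Greedy LD pruning: scan SNPs in (chrom, pos) order and drop any SNP whose
    dosage r^2 with a previously retained SNP (same chrom, last ``window``
    retained) exceeds ``r2_max``.  Requires complete (imputed) genotypes.
    """
    if (table.genotypes == MISSING).any():
        raise ValueError("ld_prune requires complete genotypes (impute first)")
    meta = table.snp_meta.reset_index()
    order = meta.sort_values(["chrom", "pos"]).index.to_numpy()
    g = table.genotypes.astype(float)
    retained_ids = []
    kept_cols: dict = {}  # chrom -> list of column indices retained
    for j in order:
        chrom = meta["chrom"].iloc[j]
        cols = kept_cols.get(chrom, [])[-window:]
        x = g[:, j]
        keep = True
        if cols:
            block = g[:, cols]
            xc = x - x.mean()
            bc = block - block.mean(axis=0)
            denom = np.sqrt((xc @ xc) * (bc * bc).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (bc.T @ xc) / denom, 1.0)
            if np.any(r * r > r2_max):
                keep = False
        if keep:
            kept_cols.setdefault(chrom, []).append(j)
            retained_ids.append(meta["id"].iloc[j])
    return retained_ids
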
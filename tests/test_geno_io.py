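import math

import numpy as np
import pandas as pd
import pytest

from epiloci import geno_io as gio
from epiloci import simcohort as sc
from epiloci.geno_io import MISSING, GenotypeParseError, GenotypeTable


def _table(genotypes, labels, ids=None, positions=None):
    g = np.asarray(genotypes, dtype=np.int8)
    m = g.shape[1]
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions if positions is not None else 1000 * (np.arange(m) + 1),
            "id": ids or [f"s{i}" for i in range(m)],
            "ref": "A",
            "alt": "B",
        }
    )
    return GenotypeTable("t0", g, np.asarray(labels, bool), meta)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

TPED = """\
1 s1 0 100 A A A C A C C C
1 s2 0 200 G G G G G T T T
1 s3 0 300 A C A C C C 0 0
"""
TFAM = """\
F1 i1 0 0 0 1
F2 i2 0 0 0 1
F3 i3 0 0 0 2
F4 i4 0 0 0 2
"""


def test_tped_matches_hand_transcription(tmp_path):
    (tmp_path / "c.tped").write_text(TPED)
    (tmp_path / "c.tfam").write_text(TFAM)
    t = gio.read_tped(tmp_path / "c.tped", tmp_path / "c.tfam", "c")
    expected = np.array(
        [[0, 0, 1], [1, 0, 1], [1, 1, 2], [2, 2, MISSING]], dtype=np.int8
    )
    assert np.array_equal(t.genotypes, expected)
    assert list(t.labels) == [False, False, True, True]
    assert t.snp_ids == ["s1", "s2", "s3"]
    assert list(t.snp_meta["pos"]) == [100, 200, 300]


def test_tsv_and_tped_dialects_agree(tmp_path):
    spec = sc.AncestralSpec.uniform(12, 1, 20, 20, fst=0.0, freq_range=(0.2, 0.4), seed=5)
    (table,) = sc.simulate_tables(spec, sc.truth_null(), seed=5)
    gio.write_tped(table, tmp_path / "x")
    gio.write_tsv(table, tmp_path / "x")
    t1 = gio.read_tped(tmp_path / "x.tped", tmp_path / "x.tfam", "sub0")
    t2 = gio.read_tsv(
        tmp_path / "x.geno.tsv", tmp_path / "x.pheno.tsv", tmp_path / "x.snps.tsv", "sub0"
    )
    assert np.array_equal(t1.genotypes, t2.genotypes)
    assert np.array_equal(t1.labels, t2.labels)
    assert t1.snp_ids == t2.snp_ids


def test_truncated_row_names_line(tmp_path):
    (tmp_path / "c.tped").write_text("1 s1 0 100 A A A C A C C C\n1 s2 0 200 G G G G\n")
    (tmp_path / "c.tfam").write_text(TFAM)
    with pytest.raises(GenotypeParseError, match="line 2"):
        gio.read_tped(tmp_path / "c.tped", tmp_path / "c.tfam")


def test_minor_allele_recode_flips_major_coded_column():
    # coded allele at 75% in controls -> flipped so dosage counts the minor one
    g = np.array([[2], [2], [1], [1], [2], [0]], dtype=np.int8)
    labels = [False, False, False, False, True, True]
    dosage, meta = gio._recode_minor(
        g, np.asarray(labels), _table(g, labels).snp_meta.copy()
    )
    assert list(dosage[:, 0]) == [0, 0, 1, 1, 0, 2]
    assert meta["ref"].iloc[0] == "B" and meta["alt"].iloc[0] == "A"


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_oracle(n_aa, n_ab, n_bb):
    """Brute-force exact HWE P: integer-arithmetic enumeration over het counts."""
    n = n_aa + n_ab + n_bb
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        weights[h] = (
            2**h
            * math.factorial(n)
            // (math.factorial(h) * math.factorial(rare_hom) * math.factorial(common_hom))
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (40, 20, 40), (10, 5, 1), (3, 7, 2), (100, 1, 0)],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert gio.hwe_exact_pvalue(*counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)


def test_hwe_exact_edge_cases():
    assert gio.hwe_exact_pvalue(100, 0, 0) == 1.0
    assert gio.hwe_exact_pvalue(50, 0, 50) < 1e-20


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _qc_fixture():
    rng = np.random.default_rng(3)
    n = 100
    good = rng.binomial(2, 0.3, size=(n, 1))
    rare = np.zeros((n, 1), int)
    rare[0, 0] = 1  # MAF 0.005
    low_cr = rng.binomial(2, 0.3, size=(n, 1))
    low_cr[:6, 0] = MISSING  # call rate 0.94
    ok_cr = rng.binomial(2, 0.3, size=(n, 1))
    ok_cr[:4, 0] = MISSING  # call rate 0.96
    hwe_bad = np.r_[np.zeros(25, int), 2 * np.ones(25, int), rng.binomial(2, 0.5, 50)]
    labels = np.r_[np.zeros(50, bool), np.ones(50, bool)]  # controls first
    g = np.column_stack([good, rare, low_cr, ok_cr, hwe_bad])
    return _table(g, labels, ids=["good", "rare", "low_cr", "ok_cr", "hwe_bad"])


def test_qc_filters_and_report():
    t = _qc_fixture()
    out, rep = gio.apply_qc(t)
    assert out.snp_ids == ["good", "ok_cr"]
    assert rep.removed_maf == 1 and rep.removed_call_rate == 1 and rep.removed_hwe == 1
    assert rep.retained + rep.removed_maf + rep.removed_call_rate + rep.removed_hwe == 5


def test_qc_is_idempotent_and_keeps_clean_tables():
    t = _qc_fixture()
    out, _ = gio.apply_qc(t)
    out2, rep2 = gio.apply_qc(out)
    assert out2.snp_ids == out.snp_ids
    assert rep2.removed_maf == rep2.removed_call_rate == rep2.removed_hwe == 0
    assert np.array_equal(out2.genotypes, out.genotypes)


def test_qc_empty_panel_raises():
    g = np.zeros((20, 1), int)  # monomorphic: MAF 0 fails the frequency filter
    t = _table(g, np.r_[np.zeros(10, bool), np.ones(10, bool)])
    with pytest.raises(gio.EmptyPanelError):
        gio.apply_qc(t)


def test_qc_multi_subsample_intersection():
    t1 = _qc_fixture()
    rng = np.random.default_rng(9)
    g2 = rng.binomial(2, 0.3, size=(60, 5))
    t2 = _table(g2, np.r_[np.zeros(30, bool), np.ones(30, bool)],
                ids=["good", "rare", "low_cr", "ok_cr", "hwe_bad"])
    (o1, o2), rep = gio.apply_qc([t1, t2])
    # SNPs must pass in *all* subsamples
    assert o1.snp_ids == o2.snp_ids == ["good", "ok_cr"]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def test_impute_modal_and_tie_break():
    g = np.array([[0], [0], [1], [MISSING]], dtype=np.int8)
    t = _table(g, [False, False, True, True])
    out = gio.impute_missing(t)
    assert out.genotypes[3, 0] == 0
    # tie between 0 and 1 -> lower level
    g2 = np.array([[0], [1], [MISSING], [2]], dtype=np.int8)
    t2 = _table(g2, [False, False, True, True])
    assert gio.impute_missing(t2).genotypes[2, 0] == 0


def test_impute_uses_training_only_and_noop_when_complete():
    g = np.array([[0], [0], [2], [MISSING]], dtype=np.int8)
    t = _table(g, [False, False, True, True])
    out = gio.impute_missing(t, training_index=[2])
    assert out.genotypes[3, 0] == 2
    complete = _table(np.array([[0], [1], [2], [1]]), [False, False, True, True])
    assert gio.impute_missing(complete) is complete


def test_impute_all_missing_in_training_raises():
    g = np.array([[MISSING], [MISSING], [1], [2]], dtype=np.int8)
    t = _table(g, [False, False, True, True])
    with pytest.raises(ValueError, match="missing in training"):
        gio.impute_missing(t, training_index=[0, 1])


# ---------------------------------------------------------------------------
# Gene / pathway mapping
# ---------------------------------------------------------------------------

def _anno(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def test_snp_to_gene_window_boundary_inclusive():
    meta = pd.DataFrame(
        {"chrom": "1", "pos": [70_000, 70_001], "id": ["in", "out"], "ref": "A", "alt": "B"}
    )
    mapping = gio.map_snps_to_genes(meta, _anno([("1", 10_000, 20_000, "g")]), 50_000)
    assert mapping["g"] == ["in"]


def test_snp_in_overlapping_genes_and_row_order_invariance():
    meta = pd.DataFrame(
        {"chrom": "1", "pos": [15_000], "id": ["s"], "ref": "A", "alt": "B"}
    )
    rows = [("1", 10_000, 20_000, "g1"), ("1", 14_000, 30_000, "g2")]
    m1 = gio.map_snps_to_genes(meta, _anno(rows), 0)
    m2 = gio.map_snps_to_genes(meta, _anno(rows[::-1]), 0)
    assert m1 == m2 and m1["g1"] == ["s"] and m1["g2"] == ["s"]


def test_unknown_chromosome_rows_skipped_with_warning():
    meta = pd.DataFrame({"chrom": "1", "pos": [1], "id": ["s"], "ref": "A", "alt": "B"})
    with pytest.warns(UserWarning, match="unknown chromosomes"):
        mapping = gio.map_snps_to_genes(meta, _anno([("7", 1, 10, "g")]), 0)
    assert "g" not in mapping


def test_pathway_snpsets_union_and_exclusion():
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [10, 20, 30, 40],
            "id": ["a", "b", "c", "d"],
            "ref": "A",
            "alt": "B",
        }
    )
    gene_to_snps = {"g1": ["a", "b", "c"], "g2": ["b", "c", "d"]}
    gmt = {"shared": ["g1", "g2"], "orphan": ["unknown_gene"]}
    with pytest.warns(UserWarning):
        sets = gio.build_pathway_snpsets(gmt, gene_to_snps, meta)
    assert len(sets) == 1
    assert sets[0].name == "shared"
    assert sets[0].snp_ids == ["a", "b", "c", "d"]  # deduplicated union, pos order


def test_gmt_roundtrip(tmp_path):
    (tmp_path / "p.gmt").write_text("p1\tdesc\tg1\tg2\np2\tdesc\tg3\n")
    assert gio.read_gmt(tmp_path / "p.gmt") == {"p1": ["g1", "g2"], "p2": ["g3"]}


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_drops_later_member_of_correlated_pair(rng):
    n = 200
    a = rng.binomial(2, 0.4, n)
    b = a.copy()
    flip = rng.choice(n, 8, replace=False)
    b[flip] = rng.binomial(2, 0.4, 8)  # r^2 ~ 0.9 with a
    c = rng.binomial(2, 0.4, n)
    t = _table(np.column_stack([a, b, c]), np.r_[np.zeros(100, bool), np.ones(100, bool)])
    r2_ab = np.corrcoef(a, b)[0, 1] ** 2
    r2_ac = np.corrcoef(a, c)[0, 1] ** 2
    assert r2_ab > 0.5 and r2_ac < 0.1
    assert gio.ld_prune(t, r2_max=0.1) == ["s0", "s2"]


def test_ld_prune_duplicate_removed_independent_kept(rng):
    n = 150
    a = rng.binomial(2, 0.3, n)
    cols = [a, a.copy(), rng.binomial(2, 0.3, n), rng.binomial(2, 0.3, n)]
    t = _table(np.column_stack(cols), np.r_[np.zeros(75, bool), np.ones(75, bool)])
    kept = gio.ld_prune(t, r2_max=0.5)
    assert "s1" not in kept and {"s0", "s2", "s3"} <= set(kept)
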
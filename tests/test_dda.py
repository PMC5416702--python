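import numpy as np
import pytest
from scipy.stats import chi2, chi2_contingency

from epiloci import dda
from epiloci import simcohort as sc
from epiloci.dda import DDAModel, encode, fit_il, genomic_inflation, il_meta
from epiloci.params import PottsParams


# ---------------------------------------------------------------------------
# Coding
# ---------------------------------------------------------------------------

def test_encode_codings():
    d = np.array([[0, 1, 2, dda.MISSING]])
    assert np.array_equal(encode(d, "genotypic")[0], [0, 1, 2, dda.MISSING])
    assert np.array_equal(encode(d, "dominant")[0], [0, 1, 1, dda.MISSING])
    assert np.array_equal(encode(d, "recessive")[0], [0, 0, 1, dda.MISSING])
    with pytest.raises(ValueError):
        encode(np.array([[3]]), "genotypic")


# ---------------------------------------------------------------------------
# IL fields
# ---------------------------------------------------------------------------

def test_fit_il_matches_analytic_frequencies():
    rng = np.random.default_rng(0)
    lv = rng.choice(3, size=(40_000, 1), p=[0.25, 0.5, 0.25]).astype(np.int8)
    h = fit_il(lv, 3)
    assert h[0, 0] == 0.0
    assert h[0, 1] == pytest.approx(np.log(2), abs=0.05)
    assert h[0, 2] == pytest.approx(0.0, abs=0.05)


def test_fit_il_pseudocount_on_empty_cells():
    lv = np.zeros((10, 1), dtype=np.int8)
    h = fit_il(lv, 3, kappa=0.5)
    assert h[0, 1] == h[0, 2] == pytest.approx(np.log(0.5 / 10.5))
    assert h[0, 1] < 0


def test_fit_il_duplication_sensitivity_bounded_by_pseudocount():
    # with kappa=0 the fields are exactly invariant under duplicating the
    # sample; with kappa=0.5 the change is O(kappa/n)
    rng = np.random.default_rng(1)
    lv = rng.choice(3, size=(1000, 3), p=[0.4, 0.4, 0.2]).astype(np.int8)
    dup = np.vstack([lv, lv])
    assert np.array_equal(fit_il(lv, 3, kappa=0.0), fit_il(dup, 3, kappa=0.0))
    assert np.abs(fit_il(lv, 3) - fit_il(dup, 3)).max() < 5e-3


# ---------------------------------------------------------------------------
# Meta IL test
# ---------------------------------------------------------------------------

def _levels_from_counts(counts):
    return np.repeat(np.arange(len(counts)), counts).reshape(-1, 1).astype(np.int8)


def test_il_test_equals_g_test_oracle():
    case = _levels_from_counts([30, 15, 5])
    ctl = _levels_from_counts([20, 20, 10])
    q, df, p = il_meta([case], [ctl], 3)
    g_oracle, p_oracle, df_oracle, _ = chi2_contingency(
        [[30, 15, 5], [20, 20, 10]], correction=False, lambda_="log-likelihood"
    )
    assert q[0] == pytest.approx(g_oracle, rel=1e-10)
    assert df[0] == df_oracle == 2
    assert p[0] == pytest.approx(p_oracle, rel=1e-8)


def test_il_test_statistics_add_across_subsamples():
    case = _levels_from_counts([30, 15, 5])
    ctl = _levels_from_counts([20, 20, 10])
    q1, _, _ = il_meta([case], [ctl], 3)
    q2, df2, p2 = il_meta([case, case], [ctl, ctl], 3)
    assert q2[0] == pytest.approx(2 * q1[0])
    assert df2[0] == 4
    assert p2[0] == pytest.approx(chi2.sf(2 * q1[0], 4))


def test_il_test_identical_groups_give_null():
    same = _levels_from_counts([10, 10, 10])
    q, _, p = il_meta([same], [same.copy()], 3)
    assert q[0] == pytest.approx(0.0, abs=1e-12)
    assert p[0] == 1.0


def test_il_test_monomorphic_contributes_zero_but_counts_df():
    mono = np.zeros((30, 1), dtype=np.int8)
    q, df, p = il_meta([mono], [mono.copy()], 3)
    assert q[0] == 0.0 and df[0] == 2 and p[0] == 1.0


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------

def test_lambda_exactly_one_at_median_p():
    assert genomic_inflation(np.full(99, 0.5)) == pytest.approx(1.0)


def test_lambda_on_uniform_and_scaled_chisquare():
    rng = np.random.default_rng(2)
    assert 0.95 < genomic_inflation(rng.uniform(size=10_000)) < 1.05
    stats = 1.5 * chi2.rvs(1, size=20_000, random_state=3)
    lam = genomic_inflation(chi2.sf(stats, 1))
    assert lam == pytest.approx(1.5, rel=0.05)


# ---------------------------------------------------------------------------
# Interacting fit
# ---------------------------------------------------------------------------

def test_epsilon_zero_reproduces_il_exactly():
    rng = np.random.default_rng(4)
    lv = rng.choice(3, size=(200, 6)).astype(np.int8)
    params, _ = dda.fit_dda({"s": lv}, 0.0)
    assert np.array_equal(params["s"].h, fit_il(lv, 3))
    assert not np.any(params["s"].J)


def test_coupling_recovery_large_sample():
    # the rare homozygote-homozygote cell has sampling sd ~0.05 at n=50k,
    # so the 0.1 bound is checked on the median over a few draws
    cas, _ = sc.plant_pure_epistasis((0.3, 0.3), 1.0)
    j_errs, h_errs = [], []
    for seed in (3, 4, 5):
        g = sc.sample_potts_genotypes(cas, 50_000, seed=seed)
        params, _ = dda.fit_dda({"s": g}, 1.0, tol=1e-6)
        j_errs.append(np.abs(params["s"].J - cas.J).max())
        h_errs.append(np.abs(params["s"].h - cas.h).max())
    assert np.median(j_errs) <= 0.1
    assert np.median(h_errs) <= 0.1


def test_estimation_error_shrinks_with_sample_size():
    cas, _ = sc.plant_pure_epistasis((0.3, 0.3), 1.0)
    errs = []
    for n in (5_000, 50_000):
        g = sc.sample_potts_genotypes(cas, n, seed=6)
        params, _ = dda.fit_dda({"s": g}, 1.0, tol=1e-6)
        errs.append(np.abs(params["s"].J - cas.J).max())
    assert errs[1] <= errs[0] / 2


def test_objective_concavity_two_starts_agree():
    rng = np.random.default_rng(7)
    lv = rng.choice(3, size=(400, 5)).astype(np.int8)
    n, m = lv.shape
    L, K = 3, 2
    d = m * K
    F = dda._one_hot(lv, L)
    mask = np.ones((d, d))
    for i in range(m):
        mask[i * K : (i + 1) * K, i * K : (i + 1) * K] = 0
    args = (F, F.copy(), m, L, 0.05, 0.5 / n, mask)
    _, _, t1 = dda._fit_pl(lv, L, 0.05, 0.5 / n, None, tol=1e-7, maxiter=2000)
    _, _, t2 = dda._fit_pl(
        lv, L, 0.05, 0.5 / n, 0.1 * rng.normal(size=d + d * d), tol=1e-7, maxiter=2000
    )
    f1 = dda._pl_objective(t1, *args)[0]
    f2 = dda._pl_objective(t2, *args)[0]
    assert abs(f1 - f2) < 1e-6


def test_fitted_couplings_respect_gauge_and_symmetry():
    rng = np.random.default_rng(8)
    lv = rng.choice(3, size=(300, 4)).astype(np.int8)
    params, _ = dda.fit_dda({"s": lv}, 0.5)
    params["s"].validate()  # gauge, symmetry, zero diagonal


def test_meta_separation_subsamples_fit_independently():
    rng = np.random.default_rng(9)
    a = rng.choice(3, size=(150, 4)).astype(np.int8)
    b = rng.choice(3, size=(150, 4)).astype(np.int8)
    joint, _ = dda.fit_dda({"a": a, "b": b}, 0.3)
    alone, _ = dda.fit_dda({"a": a}, 0.3)
    assert np.allclose(joint["a"].h, alone["a"].h)
    assert np.allclose(joint["a"].J, alone["a"].J)


# ---------------------------------------------------------------------------
# Risk scores
# ---------------------------------------------------------------------------

def test_identical_models_score_zero():
    p = PottsParams.from_marginals(np.array([[0.25, 0.5, 0.25]]))
    lv = np.array([[0], [1], [2]], dtype=np.int8)
    assert np.allclose(dda.score(p, p, lv), 0.0)


def test_score_difference_matches_analytic_log_ratio():
    ctl = PottsParams.from_marginals(np.array([[0.25, 0.5, 0.25]]))
    cas = PottsParams.from_marginals(np.array([[0.5, 0.3, 0.2]]))
    s = dda.score(cas, ctl, np.array([[0], [1]], dtype=np.int8))
    assert s[1] - s[0] == pytest.approx(np.log(0.3), abs=1e-12)


def test_score_is_log_likelihood_ratio_up_to_constant():
    rng = np.random.default_rng(10)

    def rand_params():
        h = np.zeros((3, 3))
        h[:, 1:] = rng.normal(scale=0.5, size=(3, 2))
        J = np.zeros((3, 3, 3, 3))
        for i in range(3):
            for j in range(i + 1, 3):
                blk = rng.normal(scale=0.3, size=(2, 2))
                J[i, j, 1:, 1:] = blk
                J[j, i, 1:, 1:] = blk.T
        return PottsParams("genotypic", h, J)

    cas, ctl = rand_params(), rand_params()
    S, pc = sc.enumerate_potts(cas)
    _, pt = sc.enumerate_potts(ctl)
    scores = dda.score(cas, ctl, S)
    llr = np.log(pc) - np.log(pt)
    assert np.std(scores - llr) < 1e-10  # equal up to the normalizer constant


def test_score_invariant_to_snp_relabeling():
    rng = np.random.default_rng(11)
    lv = rng.choice(3, size=(200, 5)).astype(np.int8)
    params, _ = dda.fit_dda({"s": lv}, 0.3)
    p = params["s"]
    perm = np.array([3, 0, 4, 1, 2])
    p_perm = PottsParams("genotypic", p.h[perm], p.J[np.ix_(perm, perm)])
    base = dda.score(p, PottsParams.zeros(5), lv)
    permuted = dda.score(p_perm, PottsParams.zeros(5), lv[:, perm])
    assert np.allclose(base, permuted, atol=1e-10)


def test_model_serialization_roundtrip():
    rng = np.random.default_rng(12)
    lv = rng.choice(3, size=(100, 3)).astype(np.int8)
    case, _ = dda.fit_dda({"s": lv}, 0.5)
    ctl, _ = dda.fit_dda({"s": lv[::-1]}, 0.5)
    model = DDAModel("genotypic", 0.5, ["a", "b", "c"], case, ctl, {"s": 0.12})
    back = DDAModel.from_json(model.to_json())
    assert back.epsilon == 0.5 and back.snp_ids == ["a", "b", "c"]
    assert np.allclose(back.case["s"].J, model.case["s"].J)
    assert np.allclose(
        back.score(lv, "s"), model.score(lv, "s")
    )
    with pytest.raises(KeyError):
        back.score(lv, "nope")
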
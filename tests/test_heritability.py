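"""LD scores, LD-score regression, liability conversion, X estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from gwaskit.genotypes import FEMALE, MALE, GenotypeMatrix, simulate_ld_reference
from gwaskit.heritability import (
    LDScoreRegression,
    compute_ld_scores,
    estimate_diff_ztest,
    ldsc_rg,
    liability_transform,
    m_eff_from_ld_scores,
    read_ld_scores,
    write_ld_scores,
    xchr_h2,
    xchr_rg,
)
from gwaskit.liability import LiabilityModelParams, run_single_snp_gwas, simulate_liability_phenotypes
from gwaskit.sumstats import SumStats


# ---------------------------------------------------------------- LD scores

def test_independent_variants_have_unit_ld_score():
    rng = np.random.default_rng(0)
    m, n = 100, 20_000
    dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    var = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": "1",
                        "pos": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "G",
                        "freq": 0.3})
    scores = compute_ld_scores(GenotypeMatrix(dos, var), window_kb=1000)
    np.testing.assert_allclose(scores["ldscore"], 1.0, atol=0.05)
    assert abs(scores["ldscore"].mean() - 1.0) < 0.005


def test_perfectly_correlated_block_scores_equal_block_size():
    rng = np.random.default_rng(1)
    col = rng.binomial(2, 0.4, size=500).astype(float)
    m = 6
    dos = np.tile(col[:, None], (1, m))
    var = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": "1",
                        "pos": np.arange(1, m + 1) * 100, "a1": "A", "a2": "G",
                        "freq": 0.4})
    scores = compute_ld_scores(GenotypeMatrix(dos, var), window_kb=10)
    np.testing.assert_allclose(scores["ldscore"], m, atol=1e-9)


def test_interior_ar1_score_matches_geometric_series():
    # interior variant of an AR(1) block: l ~ 1 + 2 rho^2/(1 - rho^2)
    rho = 0.6
    g = simulate_ld_reference(n=60_000, blocks=30, block_size=15, rho=rho, seed=2)
    scores = compute_ld_scores(g, window_kb=1000)
    interior = scores["ldscore"].to_numpy().reshape(30, 15)[:, 7]
    expected = 1 + 2 * rho**2 / (1 - rho**2)
    assert abs(interior.mean() - expected) < 0.1


def test_ld_scores_need_three_individuals():
    var = pd.DataFrame({"id": ["a"], "chrom": "1", "pos": [1], "a1": "A",
                        "a2": "G", "freq": 0.5})
    with pytest.raises(ValueError):
        compute_ld_scores(GenotypeMatrix(np.ones((2, 1)), var))


def test_ld_score_tsv_round_trip(tmp_path):
    g = simulate_ld_reference(n=200, blocks=3, block_size=3, rho=0.5, seed=3)
    scores = compute_ld_scores(g)
    write_ld_scores(scores, tmp_path / "l2.tsv")
    back = read_ld_scores(tmp_path / "l2.tsv")
    np.testing.assert_allclose(back["ldscore"], scores["ldscore"], rtol=1e-9)


# ---------------------------------------------------- LD score regression

def quantitative_study(rng, h2=0.0, n=20_000, blocks=200, block_size=10):
    g = simulate_ld_reference(n=n, blocks=blocks, block_size=block_size,
                              rho=(0.0, 0.9), seed=int(rng.integers(2**31)))
    m = g.m_variants
    zstd = g.standardized()
    betas = rng.standard_normal(m) * np.sqrt(h2 / m)
    genet = zstd @ betas
    y = genet + rng.standard_normal(n) * np.sqrt(max(1 - genet.var(), 0.05))
    r = (zstd.T @ (y - y.mean())) / (n * y.std())
    z = r * np.sqrt(n)
    df = pd.DataFrame({"id": g.variant_ids, "chrom": g.variants["chrom"],
                       "pos": g.variants["pos"], "a1": g.variants["a1"],
                       "a2": g.variants["a2"], "freq": g.variants["freq"],
                       "z": z, "p": np.clip(2 * spstats.norm.sf(np.abs(z)), 1e-300, 1),
                       "n": n})
    return g, SumStats(df)


def test_null_trait_gives_zero_h2_and_unit_intercept():
    rng = np.random.default_rng(4)
    g, ss = quantitative_study(rng, h2=0.0)
    scores = compute_ld_scores(g)
    res = LDScoreRegression(ss, scores, n_blocks=200).fit()
    assert abs(res.h2_obs) < 2 * res.h2_obs_se
    assert abs(res.intercept - 1) < 2 * res.intercept_se


def test_known_observed_scale_h2_recovered():
    rng = np.random.default_rng(5)
    g, ss = quantitative_study(rng, h2=0.2)
    scores = compute_ld_scores(g)
    res = LDScoreRegression(ss, scores, n_blocks=200).fit()
    assert abs(res.h2_obs - 0.2) < 2 * res.h2_obs_se
    assert res.h2_obs_se < 0.1


def test_constant_chi2_shift_moves_intercept_not_slope():
    rng = np.random.default_rng(6)
    g, ss = quantitative_study(rng, h2=0.1, n=5_000, blocks=100, block_size=10)
    scores = compute_ld_scores(g)
    kwargs = dict(n_blocks=100, two_step_cut=np.inf, weight_iterations=0)
    base = LDScoreRegression(ss, scores, **kwargs).fit()
    shifted = ss.df.copy()
    c = 0.37
    chi = shifted["z"] ** 2 + c
    shifted["z"] = np.sign(shifted["z"]) * np.sqrt(chi)
    shifted["p"] = np.clip(2 * spstats.norm.sf(np.abs(shifted["z"])), 1e-300, 1)
    res = LDScoreRegression(SumStats(shifted), scores, **kwargs).fit()
    assert res.intercept - base.intercept == pytest.approx(c, abs=1e-6)
    assert res.h2_obs == pytest.approx(base.h2_obs, abs=1e-6)


def test_constant_ld_scores_rejected():
    rng = np.random.default_rng(7)
    g, ss = quantitative_study(rng, h2=0.0, n=3_000, blocks=300, block_size=10)
    scores = compute_ld_scores(g)
    scores["ldscore"] = 1.5
    with pytest.raises(ValueError, match="unidentifiable|constant"):
        LDScoreRegression(ss, scores, n_blocks=200)


def test_confounding_raises_intercept_more_than_slope():
    """Subpopulation stratification inflates the intercept; the slope-based
    h2 moves less than the uncorrected mean-chi2 estimator."""
    results = {}
    for shift, fst in ((0.0, 0.0), (0.35, 0.008)):
        g = simulate_ld_reference(n=15_000, blocks=400, block_size=5,
                                  rho=(0.0, 0.9), seed=8, fst=fst)
        par = LiabilityModelParams(h2_liab=0.2, m_causal=400, strat_shift=shift, seed=9)
        phen = simulate_liability_phenotypes(g, par)
        ss = run_single_snp_gwas(g, phen)
        scores = compute_ld_scores(g)
        res = LDScoreRegression(ss, scores, n_blocks=200).fit()
        h2_mean_chi2, _ = xchr_h2(res.mean_chi2, 15_000, m_eff_from_ld_scores(scores))
        results[shift] = (res.intercept, res.h2_obs, h2_mean_chi2)
    clean_int, clean_h2, _ = results[0.0]
    conf_int, conf_h2, conf_naive = results[0.35]
    assert conf_int > clean_int + 0.3
    assert abs(conf_h2 - clean_h2) < abs(conf_naive - clean_h2)


def test_liability_recovery_across_grid():
    """Median absolute liability-scale error over an (h2, K) grid stays
    below 0.05 at M = 2000, N = 20000."""
    errors = []
    seed = 100
    for h2 in (0.1, 0.2, 0.3):
        for K in (0.05, 0.09):
            for _ in range(2):
                seed += 1
                g = simulate_ld_reference(n=20_000, blocks=200, block_size=10,
                                          rho=(0.0, 0.9), seed=seed)
                par = LiabilityModelParams(h2_liab=h2, m_causal=500,
                                           prevalence_male=K, prevalence_female=K,
                                           seed=seed + 1000)
                phen = simulate_liability_phenotypes(g, par)
                ss = run_single_snp_gwas(g, phen)
                scores = compute_ld_scores(g)
                res = LDScoreRegression(ss, scores, n_blocks=200).fit()
                res.to_liability(K=K, P=float(phen.df["case"].mean()))
                errors.append(abs(res.h2_liab - h2))
    assert np.median(errors) < 0.05


# ---------------------------------------------------- liability transform

def test_liability_transform_closed_forms():
    assert liability_transform(0.0, 0.1, 0.3) == 0.0
    # K = P = 0.5: threshold 0, z = phi(0), multiplier = pi/2
    assert liability_transform(1.0, 0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-6)


def test_liability_transform_matches_numeric_oracle():
    # independent numeric evaluation of z via a central difference of the
    # normal CDF at the threshold
    K, P = 0.09, 0.27
    t = spstats.norm.ppf(1 - K)
    eps = 1e-6
    z_num = (spstats.norm.cdf(t + eps) - spstats.norm.cdf(t - eps)) / (2 * eps)
    expected = K**2 * (1 - K) ** 2 / (P * (1 - P) * z_num**2)
    assert liability_transform(1.0, K, P) == pytest.approx(expected, rel=1e-6)


def test_liability_transform_linear_and_continuous():
    base = liability_transform(0.1, 0.09, 0.3)
    assert liability_transform(0.2, 0.09, 0.3) == pytest.approx(2 * base, rel=1e-12)
    # numeric derivative in K is finite and smooth
    eps = 1e-6
    d1 = (liability_transform(0.1, 0.09 + eps, 0.3) - base) / eps
    d2 = (liability_transform(0.1, 0.09 + 2 * eps, 0.3)
          - liability_transform(0.1, 0.09 + eps, 0.3)) / eps
    assert np.isfinite(d1) and abs(d1 - d2) < 1e-3 * max(abs(d1), 1)


def test_liability_transform_domain():
    with pytest.raises(ValueError):
        liability_transform(0.1, 0.0, 0.3)


# ------------------------------------------------------ genetic correlation

def correlated_trait_pair(rng, rho_g, h2=0.25, n=10_000, blocks=150, block_size=10):
    """Two cohorts on separate individuals whose causal effects correlate
    rho_g; returns (panel, stats1, stats2)."""
    seed = int(rng.integers(2**31))
    g1 = simulate_ld_reference(n=n, blocks=blocks, block_size=block_size,
                               rho=(0.0, 0.9), seed=seed)
    g2 = simulate_ld_reference(n=n, blocks=blocks, block_size=block_size,
                               rho=(0.0, 0.9), seed=seed)
    m = g1.m_variants
    b1 = rng.standard_normal(m)
    b2 = rho_g * b1 + np.sqrt(1 - rho_g**2) * rng.standard_normal(m)
    out = []
    for g, b in ((g1, b1), (g2, b2)):
        zstd = g.standardized()
        genet = zstd @ (b * np.sqrt(h2 / m))
        y = genet + rng.standard_normal(n) * np.sqrt(max(1 - genet.var(), 0.05))
        r = (zstd.T @ (y - y.mean())) / (n * y.std())
        z = r * np.sqrt(n)
        out.append(SumStats(pd.DataFrame({
            "id": g.variant_ids, "chrom": g.variants["chrom"],
            "pos": g.variants["pos"], "a1": g.variants["a1"],
            "a2": g.variants["a2"], "freq": g.variants["freq"], "z": z,
            "p": np.clip(2 * spstats.norm.sf(np.abs(z)), 1e-300, 1), "n": n})))
    return g1, out[0], out[1]


def test_rg_of_trait_with_itself_is_one():
    rng = np.random.default_rng(10)
    g, ss, _ = correlated_trait_pair(rng, rho_g=1.0)
    scores = compute_ld_scores(g)
    res = ldsc_rg(ss, ss, scores, n_blocks=100)
    assert res.defined
    assert abs(res.rg - 1.0) < max(2 * res.rg_se, 0.02)


def test_rg_recovers_shared_effect_correlation():
    rng = np.random.default_rng(11)
    g, s1, s2 = correlated_trait_pair(rng, rho_g=0.7)
    scores = compute_ld_scores(g)
    res = ldsc_rg(s1, s2, scores, n_blocks=100)
    assert res.defined
    assert abs(res.rg - 0.7) < 2.5 * res.rg_se


def test_rg_of_independent_traits_is_zero():
    rng = np.random.default_rng(12)
    g, s1, s2 = correlated_trait_pair(rng, rho_g=0.0)
    scores = compute_ld_scores(g)
    res = ldsc_rg(s1, s2, scores, n_blocks=100)
    assert abs(res.rg) < 2.5 * res.rg_se


def test_rg_flagged_undefined_for_null_trait():
    rng = np.random.default_rng(13)
    g, s1, _ = correlated_trait_pair(rng, rho_g=0.0, h2=0.25, n=4_000,
                                     blocks=100, block_size=10)
    scores = compute_ld_scores(g)
    null = s1.df.copy()
    # chi2 decreasing in the LD score forces a negative fitted slope (h2 < 0)
    merged = null.merge(scores[["id", "ldscore"]], on="id")
    chi = np.maximum(1.5 - 0.3 * merged["ldscore"].to_numpy(), 0.05)
    null["z"] = np.sqrt(chi) * rng.choice([-1, 1], len(null))
    null["p"] = np.clip(2 * spstats.norm.sf(np.abs(null["z"])), 1e-300, 1)
    res = ldsc_rg(SumStats(null), SumStats(null), scores, n_blocks=100)
    assert not res.defined
    assert np.isnan(res.rg)


# ------------------------------------------------------------ Z difference

def test_diff_ztest_values():
    z, p = estimate_diff_ztest(0.5, 0.1, 0.5, 0.1)
    assert z == 0 and p == 1
    z, p = estimate_diff_ztest(0.5, 0.25, 0.0, 1e-12)
    assert z == pytest.approx(2.0, rel=1e-6)
    assert p == pytest.approx(0.0455, abs=2e-4)
    z, p = estimate_diff_ztest(1.5, 0.25, kind="vs_one")
    assert z == pytest.approx(2.0)


def test_printed_x_chromosome_h2_difference_not_significant():
    # male 0.0032 (se 0.0018) vs female 0.0047 (se 0.0012) -> p ~ 0.49
    _, p = estimate_diff_ztest(0.0032, 0.0018, 0.0047, 0.0012)
    assert p == pytest.approx(0.49, abs=0.01)


# ------------------------------------------------------------ chromosome X

def test_xchr_h2_moment_formula():
    h2, neg = xchr_h2(1.0, 10_000, 500)
    assert h2 == 0 and not neg
    h2, neg = xchr_h2(1.35, 100_000, 1_000)
    assert h2 == pytest.approx(0.0035, rel=1e-12)
    h2, neg = xchr_h2(0.9, 10_000, 500)
    assert h2 < 0 and neg


def test_xchr_rg_requires_signal():
    rng = np.random.default_rng(14)
    z = rng.standard_normal(500) * 0.9
    with pytest.raises(ValueError, match="mean chi2"):
        xchr_rg(z, z * 1.01)


def x_linked_study(rng, h2=0.004, n_per_sex=30_000, m=400):
    g = simulate_ld_reference(n=2 * n_per_sex, blocks=m // 4, block_size=4,
                              rho=(0.0, 0.7), seed=int(rng.integers(2**31)),
                              chrom="X",
                              sex=np.array([MALE] * n_per_sex + [FEMALE] * n_per_sex,
                                           dtype=object))
    b = rng.standard_normal(m) * np.sqrt(h2 / m)
    zres = {}
    for code in (MALE, FEMALE):
        mask = g.sex == code
        sub = GenotypeMatrix(g.dosages[mask], g.variants, sex=g.sex[mask])
        zc = sub.standardized()  # standardize within the sex stratum
        genet = zc @ b
        y = genet + rng.standard_normal(mask.sum()) * np.sqrt(1 - h2)
        r = (zc.T @ (y - y.mean())) / (mask.sum() * y.std())
        zres[code] = r * np.sqrt(mask.sum())
    return g, zres


def test_x_linked_h2_recovered_within_simulation_ci():
    rng = np.random.default_rng(15)
    h2 = 0.004
    g, zres = x_linked_study(rng, h2=h2)
    scores = compute_ld_scores(g)
    m_eff = m_eff_from_ld_scores(scores)
    for code in (MALE, FEMALE):
        chi2 = float(np.mean(zres[code] ** 2))
        n_sex = int((g.sex == code).sum())
        est, _ = xchr_h2(chi2, n_sex, m_eff)
        se = float(np.std(zres[code] ** 2) / np.sqrt(len(zres[code]))) * m_eff / n_sex
        assert abs(est - h2) < 3 * se


def test_split_half_xchr_rg_near_one():
    rng = np.random.default_rng(16)
    g, zres = x_linked_study(rng, h2=0.006, n_per_sex=40_000)
    rg, raw = xchr_rg(zres[MALE], zres[FEMALE])
    assert rg == pytest.approx(1.0, abs=0.35)
    assert rg <= 1.0  # clipped value
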
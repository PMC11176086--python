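"""Demography resampling, PRS, interaction GLM, classifier evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats
from sklearn.model_selection import StratifiedKFold

from gwaskit.genotypes import FEMALE, MALE, simulate_ld_reference
from gwaskit.liability import LiabilityModelParams, simulate_liability_phenotypes
from gwaskit.prediction import (
    GLMLearner,
    InteractionLogit,
    SimulatedPopulation,
    TreeEnsembleLearner,
    compute_prs,
    cross_validated_scores,
    evaluate_classifier,
    five_year_labels,
    interaction_variance_share,
    nagelkerke_r2,
    nagelkerke_r2_from_loglik,
    resample_population,
)


def demography(rows):
    return pd.DataFrame(rows, columns=["SEX", "AGE_LO", "AGE_HI", "PROPORTION",
                                       "CUM_INCIDENCE"])


@pytest.fixture(scope="module")
def source_cohort():
    g = simulate_ld_reference(n=12_000, blocks=40, block_size=1, rho=0.0, seed=1)
    params = LiabilityModelParams(h2_liab=0.3, m_causal=40, prevalence_male=0.15,
                                  prevalence_female=0.15, seed=2)
    phen = simulate_liability_phenotypes(g, params)
    return g, phen


GERMAN_LIKE_DEMOGRAPHY = demography([
    (MALE, 20, 40, 0.16, 0.02), (MALE, 40, 60, 0.18, 0.05), (MALE, 60, 80, 0.14, 0.08),
    (FEMALE, 20, 40, 0.16, 0.03), (FEMALE, 40, 60, 0.19, 0.08), (FEMALE, 60, 80, 0.17, 0.14),
])


def test_single_stratum_demography_draws_only_from_it(source_cohort):
    g, phen = source_cohort
    demo = demography([(FEMALE, 40, 60, 1.0, 0.1)])
    pop = resample_population(phen, g.dosages, g.variant_ids, demo,
                              target_n=2_000, seed=3)
    assert (pop.df["sex"] == FEMALE).all()
    assert pop.df["age"].between(40, 60).all()


def test_resampled_pyramid_matches_demography(source_cohort):
    g, phen = source_cohort
    pop = resample_population(phen, g.dosages, g.variant_ids,
                              GERMAN_LIKE_DEMOGRAPHY, target_n=100_000, seed=4)
    counts = []
    for row in GERMAN_LIKE_DEMOGRAPHY.itertuples(index=False):
        mask = ((pop.df["sex"] == row.SEX) & (pop.df["age"] >= row.AGE_LO)
                & (pop.df["age"] < row.AGE_HI))
        counts.append(mask.sum())
    props = GERMAN_LIKE_DEMOGRAPHY["PROPORTION"] / GERMAN_LIKE_DEMOGRAPHY["PROPORTION"].sum()
    res = spstats.chisquare(counts, f_exp=props * sum(counts))
    assert res.pvalue > 0.01


def test_resampled_prevalence_tracks_incidence_curve(source_cohort):
    g, phen = source_cohort
    pop = resample_population(phen, g.dosages, g.variant_ids,
                              GERMAN_LIKE_DEMOGRAPHY, target_n=100_000, seed=5)
    for row in GERMAN_LIKE_DEMOGRAPHY.itertuples(index=False):
        mask = ((pop.df["sex"] == row.SEX) & (pop.df["age"] >= row.AGE_LO)
                & (pop.df["age"] < row.AGE_HI))
        n = mask.sum()
        frac = pop.df.loc[mask, "case"].mean()
        se = np.sqrt(row.CUM_INCIDENCE * (1 - row.CUM_INCIDENCE) / n)
        assert abs(frac - row.CUM_INCIDENCE) < 4 * se + 1e-3


def test_onset_precedes_age_and_folds_partition(source_cohort):
    g, phen = source_cohort
    pop = resample_population(phen, g.dosages, g.variant_ids,
                              GERMAN_LIKE_DEMOGRAPHY, target_n=5_000, seed=6,
                              n_folds=10)
    cases = pop.df[pop.df["case"] == 1]
    assert (cases["onset_age"] <= cases["age"]).all()
    assert set(pop.df["fold"]) == set(range(10))


def test_missing_stratum_rejected(source_cohort):
    g, phen = source_cohort
    # all-male source subset cannot serve a female stratum
    males = phen.df["sex"] == MALE
    from gwaskit.liability import PhenotypeTable

    male_only = PhenotypeTable(phen.df[males].reset_index(drop=True))
    demo = demography([(FEMALE, 40, 60, 1.0, 0.1)])
    with pytest.raises(ValueError, match="female"):
        resample_population(male_only, g.dosages[males.to_numpy()],
                            g.variant_ids, demo, target_n=100, seed=7)


def test_prs_distribution_preserved_per_stratum(source_cohort):
    g, phen = source_cohort
    w = pd.DataFrame({"id": g.variant_ids,
                      "weight": np.linspace(-0.2, 0.2, g.m_variants)})
    src_prs, _ = compute_prs(g.dosages, g.variant_ids, w)
    pop = resample_population(phen, g.dosages, g.variant_ids,
                              GERMAN_LIKE_DEMOGRAPHY, target_n=50_000, seed=8)
    pop_prs, _ = compute_prs(pop.dosages, pop.variant_ids, w)
    # controls in a stratum are draws from the source controls of that sex
    for sex in (MALE, FEMALE):
        src = src_prs[((phen.df["sex"] == sex) & (phen.df["case"] == 0)).to_numpy()]
        new = pop_prs[((pop.df["sex"] == sex) & (pop.df["case"] == 0)).to_numpy()]
        assert spstats.ks_2samp(src, new).pvalue > 0.01


def test_prs_trivial_values():
    dos = np.array([[2.0, 1.0], [0.0, 0.0]])
    ids = np.array(["a", "b"])
    zero = pd.DataFrame({"id": ids, "weight": [0.0, 0.0]})
    prs, _ = compute_prs(dos, ids, zero)
    np.testing.assert_allclose(prs, 0.0)
    single = pd.DataFrame({"id": ["a"], "weight": [0.2]})
    prs, _ = compute_prs(dos, ids, single)
    np.testing.assert_allclose(prs, [0.4, 0.0])


def test_prs_matches_brute_force_loop():
    rng = np.random.default_rng(9)
    n, m = 300, 216
    dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    ids = np.array([f"s{i}" for i in range(m)])
    w = pd.DataFrame({"id": rng.permutation(ids), "weight": rng.normal(0, 0.1, m)})
    prs, _ = compute_prs(dos, ids, w)
    wmap = dict(zip(w["id"], w["weight"]))
    col = {v: j for j, v in enumerate(ids)}
    brute = np.zeros(n)
    for i in range(n):
        for vid, wt in wmap.items():
            brute[i] += wt * dos[i, col[vid]]
    np.testing.assert_allclose(prs, brute, atol=1e-12)


def test_prs_missing_dosages_imputed_and_flagged():
    dos = np.array([[np.nan, 1.0], [2.0, 0.0], [0.0, 1.0]])
    ids = np.array(["a", "b"])
    w = pd.DataFrame({"id": ids, "weight": [0.5, 0.5]})
    prs, report = compute_prs(dos, ids, w, freqs=np.array([0.25, 0.3]),
                              max_missing_frac=0.4)
    assert report["n_imputed"] == 1
    assert list(report["flagged_individuals"]) == [0]
    assert prs[0] == pytest.approx(0.5 * (2 * 0.25) + 0.5 * 1.0)


def synthetic_population(rng, n, b_prs=1.0, b_prs_age=0.0, threshold_term=0.0,
                         n_pcs=10):
    prs = rng.standard_normal(n)
    sex01 = rng.integers(0, 2, n).astype(float)
    age = rng.uniform(20, 80, n)
    bins = np.floor(age / 20).astype(int)
    oldbin = (bins >= 3).astype(float)
    pcs = rng.standard_normal((n, n_pcs))
    logit = (-2.5 + b_prs * prs + 0.5 * sex01 + 0.4 * (bins - 1)
             + b_prs_age * prs * oldbin + threshold_term * (prs > 1.0))
    pr = 1 / (1 + np.exp(-logit))
    case = (rng.random(n) < pr).astype(int)
    onset = np.where(case == 1, age - rng.uniform(0, 10, n), np.nan)
    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
    fold = np.empty(n, dtype=int)
    for k, (_, te) in enumerate(skf.split(np.zeros(n), case)):
        fold[te] = k
    df = pd.DataFrame({"sex": np.where(sex01 == 1, FEMALE, MALE),
                       "birth_year": 2020 - age, "age": age, "case": case,
                       "onset_age": onset, "fold": fold, "prs": prs})
    return SimulatedPopulation(df=df, dosages=np.zeros((n, 1)),
                               variant_ids=np.array(["dummy"]), pcs=pcs)


def test_negative_prs_age_interaction_recovered():
    rng = np.random.default_rng(10)
    pop = synthetic_population(rng, 50_000, b_prs=1.0, b_prs_age=-0.4)
    fit = InteractionLogit(pop).fit()
    beta, se = fit.coef("prs:age3")
    assert beta < 0
    assert abs(beta) > 1.96 * se  # CI excludes zero


def test_null_interactions_stay_null():
    rng = np.random.default_rng(11)
    pop = synthetic_population(rng, 50_000)
    fit = InteractionLogit(pop).fit()
    for term in fit.table["term"]:
        if ":" in term:  # every interaction coefficient
            beta, se = fit.coef(term)
            assert abs(beta) < 3 * se


def test_constant_prs_rejected():
    rng = np.random.default_rng(12)
    pop = synthetic_population(rng, 2_000)
    pop.df["prs"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        InteractionLogit(pop)


def test_or_per_sd_consistent_with_coefficient():
    rng = np.random.default_rng(13)
    pop = synthetic_population(rng, 20_000, b_prs=0.8)
    fit = InteractionLogit(pop).fit()
    b1 = fit.coef("prs")[0]
    assert fit.or_per_prs_sd() == pytest.approx(np.exp(b1 * fit.prs_sd), rel=1e-8)


def test_nagelkerke_closed_forms():
    assert nagelkerke_r2(0.5, 0.5, 100) == 0.0
    assert nagelkerke_r2(0.5, 1.0, 100) == pytest.approx(1.0)
    # log L0 = -60, log L1 = -50, N = 100
    val = nagelkerke_r2_from_loglik(-60.0, -50.0, 100)
    assert val == pytest.approx((1 - np.exp(-0.2)) / (1 - np.exp(-1.2)), rel=1e-9)
    assert val == pytest.approx(0.2594, abs=2e-4)
    with pytest.raises(ValueError, match="nesting"):
        nagelkerke_r2(0.9, 0.5, 100)


def test_five_year_labels_window_rules():
    df = pd.DataFrame({
        "sex": [MALE] * 5, "birth_year": 1960.0,
        "age": [80.0, 80.0, 80.0, 52.0, 80.0],
        "case": [1, 1, 1, 0, 0],
        "onset_age": [53.0, 57.0, 40.0, np.nan, np.nan],
        "fold": [0, 1, 2, 3, 4], "prs": [0.0] * 5,
    })
    pop = SimulatedPopulation(df=df, dosages=np.zeros((5, 1)),
                              variant_ids=np.array(["d"]), pcs=np.zeros((5, 1)))
    labels, idx = five_year_labels(pop, landmark_age=50)
    by_row = dict(zip(idx, labels))
    assert by_row[0] == 1      # onset 3 y after landmark
    assert by_row[1] == 0      # onset 7 y after landmark
    assert 2 not in by_row     # prevalent case at landmark excluded
    assert 3 not in by_row     # censored at 52 without event excluded
    assert by_row[4] == 0      # fully observed control
    with pytest.raises(ValueError):
        five_year_labels(pop, landmark_age=200)


def test_auc_hand_values():
    m = evaluate_classifier(np.array([0.9, 0.8, 0.7, 0.2]),
                            np.array([1, 1, 1, 0]), n_boot=10)
    assert m.auc == 1.0
    m = evaluate_classifier(np.array([0.9, 0.8, 0.3, 0.2]),
                            np.array([1, 0, 1, 0]), n_boot=10)
    assert m.auc == pytest.approx(0.75)
    with pytest.raises(ValueError):
        evaluate_classifier(np.array([0.1, 0.2]), np.array([1, 1]))


def test_auc_null_scores_near_half():
    rng = np.random.default_rng(14)
    scores = rng.random(10_000)
    labels = rng.integers(0, 2, 10_000)
    m = evaluate_classifier(scores, labels, n_boot=20)
    assert 0.48 <= m.auc <= 0.52


def test_interaction_variance_share_rules():
    assert interaction_variance_share(0.3, 0.3) == 0.0
    assert interaction_variance_share(0.22, 0.36) == pytest.approx(0.389, abs=1e-3)
    with pytest.warns(UserWarning):
        assert interaction_variance_share(0.4, 0.3) == 0.0
    with pytest.raises(ValueError):
        interaction_variance_share(0.1, 0.0)


def test_tree_ensemble_beats_linear_glm_on_interaction_data():
    """Nonlinear generative model (PRS x age and a PRS threshold): the tree
    ensemble's cross-validated AUC must exceed the linear GLM's."""
    rng = np.random.default_rng(15)
    pop = synthetic_population(rng, 50_000, b_prs=0.6, b_prs_age=-1.2,
                               threshold_term=1.5)
    sub = pop.df["fold"] < 5  # five folds
    feats = np.column_stack([pop.df["prs"], (pop.df["sex"] == FEMALE).astype(float),
                             pop.df["age"]])[sub.to_numpy()]
    labels = pop.df.loc[sub, "case"].to_numpy()
    folds = pop.df.loc[sub, "fold"].to_numpy()
    glm_scores = cross_validated_scores(GLMLearner, feats, labels, folds)
    tree_scores = cross_validated_scores(TreeEnsembleLearner, feats, labels, folds)
    auc_glm = evaluate_classifier(glm_scores, labels, n_boot=10).auc
    auc_tree = evaluate_classifier(tree_scores, labels, n_boot=10).auc
    assert auc_tree > auc_glm


def test_cross_validation_invariant_to_ordering():
    rng = np.random.default_rng(16)
    pop = synthetic_population(rng, 4_000, b_prs=0.8)
    feats = np.column_stack([pop.df["prs"], pop.df["age"]])
    labels = pop.df["case"].to_numpy()
    folds = pop.df["fold"].to_numpy()
    base = cross_validated_scores(GLMLearner, feats, labels, folds)
    perm = rng.permutation(len(labels))
    shuffled = cross_validated_scores(GLMLearner, feats[perm], labels[perm], folds[perm])
    np.testing.assert_allclose(np.sort(base), np.sort(shuffled), atol=1e-9)
    auc1 = evaluate_classifier(base, labels, n_boot=5).auc
    auc2 = evaluate_classifier(shuffled, labels[perm], n_boot=5).auc
    assert auc1 == pytest.approx(auc2, abs=1e-12)
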
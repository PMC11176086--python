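"""Polygenic-score risk prediction on a demography-matched population.

Case-control GWAS cohorts oversample cases, so predictive models trained on
them miscalibrate against the general population.  This module resamples a
case-control cohort into a synthetic population whose age-sex pyramid
matches a demography table and whose age-specific prevalence follows a
cumulative-incidence curve; computes the lead-SNP polygenic risk score
``PRS = sum_j w_j g_j``; fits the interaction logistic model

    logit P(case) = b0 + b1 PRS + b2 sex + b3 age + b4 PRS x sex
                    + b5 PRS x age + b6 sex x age + b7 PRS x sex x age
                    + gamma . PC,

with age entering as 20-year-bin dummies; and evaluates binary and 5-year
landmark prediction with ROC/PR AUC, odds ratio per PRS standard deviation
and Nagelkerke pseudo-R^2.  Any learner exposing ``fit`` /
``predict_scores`` plugs into the cross-validated evaluation harness; a
logistic GLM and a gradient-boosted tree ensemble ship natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .genotypes import FEMALE, GenotypeMatrix
from .liability import PhenotypeTable

__all__ = [
    "SimulatedPopulation",
    "resample_population",
    "compute_prs",
    "InteractionLogit",
    "InteractionGLMFit",
    "nagelkerke_r2",
    "nagelkerke_r2_from_loglik",
    "five_year_labels",
    "evaluate_classifier",
    "PredictionMetrics",
    "interaction_variance_share",
    "GLMLearner",
    "TreeEnsembleLearner",
    "cross_validated_scores",
]

DEMOGRAPHY_COLUMNS = ["SEX", "AGE_LO", "AGE_HI", "PROPORTION", "CUM_INCIDENCE"]


@dataclass
class SimulatedPopulation:
    """Demography-matched individuals for prediction modelling.

    ``df`` columns: sex, birth_year, age, case, onset_age (NaN for
    controls), prs (filled by :func:`compute_prs` or externally), fold.
    ``dosages`` holds the lead-SNP dosage vectors row-aligned with ``df``;
    ``pcs`` the per-individual principal-component covariates.
    """

    df: pd.DataFrame
    dosages: np.ndarray
    variant_ids: np.ndarray
    pcs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.df) != self.dosages.shape[0] or len(self.df) != self.pcs.shape[0]:
            raise ValueError("row mismatch between df, dosages and pcs")
        prevalent = self.df["case"] == 1
        onset = self.df.loc[prevalent, "onset_age"]
        if (onset > self.df.loc[prevalent, "age"] + 1e-9).any():
            raise ValueError("onset after current age for a prevalent case")
        folds = self.df["fold"].to_numpy()
        if np.any(folds < 0):
            raise ValueError("fold assignment must cover all individuals")


def resample_population(
    cohort: PhenotypeTable,
    dosages: np.ndarray,
    variant_ids: np.ndarray,
    demography: pd.DataFrame,
    target_n: int,
    seed: int = 0,
    n_folds: int = 10,
    n_pcs: int = 10,
    current_year: int = 2020,
) -> SimulatedPopulation:
    """Resample a case-control cohort to match a population pyramid.

    ``demography`` rows (SEX, AGE_LO, AGE_HI, PROPORTION, CUM_INCIDENCE)
    define age-sex strata; stratum sizes are drawn multinomially from the
    normalized proportions, ages uniformly within the bin, and case status
    Bernoulli at the stratum's cumulative incidence.  Case draws resample
    source cases (with replacement) whose onset precedes the drawn age;
    control draws resample source controls of the same sex.  The synthetic
    PCs are standard-normal noise covariates (no structure is simulated).
    Folds are stratified on case status.
    """
    for c in DEMOGRAPHY_COLUMNS:
        if c not in demography.columns:
            raise ValueError(f"demography table missing column {c}")
    rng = np.random.default_rng(seed)
    props = demography["PROPORTION"].to_numpy(dtype=float)
    props = props / props.sum()
    counts = rng.multinomial(target_n, props)

    src = cohort.df
    rows = []
    dos_rows = []
    for (stratum, n_s) in zip(demography.itertuples(index=False), counts):
        if n_s == 0:
            continue
        sex = stratum.SEX
        sex_mask = (src["sex"] == sex).to_numpy()
        cases = np.flatnonzero(sex_mask & (src["case"] == 1).to_numpy())
        controls = np.flatnonzero(sex_mask & (src["case"] == 0).to_numpy())
        label = f"{sex}:[{stratum.AGE_LO},{stratum.AGE_HI})"
        if not sex_mask.any():
            raise ValueError(f"no source individuals for stratum {label}")
        ages = rng.uniform(stratum.AGE_LO, stratum.AGE_HI, size=n_s)
        is_case = rng.random(n_s) < stratum.CUM_INCIDENCE
        onsets_src = src["onset_age"].to_numpy()
        for a, c in zip(ages, is_case):
            if c:
                eligible = cases[onsets_src[cases] <= a]
                if len(eligible) == 0:
                    raise ValueError(f"no source case with onset <= {a:.0f} for stratum {label}")
                pick = int(rng.choice(eligible))
                onset = float(onsets_src[pick])
            else:
                if len(controls) == 0:
                    raise ValueError(f"no source controls for stratum {label}")
                pick = int(rng.choice(controls))
                onset = np.nan
            rows.append({"sex": sex, "birth_year": current_year - a, "age": a,
                         "case": int(c), "onset_age": onset, "source_row": pick})
            dos_rows.append(pick)

    df = pd.DataFrame(rows)
    dos = dosages[np.asarray(dos_rows, dtype=int)]
    pcs = rng.standard_normal((len(df), n_pcs))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    fold = np.empty(len(df), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(df)), df["case"])):
        fold[test_idx] = k
    df["fold"] = fold
    df["prs"] = np.nan
    return SimulatedPopulation(df=df, dosages=dos,
                               variant_ids=np.asarray(variant_ids), pcs=pcs)


def compute_prs(
    dosages: np.ndarray,
    variant_ids: np.ndarray,
    weights: pd.DataFrame,
    variant_a1: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    max_missing_frac: float = 0.10,
) -> tuple[np.ndarray, dict]:
    """Weighted allele score ``PRS_i = sum_j w_j g_ij``.

    ``weights`` needs columns ``id`` and ``weight`` (optionally ``a1``; when
    given together with ``variant_a1`` the dosage is flipped to ``2 - g``
    for weights stated on the other allele).  Every weight id must be
    present among ``variant_ids``.  NaN dosages are imputed to ``2 * freq``
    (variant frequency from ``freqs`` or the observed mean) and counted;
    individuals missing more than ``max_missing_frac`` of weighted variants
    are flagged.  Returns ``(prs, report)``.
    """
    ids = list(variant_ids)
    col_of = {v: i for i, v in enumerate(ids)}
    unknown = [v for v in weights["id"] if v not in col_of]
    if unknown:
        raise ValueError(f"weight ids absent from dosage matrix: {unknown[:5]}")
    cols = np.array([col_of[v] for v in weights["id"]], dtype=int)
    w = weights["weight"].to_numpy(dtype=float)
    g = dosages[:, cols].astype(float)
    if "a1" in weights.columns and variant_a1 is not None:
        flip = weights["a1"].to_numpy() != np.asarray(variant_a1)[cols]
        g[:, flip] = 2.0 - g[:, flip]
    miss = ~np.isfinite(g)
    n_imputed = int(miss.sum())
    if n_imputed:
        if freqs is not None:
            fill = 2.0 * np.asarray(freqs)[cols]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fill = np.nanmean(g, axis=0)
            fill = np.where(np.isfinite(fill), fill, 0.0)
        g = np.where(miss, fill[None, :], g)
    flagged = np.flatnonzero(miss.mean(axis=1) > max_missing_frac)
    prs = g @ w
    report = {"n_imputed": n_imputed, "flagged_individuals": flagged}
    return prs, report


def _age_bin(age: np.ndarray, width: float = 20.0) -> np.ndarray:
    return np.floor(np.asarray(age) / width).astype(int)


def _design_matrix(prs: np.ndarray, sex01: np.ndarray, age: np.ndarray,
                   pcs: np.ndarray) -> tuple[np.ndarray, list[str], int]:
    bins = _age_bin(age)
    ref = int(bins.min())
    levels = sorted(set(bins) - {ref})
    cols = [np.ones(len(prs)), prs, sex01]
    names = ["const", "prs", "sex"]
    for lv in levels:
        d = (bins == lv).astype(float)
        cols += [d, prs * d, sex01 * d, prs * sex01 * d]
        names += [f"age{lv}", f"prs:age{lv}", f"sex:age{lv}", f"prs:sex:age{lv}"]
    cols.append(prs * sex01)
    names.append("prs:sex")
    for j in range(pcs.shape[1]):
        cols.append(pcs[:, j])
        names.append(f"pc{j + 1}")
    return np.column_stack(cols), names, ref


@dataclass
class InteractionGLMFit:
    """Coefficients of the interaction logistic model.

    ``table`` rows: term, beta, se, z, p.  Age enters as 20-year-bin
    dummies relative to the youngest bin present (``reference_bin``).
    """

    table: pd.DataFrame
    loglik: float
    n: int
    prs_sd: float
    reference_bin: int

    def coef(self, term: str) -> tuple[float, float]:
        row = self.table[self.table["term"] == term]
        if not len(row):
            raise KeyError(term)
        return float(row["beta"].iloc[0]), float(row["se"].iloc[0])

    def or_per_prs_sd(self, sex: int = 0, age_bin: int | None = None) -> float:
        """Odds ratio per PRS standard deviation in a given stratum; at the
        reference stratum this is exactly ``exp(beta_prs * sd(PRS))``."""
        b = dict(zip(self.table["term"], self.table["beta"]))
        slope = b["prs"] + sex * b.get("prs:sex", 0.0)
        if age_bin is not None and age_bin != self.reference_bin:
            slope += b.get(f"prs:age{age_bin}", 0.0)
            slope += sex * b.get(f"prs:sex:age{age_bin}", 0.0)
        return float(np.exp(slope * self.prs_sd))

    def summary(self) -> str:
        lines = [f"Interaction logistic model (N = {self.n}, logL = {self.loglik:.2f})"]
        for r in self.table.itertuples(index=False):
            lines.append(f"  {r.term:>14s}  {r.beta:+.4f}  (se {r.se:.4f}, p {r.p:.3g})")
        return "\n".join(lines)


class InteractionLogit:
    """Maximum-likelihood fit of the PRS x sex x age interaction model."""

    def __init__(self, pop: SimulatedPopulation):
        prs = pop.df["prs"].to_numpy(dtype=float)
        if not np.isfinite(prs).all():
            raise ValueError("population PRS not computed")
        if prs.std() == 0:
            raise ValueError("PRS is constant; its effect is inestimable")
        self.y = pop.df["case"].to_numpy(dtype=float)
        sex01 = (pop.df["sex"].to_numpy() == FEMALE).astype(float)
        self.x, self.names, self.ref_bin = _design_matrix(
            prs, sex01, pop.df["age"].to_numpy(dtype=float), pop.pcs)
        self.prs_sd = float(prs.std())

    def fit(self) -> InteractionGLMFit:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                res = sm.Logit(self.y, self.x).fit(disp=0, maxiter=200)
            except Exception as exc:  # separation, non-convergence, singular design
                raise ValueError(f"interaction GLM could not be fitted: {exc}") from exc
        if not np.isfinite(res.llf):
            raise ValueError("non-finite likelihood (quasi-complete separation?)")
        tab = pd.DataFrame({"term": self.names, "beta": res.params, "se": res.bse,
                            "z": res.tvalues, "p": res.pvalues})
        return InteractionGLMFit(table=tab, loglik=float(res.llf), n=len(self.y),
                                 prs_sd=self.prs_sd, reference_bin=self.ref_bin)


def nagelkerke_r2(l0: float, l1: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from raw likelihoods:
    ``(1 - (L0/L1)^(2/N)) / (1 - L0^(2/N))``."""
    if not (0 < l0 <= 1) or not (0 < l1 <= 1):
        raise ValueError("likelihoods must lie in (0, 1]")
    if l0 > l1:
        raise ValueError("L0 > L1 violates model nesting")
    return nagelkerke_r2_from_loglik(np.log(l0), np.log(l1), n)


def nagelkerke_r2_from_loglik(ll0: float, ll1: float, n: int) -> float:
    """Underflow-safe form on log-likelihoods."""
    if ll0 > ll1 + 1e-12:
        raise ValueError("ll0 > ll1 violates model nesting")
    num = 1.0 - np.exp(2.0 / n * (ll0 - ll1))
    den = 1.0 - np.exp(2.0 / n * ll0)
    if den == 0:
        return 0.0
    return float(num / den)


def five_year_labels(pop: SimulatedPopulation, landmark_age: float,
                     horizon: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary onset-within-horizon labels at a landmark age.

    Returns ``(labels, index)`` over individuals at risk: label 1 when
    onset falls in ``(landmark, landmark + horizon]``; prevalent cases at
    the landmark are excluded, as are individuals censored (current age)
    before ``landmark + horizon`` without an event in the window.
    """
    age = pop.df["age"].to_numpy(dtype=float)
    onset = pop.df["onset_age"].to_numpy(dtype=float)
    event_in = np.isfinite(onset) & (onset > landmark_age) & (onset <= landmark_age + horizon)
    prevalent = np.isfinite(onset) & (onset <= landmark_age)
    fully_observed = age >= landmark_age + horizon
    at_risk = ~prevalent & (event_in | fully_observed)
    idx = np.flatnonzero(at_risk)
    if len(idx) == 0:
        raise ValueError(f"no individuals at risk at landmark age {landmark_age}")
    return event_in[idx].astype(int), idx


@dataclass
class PredictionMetrics:
    auc: float
    auc_se: float
    pr_auc: float
    or_per_sd: float
    or_ci: tuple[float, float]
    n: int
    n_cases: int

    def summary(self) -> str:
        return (f"AUC {self.auc:.4f} (se {self.auc_se:.4f}); PR-AUC {self.pr_auc:.4f}; "
                f"OR/sd {self.or_per_sd:.3f} ({self.or_ci[0]:.3f}-{self.or_ci[1]:.3f}); "
                f"N {self.n} ({self.n_cases} cases)")


def evaluate_classifier(scores: np.ndarray, labels: np.ndarray,
                        n_boot: int = 200, seed: int = 0) -> PredictionMetrics:
    """Rank-statistic ROC AUC with bootstrap se, step-interpolated PR AUC,
    and the odds ratio per score standard deviation from a univariate
    logistic refit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    pr = float(average_precision_score(labels, scores))
    rng = np.random.default_rng(seed)
    n = len(labels)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if labels[idx].min() == labels[idx].max():
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    auc_se = float(np.std(boots)) if boots else np.nan

    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else scores * 0.0
    import statsmodels.api as sm

    res = sm.Logit(labels, sm.add_constant(z)).fit(disp=0)
    b, se = float(res.params[1]), float(res.bse[1])
    with np.errstate(over="ignore"):
        or_sd = float(np.exp(b))
        ci = (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))
    return PredictionMetrics(
        auc=auc, auc_se=auc_se, pr_auc=pr, or_per_sd=or_sd, or_ci=ci,
        n=n, n_cases=int(labels.sum()),
    )


def interaction_variance_share(r2_linear: float, r2_full: float) -> float:
    """Share of explained variance attributable to nonlinearities and
    interactions: ``(r2_full - r2_linear) / r2_full``, floored at zero with
    a warning when the full model explains less."""
    if r2_full == 0:
        raise ValueError("r2_full is zero; share undefined")
    share = (r2_full - r2_linear) / r2_full
    if share < 0:
        warnings.warn("full model explains less than the linear model; share floored at 0")
        return 0.0
    return float(share)


class GLMLearner:
    """Plain logistic regression on the raw feature columns."""

    def __init__(self, **kwargs):
        self.model = LogisticRegression(max_iter=1000, **kwargs)

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "GLMLearner":
        self.model.fit(features, labels)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(features)[:, 1]


class TreeEnsembleLearner:
    """Gradient-boosted tree ensemble; captures interactions and threshold
    nonlinearities the linear GLM cannot."""

    def __init__(self, **kwargs):
        kwargs.setdefault("max_iter", 200)
        kwargs.setdefault("random_state", 0)
        self.model = HistGradientBoostingClassifier(**kwargs)

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "TreeEnsembleLearner":
        self.model.fit(features, labels)
        return self

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(features)[:, 1]


def cross_validated_scores(learner_factory, features: np.ndarray, labels: np.ndarray,
                           folds: np.ndarray) -> np.ndarray:
    """Out-of-fold prediction scores under a precomputed fold assignment;
    invariant to individual ordering by construction."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    scores = np.empty(len(labels), dtype=float)
    for k in np.unique(folds):
        test = folds == k
        train = ~test
        if len(set(labels[train].tolist())) < 2:
            raise ValueError(f"fold {k}: training data contains a single class")
        model = learner_factory().fit(features[train], labels[train])
        scores[test] = model.predict_scores(features[test])
    return scores
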
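"""Liability-threshold phenotypes with sex-specific prevalence and G x E.

Disease status arises from a latent Gaussian liability

    L = a * S + c_E * E + c_sex * (S x E) + strat_shift * U + eps,

where ``S`` is the standardized polygenic score over the causal variants,
``a = sqrt(h2_liab)``, ``E`` is an (optional) environmental exposure whose
distribution may differ between sexes, ``c_sex`` is a sex-specific
gene-environment interaction coefficient, and ``U`` is a standardized
genome-wide "drift" score emulating uncorrected population stratification.
Residual variance is chosen so the total liability variance equals one in
expectation (the realized variance is checked by tests, not forced), and an
individual is a case when L exceeds the sex-specific threshold
``Phi^-1(1 - K_sex)`` set by the population prevalence of that sex.

A sex-asymmetric interaction (``c_f > c_m``) with a positive-mean exposure
inflates the marginal per-variant effects in females by the factor
``a + c_f * mean(E)`` versus ``a + c_m * mean(E)`` in males while leaving
the cross-sex effect correlation at one -- the mechanism by which an
unobserved exposure can produce a large sex gap in estimated SNP
heritability despite a genetic correlation of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import FEMALE, MALE, GenotypeMatrix
from .sumstats import SumStats

__all__ = [
    "LiabilityModelParams",
    "PhenotypeTable",
    "simulate_liability_phenotypes",
    "run_single_snp_gwas",
]


@dataclass
class LiabilityModelParams:
    """Generative parameters of the liability model.

    ``exposure_kind`` is one of ``none`` (E = 0), ``binary``
    (E ~ Bernoulli(q_sex)) or ``continuous`` (E ~ Normal(q_sex, 1)).
    ``gxe_m``/``gxe_f`` are the sex-specific interaction coefficients whose
    ratio is the quantity of interest in sex-differential heritability
    analyses.
    """

    h2_liab: float = 0.2
    m_causal: int = 100
    prevalence_male: float = 0.09
    prevalence_female: float = 0.09
    exposure_kind: str = "none"  # none | binary | continuous
    exposure_rate_male: float = 0.0
    exposure_rate_female: float = 0.0
    env_main_effect: float = 0.0
    gxe_m: float = 0.0
    gxe_f: float = 0.0
    strat_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2_liab < 1):
            raise ValueError("h2_liab must be in [0, 1)")
        for k in (self.prevalence_male, self.prevalence_female):
            if not (0 < k < 1):
                raise ValueError("prevalences must be in (0, 1)")
        if self.exposure_kind not in ("none", "binary", "continuous"):
            raise ValueError(f"unknown exposure_kind: {self.exposure_kind}")

    def exposure_moments(self, sex: str) -> tuple[float, float]:
        """(mean, variance) of the exposure for the given sex."""
        q = self.exposure_rate_male if sex == MALE else self.exposure_rate_female
        if self.exposure_kind == "none":
            return 0.0, 0.0
        if self.exposure_kind == "binary":
            return q, q * (1 - q)
        return q, 1.0


@dataclass
class PhenotypeTable:
    """Per-individual phenotype records backed by a DataFrame with columns
    ``case`` (0/1), ``liability``, ``onset_age`` (NaN for controls),
    ``age``, ``sex``, ``exposure``."""

    df: pd.DataFrame
    params: LiabilityModelParams | None = None
    causal_idx: np.ndarray | None = None
    causal_betas: np.ndarray | None = None

    def __post_init__(self) -> None:
        needed = {"case", "liability", "age", "sex"}
        if not needed <= set(self.df.columns):
            raise ValueError(f"phenotype table missing columns: {needed - set(self.df.columns)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def case(self) -> np.ndarray:
        return self.df["case"].to_numpy(dtype=int)

    @property
    def n_cases(self) -> int:
        return int(self.case.sum())


def _truncnorm_onset(rng: np.random.Generator, ages: np.ndarray,
                     mean: float = 45.0, sd: float = 15.0, lo: float = 5.0) -> np.ndarray:
    """Onset ages ~ Normal(mean, sd) truncated to [lo, current age]."""
    a = (lo - mean) / sd
    b = (ages - mean) / sd
    u = rng.random(len(ages))
    lo_cdf = stats.norm.cdf(a)
    hi_cdf = stats.norm.cdf(b)
    return mean + sd * stats.norm.ppf(lo_cdf + u * np.maximum(hi_cdf - lo_cdf, 1e-12))


def simulate_liability_phenotypes(g: GenotypeMatrix, params: LiabilityModelParams) -> PhenotypeTable:
    """Draw phenotypes for every individual in ``g`` under the liability model.

    Raises ``ValueError`` with a variance diagnostic if the systematic terms
    already exceed unit variance for either sex.  Deterministic given
    ``params.seed``.
    """
    if params.m_causal > g.m_variants:
        raise ValueError("m_causal exceeds number of variants")
    rng = np.random.default_rng(params.seed)
    n = g.n_individuals
    a = float(np.sqrt(params.h2_liab))

    causal = np.sort(rng.choice(g.m_variants, size=params.m_causal, replace=False))
    betas = rng.standard_normal(params.m_causal)
    z = g.standardized()[:, causal]
    raw = z @ betas
    sd = raw.std()
    score = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)

    is_female = g.sex == FEMALE
    exposure = np.zeros(n)
    if params.exposure_kind == "binary":
        q = np.where(is_female, params.exposure_rate_female, params.exposure_rate_male)
        exposure = (rng.random(n) < q).astype(float)
    elif params.exposure_kind == "continuous":
        q = np.where(is_female, params.exposure_rate_female, params.exposure_rate_male)
        exposure = rng.standard_normal(n) + q

    c_sex = np.where(is_female, params.gxe_f, params.gxe_m)
    # confounding: liability offset +-1/2 by subpopulation label (paired with
    # allele-frequency drift in the genotype panel this inflates association
    # statistics uniformly across variants, the LDSC-intercept signature)
    strat = np.zeros(n)
    strat_var = 0.0
    if params.strat_shift != 0.0:
        strat = np.where(g.subpop == 1, 0.5, -0.5)
        strat = strat - strat.mean()
        strat_var = float(np.mean(strat**2))

    resid_var = np.empty(n)
    for sex, mask in ((MALE, ~is_female), (FEMALE, is_female)):
        if not mask.any():
            continue
        mu_e, var_e = params.exposure_moments(sex)
        c = params.gxe_f if sex == FEMALE else params.gxe_m
        systematic = (
            a * a
            + c * c * (var_e + mu_e * mu_e)
            + 2 * a * c * mu_e
            + params.env_main_effect ** 2 * var_e
            + params.strat_shift ** 2 * strat_var
        )
        if systematic >= 1:
            raise ValueError(
                f"systematic liability variance {systematic:.3f} >= 1 for sex={sex}; "
                "reduce h2_liab, exposure or interaction effects"
            )
        resid_var[mask] = 1.0 - systematic

    liability = (
        a * score
        + params.env_main_effect * exposure
        + c_sex * score * exposure
        + params.strat_shift * strat
        + rng.standard_normal(n) * np.sqrt(resid_var)
    )

    thr = np.where(is_female,
                   stats.norm.ppf(1 - params.prevalence_female),
                   stats.norm.ppf(1 - params.prevalence_male))
    case = (liability > thr).astype(int)

    age = rng.uniform(20.0, 80.0, size=n)
    onset = np.full(n, np.nan)
    idx = np.flatnonzero(case == 1)
    if len(idx):
        onset[idx] = _truncnorm_onset(rng, age[idx])

    df = pd.DataFrame(
        {"case": case, "liability": liability, "onset_age": onset,
         "age": age, "sex": g.sex, "exposure": exposure}
    )
    return PhenotypeTable(df, params=params, causal_idx=causal, causal_betas=betas * a / sd)


def _logistic_null(y: np.ndarray, x: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Newton fit of logistic y ~ x; returns fitted probabilities."""
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = x.T @ (y - p)
        hess = (x * w[:, None]).T @ x
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return 1.0 / (1.0 + np.exp(-(x @ beta)))


def run_single_snp_gwas(
    g: GenotypeMatrix,
    phen: PhenotypeTable,
    covariates: np.ndarray | None = None,
    trait: str = "case",
    cohort: str = "sim",
    sex_stratum: str = "pooled",
) -> SumStats:
    """Per-variant additive association scan.

    For the binary trait the statistic is the logistic-regression score test
    of each dosage column against case status adjusting for covariates (the
    per-variant effect and standard error are the one-step score-based
    estimates); for ``trait="liability"`` an ordinary least-squares scan on
    the quantitative liability is used.  Monomorphic variants are flagged
    missing (``missing=True``, NaN statistics) rather than dropped.
    """
    y = phen.case.astype(float) if trait == "case" else phen.df["liability"].to_numpy()
    n = len(y)
    if trait == "case":
        n_case = int(y.sum())
        n_control = n - n_case
        if n_case < 2 or n_control < 2:
            raise ValueError("need at least 2 cases and 2 controls")
    else:
        n_case = n_control = 0

    x = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    dos = g.dosages.astype(np.float64)
    mono = dos.std(axis=0) == 0

    if trait == "case":
        p0 = _logistic_null(y, x)
        w = p0 * (1 - p0)
        resid = y - p0
        # project dosages off the covariate space in the W metric
        xtwx = (x * w[:, None]).T @ x
        xtwg = (x * w[:, None]).T @ dos
        adj = x @ np.linalg.solve(xtwx, xtwg)
        u = dos.T @ resid
        v = np.einsum("ij,ij->j", dos * w[:, None], dos) - np.einsum(
            "ij,ij->j", adj * w[:, None], dos
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(v <= 0, np.nan, v)
            zscore = u / np.sqrt(v)
            beta = u / v
            se = 1.0 / np.sqrt(v)
        pval = 2 * stats.norm.sf(np.abs(zscore))
    else:
        # per-variant OLS after residualizing on covariates; the per-variant
        # residual variance and t reference keep null p-values exactly uniform
        q, _ = np.linalg.qr(x)
        yr = y - q @ (q.T @ y)
        gr = dos - q @ (q.T @ dos)
        u = gr.T @ yr
        gss = np.einsum("ij,ij->j", gr, gr)
        yss = float(yr @ yr)
        dof = max(n - x.shape[1] - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gss = np.where(gss <= 0, np.nan, gss)
            beta = u / gss
            sigma2 = np.maximum(yss - u**2 / gss, 0.0) / dof
            se = np.sqrt(sigma2 / gss)
            zscore = beta / se
        pval = 2 * stats.t.sf(np.abs(zscore), dof)
    zscore[mono] = np.nan
    beta[mono] = np.nan
    se[mono] = np.nan
    # keep p in (0, 1]
    pval = np.where(np.isnan(zscore), np.nan, np.clip(pval, 5e-324, 1.0))

    out = g.variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    out["freq"] = np.clip(dos.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    out["beta"] = beta
    out["se"] = se
    out["z"] = zscore
    out["p"] = pval
    out["n"] = n
    out["n_case"] = n_case
    out["n_control"] = n_control
    out["missing"] = mono
    return SumStats(out, cohort=cohort, trait=trait, sex_stratum=sex_stratum)
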
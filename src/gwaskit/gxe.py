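"""Sex-stratified simulation study of gene-environment interaction.

The question this module answers: can an unobserved environmental factor
whose interaction with the polygenic liability differs between the sexes
explain a large male/female gap in estimated SNP heritability even when the
cross-sex genetic correlation is one?  Under the liability model used here
the marginal per-variant effect in sex k is proportional to
``sqrt(h2) + c_k * mean(E_k)``, so a female-only interaction with a
positive-mean exposure inflates female marginal heritability while leaving
the effect-vector correlation at exactly one.

Candidate generative models (no interaction, binary exposure, continuous
exposure) are compared against an observed triple
``(h2_male, h2_female, rg)`` by approximate Bayesian computation: draw
parameters from uniform priors, simulate a sex-stratified GWAS study,
summarize it with the fast moment estimators from the heritability module,
and accept a draw when the Mahalanobis distance (scaled by the observed
standard errors) falls below a pooled-quantile threshold.  Acceptance rates
approximate marginal likelihoods, giving log10 Bayes factors between
models, and the accepted draws of the winning interaction model provide a
posterior for the female/male interaction-strength ratio ``c_f / c_m``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import FEMALE, MALE, GenotypeMatrix, simulate_ld_reference
from .heritability import (
    compute_ld_scores,
    liability_transform,
    m_eff_from_ld_scores,
    xchr_h2,
    xchr_rg,
)
from .liability import LiabilityModelParams, run_single_snp_gwas, simulate_liability_phenotypes
from .sumstats import SumStats

__all__ = [
    "GxEModelSpec",
    "ObservedSummaries",
    "StudySummaries",
    "ModelComparison",
    "simulate_sex_stratified_study",
    "abc_model_comparison",
    "estimate_rgxe_ratio",
    "RgxeRatio",
]

MODEL_CLASSES = ("no_gxe", "gxe_binary", "gxe_continuous")


@dataclass
class GxEModelSpec:
    """One candidate generative model for the sex-stratified study.

    ``model_class`` fixes the exposure kind; ``no_gxe`` forces both
    interaction coefficients to zero.  ``n_per_sex`` individuals per sex are
    simulated over ``blocks x block_size`` variants with within-block LD
    parameter ``rho``.
    """

    base: LiabilityModelParams
    model_class: str = "no_gxe"
    n_per_sex: int = 20000
    blocks: int = 100
    block_size: int = 10
    rho: float = 0.5
    n_replicates: int = 1
    name: str | None = None

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        if self.model_class == "no_gxe":
            self.base = replace(self.base, gxe_m=0.0, gxe_f=0.0, exposure_kind="none")
        elif self.model_class == "gxe_binary":
            self.base = replace(self.base, exposure_kind="binary")
        else:
            self.base = replace(self.base, exposure_kind="continuous")
        if self.name is None:
            self.name = self.model_class

    @property
    def m_variants(self) -> int:
        return self.blocks * self.block_size


@dataclass
class ObservedSummaries:
    """The target triple a candidate model must reproduce."""

    h2_m: float
    h2_m_se: float
    h2_f: float
    h2_f_se: float
    rg: float
    rg_se: float

    def __post_init__(self) -> None:
        if min(self.h2_m_se, self.h2_f_se, self.rg_se) <= 0:
            raise ValueError("standard errors must be positive")

    @classmethod
    def illustrative(cls) -> "ObservedSummaries":
        """Round-number defaults in the range reported for sex-differential
        heritability of a common neurological trait; for demonstrations
        only, not a test truth."""
        return cls(h2_m=0.13, h2_m_se=0.03, h2_f=0.32, h2_f_se=0.03, rg=0.96, rg_se=0.07)

    def as_array(self) -> np.ndarray:
        return np.array([self.h2_m, self.h2_f, self.rg])

    def se_array(self) -> np.ndarray:
        return np.array([self.h2_m_se, self.h2_f_se, self.rg_se])


@dataclass
class StudySummaries:
    """Realized estimates from one simulated sex-stratified study."""

    h2_m: float
    h2_m_se: float
    h2_f: float
    h2_f_se: float
    rg: float
    rg_se: float
    male_stats: SumStats | None = None
    female_stats: SumStats | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.h2_m, self.h2_f, self.rg])


def _zprod_rg(zm: np.ndarray, zf: np.ndarray, n_blocks: int = 50) -> tuple[float, float]:
    """Cross-sex rg by the Z-product moment formula with a block-jackknife
    se; NaN when a mean chi-square is at or below one."""
    try:
        rg, _raw = xchr_rg(zm, zf)
    except ValueError:
        return np.nan, np.nan
    nb = min(n_blocks, len(zm) // 10)
    blocks = np.array_split(np.arange(len(zm)), nb)
    vals = []
    for idx in blocks:
        mask = np.ones(len(zm), dtype=bool)
        mask[idx] = False
        try:
            v, _ = xchr_rg(zm[mask], zf[mask])
        except ValueError:
            v = rg
        vals.append(v)
    vals = np.asarray(vals)
    se = float(np.sqrt((nb - 1) / nb * np.sum((vals - vals.mean()) ** 2)))
    return rg, se


def simulate_sex_stratified_study(
    spec: GxEModelSpec,
    seed: int,
    genotypes: GenotypeMatrix | None = None,
    m_eff: float | None = None,
) -> StudySummaries:
    """Simulate one study: shared genetic architecture, sex-specific
    exposure/interaction, per-sex GWAS, then h2 per sex (moment estimator on
    the liability scale) and cross-sex rg.

    ``genotypes``/``m_eff`` may be passed to reuse a panel across replicate
    studies (phenotypes and effects are redrawn each call).
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    if genotypes is None:
        n = 2 * spec.n_per_sex
        sex = np.array([MALE] * spec.n_per_sex + [FEMALE] * spec.n_per_sex, dtype=object)
        genotypes = simulate_ld_reference(
            n=n, blocks=spec.blocks, block_size=spec.block_size, rho=spec.rho,
            seed=int(sub[0]), sex=sex,
        )
    if m_eff is None:
        scores = compute_ld_scores(genotypes, window_kb=1000)
        m_eff = m_eff_from_ld_scores(scores)

    params = replace(spec.base, seed=int(sub[1]))
    phen = simulate_liability_phenotypes(genotypes, params)

    out = {}
    zvecs = {}
    for sex_code, K in ((MALE, params.prevalence_male), (FEMALE, params.prevalence_female)):
        mask = genotypes.sex == sex_code
        g_sex = GenotypeMatrix(genotypes.dosages[mask], genotypes.variants, genotypes.sex[mask])
        from .liability import PhenotypeTable

        p_sex = PhenotypeTable(phen.df[mask].reset_index(drop=True))
        stats_sex = run_single_snp_gwas(g_sex, p_sex, sex_stratum=sex_code)
        z = stats_sex.df["z"].to_numpy(dtype=float)
        z = np.where(np.isfinite(z), z, 0.0)
        n_sex = int(mask.sum())
        chi2 = float(np.mean(z**2))
        h2_obs, _neg = xchr_h2(chi2, n_sex, m_eff)
        # moment-estimator se: var(chi2) ~ 2 + 4*(chi2-1) per variant
        se_obs = float(np.sqrt(np.var(z**2) / len(z)) * m_eff / n_sex)
        P = p_sex.df["case"].mean()
        P = min(max(P, 1e-4), 1 - 1e-4)
        mult = liability_transform(1.0, K, P)
        out[sex_code] = (h2_obs * mult, se_obs * mult, stats_sex)
        zvecs[sex_code] = z

    rg, rg_se = _zprod_rg(zvecs[MALE], zvecs[FEMALE])
    return StudySummaries(
        h2_m=out[MALE][0], h2_m_se=out[MALE][1],
        h2_f=out[FEMALE][0], h2_f_se=out[FEMALE][1],
        rg=rg, rg_se=rg_se,
        male_stats=out[MALE][2], female_stats=out[FEMALE][2],
    )


@dataclass
class ModelComparison:
    """ABC output: per-model acceptance, Bayes factors and posteriors."""

    models: list[GxEModelSpec]
    n_draws: int
    threshold: float
    accepted: dict[str, pd.DataFrame]
    acceptance: dict[str, int]
    likelihood_floored: dict[str, bool]
    log10_marglik: dict[str, float]
    log10_bf: dict[str, float]  # vs the first (reference) model
    log10_bf_se: dict[str, float]

    def winning_model(self) -> GxEModelSpec:
        best = max(self.log10_marglik, key=lambda k: self.log10_marglik[k])
        return next(m for m in self.models if m.name == best)

    def summary(self) -> str:
        lines = [f"ABC model comparison ({self.n_draws} draws per model, "
                 f"distance threshold {self.threshold:.3f})"]
        ref = self.models[0].name
        for m in self.models:
            flag = " (floored)" if self.likelihood_floored[m.name] else ""
            lines.append(
                f"  {m.name}: accepted {self.acceptance[m.name]}, "
                f"log10 ML {self.log10_marglik[m.name]:.3f}{flag}, "
                f"log10 BF vs {ref}: {self.log10_bf[m.name]:+.3f} "
                f"(MC se {self.log10_bf_se[m.name]:.3f})"
            )
        return "\n".join(lines)


def abc_model_comparison(
    obs: ObservedSummaries,
    models: list[GxEModelSpec],
    priors: dict[str, tuple[float, float]],
    n_draws: int = 500,
    tolerance: float = 0.1,
    seed: int = 0,
) -> ModelComparison:
    """Approximate Bayesian computation over candidate G x E models.

    For each model, ``n_draws`` parameter vectors are drawn from independent
    uniform priors (keys of ``priors`` name ``LiabilityModelParams`` fields,
    e.g. ``h2_liab``, ``gxe_m``, ``gxe_f``); each draw simulates a study on
    a genotype panel shared across that model's draws and is summarized as
    ``(h2_m, h2_f, rg)``.  The acceptance threshold is the ``tolerance``
    quantile of the distances pooled over all models, so acceptance rates
    are comparable and their ratios approximate Bayes factors.  A model with
    zero acceptances has its likelihood floored at ``1/(n_draws + 1)`` and
    is flagged.  Deterministic given ``seed``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if not (0 < tolerance < 1):
        raise ValueError("tolerance is an acceptance quantile in (0, 1)")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique")

    se = obs.se_array()
    target = obs.as_array()

    records: dict[str, list[dict]] = {m.name: [] for m in models}
    for m in models:
        # stream keyed by (seed, model name), not list position: results are
        # invariant to model order, making Bayes factors exactly antisymmetric
        rng = np.random.default_rng([seed, zlib.crc32(m.name.encode())])
        panel_seed = int(rng.integers(0, 2**31 - 1))
        sex = np.array([MALE] * m.n_per_sex + [FEMALE] * m.n_per_sex, dtype=object)
        panel = simulate_ld_reference(
            n=2 * m.n_per_sex, blocks=m.blocks, block_size=m.block_size,
            rho=m.rho, seed=panel_seed, sex=sex,
        )
        scores = compute_ld_scores(panel, window_kb=1000)
        m_eff = m_eff_from_ld_scores(scores)
        for d in range(n_draws):
            draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in priors.items()}
            if m.model_class == "no_gxe":
                draw.pop("gxe_m", None)
                draw.pop("gxe_f", None)
            base = replace(m.base, **draw)
            spec_d = replace(m, base=base)
            study_seed = int(rng.integers(0, 2**31 - 1))
            try:
                s = simulate_sex_stratified_study(spec_d, study_seed,
                                                  genotypes=panel, m_eff=m_eff)
                summ = s.as_array()
                if np.all(np.isfinite(summ)):
                    dist = float(np.sqrt(np.sum(((summ - target) / se) ** 2)))
                else:
                    dist = np.inf
            except ValueError:
                summ = np.full(3, np.nan)
                dist = np.inf
            rec = {"model": m.name, "distance": dist,
                   "h2_m": summ[0], "h2_f": summ[1], "rg": summ[2]}
            rec.update({k: base.__dict__[k] for k in ("h2_liab", "gxe_m", "gxe_f")})
            records[m.name].append(rec)

    all_dist = np.concatenate([np.array([r["distance"] for r in records[n]]) for n in names])
    finite = all_dist[np.isfinite(all_dist)]
    if len(finite) == 0:
        raise ValueError("all simulated distances are infinite; check the model specs")
    threshold = float(np.quantile(finite, tolerance))

    accepted, acc_n, floored, logml = {}, {}, {}, {}
    for nme in names:
        df = pd.DataFrame(records[nme])
        acc = df[df["distance"] <= threshold].reset_index(drop=True)
        accepted[nme] = acc
        acc_n[nme] = len(acc)
        if len(acc) == 0:
            floored[nme] = True
            logml[nme] = float(np.log10(1.0 / (n_draws + 1)))
        else:
            floored[nme] = False
            logml[nme] = float(np.log10(len(acc) / n_draws))

    ref = names[0]
    bf, bf_se = {}, {}
    for nme in names:
        bf[nme] = logml[nme] - logml[ref]
        se_terms = 0.0
        for key in (nme, ref):
            k = max(acc_n[key], 1)
            se_terms += (1 - k / n_draws) / k
        bf_se[nme] = float(np.sqrt(se_terms) / np.log(10))
    return ModelComparison(
        models=models, n_draws=n_draws, threshold=threshold, accepted=accepted,
        acceptance=acc_n, likelihood_floored=floored, log10_marglik=logml,
        log10_bf=bf, log10_bf_se=bf_se,
    )


@dataclass
class RgxeRatio:
    ratio: float
    ci_low: float
    ci_high: float
    level: float
    one_sided: bool
    n_accepted: int


def estimate_rgxe_ratio(
    comparison: ModelComparison,
    bootstrap_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    zero_fraction_cutoff: float = 0.05,
) -> RgxeRatio:
    """Posterior ratio ``c_f / c_m`` from the winning model's accepted draws.

    The point estimate is the posterior median; the CI is the percentile
    credible interval of the accepted ratios (computed on a bootstrap pool
    of ``bootstrap_reps`` resamples to smooth small acceptance sets).  When
    the accepted male-interaction posterior has appreciable mass at zero
    (lower ``zero_fraction_cutoff`` quantile below 5% of its prior span) the
    ratio is unbounded above and a one-sided lower bound is reported.
    """
    win = comparison.winning_model()
    if win.model_class == "no_gxe":
        raise ValueError("winning model has no interaction; ratio undefined")
    acc = comparison.accepted[win.name]
    if len(acc) == 0:
        raise ValueError("no accepted draws for the winning model")
    rng = np.random.default_rng(seed)
    c_m = acc["gxe_m"].to_numpy(dtype=float)
    c_f = acc["gxe_f"].to_numpy(dtype=float)
    span = max(np.abs(c_m).max(), np.abs(c_f).max(), 1e-12)
    alpha = 1.0 - level
    one_sided = np.quantile(np.abs(c_m), zero_fraction_cutoff) < 0.05 * span
    with np.errstate(divide="ignore"):
        ratios = np.where(c_m != 0, c_f / c_m, np.inf)
    pool = rng.choice(ratios, size=bootstrap_reps * max(len(ratios) // 10, 1), replace=True)
    pool = np.concatenate([ratios, pool])
    if one_sided:
        fin = pool[np.isfinite(pool)]
        lo = float(np.quantile(fin, alpha)) if len(fin) else np.nan
        return RgxeRatio(ratio=np.inf, ci_low=lo, ci_high=np.inf, level=level,
                         one_sided=True, n_accepted=len(acc))
    lo = float(np.quantile(pool, alpha / 2))
    hi = float(np.quantile(pool, 1 - alpha / 2))
    return RgxeRatio(ratio=float(np.median(ratios)), ci_low=lo, ci_high=hi,
                     level=level, one_sided=False, n_accepted=len(acc))
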
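"""LD-score regression heritability and genetic correlation.

Under a polygenic model in which every variant is expected to contribute
equally to heritability, the expected association chi-square of variant j is

    E[chi2_j] = N * h2 / M * l_j + intercept,

where ``l_j`` is the LD score (sum of squared correlations with variants in
a local window, with the small-sample bias adjustment
``r~2 = r2 - (1 - r2)/(n - 2)``), M is the number of variants and N the
sample size.  The slope of a weighted regression of chi2 on l yields the
observed-scale SNP heritability while the intercept captures confounding
(population stratification, cryptic relatedness); the ratio
``(intercept - 1)/(mean chi2 - 1)`` measures the confounded share of the
inflation.  Standard errors come from a delete-one block jackknife over
contiguous genomic blocks.  A cross-trait regression of ``Z1 * Z2`` on l
yields the genetic covariance and hence the genetic correlation, with
sample overlap absorbed by the cross intercept.

Observed-scale estimates for case-control traits are mapped to the liability
scale via ``h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2)`` with population
prevalence K, sample case fraction P and ``z`` the standard-normal density
at the liability threshold.

For chromosome X, where the LD-score machinery is not applicable, the
moment estimators are ``h2_k = (mean chi2_k - 1) * M_eff / N_k`` per sex k
and the cross-sex genetic correlation
``rg = mean(Zm * Zf) / sqrt((mean chi2_f - 1)(mean chi2_m - 1))`` for
independent male and female samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .sumstats import SumStats

__all__ = [
    "compute_ld_scores",
    "write_ld_scores",
    "read_ld_scores",
    "LDScoreRegression",
    "LDSCResults",
    "liability_transform",
    "ldsc_rg",
    "RgResult",
    "estimate_diff_ztest",
    "xchr_h2",
    "xchr_rg",
    "XChromosomeEstimate",
    "m_eff_from_ld_scores",
]


def compute_ld_scores(ld: GenotypeMatrix, window_kb: float = 1000.0) -> pd.DataFrame:
    """Windowed LD scores with the unbiased small-sample adjustment.

    ``l_j = sum_{k : |bp_j - bp_k| <= window} r~2_jk`` including the self
    term, where ``r~2 = r2 - (1 - r2)/(n - 2)``.  Requires n >= 3.
    Returns a DataFrame with columns id, chrom, pos, ldscore.
    """
    n = ld.n_individuals
    if n < 3:
        raise ValueError("need at least 3 individuals for the r2 bias adjustment")
    if window_kb < 0:
        raise ValueError("window must be non-negative")
    zstd = ld.standardized()
    out = np.empty(ld.m_variants)
    window_bp = window_kb * 1000
    for chrom, grp in ld.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        zc = zstd[:, idx]
        m = len(idx)
        chunk = 512
        for i0 in range(0, m, chunk):
            i1 = min(i0 + chunk, m)
            # banded window: positions are sorted within a chromosome
            j0 = int(np.searchsorted(pos, pos[i0] - window_bp, side="left"))
            j1 = int(np.searchsorted(pos, pos[i1 - 1] + window_bp, side="right"))
            r = (zc[:, i0:i1].T @ zc[:, j0:j1]) / n
            r2 = r**2
            r2adj = r2 - (1.0 - r2) / (n - 2)
            inwin = np.abs(pos[i0:i1, None] - pos[None, j0:j1]) <= window_bp
            out[idx[i0:i1]] = np.sum(np.where(inwin, r2adj, 0.0), axis=1)
    return pd.DataFrame(
        {"id": ld.variants["id"], "chrom": ld.variants["chrom"],
         "pos": ld.variants["pos"], "ldscore": out}
    )


def write_ld_scores(scores: pd.DataFrame, path: str | Path) -> None:
    tab = scores.rename(columns={"id": "ID", "chrom": "CHR", "pos": "BP", "ldscore": "L2"})
    tab.to_csv(Path(path), sep="\t", index=False)


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(Path(path), sep="\t", dtype={"CHR": str})
    return tab.rename(columns={"ID": "id", "CHR": "chrom", "BP": "pos", "L2": "ldscore"})


def _two_step_fit(chi2: np.ndarray, l: np.ndarray, two_step_cut: float,
                  n_iter: int = 2) -> tuple[float, float]:
    """Two-step weighted fit of chi2 on l; returns (slope, intercept).

    Step 1 estimates the intercept on chi2 < cut; step 2 fixes it and
    re-estimates the slope on all variants.  Heteroskedasticity and
    LD-overcounting weights ``1/(l * max(1, fitted chi2)^2)`` are iterated
    ``n_iter`` times; with ``n_iter=0`` the weights are the fixed ``1/l``
    scheme (useful because the fit is then exactly equivariant under a
    constant shift of the chi-squares).
    """
    lsafe = np.maximum(l, 1.0)
    slope = max((chi2.mean() - 1.0), 0.0) / max(l.mean(), 1e-12)
    intercept = 1.0
    for _ in range(n_iter + 1):
        if n_iter == 0:
            w = 1.0 / lsafe
        else:
            pred = np.maximum(intercept + slope * l, 1.0)
            w = 1.0 / (lsafe * pred**2)
        sub = chi2 < two_step_cut
        if sub.sum() >= 10:
            ws, ls, cs = w[sub], l[sub], chi2[sub]
            sw = ws.sum()
            lbar = (ws * ls).sum() / sw
            cbar = (ws * cs).sum() / sw
            varl = (ws * (ls - lbar) ** 2).sum()
            if varl > 0:
                s1 = (ws * (ls - lbar) * (cs - cbar)).sum() / varl
                intercept = cbar - s1 * lbar
        # step 2: slope through fixed intercept on all variants
        slope = (w * l * (chi2 - intercept)).sum() / (w * l * l).sum()
    return slope, intercept


@dataclass
class LDSCResults:
    """Heritability estimates from LD-score regression."""

    h2_obs: float
    h2_obs_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    m_variants: int
    n_bar: float
    n_blocks: int
    h2_liab: float | None = None
    h2_liab_se: float | None = None
    prevalence: float | None = None
    case_fraction: float | None = None

    @property
    def ratio(self) -> float:
        """Confounding inflation ratio (intercept - 1)/(mean chi2 - 1);
        defined only when mean chi2 exceeds one."""
        if self.mean_chi2 <= 1:
            return np.nan
        return (self.intercept - 1.0) / (self.mean_chi2 - 1.0)

    def to_liability(self, K: float, P: float) -> "LDSCResults":
        """Attach liability-scale estimates for prevalence K and sample case
        fraction P (the jackknife se scales by the same multiplier)."""
        mult = liability_transform(1.0, K, P)
        self.h2_liab = self.h2_obs * mult
        self.h2_liab_se = self.h2_obs_se * mult
        self.prevalence = K
        self.case_fraction = P
        return self

    def summary(self) -> str:
        lines = [
            "LD-score regression",
            f"  variants: {self.m_variants}   mean chi2: {self.mean_chi2:.4f}   N: {self.n_bar:.0f}",
            f"  h2 (observed): {self.h2_obs:.4f} (se {self.h2_obs_se:.4f})",
            f"  intercept:     {self.intercept:.4f} (se {self.intercept_se:.4f})",
            f"  ratio:         {self.ratio:.4f}" if np.isfinite(self.ratio) else "  ratio:         undefined (mean chi2 <= 1)",
            f"  jackknife blocks: {self.n_blocks}",
        ]
        if self.h2_liab is not None:
            lines.insert(3, f"  h2 (liability, K={self.prevalence}, P={self.case_fraction}): "
                            f"{self.h2_liab:.4f} (se {self.h2_liab_se:.4f})")
        return "\n".join(lines)


class LDScoreRegression:
    """Model object for LD-score regression of one trait's chi-squares.

    Parameters
    ----------
    stats
        Summary statistics; variants are matched to ``scores`` on id and
        filtered to freq > 0.01 (and INFO >= 0.9 when an ``info`` column is
        present).
    scores
        LD score table from :func:`compute_ld_scores`.
    m_variants
        Reference panel variant count M entering ``h2 = slope * M / N``;
        defaults to the number of matched variants.
    """

    def __init__(self, stats: SumStats, scores: pd.DataFrame,
                 m_variants: int | None = None, two_step_cut: float = 30.0,
                 n_blocks: int = 200, maf_min: float = 0.01,
                 weight_iterations: int = 2):
        merged = stats.df.merge(scores[["id", "ldscore"]], on="id", how="inner")
        if "freq" in merged.columns:
            f = merged["freq"].to_numpy(dtype=float)
            maf = np.minimum(f, 1 - f)
            merged = merged[maf > maf_min]
        if "info" in merged.columns:
            merged = merged[merged["info"] >= 0.9]
        merged = merged.dropna(subset=["z", "ldscore"])
        if "n" not in merged.columns or merged["n"].isna().all():
            raise ValueError("sample size column 'n' required")
        if len(merged) < 10 * n_blocks:
            raise ValueError(
                f"only {len(merged)} variants after filtering; need >= {10 * n_blocks} "
                f"for {n_blocks} jackknife blocks"
            )
        if np.ptp(merged["ldscore"].to_numpy()) < 1e-12:
            raise ValueError("constant LD scores: slope unidentifiable")
        self.df = merged.reset_index(drop=True)
        self.m_variants = int(m_variants) if m_variants is not None else len(self.df)
        self.two_step_cut = two_step_cut
        self.n_blocks = n_blocks
        self.weight_iterations = weight_iterations

    def fit(self) -> LDSCResults:
        chi2 = self.df["z"].to_numpy(dtype=float) ** 2
        l = self.df["ldscore"].to_numpy(dtype=float)
        nbar = float(self.df["n"].mean())
        m = self.m_variants
        slope, intercept = _two_step_fit(chi2, l, self.two_step_cut, self.weight_iterations)
        h2 = slope * m / nbar

        # delete-one-block jackknife in genome order
        blocks = np.array_split(np.arange(len(chi2)), self.n_blocks)
        h2_jk = np.empty(self.n_blocks)
        int_jk = np.empty(self.n_blocks)
        for b, idx in enumerate(blocks):
            mask = np.ones(len(chi2), dtype=bool)
            mask[idx] = False
            s_b, i_b = _two_step_fit(chi2[mask], l[mask], self.two_step_cut, self.weight_iterations)
            h2_jk[b] = s_b * m / nbar
            int_jk[b] = i_b
        nb = self.n_blocks
        h2_se = float(np.sqrt((nb - 1) / nb * np.sum((h2_jk - h2_jk.mean()) ** 2)))
        int_se = float(np.sqrt((nb - 1) / nb * np.sum((int_jk - int_jk.mean()) ** 2)))
        return LDSCResults(
            h2_obs=float(h2), h2_obs_se=h2_se, intercept=float(intercept),
            intercept_se=int_se, mean_chi2=float(chi2.mean()),
            m_variants=m, n_bar=nbar, n_blocks=nb,
        )


def liability_transform(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale conversion for case-control data.

    ``h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2)`` where ``z`` is the
    standard-normal density at the ``1-K`` quantile.  Linear in ``h2_obs``.
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise ValueError("K and P must lie in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1 - K))
    return h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)


@dataclass
class RgResult:
    rg: float
    rg_se: float
    gencov: float
    h2_1: float
    h2_2: float
    cross_intercept: float
    n_blocks: int
    defined: bool = True

    def summary(self) -> str:
        if not self.defined:
            return "genetic correlation undefined (non-positive h2 in one trait)"
        return (f"rg = {self.rg:.4f} (se {self.rg_se:.4f}); gencov = {self.gencov:.4f}; "
                f"h2_1 = {self.h2_1:.4f}, h2_2 = {self.h2_2:.4f}; "
                f"cross intercept = {self.cross_intercept:.4f}")


def ldsc_rg(stats1: SumStats, stats2: SumStats, scores: pd.DataFrame,
            m_variants: int | None = None, two_step_cut: float = 30.0,
            n_blocks: int = 200) -> RgResult:
    """Cross-trait LD-score regression genetic correlation.

    The regression of ``Z1 * Z2`` on l estimates the genetic covariance
    (slope * M / sqrt(N1 N2)); its intercept absorbs sample overlap.
    ``rg = gencov / sqrt(h2_1 h2_2)``; flagged undefined when either h2 is
    non-positive.  The jackknife re-runs all three regressions per block.
    """
    a = stats1.df.merge(scores[["id", "ldscore"]], on="id", how="inner")
    b = stats2.indexed()
    a = a[a["id"].isin(b.index)].reset_index(drop=True)
    if len(a) < 10 * n_blocks:
        raise ValueError(f"only {len(a)} shared variants; need >= {10 * n_blocks}")
    b = b.loc[a["id"]]
    z1 = a["z"].to_numpy(dtype=float)
    z2 = b["z"].to_numpy(dtype=float)
    l = a["ldscore"].to_numpy(dtype=float)
    n1 = float(a["n"].mean())
    n2 = float(b["n"].mean())
    m = int(m_variants) if m_variants is not None else len(a)

    def _all_three(mask: np.ndarray) -> tuple[float, float, float, float]:
        s1, _ = _two_step_fit(z1[mask] ** 2, l[mask], two_step_cut)
        s2, _ = _two_step_fit(z2[mask] ** 2, l[mask], two_step_cut)
        sx, ix = _cross_fit(z1[mask] * z2[mask], l[mask], two_step_cut)
        h2a = s1 * m / n1
        h2b = s2 * m / n2
        cov = sx * m / np.sqrt(n1 * n2)
        return h2a, h2b, cov, ix

    full = np.ones(len(l), dtype=bool)
    h2a, h2b, cov, ix = _all_three(full)
    if h2a <= 0 or h2b <= 0:
        return RgResult(np.nan, np.nan, cov, h2a, h2b, ix, n_blocks, defined=False)
    rg = cov / np.sqrt(h2a * h2b)

    blocks = np.array_split(np.arange(len(l)), n_blocks)
    rg_jk = np.empty(n_blocks)
    for k, idx in enumerate(blocks):
        mask = np.ones(len(l), dtype=bool)
        mask[idx] = False
        ha, hb, cv, _ = _all_three(mask)
        rg_jk[k] = cv / np.sqrt(ha * hb) if ha > 0 and hb > 0 else rg
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((rg_jk - rg_jk.mean()) ** 2)))
    return RgResult(float(rg), se, float(cov), float(h2a), float(h2b), float(ix), n_blocks)


def _cross_fit(zz: np.ndarray, l: np.ndarray, cut: float, n_iter: int = 2) -> tuple[float, float]:
    """Weighted two-step regression of Z1*Z2 on l (free intercept kept)."""
    lsafe = np.maximum(l, 1.0)
    slope = zz.mean() / max(l.mean(), 1e-12)
    intercept = 0.0
    for _ in range(n_iter + 1):
        pred = 1.0 + np.abs(slope) * l
        w = 1.0 / (lsafe * pred**2)
        sub = np.abs(zz) < cut
        ws, ls, cs = w[sub], l[sub], zz[sub]
        sw = ws.sum()
        lbar = (ws * ls).sum() / sw
        cbar = (ws * cs).sum() / sw
        varl = (ws * (ls - lbar) ** 2).sum()
        if varl > 0:
            s1 = (ws * (ls - lbar) * (cs - cbar)).sum() / varl
            intercept = cbar - s1 * lbar
        slope = (w * l * (zz - intercept)).sum() / (w * l * l).sum()
    return slope, intercept


def estimate_diff_ztest(est1: float, se1: float, est2: float | None = None,
                        se2: float | None = None, kind: str = "two_sample") -> tuple[float, float]:
    """Z-test comparing two estimates, or one estimate against one.

    ``two_sample``: z = (est1 - est2)/sqrt(se1^2 + se2^2);
    ``vs_one``: z = (est1 - 1)/se1.  Two-sided normal p.
    """
    if kind == "two_sample":
        if est2 is None or se2 is None:
            raise ValueError("two_sample requires est2 and se2")
        if se1 <= 0 or se2 <= 0:
            raise ValueError("standard errors must be positive")
        z = (est1 - est2) / np.sqrt(se1**2 + se2**2)
    elif kind == "vs_one":
        if se1 <= 0:
            raise ValueError("standard error must be positive")
        z = (est1 - 1.0) / se1
    else:
        raise ValueError(f"unknown kind: {kind}")
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def xchr_h2(mean_chi2: float, n: float, m_eff: float) -> tuple[float, bool]:
    """Moment-based h2 = (mean chi2 - 1) * M_eff / N.

    Returns ``(h2, negative_flag)``; negative estimates are reported as-is
    with the flag set (needed for unbiased difference testing).
    """
    if n <= 0 or m_eff <= 0:
        raise ValueError("N and M_eff must be positive")
    h2 = (mean_chi2 - 1.0) * m_eff / n
    return float(h2), bool(h2 < 0)


def m_eff_from_ld_scores(scores: pd.DataFrame) -> float:
    """Effective number of independent loci, M / mean(l), of a reference
    region (used for chromosome X where LD-score regression itself is not
    applied)."""
    l = scores["ldscore"].to_numpy(dtype=float)
    return float(len(l) / l.mean())


@dataclass
class XChromosomeEstimate:
    mean_chi2_male: float
    mean_chi2_female: float
    n_male: float
    n_female: float
    m_eff: float
    h2_male: float
    h2_female: float
    rg: float
    rg_raw: float


def xchr_rg(z_male: np.ndarray, z_female: np.ndarray) -> tuple[float, float]:
    """Cross-sex genetic correlation from matched X-chromosome Z scores.

    ``rg = mean(Zm * Zf) / sqrt((mean chi2_f - 1)(mean chi2_m - 1))`` for
    independent male and female samples.  Returns ``(clipped, raw)`` where
    the clipped value lies in [-1, 1].  Raises when either mean chi2 <= 1.
    """
    zm = np.asarray(z_male, dtype=float)
    zf = np.asarray(z_female, dtype=float)
    if zm.shape != zf.shape:
        raise ValueError("Z vectors must be matched per variant")
    cm = float(np.mean(zm**2))
    cf = float(np.mean(zf**2))
    if cm <= 1 or cf <= 1:
        raise ValueError(f"mean chi2 must exceed 1 in both sexes (male {cm:.3f}, female {cf:.3f})")
    raw = float(np.mean(zm * zf) / np.sqrt((cf - 1) * (cm - 1)))
    return float(np.clip(raw, -1.0, 1.0)), raw


def estimate_xchr(male: SumStats, female: SumStats, m_eff: float) -> XChromosomeEstimate:
    """Sex-specific X-chromosome h2 and cross-sex rg from matched stats."""
    m = male.indexed()
    f = female.indexed()
    common = m.index.intersection(f.index)
    zm = m.loc[common, "z"].to_numpy(dtype=float)
    zf = f.loc[common, "z"].to_numpy(dtype=float)
    nm = float(m.loc[common, "n"].mean())
    nf = float(f.loc[common, "n"].mean())
    cm, cf = float(np.mean(zm**2)), float(np.mean(zf**2))
    h2m, _ = xchr_h2(cm, nm, m_eff)
    h2f, _ = xchr_h2(cf, nf, m_eff)
    rg, raw = xchr_rg(zm, zf)
    return XChromosomeEstimate(cm, cf, nm, nf, m_eff, h2m, h2f, rg, raw)
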
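"""Two-sample summary-statistic Mendelian randomization.

Instruments are genome-wide significant exposure variants pruned to near
independence (r^2 < 0.01 against an LD panel), harmonized so exposure and
outcome effects refer to the same effect allele.  The inverse-variance
weighted (IVW) estimate is the weighted average of per-instrument Wald
ratios ``b_out / b_exp`` with first-order weights ``b_exp^2 / se_out^2``,
equivalent to a zero-intercept weighted regression of outcome on exposure
effects; MR-Egger frees the intercept, which then measures directional
pleiotropy.  Steiger filtering removes instruments explaining more variance
in the outcome than in the exposure (r^2 approximated by
``Z^2 / (Z^2 + N)``), guarding against reverse causation.  Across a screen
of many outcome traits, p-values are controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix
from .meta import _align_sign
from .sumstats import SumStats

__all__ = [
    "HarmonizedInstruments",
    "harmonize",
    "MREstimate",
    "IVW",
    "Egger",
    "steiger_filter",
    "bh_fdr",
]

#: drop reason codes
KEPT = "kept"
PALINDROMIC = "palindromic_ambiguous"
STRAND = "strand_unresolved"
MISSING_OUT = "missing_in_outcome"
STEIGER = "steiger_removed"
LD_PRUNED = "ld_pruned"
WEAK = "below_instrument_threshold"


@dataclass
class HarmonizedInstruments:
    """Aligned instrument table with a drop-reason audit trail.

    ``df`` has one row per exposure-significant variant with columns
    ``id, beta_exp, se_exp, beta_out, se_out, n_exp, n_out, reason``; kept
    instruments have ``reason == "kept"``.
    """

    df: pd.DataFrame
    exposure: str = "exposure"
    outcome: str = "outcome"

    @property
    def kept(self) -> pd.DataFrame:
        return self.df[self.df["reason"] == KEPT].reset_index(drop=True)

    @property
    def n_kept(self) -> int:
        return int((self.df["reason"] == KEPT).sum())

    def drop_counts(self) -> pd.Series:
        return self.df["reason"].value_counts()


def _greedy_ld_prune(d: pd.DataFrame, ld: GenotypeMatrix, r2_max: float) -> set[str]:
    """Ids surviving greedy pruning by ascending exposure p at r2 < r2_max."""
    col_of = {vid: i for i, vid in enumerate(ld.variant_ids)}
    zstd = None
    kept_cols: list[int] = []
    kept_ids: set[str] = set()
    for row in d.sort_values("p_exp", kind="mergesort").itertuples(index=False):
        if row.id not in col_of:
            kept_ids.add(row.id)  # uncovered: keep, cannot assess LD
            continue
        c = col_of[row.id]
        if zstd is None:
            x = ld.dosages.astype(np.float64)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            zstd = (x - x.mean(axis=0)) / sd
        if kept_cols:
            r = (zstd[:, kept_cols].T @ zstd[:, c]) / zstd.shape[0]
            if np.any(r**2 >= r2_max):
                continue
        kept_cols.append(c)
        kept_ids.add(row.id)
    return kept_ids


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    ld: GenotypeMatrix | None = None,
    p_instr: float = 5e-8,
    r2_max: float = 0.01,
    palindromic_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstruments:
    """Select and align instruments for two-sample MR.

    Exposure variants with ``p < p_instr`` are greedily pruned to pairwise
    ``r^2 < r2_max``; outcome effects are aligned to the exposure effect
    allele (sign flip on allele swap, strand complementation attempted).
    Palindromic variants with exposure frequency inside ``palindromic_band``
    are dropped as ambiguous.  Every exclusion carries a reason code; an
    empty instrument set is returned, not raised.
    """
    exp = exposure.df
    sig = exp[exp["p"] < p_instr].copy()
    sig = sig.rename(columns={"p": "p_exp"})
    out_idx = outcome.indexed()
    rows = []
    surviving = _greedy_ld_prune(sig, ld, r2_max) if ld is not None and len(sig) else set(sig["id"])
    for row in sig.itertuples(index=False):
        rec = {
            "id": row.id,
            "beta_exp": row.beta, "se_exp": row.se,
            "beta_out": np.nan, "se_out": np.nan,
            "n_exp": getattr(row, "n", np.nan), "n_out": np.nan,
            "reason": KEPT,
        }
        freq = getattr(row, "freq", np.nan)
        a1, a2 = row.a1.upper(), row.a2.upper()
        from .meta import _is_palindromic

        if row.id not in surviving:
            rec["reason"] = LD_PRUNED
            rows.append(rec)
            continue
        if _is_palindromic(a1, a2) and np.isfinite(freq) and \
                palindromic_band[0] <= freq <= palindromic_band[1]:
            rec["reason"] = PALINDROMIC
            rows.append(rec)
            continue
        if row.id not in out_idx.index:
            rec["reason"] = MISSING_OUT
            rows.append(rec)
            continue
        o = out_idx.loc[row.id]
        sign = _align_sign(str(o["a1"]), str(o["a2"]), a1, a2,
                           o.get("freq", np.nan), freq)
        if sign == 0:
            rec["reason"] = STRAND
            rows.append(rec)
            continue
        rec["beta_out"] = sign * float(o["beta"])
        rec["se_out"] = float(o["se"])
        rec["n_out"] = float(o["n"]) if "n" in o.index else np.nan
        rows.append(rec)
    cols = ["id", "beta_exp", "se_exp", "beta_out", "se_out", "n_exp", "n_out", "reason"]
    return HarmonizedInstruments(pd.DataFrame(rows, columns=cols),
                                 exposure=exposure.trait, outcome=outcome.trait)


@dataclass
class MREstimate:
    """Causal-effect estimate from a summary-statistic MR method."""

    method: str  # ivw | egger
    effect: float
    se: float
    p: float
    n_instruments: int
    q: float
    q_p: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    fdr_q: float | None = None

    def summary(self) -> str:
        lines = [
            f"MR ({self.method.upper()}), {self.n_instruments} instruments",
            f"  causal effect: {self.effect:.4f} (se {self.se:.4f}, p {self.p:.3g})",
            f"  heterogeneity Q: {self.q:.2f} (p {self.q_p:.3g})",
        ]
        if self.method == "egger":
            lines.append(
                f"  intercept: {self.egger_intercept:.4f} "
                f"(se {self.egger_intercept_se:.4f}, p {self.egger_intercept_p:.3g})"
            )
        return "\n".join(lines)


class IVW:
    """Inverse-variance-weighted MR model; ``fit()`` returns :class:`MREstimate`.

    Instruments with a zero exposure effect are excluded with a warning
    (their Wald ratio is undefined).
    """

    def __init__(self, instruments: HarmonizedInstruments):
        k = instruments.kept
        nz = k["beta_exp"] != 0
        if (~nz).any():
            warnings.warn(f"{int((~nz).sum())} instruments with zero exposure effect excluded")
        k = k[nz]
        if len(k) < 1:
            raise ValueError("IVW needs at least one instrument")
        self.data = k.reset_index(drop=True)

    def fit(self) -> MREstimate:
        d = self.data
        wald = d["beta_out"] / d["beta_exp"]
        w = d["beta_exp"] ** 2 / d["se_out"] ** 2
        eff = float(np.sum(w * wald) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        z = eff / se
        p = float(2 * stats.norm.sf(abs(z)))
        q = float(np.sum(w * (wald - eff) ** 2))
        df = len(d) - 1
        q_p = float(stats.chi2.sf(q, df)) if df >= 1 else np.nan
        return MREstimate(method="ivw", effect=eff, se=se, p=p,
                          n_instruments=len(d), q=q, q_p=q_p)


class Egger:
    """MR-Egger regression; the free intercept estimates directional
    pleiotropy.  Requires at least three instruments; exposure effects are
    oriented positive before fitting (the standard Egger convention)."""

    def __init__(self, instruments: HarmonizedInstruments):
        k = instruments.kept
        k = k[k["beta_exp"] != 0]
        if len(k) < 3:
            raise ValueError("MR-Egger needs at least three instruments")
        self.data = k.reset_index(drop=True)

    def fit(self) -> MREstimate:
        d = self.data
        flip = np.sign(d["beta_exp"].to_numpy())
        bx = d["beta_exp"].to_numpy() * flip
        by = d["beta_out"].to_numpy() * flip
        w = 1.0 / d["se_out"].to_numpy() ** 2
        sw = w.sum()
        xbar = (w * bx).sum() / sw
        ybar = (w * by).sum() / sw
        sxx = (w * (bx - xbar) ** 2).sum()
        slope = (w * (bx - xbar) * (by - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = by - intercept - slope * bx
        df = len(d) - 2
        # multiplicative overdispersion, floored at 1 (fixed-effect minimum)
        sigma2 = max((w * resid**2).sum() / df, 1.0)
        se_slope = float(np.sqrt(sigma2 / sxx))
        se_int = float(np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx)))
        p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
        p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
        q = float((w * resid**2).sum())
        q_p = float(stats.chi2.sf(q, df))
        return MREstimate(
            method="egger", effect=float(slope), se=se_slope, p=p_slope,
            n_instruments=len(d), q=q, q_p=q_p,
            egger_intercept=float(intercept), egger_intercept_se=se_int,
            egger_intercept_p=p_int,
        )


def steiger_filter(instruments: HarmonizedInstruments) -> HarmonizedInstruments:
    """Remove instruments whose explained variance on the outcome exceeds
    that on the exposure; ties are kept (documented convention).

    Explained variance is approximated as ``r^2 = Z^2 / (Z^2 + N)`` per
    side; instruments lacking N on either side are kept unchanged.
    """
    df = instruments.df.copy()
    kept = df["reason"] == KEPT
    z_exp = (df["beta_exp"] / df["se_exp"]) ** 2
    z_out = (df["beta_out"] / df["se_out"]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_exp = z_exp / (z_exp + df["n_exp"])
        r2_out = z_out / (z_out + df["n_out"])
    removable = kept & np.isfinite(r2_exp) & np.isfinite(r2_out) & (r2_out > r2_exp)
    df.loc[removable, "reason"] = STEIGER
    return HarmonizedInstruments(df, exposure=instruments.exposure,
                                 outcome=instruments.outcome)


def low_heritability_precheck(stats: SumStats, scores: pd.DataFrame,
                              h2_min: float = 0.025, p_max: float = 0.05,
                              **ldsc_kwargs) -> tuple[bool, float, float]:
    """Screen a trait before MR: exclude when its SNP heritability is below
    ``h2_min`` or not distinguishable from zero (``p > p_max``).

    Returns ``(eligible, h2_obs, h2_p)`` using LD-score regression from the
    heritability module.
    """
    from scipy import stats as spstats

    from .heritability import LDScoreRegression

    res = LDScoreRegression(stats, scores, **ldsc_kwargs).fit()
    z = res.h2_obs / res.h2_obs_se if res.h2_obs_se > 0 else 0.0
    p = float(2 * spstats.norm.sf(abs(z)))
    eligible = res.h2_obs >= h2_min and p <= p_max
    return eligible, res.h2_obs, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
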
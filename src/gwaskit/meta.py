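"""Sample-size-weighted multivariate GWAS meta-analysis.

The combiner is the N-weighted multivariate scheme: with per-cohort Z
scores ``Z_i``, weights ``w_i = sqrt(N_i)`` and a cohort-correlation matrix
``C`` capturing dependence induced by sample overlap,

    Z_meta = sum_i w_i Z_i / sqrt(sum_ij w_i w_j C_ij).

With ``C = I`` this reduces to the classical sample-size-weighted scheme;
fully dependent cohorts (``C_ij = 1``) add no information.  The effective
sample size is reported as ``(sum w)^2 / (w' C w) * mean(N_i)`` over the
cohorts in which the variant is present, which equals ``sum N_i`` for
independent cohorts of equal size.

Between-cohort (and between-sex) effect heterogeneity is tested with
Cochran's Q on inverse-variance weights, and a METAL-style single round of
genomic control is provided (never deflating: lambda <= 1 leaves the
statistics untouched).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats

__all__ = [
    "CohortCorrelationMatrix",
    "estimate_cohort_correlation",
    "NWeightedMeta",
    "MetaResult",
    "cochran_q",
    "genomic_control",
    "sex_heterogeneity",
]

#: null median of a 1-df chi-square
CHI2_NULL_MEDIAN = 0.4549364231195724

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2


@dataclass
class CohortCorrelationMatrix:
    """k x k symmetric PSD matrix with unit diagonal describing cross-cohort
    dependence of the null Z scores (sample overlap)."""

    values: np.ndarray
    method: str = "given"

    def __post_init__(self) -> None:
        c = np.asarray(self.values, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-8):
            raise ValueError("C must have unit diagonal")
        if np.any(np.abs(c) > 1 + 1e-10):
            raise ValueError("|C_ij| must be <= 1")
        eig = np.linalg.eigvalsh(c)
        if eig.min() < -1e-8:
            raise ValueError("C is not positive semi-definite")
        self.values = c

    @classmethod
    def identity(cls, k: int) -> "CohortCorrelationMatrix":
        return cls(np.eye(k), method="identity")


def estimate_cohort_correlation(cohorts: Sequence[SumStats],
                                z_null: float = 1.96) -> CohortCorrelationMatrix:
    """Estimate C off-diagonals as the correlation of Z across variants where
    both cohorts are null (|Z| < ``z_null``), the cross-trait-intercept
    convention for absorbing sample overlap."""
    k = len(cohorts)
    tables = [c.indexed()["z"] for c in cohorts]
    c = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            joined = pd.concat([tables[i], tables[j]], axis=1, join="inner")
            joined = joined.dropna()
            zi, zj = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
            mask = (np.abs(zi) < z_null) & (np.abs(zj) < z_null)
            if mask.sum() >= 10:
                c[i, j] = c[j, i] = np.corrcoef(zi[mask], zj[mask])[0, 1]
    # guard PSD by eigenvalue clipping
    w, v = np.linalg.eigh(c)
    if w.min() < 0:
        c = (v * np.clip(w, 0, None)) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return CohortCorrelationMatrix(c, method="null-z correlation")


@dataclass
class MetaResult:
    """Per-variant meta-analysis output.

    ``df`` columns: id, chrom, pos, a1, a2, freq, z, p, n_eff, per-cohort z
    (``z_<cohort>``), and heterogeneity q/q_df/q_p where computable.
    """

    df: pd.DataFrame
    cohorts: list[str]
    n_dropped_alleles: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def to_sumstats(self, cohort: str = "meta", trait: str = "trait",
                    sex_stratum: str = "pooled") -> SumStats:
        cols = ["id", "chrom", "pos", "a1", "a2", "z", "p"]
        out = self.df[cols].copy()
        if "freq" in self.df.columns:
            out["freq"] = self.df["freq"]
        out["n"] = self.df["n_eff"]
        return SumStats(out, cohort=cohort, trait=trait, sex_stratum=sex_stratum)

    def summary(self) -> str:
        d = self.df
        lines = [
            "N-weighted meta-analysis",
            f"  cohorts: {', '.join(self.cohorts)}",
            f"  variants: {len(d)}",
            f"  dropped (allele mismatch): {self.n_dropped_alleles}",
            f"  genome-wide significant (p < 5e-8): {(d['p'] < 5e-8).sum()}",
            f"  median chi2: {np.nanmedian(d['z'] ** 2):.4f}",
        ]
        return "\n".join(lines)


class NWeightedMeta:
    """Model object combining cohort summary statistics; ``fit()`` returns a
    :class:`MetaResult`.

    Variants are matched across cohorts on id; alleles are aligned to the
    first cohort carrying the variant, flipping the Z sign when effect and
    other allele are swapped and attempting strand complementation
    otherwise.  Palindromic variants are matched on allele-frequency
    proximity (|df| < 0.2) and dropped when ambiguous; unresolvable variants
    are dropped and counted.
    """

    def __init__(self, cohorts: Sequence[SumStats],
                 correlation: CohortCorrelationMatrix | None = None):
        if len(cohorts) < 1:
            raise ValueError("need at least one cohort")
        self.cohorts = list(cohorts)
        k = len(cohorts)
        self.correlation = correlation or CohortCorrelationMatrix.identity(k)
        if self.correlation.values.shape[0] != k:
            raise ValueError("correlation matrix size does not match cohort count")

    def _aligned(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
        """Return (meta variant table, Z matrix, N matrix, n_dropped)."""
        ref: dict[str, tuple] = {}
        order: list[str] = []
        for c in self.cohorts:
            for row in c.df.itertuples(index=False):
                if row.id not in ref:
                    ref[row.id] = row
                    order.append(row.id)
        ids = order
        k = len(self.cohorts)
        z = np.full((len(ids), k), np.nan)
        nn = np.full((len(ids), k), np.nan)
        pos_of = {vid: i for i, vid in enumerate(ids)}
        dropped: set[str] = set()
        for ci, c in enumerate(self.cohorts):
            has_n = "n" in c.df.columns
            has_f = "freq" in c.df.columns
            for row in c.df.itertuples(index=False):
                i = pos_of[row.id]
                r = ref[row.id]
                sign = _align_sign(
                    row.a1, row.a2, r.a1, r.a2,
                    getattr(row, "freq", np.nan) if has_f else np.nan,
                    getattr(r, "freq", np.nan),
                )
                if sign == 0:
                    dropped.add(row.id)
                    continue
                z[i, ci] = sign * row.z
                nn[i, ci] = getattr(row, "n", np.nan) if has_n else np.nan
        keep = np.array([vid not in dropped for vid in ids])
        meta = pd.DataFrame(
            {
                "id": ids,
                "chrom": [ref[v].chrom for v in ids],
                "pos": [ref[v].pos for v in ids],
                "a1": [ref[v].a1 for v in ids],
                "a2": [ref[v].a2 for v in ids],
                "freq": [getattr(ref[v], "freq", np.nan) for v in ids],
            }
        )
        return meta[keep].reset_index(drop=True), z[keep], nn[keep], len(dropped)

    def fit(self) -> MetaResult:
        meta, z, nn, n_drop = self._aligned()
        c = self.correlation.values
        k = len(self.cohorts)
        nn = np.where(np.isnan(nn), 0.0, nn)
        present = ~np.isnan(z) & (nn > 0)
        w = np.sqrt(np.where(present, nn, 0.0))
        num = np.nansum(np.where(present, z, 0.0) * w, axis=1)
        denom2 = np.einsum("vi,ij,vj->v", w, c, w)
        with np.errstate(divide="ignore", invalid="ignore"):
            zm = num / np.sqrt(denom2)
            mean_n = np.where(present.any(axis=1),
                              nn.sum(axis=1) / np.maximum(present.sum(axis=1), 1), np.nan)
            n_eff = (w.sum(axis=1) ** 2) / denom2 * mean_n
        pm = 2 * stats.norm.sf(np.abs(zm))
        pm = np.clip(pm, 5e-324, 1.0)

        out = meta.copy()
        out["z"] = zm
        out["p"] = pm
        out["n_eff"] = n_eff
        for ci, coh in enumerate(self.cohorts):
            out[f"z_{coh.cohort}"] = z[:, ci]

        # Cochran's Q across cohorts where beta and se are available
        betas = np.full_like(z, np.nan)
        ses = np.full_like(z, np.nan)
        for ci, coh in enumerate(self.cohorts):
            if {"beta", "se"} <= set(coh.df.columns):
                idx = coh.indexed()
                common = meta["id"][meta["id"].isin(idx.index)]
                loc = meta["id"].isin(idx.index).to_numpy()
                # aligned sign already applied to z; re-derive beta sign from z
                sub = idx.loc[common]
                betas[loc, ci] = np.sign(z[loc, ci]) * np.abs(sub["beta"].to_numpy())
                ses[loc, ci] = sub["se"].to_numpy()
        qv = np.full(len(out), np.nan)
        qdf = np.full(len(out), np.nan)
        qp = np.full(len(out), np.nan)
        ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
        rows = np.flatnonzero(ok.sum(axis=1) >= 2)
        for i in rows:
            m = ok[i]
            q, df_, p_ = cochran_q(betas[i, m], ses[i, m])
            qv[i], qdf[i], qp[i] = q, df_, p_
        out["q"] = qv
        out["q_df"] = qdf
        out["q_p"] = qp
        return MetaResult(out, cohorts=[c_.cohort for c_ in self.cohorts],
                          n_dropped_alleles=n_drop)


def _align_sign(a1: str, a2: str, ref_a1: str, ref_a2: str,
                freq: float, ref_freq: float) -> int:
    """+1 keep, -1 flip, 0 drop (unresolvable)."""
    a1, a2, ref_a1, ref_a2 = a1.upper(), a2.upper(), ref_a1.upper(), ref_a2.upper()
    if _is_palindromic(a1, a2):
        if not (np.isfinite(freq) and np.isfinite(ref_freq)):
            return 0
        if abs(freq - ref_freq) < 0.2:
            return 1
        if abs((1 - freq) - ref_freq) < 0.2:
            return -1
        return 0
    if (a1, a2) == (ref_a1, ref_a2):
        return 1
    if (a1, a2) == (ref_a2, ref_a1):
        return -1
    c1, c2 = _complement(a1), _complement(a2)
    if (c1, c2) == (ref_a1, ref_a2):
        return 1
    if (c1, c2) == (ref_a2, ref_a1):
        return -1
    return 0


def cochran_q(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q across k effect estimates.

    ``Q = sum_i w_i (b_i - b_bar)^2`` with ``w_i = 1/se_i^2`` and the
    inverse-variance-weighted mean ``b_bar``; p is the upper tail of a
    chi-square with ``k - 1`` degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be 1-D and equally sized")
    if len(betas) < 2:
        raise ValueError("need at least two estimates")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    bbar = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - bbar) ** 2))
    df = len(betas) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


class GenomicControlResult(NamedTuple):
    stats: SumStats
    lambda_gc: float


def genomic_control(stats_in: SumStats) -> GenomicControlResult:
    """One round of genomic control: lambda = median(Z^2) / 0.4549364...

    When lambda > 1 every Z^2 is divided by lambda (standard errors are
    inflated by sqrt(lambda) where present) and p-values recomputed; lambda
    <= 1 leaves the statistics unchanged (no deflation).
    """
    if len(stats_in) < 100:
        raise ValueError("genomic control needs >= 100 variants")
    z = stats_in.df["z"].to_numpy(dtype=float)
    lam = float(np.nanmedian(z**2) / CHI2_NULL_MEDIAN)
    if lam <= 1:
        return GenomicControlResult(stats_in, lam)
    df = stats_in.df.copy()
    df["z"] = z / np.sqrt(lam)
    if "se" in df.columns:
        df["se"] = df["se"] * np.sqrt(lam)
    df["p"] = np.clip(2 * stats.norm.sf(np.abs(df["z"])), 5e-324, 1.0)
    out = SumStats(df, cohort=stats_in.cohort, trait=stats_in.trait,
                   sex_stratum=stats_in.sex_stratum)
    return GenomicControlResult(out, lam)


def sex_heterogeneity(lead_ids: Sequence[str], male: SumStats, female: SumStats,
                      n_tests: int = 221) -> tuple[pd.DataFrame, list[str]]:
    """Between-sex effect heterogeneity at lead variants.

    Per variant, Cochran's Q (df = 1) between the male and female effect
    estimates; a variant is flagged when the upper-tail p is at or below the
    Bonferroni threshold ``0.05 / n_tests``.  Variants missing in either
    stratum are excluded and returned separately.
    """
    m = male.indexed()
    f = female.indexed()
    rows = []
    excluded = []
    thresh = 0.05 / n_tests
    for vid in lead_ids:
        if vid not in m.index or vid not in f.index:
            excluded.append(vid)
            continue
        rm, rf = m.loc[vid], f.loc[vid]
        sign = _align_sign(rf["a1"], rf["a2"], rm["a1"], rm["a2"],
                           rf.get("freq", np.nan), rm.get("freq", np.nan))
        if sign == 0:
            excluded.append(vid)
            continue
        q, df_, p = cochran_q(
            np.array([rm["beta"], sign * rf["beta"]]),
            np.array([rm["se"], rf["se"]]),
        )
        rows.append({"id": vid, "beta_male": rm["beta"], "beta_female": sign * rf["beta"],
                     "se_male": rm["se"], "se_female": rf["se"],
                     "q": q, "p": p, "flagged": p <= thresh})
    cols = ["id", "beta_male", "beta_female", "se_male", "se_female", "q", "p", "flagged"]
    return pd.DataFrame(rows, columns=cols), excluded
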
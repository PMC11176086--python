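"""Risk-locus definition: LD clumping, locus merging, and conditional
stepwise selection of independent lead signals.

Clumping follows the PLINK convention: index variants are chosen greedily by
ascending p-value among variants below ``p1``; variants below ``p2`` within
the distance window and in LD (r^2 above the threshold) with the index are
absorbed.  Clumps on one chromosome are merged into a genomic risk locus
when their member spans overlap or lie closer than the merge gap, with
transitive closure.  Conditionally independent lead signals are found by a
forward stepwise joint model on summary statistics (GCTA-COJO style) using
the standardized-genotype approximation: marginal standardized effects are
``z_j / sqrt(N_j)`` and joint effects come from solving against the LD
correlation matrix of the selected set, subject to a colinearity cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .meta import MetaResult

__all__ = ["Clump", "Locus", "LeadSignal", "ld_clump", "merge_loci", "stepwise_joint_selection"]


@dataclass
class Clump:
    index_id: str
    index_p: float
    chrom: str
    start: int  # min bp over members (1-based inclusive)
    end: int    # max bp over members
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    index_id: str
    member_clump_ids: list[str] = field(default_factory=list)


@dataclass
class LeadSignal:
    variant_id: str
    joint_beta: float
    joint_se: float
    joint_p: float
    entry_order: int


def _ld_corr(ld: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    x = ld.dosages[:, cols].astype(np.float64)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xc = (x - x.mean(axis=0)) / sd
    return (xc.T @ xc) / x.shape[0]


def ld_clump(
    meta: MetaResult | pd.DataFrame,
    ld: GenotypeMatrix,
    r2_thresh: float = 0.05,
    kb: float = 500.0,
    p1: float = 5e-8,
    p2: float = 1e-5,
) -> list[Clump]:
    """Greedy LD clumping of a meta-analysis result against an LD panel.

    Variants absent from the panel cannot serve as indices or members; their
    count is reported via a warning.  Ties in p are broken by chromosome
    then position.
    """
    df = meta.df if isinstance(meta, MetaResult) else meta
    col_of = {vid: i for i, vid in enumerate(ld.variant_ids)}
    covered = df["id"].map(col_of).notna()
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        warnings.warn(f"{n_uncovered} variants not covered by the LD reference")
    d = df[covered].copy()
    d["ldcol"] = d["id"].map(col_of).astype(int)
    d = d.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    assigned: set[str] = set()
    clumps: list[Clump] = []
    cand = d[d["p"] < p2].reset_index(drop=True)
    zstd = None
    for row in d[d["p"] < p1].itertuples(index=False):
        if row.id in assigned:
            continue
        members = [row.id]
        positions = [row.pos]
        assigned.add(row.id)
        near = cand[
            (cand["chrom"] == row.chrom)
            & (np.abs(cand["pos"] - row.pos) <= kb * 1000)
            & (~cand["id"].isin(assigned))
        ]
        if len(near):
            if zstd is None:
                x = ld.dosages.astype(np.float64)
                sd = x.std(axis=0)
                sd[sd == 0] = 1.0
                zstd = (x - x.mean(axis=0)) / sd
            gi = zstd[:, row.ldcol]
            r = (zstd[:, near["ldcol"].to_numpy()].T @ gi) / len(gi)
            take = near[r**2 > r2_thresh]
            for m in take.itertuples(index=False):
                members.append(m.id)
                positions.append(m.pos)
                assigned.add(m.id)
        clumps.append(
            Clump(index_id=row.id, index_p=float(row.p), chrom=str(row.chrom),
                  start=int(min(positions)), end=int(max(positions)),
                  member_ids=members)
        )
    return clumps


def merge_loci(clumps: list[Clump], gap_bp: int = 500_000) -> list[Locus]:
    """Merge clumps into disjoint risk loci.

    Two clumps merge when they sit on the same chromosome and their member
    spans overlap or are separated by less than ``gap_bp``; merging is
    applied transitively.  The locus index variant is the most significant
    clump index among the merged members.
    """
    loci: list[Locus] = []
    by_chrom: dict[str, list[Clump]] = {}
    for c in clumps:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda c: (c.start, c.end))
        current: list[Clump] = []
        for c in group:
            if current and c.start - max(x.end for x in current) < gap_bp:
                current.append(c)
            else:
                if current:
                    loci.append(_make_locus(chrom, current))
                current = [c]
        if current:
            loci.append(_make_locus(chrom, current))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def _make_locus(chrom: str, group: list[Clump]) -> Locus:
    best = min(group, key=lambda c: c.index_p)
    return Locus(chrom=chrom, start=min(c.start for c in group),
                 end=max(c.end for c in group), index_id=best.index_id,
                 member_clump_ids=[c.index_id for c in group])


def write_loci_bed(loci: list[Locus], path) -> None:
    """BED-like TSV: CHR, START-1, END, INDEX_ID (0-based half-open spans)."""
    rows = [{"CHR": l.chrom, "START": l.start - 1, "END": l.end, "INDEX_ID": l.index_id}
            for l in loci]
    pd.DataFrame(rows, columns=["CHR", "START", "END", "INDEX_ID"]).to_csv(
        path, sep="\t", index=False, header=False)


def stepwise_joint_selection(
    meta: MetaResult | pd.DataFrame,
    ld: GenotypeMatrix,
    p_thresh: float = 5e-8,
    window_mb: float = 10.0,
    colinearity: float = 0.9,
) -> list[LeadSignal]:
    """Forward stepwise selection of conditionally independent signals.

    At each step, the candidate with the smallest conditional p given the
    selected set enters if that p is below ``p_thresh`` and its r^2 with
    every selected variant within ``window_mb`` is below ``colinearity``.
    Joint effects are on the standardized-genotype scale: the joint
    estimates solve ``R b = z / sqrt(N)`` over the selected set, with
    ``se_j = sqrt([R^-1]_jj / N_j)``.  Variants whose LD submatrix is
    numerically singular are skipped with a warning.
    """
    df = meta.df if isinstance(meta, MetaResult) else meta
    col_of = {vid: i for i, vid in enumerate(ld.variant_ids)}
    d = df[df["id"].isin(col_of)].reset_index(drop=True)
    if not len(d):
        return []
    cols = d["id"].map(col_of).to_numpy(dtype=int)
    z = d["z"].to_numpy(dtype=float)
    ncol = "n_eff" if "n_eff" in d.columns else "n"
    n = d[ncol].to_numpy(dtype=float) if ncol in d.columns else np.full(len(d), np.nan)
    if not np.isfinite(n).all():
        raise ValueError("per-variant sample sizes required for joint selection")
    pos = d["pos"].to_numpy(dtype=float)
    chrom = d["chrom"].astype(str).to_numpy()

    x = ld.dosages[:, cols].astype(np.float64)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    zstd = (x - x.mean(axis=0)) / sd
    nref = zstd.shape[0]

    m = len(d)
    selected: list[int] = []
    excluded: set[int] = set()
    window_bp = window_mb * 1e6

    def in_window(j: int, sel: list[int]) -> np.ndarray:
        return np.array([(chrom[j] == chrom[s]) and (abs(pos[j] - pos[s]) <= window_bp)
                         for s in sel])

    while True:
        if not selected:
            cond_z = z.copy()
        else:
            r_ss = (zstd[:, selected].T @ zstd[:, selected]) / nref
            try:
                r_inv = np.linalg.inv(r_ss)
            except np.linalg.LinAlgError:
                warnings.warn("singular LD submatrix among selected variants; stopping")
                break
            r_all = (zstd.T @ zstd[:, selected]) / nref  # m x |S|
            zs = z[selected]
            num = z - r_all @ (r_inv @ zs)
            den = 1.0 - np.einsum("ij,jk,ik->i", r_all, r_inv, r_all)
            with np.errstate(invalid="ignore", divide="ignore"):
                cond_z = np.where(den > 1e-8, num / np.sqrt(np.maximum(den, 1e-12)), 0.0)
        cond_p = 2 * stats.norm.sf(np.abs(cond_z))
        cond_p[list(selected)] = 1.0
        cond_p[list(excluded)] = 1.0
        order = np.argsort(cond_p, kind="mergesort")
        entered = False
        for j in order:
            if cond_p[j] >= p_thresh:
                break
            if selected:
                mask = in_window(int(j), selected)
                if mask.any():
                    r_js = (zstd[:, selected].T @ zstd[:, j]) / nref
                    if np.any((r_js[mask] ** 2) >= colinearity):
                        excluded.add(int(j))
                        continue
            selected.append(int(j))
            entered = True
            break
        if not entered:
            break

    if not selected:
        return []
    r_ss = (zstd[:, selected].T @ zstd[:, selected]) / nref
    try:
        r_inv = np.linalg.inv(r_ss)
    except np.linalg.LinAlgError:
        r_inv = np.linalg.pinv(r_ss)
        warnings.warn("singular LD submatrix in final joint fit; pseudo-inverse used")
    bmarg = z[selected] / np.sqrt(n[selected])
    bjoint = r_inv @ bmarg
    sejoint = np.sqrt(np.diag(r_inv) / n[selected])
    zjoint = bjoint / sejoint
    pjoint = 2 * stats.norm.sf(np.abs(zjoint))
    return [
        LeadSignal(variant_id=d["id"].iloc[s], joint_beta=float(bjoint[k]),
                   joint_se=float(sejoint[k]), joint_p=float(pjoint[k]), entry_order=k)
        for k, s in enumerate(selected)
    ]
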
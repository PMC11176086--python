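"""Synthetic genotype panels with block-structured linkage disequilibrium.

The simulator produces an individuals x variants dosage matrix organised in
independent LD blocks.  Within a block, haplotype alleles follow a two-state
Markov "copying" chain: the allele at variant ``j+1`` is copied from variant
``j`` with probability ``rho`` and otherwise redrawn at the block allele
frequency.  The chain is stationary, so allele frequencies are preserved
exactly and the genotype correlation between variants ``j`` and ``j+k``
within a block is ``rho**k`` -- a first-order autoregressive LD profile on
the genotype scale itself (not merely on a latent scale).  Blocks are
generated independently, so cross-block LD is zero in expectation.

Diploid autosomal dosages are the sum of two independent haplotypes; on
chromosome X male dosages are coded 0/2 (single haplotype, no dosage
compensation) while female dosages remain 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "simulate_ld_reference", "write_genotype_fixture", "read_genotype_fixture"]

#: variant metadata columns, in file order
VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "freq"]

MALE = "male"
FEMALE = "female"


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus per-variant metadata and per-individual sex.

    Parameters
    ----------
    dosages
        ``(n_individuals, m_variants)`` array with entries in ``[0, 2]``.
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2, freq``; positions
        are 1-based and strictly increasing within a chromosome.
    sex
        Length-``n`` array of ``"male"`` / ``"female"`` codes.
    subpop
        Optional length-``n`` integer subpopulation labels (0/1) when the
        panel was simulated with allele-frequency drift between two
        subpopulations; zeros otherwise.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sex: np.ndarray = field(default=None)  # type: ignore[assignment]
    subpop: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError(f"variant table has {len(self.variants)} rows for {m} dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")
        if self.sex is None:
            self.sex = np.full(n, FEMALE, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        if self.sex.shape[0] != n:
            raise ValueError("sex vector length mismatch")
        if self.subpop is None:
            self.subpop = np.zeros(n, dtype=int)
        self.subpop = np.asarray(self.subpop, dtype=int)
        if self.subpop.shape[0] != n:
            raise ValueError("subpop vector length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, unit variance); monomorphic
        columns are returned as zeros."""
        x = self.dosages.astype(np.float64)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return (x - mu) / sd

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            sex=self.sex,
            subpop=self.subpop,
        )

    def ld_r2(self, i: int, j: int) -> float:
        """Squared Pearson correlation between dosage columns i and j."""
        gi, gj = self.dosages[:, i], self.dosages[:, j]
        si, sj = gi.std(), gj.std()
        if si == 0 or sj == 0:
            return np.nan
        r = np.corrcoef(gi, gj)[0, 1]
        return float(r * r)


def _haplotype_block(rng: np.random.Generator, n: int, size: int, rho: float, maf: float) -> np.ndarray:
    """Stationary Markov chain of alleles for one haplotype block."""
    alleles = np.empty((n, size), dtype=np.float32)
    alleles[:, 0] = rng.random(n) < maf
    for j in range(1, size):
        fresh = rng.random(n) < maf
        copy = rng.random(n) < rho
        alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
    return alleles


def simulate_ld_reference(
    n: int,
    blocks: int,
    block_size: int,
    rho: float | tuple[float, float],
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
    chrom: str = "1",
    spacing_bp: int = 5_000,
    block_gap_bp: int = 100_000,
    sex: np.ndarray | None = None,
    female_fraction: float = 0.5,
    fst: float = 0.0,
) -> GenotypeMatrix:
    """Simulate a block-diagonal LD panel of diploid dosages.

    Parameters
    ----------
    n
        Number of individuals (>= 2).
    blocks, block_size
        Number of independent LD blocks and variants per block.
    rho
        Adjacent-variant genotype correlation within a block, in ``[0, 1)``.
        LD decays as ``rho**distance`` (AR(1) profile).  A ``(lo, hi)``
        tuple draws one rho per block uniformly, producing a spread of LD
        scores across blocks (needed to identify LD-score regressions).
    maf_range
        ``(lo, hi)`` interval from which one minor-allele frequency per block
        is drawn uniformly.  Must be non-empty and inside ``(0, 0.5]``.
    chrom
        Chromosome label; ``"X"`` switches males to 0/2 hemizygous coding.
    spacing_bp, block_gap_bp
        Base-pair spacing between adjacent variants and extra gap between
        blocks.
    sex
        Optional explicit per-individual sex codes; otherwise assigned
        randomly with ``female_fraction``.
    fst
        When positive, individuals are split into two equal subpopulations
        whose block allele frequencies drift apart with between-population
        variance ``fst * p * (1 - p)`` (Balding-Nichols scale); used to
        emulate uncorrected population stratification.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rho_lo, rho_hi = (rho, rho) if np.isscalar(rho) else rho
    if not (0 <= rho_lo <= rho_hi < 1):
        raise ValueError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"empty or invalid maf_range: {maf_range}")

    rng = np.random.default_rng(seed)
    if sex is None:
        sex = np.where(rng.random(n) < female_fraction, FEMALE, MALE)
    sex = np.asarray(sex, dtype=object)
    is_male = sex == MALE
    x_coding = str(chrom).upper() == "X"
    subpop = np.zeros(n, dtype=int)
    if fst > 0:
        subpop[n // 2:] = 1

    m = blocks * block_size
    dos = np.empty((n, m), dtype=np.float32)
    freqs = np.empty(m)
    pos = np.empty(m, dtype=np.int64)
    cur = 1
    for b in range(blocks):
        maf = rng.uniform(lo, hi)
        rho_b = rng.uniform(rho_lo, rho_hi) if rho_hi > rho_lo else rho_lo
        if fst > 0:
            drift = rng.normal(0.0, np.sqrt(fst * maf * (1 - maf)))
            maf_by_pop = (np.clip(maf + drift, 0.01, 0.99),
                          np.clip(maf - drift, 0.01, 0.99))
        else:
            maf_by_pop = (maf, maf)
        sl = slice(b * block_size, (b + 1) * block_size)
        block = np.empty((n, block_size), dtype=np.float32)
        for pop_label, maf_p in enumerate(maf_by_pop):
            rows = subpop == pop_label
            n_p = int(rows.sum())
            if n_p == 0:
                continue
            hap1 = _haplotype_block(rng, n_p, block_size, rho_b, maf_p)
            hap2 = _haplotype_block(rng, n_p, block_size, rho_b, maf_p)
            sub_block = hap1 + hap2
            if x_coding:
                male_rows = is_male[rows]
                sub_block[male_rows] = 2.0 * hap1[male_rows]
            block[rows] = sub_block
        dos[:, sl] = block
        freqs[sl] = maf
        for k in range(block_size):
            pos[b * block_size + k] = cur
            cur += spacing_bp
        cur += block_gap_bp

    alleles = np.array(["A", "C", "G", "T"])
    a1 = rng.choice(alleles, size=m)
    # pick a2 different from a1
    a2 = np.array([rng.choice(alleles[alleles != x]) for x in a1])
    variants = pd.DataFrame(
        {
            "id": [f"rs{chrom}_{i + 1}" for i in range(m)],
            "chrom": str(chrom),
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "freq": freqs,
        }
    )
    return GenotypeMatrix(dosages=dos, variants=variants, sex=sex, subpop=subpop)


def write_genotype_fixture(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write dosages as a whitespace matrix plus a TSV variant sidecar.

    Files written: ``<prefix>.dosage`` (n rows, m columns) and
    ``<prefix>.variants.tsv`` (ID, CHR, BP, A1, A2, FRQ).
    """
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".dosage"), g.dosages, fmt="%.3f")
    tab = g.variants.rename(
        columns={"id": "ID", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2", "freq": "FRQ"}
    )
    tab.to_csv(prefix.with_suffix(".variants.tsv"), sep="\t", index=False)


def read_genotype_fixture(prefix: str | Path, sex: np.ndarray | None = None) -> GenotypeMatrix:
    prefix = Path(prefix)
    dos = np.loadtxt(prefix.with_suffix(".dosage"), ndmin=2)
    tab = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t", dtype={"CHR": str})
    tab = tab.rename(columns={"ID": "id", "CHR": "chrom", "BP": "pos", "A1": "a1", "A2": "a2", "FRQ": "freq"})
    return GenotypeMatrix(dosages=dos, variants=tab, sex=sex)
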
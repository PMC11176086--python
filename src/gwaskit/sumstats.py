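"""Per-variant GWAS summary statistics: container, validation and TSV I/O.

The on-disk dialect is a tab-separated table with upper-case headers
(ID, CHR, BP, A1, A2, FRQ, BETA, SE, Z, P, N, N_CASE, N_CONTROL).  ID, CHR,
BP, A1, A2 and P are required together with at least one of BETA or Z and
one of SE or N; the remaining columns are optional and survive a lossless
round trip when present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SumStats", "read_sumstats", "write_sumstats"]

# internal column name -> file header
_FILE_COLUMNS = {
    "id": "ID",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "freq": "FRQ",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "p": "P",
    "n": "N",
    "n_case": "N_CASE",
    "n_control": "N_CONTROL",
}
_REQUIRED = ["ID", "CHR", "BP", "A1", "A2", "P"]

POOLED, MALE_STRATUM, FEMALE_STRATUM = "pooled", "male", "female"


@dataclass
class SumStats:
    """One cohort's association results.

    ``df`` holds one row per variant with columns from
    ``id, chrom, pos, a1, a2, freq, beta, se, z, p, n, n_case, n_control``
    (a subset is allowed as long as ``z`` or ``beta``/``se`` is present).
    """

    df: pd.DataFrame
    cohort: str = "cohort"
    trait: str = "trait"
    sex_stratum: str = POOLED

    def __post_init__(self) -> None:
        df = self.df
        if "id" not in df.columns:
            raise ValueError("SumStats requires an 'id' column")
        if "z" not in df.columns and not {"beta", "se"} <= set(df.columns):
            raise ValueError("SumStats requires 'z' or both 'beta' and 'se'")
        if "z" not in df.columns:
            df = df.copy()
            df["z"] = df["beta"] / df["se"]
            self.df = df
        self.validate()

    def validate(self) -> None:
        df = self.df
        if {"beta", "se", "z"} <= set(df.columns):
            ok = np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
            ratio = df.loc[ok, "beta"] / df.loc[ok, "se"]
            z = df.loc[ok, "z"]
            scale = np.maximum(np.abs(z), 1e-12)
            if len(z) and np.nanmax(np.abs(ratio - z) / scale) > 1e-6:
                raise ValueError("z inconsistent with beta/se (relative tolerance 1e-6)")
        if "p" in df.columns:
            p = df["p"].to_numpy(dtype=float)
            fin = np.isfinite(p)
            if np.any((p[fin] <= 0) | (p[fin] > 1)):
                raise ValueError("p values must lie in (0, 1]")
        if "freq" in df.columns:
            f = df["freq"].to_numpy(dtype=float)
            fin = np.isfinite(f)
            if np.any((f[fin] <= 0) | (f[fin] >= 1)):
                raise ValueError("freq values must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chi2(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float) ** 2

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("id", drop=False)


def read_sumstats(path: str | Path, cohort: str = "cohort", trait: str = "trait",
                  sex_stratum: str = POOLED) -> SumStats:
    """Read the TSV dialect; rejects missing required columns by name and
    non-numeric P entries by line number.  Scientific-notation p-values such
    as ``1e-300`` are parsed as floats without underflow to zero."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip().upper() for c in raw.columns]
    for col in _REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"missing required column: {col}")
    if "BETA" not in raw.columns and "Z" not in raw.columns:
        raise ValueError("missing required column: BETA or Z")
    if "SE" not in raw.columns and "N" not in raw.columns:
        raise ValueError("missing required column: SE or N")

    p = pd.to_numeric(raw["P"], errors="coerce")
    bad = np.flatnonzero(p.isna().to_numpy() & raw["P"].notna().to_numpy())
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"non-numeric P value at line {bad[0] + 2}: {raw['P'].iloc[bad[0]]!r}")

    out = pd.DataFrame({"id": raw["ID"], "chrom": raw["CHR"].astype(str),
                        "pos": pd.to_numeric(raw["BP"]).astype(np.int64),
                        "a1": raw["A1"].str.upper(), "a2": raw["A2"].str.upper(),
                        "p": p})
    for name, col in [("freq", "FRQ"), ("beta", "BETA"), ("se", "SE"), ("z", "Z")]:
        if col in raw.columns:
            out[name] = pd.to_numeric(raw[col], errors="coerce")
    for name, col in [("n", "N"), ("n_case", "N_CASE"), ("n_control", "N_CONTROL")]:
        if col in raw.columns:
            out[name] = pd.to_numeric(raw[col], errors="coerce")
    return SumStats(out, cohort=cohort, trait=trait, sex_stratum=sex_stratum)


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    cols = [c for c in _FILE_COLUMNS if c in stats.df.columns]
    tab = stats.df[cols].rename(columns=_FILE_COLUMNS)
    tab.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
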
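"""Instrumental-variable selection for two-sample MR.

The selection cascade mirrors standard practice for metabolite GWAS
instruments: a genome-wide-suggestive p-value threshold (default 1e-5),
greedy LD clumping (r^2 < 0.1 within a 500 kb window), a minor-allele
frequency floor (0.01), removal of SNPs known to associate with confounders,
and instrument-strength metrics (per-SNP F statistic and variance explained).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sumstats import SummaryStatTable


@dataclasses.dataclass
class LDMatrix:
    """Pairwise correlation (r, not r^2) between variants plus their positions.

    Stands in for an external LD reference panel; symmetric with unit
    diagonal.  ``pos`` maps variant_id -> (chrom, pos).
    """

    snp_ids: list[str]
    r: np.ndarray
    pos: dict[str, tuple[str, int]]

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal not 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)


def read_ld_matrix(matrix_path: str | Path, pos_path: str | Path) -> LDMatrix:
    """Read a square delimited r matrix (header row/col of variant IDs) and a
    3-column position map (variant_id, chrom, pos)."""
    mat = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
    pos_df = pd.read_csv(pos_path, sep=None, engine="python")
    pos = {
        str(row.variant_id): (str(row.chrom), int(row.pos)) for row in pos_df.itertuples()
    }
    snp_ids = [str(c) for c in mat.columns]
    return LDMatrix(snp_ids, mat.to_numpy(dtype=float), pos)


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, pos_path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        [(s, ld.pos[s][0], ld.pos[s][1]) for s in ld.snp_ids],
        columns=["variant_id", "chrom", "pos"],
    ).to_csv(pos_path, sep="\t", index=False)


def read_blacklist(path: str | Path) -> set[str]:
    """One variant_id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


@dataclasses.dataclass
class InstrumentSet:
    """Selected instruments for one exposure with strength metrics."""

    exposure_id: str
    snp_ids: list[str]
    f_stats: np.ndarray
    r2: np.ndarray
    total_r2: float

    def __post_init__(self):
        self.f_stats = np.asarray(self.f_stats, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any(self.f_stats < 0):
            raise ValueError("negative F statistic")
        if not (0 <= self.total_r2 < 1):
            raise ValueError("total_r2 outside [0,1)")

    @property
    def min_f(self) -> float:
        return float(self.f_stats.min()) if len(self.f_stats) else float("nan")

    @property
    def weak_flags(self) -> np.ndarray:
        """Instruments with F <= 10 are flagged weak, not dropped."""
        return self.f_stats <= 10.0


def filter_pvalue(
    table: SummaryStatTable, threshold: float = 1e-5
) -> SummaryStatTable:
    """Keep records with pval strictly below ``threshold`` (order preserved)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0,1]")
    return SummaryStatTable(
        table.trait_id, table.trait_role, table.df[table.df["pval"] < threshold]
    )


def filter_maf(
    table: SummaryStatTable, maf_min: float = 0.01, drop_log: list | None = None
) -> SummaryStatTable:
    """Keep records with min(eaf, 1-eaf) >= maf_min.

    Records with missing eaf are retained and logged — frequency is optional
    in many sources and is not used for inference downstream.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    eaf = table.df["eaf"]
    maf = np.minimum(eaf, 1 - eaf)
    missing = eaf.isna()
    keep = missing | (maf >= maf_min)
    if drop_log is not None:
        for snp in table.df.loc[missing, "variant_id"]:
            drop_log.append((snp, "eaf_missing_retained"))
    return SummaryStatTable(table.trait_id, table.trait_role, table.df[keep])


def apply_blacklist(
    table: SummaryStatTable,
    blacklist: Iterable[str],
    drop_log: list | None = None,
) -> SummaryStatTable:
    """Remove confounder-associated SNPs listed in ``blacklist``."""
    bl = set(blacklist)
    hit = table.df["variant_id"].isin(bl)
    if drop_log is not None:
        for snp in table.df.loc[hit, "variant_id"]:
            drop_log.append((snp, "confounder"))
    return SummaryStatTable(table.trait_id, table.trait_role, table.df[~hit])


def greedy_clump(
    table: SummaryStatTable,
    ld: LDMatrix,
    r2_max: float = 0.1,
    window_kb: int = 500,
    drop_log: list | None = None,
) -> SummaryStatTable:
    """Greedy LD clumping: repeatedly keep the most significant remaining SNP
    and discard SNPs correlated with it (r^2 >= ``r2_max``) on the same
    chromosome within +/- ``window_kb`` (inclusive).

    Ties on p-value break by smaller genomic position, then lexicographic
    variant_id.  SNPs absent from the LD panel are removed and logged.
    Output rows are ordered by selection (most significant index SNP first).
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0,1]")
    df = table.df
    in_panel = df["variant_id"].map(lambda s: s in ld).astype(bool)
    if drop_log is not None:
        for snp in df.loc[~in_panel, "variant_id"]:
            drop_log.append((snp, "absent_from_ld_panel"))
    df = df[in_panel]

    remaining: dict[str, tuple[float, str, int]] = {}
    for row in df.itertuples():
        chrom, pos = ld.pos[row.variant_id]
        remaining[row.variant_id] = (row.pval, chrom, pos)

    window_bp = window_kb * 1000
    selected: list[str] = []
    while remaining:
        index_snp = min(
            remaining, key=lambda s: (remaining[s][0], remaining[s][2], s)
        )
        selected.append(index_snp)
        _, ichrom, ipos = remaining.pop(index_snp)
        for snp in list(remaining):
            _, chrom, pos = remaining[snp]
            if chrom == ichrom and abs(pos - ipos) <= window_bp:
                if ld.r2(index_snp, snp) >= r2_max:
                    del remaining[snp]
                    if drop_log is not None:
                        drop_log.append((snp, f"clumped_with_{index_snp}"))

    out = df.set_index("variant_id").loc[selected].reset_index()
    return SummaryStatTable(table.trait_id, table.trait_role, out)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, beta^2 / se^2."""
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be > 0")
    return np.asarray(beta, dtype=float) ** 2 / np.asarray(se, dtype=float) ** 2


def variance_explained(beta, se, n) -> float:
    """Per-SNP trait variance explained from beta, se and sample size.

    Uses the t-statistic identity r^2 = t^2 / (t^2 + n - 2), the standard
    conversion from a regression coefficient's test statistic.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("sample size must exceed 2")
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be > 0")
    t2 = (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2
    return t2 / (t2 + n - 2)


def select_instruments(
    table: SummaryStatTable,
    ld: LDMatrix,
    blacklist: Iterable[str] = (),
    iv_pval: float = 1e-5,
    clump_r2: float = 0.1,
    clump_window_kb: int = 500,
    maf_min: float = 0.01,
    drop_log: list | None = None,
) -> tuple[SummaryStatTable, InstrumentSet]:
    """Full selection cascade: p-value filter, LD clumping, MAF filter,
    confounder blacklist; returns the surviving table plus strength metrics."""
    t = filter_pvalue(table, iv_pval)
    t = greedy_clump(t, ld, clump_r2, clump_window_kb, drop_log=drop_log)
    t = filter_maf(t, maf_min, drop_log=drop_log)
    t = apply_blacklist(t, blacklist, drop_log=drop_log)
    f = f_statistic(t.df["beta"].to_numpy(), t.df["se"].to_numpy())
    r2 = variance_explained(
        t.df["beta"].to_numpy(), t.df["se"].to_numpy(), t.df["n"].to_numpy()
    )
    total = float(min(np.sum(r2), 1 - 1e-12))
    inst = InstrumentSet(table.trait_id, t.variant_ids, f, r2, total)
    return t, inst
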
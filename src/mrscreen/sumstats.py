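"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR works from per-variant association tables: for each SNP an
effect size (beta) on the trait per copy of the *effect allele*, its standard
error, p-value and sample size.  Before any estimator can run, the exposure
and outcome tables must be aligned so that both betas refer to the same
allele.  Variants whose alleles cannot be reconciled (different loci coded
with incompatible allele pairs) and palindromic variants (A/T or G/C, whose
strand cannot be resolved from alleles alone) are excluded outright.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical internal column order
STANDARD_FIELDS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: default header names follow the GWAS-SSF convention; the internal name is
#: accepted as a fallback so round-tripped files need no mapping.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

#: closed vocabulary of harmonization exclusion reasons
EXCLUSION_REASONS = frozenset(
    {"palindromic", "incompatible_alleles", "missing_in_outcome", "duplicate"}
)


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics input."""


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One per-variant association record.

    ``beta`` is the additive effect per effect-allele copy in standardized
    trait units; ``se`` its standard error.  ``eaf`` may be missing (NaN).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: bad effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: bad other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: p-value outside (0,1]")
        if not np.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf outside [0,1]")
        if self.n < 2:
            raise ValueError(f"{self.variant_id}: sample size < 2")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be 1-based")


class SummaryStatTable:
    """Ordered, variant_id-unique collection of association records for one trait.

    Thin wrapper over a :class:`pandas.DataFrame` with the standard columns;
    row order is preserved through filtering and round-trip I/O.
    """

    def __init__(self, trait_id: str, trait_role: str, df: pd.DataFrame):
        if trait_role not in ("exposure", "outcome"):
            raise ValueError("trait_role must be 'exposure' or 'outcome'")
        if df["variant_id"].duplicated().any():
            dupes = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant_id(s): {dupes[:5]}")
        self.trait_id = trait_id
        self.trait_role = trait_role
        self.df = df.reset_index(drop=True)[STANDARD_FIELDS]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SummaryStatTable):
            return NotImplemented
        return (
            self.trait_id == other.trait_id
            and self.trait_role == other.trait_role
            and self.df.equals(other.df)
        )

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def records(self) -> list[VariantRecord]:
        return [VariantRecord(**row) for row in self.df.to_dict("records")]

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatTable":
        """Rows whose variant_id is in ``variant_ids``, original order kept."""
        keep = set(variant_ids)
        return SummaryStatTable(
            self.trait_id, self.trait_role, self.df[self.df["variant_id"].isin(keep)]
        )

    @classmethod
    def from_records(
        cls, trait_id: str, trait_role: str, records: Sequence[VariantRecord]
    ) -> "SummaryStatTable":
        for rec in records:
            rec.validate()
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=STANDARD_FIELDS)
        df = df.astype({"pos": np.int64, "n": np.int64, "chrom": str})
        return cls(trait_id, trait_role, df)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_role: str = "exposure",
    drop_log: list | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a :class:`SummaryStatTable`.

    The delimiter (tab or comma) is auto-detected from the header line and
    ``.gz`` files are read transparently.  ``column_map`` maps standard field
    names to file column names, overriding the GWAS-SSF defaults; the internal
    field name itself is always accepted.  Rows violating record invariants
    are dropped and logged to ``drop_log`` as ``(variant_id, reason)``;
    duplicate variant_ids keep the row with the smallest p-value (first
    occurrence on ties).
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"summary-statistics file not found: {path}")
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            raise SumstatsError(f"empty summary-statistics file: {path}")
        delim = _detect_delimiter(header)
        fh.seek(0)
        raw = pd.read_csv(fh, sep=delim, dtype={0: str})

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    cols: dict[str, str] = {}
    for field in STANDARD_FIELDS:
        if cmap[field] in raw.columns:
            cols[field] = cmap[field]
        elif field in raw.columns:
            cols[field] = field
        elif field == "eaf":
            continue  # eaf is optional
        else:
            raise SumstatsError(f"{path}: required column for '{field}' not found")

    df = pd.DataFrame({f: raw[c] for f, c in cols.items()})
    if "eaf" not in df.columns:
        df["eaf"] = np.nan

    log = drop_log if drop_log is not None else []
    kept = []
    for row in df.to_dict("records"):
        try:
            rec = VariantRecord(
                variant_id=str(row["variant_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=float(row["eaf"]) if not pd.isna(row["eaf"]) else float("nan"),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pval=float(row["pval"]),
                n=int(row["n"]),
            )
            rec.validate()
        except (ValueError, TypeError, KeyError) as exc:
            log.append((str(row.get("variant_id", "?")), f"invalid_record: {exc}"))
            continue
        kept.append(rec)

    # duplicate resolution: smallest p-value wins, first occurrence on ties
    best: dict[str, VariantRecord] = {}
    order: list[str] = []
    for rec in kept:
        prev = best.get(rec.variant_id)
        if prev is None:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        elif rec.pval < prev.pval:
            log.append((prev.variant_id, "duplicate"))
            best[rec.variant_id] = rec
        else:
            log.append((rec.variant_id, "duplicate"))
    records = [best[v] for v in order]
    if not records:
        raise SumstatsError(f"{path}: no valid summary-statistics rows")
    return SummaryStatTable.from_records(trait_id or path.stem, trait_role, records)


def write_sumstats(table: SummaryStatTable, path: str | Path) -> None:
    """Write a table as TSV with internal field names (round-trip safe)."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def classify_allele_pair(
    exp_ea: str, exp_oa: str, out_ea: str, out_oa: str, variant_id: str = "?"
) -> str:
    """Classify an exposure/outcome allele pairing.

    Returns one of ``aligned``, ``flipped``, ``palindromic``, ``incompatible``.
    Palindromic ({A,T} or {G,C} exposure pair) takes precedence regardless of
    the outcome coding, since strand cannot be resolved from alleles alone.
    """
    for a in (exp_ea, exp_oa, out_ea, out_oa):
        if a not in VALID_ALLELES:
            raise ValueError(f"{variant_id}: non-ACGT allele {a!r}")
    pair = {exp_ea, exp_oa}
    if pair in ({"A", "T"}, {"G", "C"}):
        return "palindromic"
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "aligned"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "flipped"
    return "incompatible"


@dataclasses.dataclass
class HarmonizedSet:
    """Index-aligned exposure/outcome effects for one analysis pair.

    ``gamma``/``se_x`` are the SNP-exposure effects and SEs, ``Gamma``/``se_y``
    the SNP-outcome effects and SEs, all referring to the exposure effect
    allele after harmonization.
    """

    exposure_id: str
    outcome_id: str
    snp_ids: list[str]
    gamma: np.ndarray
    se_x: np.ndarray
    Gamma: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray
    n_exp: int
    n_out: int
    exclusion_log: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        k = len(self.snp_ids)
        for name in ("gamma", "se_x", "Gamma", "se_y", "eaf"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"harmonized array '{name}' length != {k}")
        if k < 1:
            raise ValueError("no harmonizable instruments")
        for _, reason in self.exclusion_log:
            if reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {reason!r}")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def drop(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        """New set without the named SNPs (no exclusion log carried)."""
        out = set(snp_ids)
        keep = [i for i, s in enumerate(self.snp_ids) if s not in out]
        if not keep:
            raise ValueError("no instruments remain")
        idx = np.asarray(keep, dtype=int)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            [self.snp_ids[i] for i in keep],
            self.gamma[idx],
            self.se_x[idx],
            self.Gamma[idx],
            self.se_y[idx],
            self.eaf[idx],
            self.n_exp,
            self.n_out,
        )


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    snp_ids: Sequence[str] | None = None,
) -> HarmonizedSet:
    """Align exposure and outcome effects to the exposure effect allele.

    For flipped outcome records the outcome beta is negated and its eaf
    complemented; palindromic and incompatible variants are excluded (logged),
    as are exposure SNPs absent from the outcome table.
    """
    if snp_ids is None:
        snp_ids = exposure.variant_ids
    exp_idx = exposure.df.set_index("variant_id")
    missing = set(snp_ids) - set(exp_idx.index)
    if missing:
        raise ValueError(f"snp_ids not in exposure table: {sorted(missing)[:5]}")
    out_idx = outcome.df.set_index("variant_id")

    log: list[tuple[str, str]] = []
    rows = []
    for snp in snp_ids:
        e = exp_idx.loc[snp]
        if snp not in out_idx.index:
            log.append((snp, "missing_in_outcome"))
            continue
        o = out_idx.loc[snp]
        cls = classify_allele_pair(
            e.effect_allele, e.other_allele, o.effect_allele, o.other_allele, snp
        )
        if cls == "palindromic":
            log.append((snp, "palindromic"))
            continue
        if cls == "incompatible":
            log.append((snp, "incompatible_alleles"))
            continue
        Gamma = o.beta if cls == "aligned" else -o.beta
        rows.append((snp, e.beta, e.se, Gamma, o.se, e.eaf))

    if not rows:
        raise ValueError("no harmonizable instruments")
    snp_list, gamma, se_x, Gamma, se_y, eaf = map(list, zip(*rows))
    n_exp = int(exposure.df["n"].max())
    n_out = int(outcome.df["n"].max())
    return HarmonizedSet(
        exposure.trait_id,
        outcome.trait_id,
        snp_list,
        np.array(gamma),
        np.array(se_x),
        np.array(Gamma),
        np.array(se_y),
        np.array(eaf),
        n_exp,
        n_out,
        exclusion_log=log,
    )


def write_exclusion_log(log: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(log, columns=["variant_id", "reason"]).to_csv(path, sep="\t", index=False)
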
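"""Exposure-by-outcome MR screen with multiple-testing classification.

Runs the full pipeline for every exposure-outcome pair — instrument
selection, harmonization, the estimator suite, PRESSO where enough
instruments survive — then classifies each pair against the Bonferroni
threshold (family-wise alpha over the number of exposures screened) and a
suggestive tier (nominal p < alpha without surviving correction).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
import pandas as pd
import yaml

from .instruments import LDMatrix, read_blacklist, read_ld_matrix, select_instruments
from .model import MRModel
from .sumstats import harmonize, read_sumstats

logger = logging.getLogger("mrscreen")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m for family-wise level ``alpha`` over ``m`` tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


@dataclasses.dataclass
class ScreenConfig:
    """Everything needed to run a screen, mirroring the YAML config layout."""

    exposures: list[dict]  # [{"id": ..., "path": ...}, ...]
    outcomes: list[dict]
    ld_matrix_path: str
    ld_pos_path: str
    blacklist_path: str | None = None
    iv_pval: float = 1e-5
    clump_r2: float = 0.1
    clump_window_kb: int = 500
    maf_min: float = 0.01
    alpha: float = 0.05
    n_tests_for_bonferroni: int | None = None  # default: number of exposures
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.iv_pval <= 1):
            raise ValueError("iv_pval outside (0,1]")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 outside (0,1]")
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min outside [0,0.5]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha outside (0,1)")
        if self.n_tests_for_bonferroni is not None and self.n_tests_for_bonferroni < 1:
            raise ValueError("n_tests_for_bonferroni must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, **overrides) -> "ScreenConfig":
        """Config pointing at a :func:`mrscreen.simulate.simulate_screen` bundle."""
        d = Path(bundle_dir)
        exposures = [
            {"id": p.stem.replace("exposure_", ""), "path": str(p)}
            for p in sorted(d.glob("exposure_*.tsv"))
        ]
        return cls(
            exposures=exposures,
            outcomes=[{"id": "outcome", "path": str(d / "outcome.tsv")}],
            ld_matrix_path=str(d / "ld_matrix.tsv"),
            ld_pos_path=str(d / "ld_pos.tsv"),
            blacklist_path=str(d / "blacklist.txt"),
            **overrides,
        )


def classify_tier(pval: float, alpha: float, m: int) -> str:
    """Partition a p-value into bonferroni / suggestive / null tiers."""
    thr = bonferroni_threshold(alpha, m)
    if pval < thr:
        return "bonferroni"
    if pval < alpha:
        return "suggestive"
    return "null"


def _sensitivity_consistent(fit) -> bool:
    """Egger, weighted-median and (when present) PRESSO-corrected estimates
    all share the IVW sign with nominal p < 0.05."""
    checks = []
    for res in (fit.egger, fit.weighted_median):
        if res is not None:
            checks.append(res)
    if fit.presso is not None and fit.presso.corrected_estimate is not None:
        checks.append(fit.presso.corrected_estimate)
    if not checks:
        return False
    sign = 1.0 if fit.ivw.beta > 0 else -1.0
    return all(r.beta * sign > 0 and r.pval < 0.05 for r in checks)


def run_screen(
    config: ScreenConfig,
    out_dir: str | Path | None = None,
    ld: LDMatrix | None = None,
) -> pd.DataFrame:
    """Run the full screen; returns one row per exposure-outcome pair.

    Pairs that fail a stage (e.g., no instruments survive selection) are kept
    with a ``status`` explaining why rather than silently dropped.  With
    ``out_dir`` set, writes ``screen_results.tsv``, ``instruments.tsv`` and
    ``exclusions.tsv``.
    """
    t0 = time.time()
    if ld is None:
        ld = read_ld_matrix(config.ld_matrix_path, config.ld_pos_path)
    blacklist = (
        read_blacklist(config.blacklist_path)
        if config.blacklist_path and Path(config.blacklist_path).exists()
        else set()
    )
    outcomes = [
        (o["id"], read_sumstats(o["path"], trait_id=o["id"], trait_role="outcome"))
        for o in config.outcomes
    ]
    m_tests = config.n_tests_for_bonferroni or len(config.exposures)

    rows = []
    exclusions: list[tuple[str, str, str]] = []  # (pair, variant_id, reason)
    instrument_rows = []
    for i, exp_spec in enumerate(config.exposures):
        exp_id = exp_spec["id"]
        exposure = read_sumstats(exp_spec["path"], trait_id=exp_id, trait_role="exposure")
        drop_log: list = []
        selected, inst = select_instruments(
            exposure,
            ld,
            blacklist,
            iv_pval=config.iv_pval,
            clump_r2=config.clump_r2,
            clump_window_kb=config.clump_window_kb,
            maf_min=config.maf_min,
            drop_log=drop_log,
        )
        logger.info(
            "stage=select pair=%s in=%d out=%d", exp_id, len(exposure), len(selected)
        )
        for snp, f, r2 in zip(inst.snp_ids, inst.f_stats, inst.r2):
            instrument_rows.append(
                {"exposure_id": exp_id, "variant_id": snp, "f_stat": f,
                 "r2": r2, "weak_flag": f <= 10}
            )
        for j, (out_id, outcome) in enumerate(outcomes):
            pair = f"{exp_id}|{out_id}"
            # fixed arithmetic so identical config+seed reproduce exactly
            pair_seed = config.seed * 100_003 + i * 211 + j
            base = {"exposure_id": exp_id, "outcome_id": out_id}
            if len(selected) == 0:
                rows.append({**base, "status": "no_instruments_selected"})
                continue
            try:
                h = harmonize(selected, outcome)
            except ValueError as exc:
                rows.append({**base, "status": f"harmonization_failed: {exc}"})
                continue
            for snp, reason in h.exclusion_log:
                exclusions.append((pair, snp, reason))
            for snp, reason in drop_log:
                exclusions.append((pair, snp, reason))
            t_pair = time.time()
            fit = MRModel(h).fit(
                n_boot=config.n_boot,
                presso_n_sim=config.presso_n_sim,
                seed=pair_seed % (2**31),
            )
            row = fit.to_row()
            row.update(base)
            row["status"] = "ok"
            row["significance_tier"] = classify_tier(
                fit.ivw.pval, config.alpha, m_tests
            )
            row["sensitivity_consistent"] = _sensitivity_consistent(fit)
            rows.append(row)
            logger.info(
                "stage=fit pair=%s k=%d tier=%s dt=%.2fs",
                pair, h.k, row["significance_tier"], time.time() - t_pair,
            )

    result = pd.DataFrame(rows)
    if result.empty or (result["status"] != "ok").all():
        raise RuntimeError("screen produced zero successful pairs")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.to_csv(out_dir / "screen_results.tsv", sep="\t", index=False)
        pd.DataFrame(
            exclusions, columns=["pair", "variant_id", "reason"]
        ).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
        pd.DataFrame(instrument_rows).to_csv(
            out_dir / "instruments.tsv", sep="\t", index=False
        )
    logger.info("screen finished: %d pairs in %.1fs", len(result), time.time() - t0)
    return result
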
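"""Model/results interface over the estimator suite.

`MRModel` is constructed from a harmonized instrument set (or directly from
exposure/outcome summary-statistic tables); `fit()` runs every applicable
estimator and diagnostic and returns an `MRFit` results object with the
estimates, their uncertainties, heterogeneity/pleiotropy/directionality
diagnostics, a `summary()` table and diagnostic plots.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .presso import PressoResult, run_presso
from .sumstats import HarmonizedSet, SummaryStatTable, harmonize


class MRModel:
    """Two-sample summary-data MR model for one exposure-outcome pair.

    Parameters
    ----------
    harmonized
        Index-aligned per-SNP effects (see :func:`mrscreen.sumstats.harmonize`).
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.data = harmonized

    @classmethod
    def from_tables(
        cls,
        exposure: SummaryStatTable,
        outcome: SummaryStatTable,
        snp_ids: Sequence[str] | None = None,
    ) -> "MRModel":
        """Harmonize the two tables and build the model."""
        return cls(harmonize(exposure, outcome, snp_ids))

    @property
    def k(self) -> int:
        return self.data.k

    def fit(
        self,
        ivw_model: str = "auto",
        n_boot: int = 1000,
        presso_n_sim: int = 1000,
        presso: bool = True,
        seed: int = 0,
    ) -> "MRFit":
        """Run the full estimator suite.

        Estimators needing more instruments than available are skipped and
        recorded in ``notes`` (Egger/weighted-median/leave-one-out need k>=3,
        PRESSO needs k>=4).
        """
        h = self.data
        notes: list[str] = []
        ivw_res, het = est.ivw(h, model=ivw_model)
        steiger_res = est.steiger(h)

        egger_res = pleio = None
        wm_res = None
        loo = None
        if h.k >= 3:
            egger_res, pleio = est.egger(h)
            wm_res = est.weighted_median(h, n_boot=n_boot, seed=seed)
            loo = est.leave_one_out(h)
        else:
            notes.append(f"k={h.k}: Egger/weighted-median/leave-one-out skipped")

        presso_res: PressoResult | None = None
        if presso and h.k >= 4:
            presso_res = run_presso(h, n_sim=presso_n_sim, seed=seed)
        elif presso:
            notes.append(f"k={h.k}: PRESSO skipped (needs >=4)")

        pleiotropy_suspect = bool(pleio is not None and pleio.pval < 0.05)
        if pleiotropy_suspect:
            notes.append("pleiotropy-suspect (Egger intercept p < 0.05)")
        return MRFit(
            model=self,
            ivw=ivw_res,
            heterogeneity=het,
            egger=egger_res,
            egger_intercept=pleio,
            weighted_median=wm_res,
            leave_one_out=loo,
            steiger=steiger_res,
            presso=presso_res,
            pleiotropy_suspect=pleiotropy_suspect,
            notes=notes,
            seed=seed,
        )


@dataclasses.dataclass
class MRFit:
    """Fitted results for one exposure-outcome pair."""

    model: MRModel
    ivw: est.MRResult
    heterogeneity: est.HeterogeneityStats
    egger: est.MRResult | None
    egger_intercept: est.PleiotropyStats | None
    weighted_median: est.MRResult | None
    leave_one_out: pd.DataFrame | None
    steiger: est.SteigerResult
    presso: PressoResult | None
    pleiotropy_suspect: bool
    notes: list[str]
    seed: int

    @property
    def data(self) -> HarmonizedSet:
        return self.model.data

    def results(self) -> list[est.MRResult]:
        out = [self.ivw]
        for r in (self.egger, self.weighted_median):
            if r is not None:
                out.append(r)
        if self.presso is not None and self.presso.corrected_estimate is not None:
            c = self.presso.corrected_estimate
            out.append(dataclasses.replace(c, method="presso_corrected"))
        return out

    def to_row(self) -> dict:
        """Flatten the suite into one wide record (screen TSV row)."""
        h = self.data
        row: dict = {
            "exposure_id": h.exposure_id,
            "outcome_id": h.outcome_id,
            "k": h.k,
            "Q": self.heterogeneity.Q,
            "Q_pval": self.heterogeneity.pval,
            "i2": self.heterogeneity.i2,
            "steiger_direction": self.steiger.direction_correct,
            "steiger_pval": self.steiger.pval,
            "pleiotropy_suspect": self.pleiotropy_suspect,
            "model_note": "; ".join([self.ivw.model_note] + self.notes),
        }
        for res in self.results():
            prefix = "ivw" if res.method.startswith("ivw") or res.method == "wald_ratio" else res.method
            for f in ("beta", "se", "ci_low", "ci_high", "pval"):
                row[f"{prefix}_{f}"] = getattr(res, f)
            if prefix == "ivw":
                row["ivw_method"] = res.method
        if self.egger_intercept is not None:
            row["egger_intercept"] = self.egger_intercept.intercept
            row["egger_intercept_pval"] = self.egger_intercept.pval
        if self.presso is not None:
            row["presso_global_pval"] = self.presso.global_pval
            row["presso_n_outliers"] = len(self.presso.outlier_ids)
            if self.presso.distortion_pval is not None:
                row["presso_distortion_pval"] = self.presso.distortion_pval
        return row

    def summary(self) -> str:
        """Human-readable summary of estimates and diagnostics."""
        h = self.data
        lines = [
            f"Two-sample MR: {h.exposure_id} -> {h.outcome_id}   "
            f"(k={h.k}, n_exp={h.n_exp}, n_out={h.n_out})",
            "-" * 78,
            f"{'method':<18}{'beta':>10}{'se':>10}{'95% CI':>24}{'p':>12}",
        ]
        for res in self.results():
            ci = f"({res.ci_low: .4f}, {res.ci_high: .4f})"
            lines.append(
                f"{res.method:<18}{res.beta:>10.4f}{res.se:>10.4f}{ci:>24}{res.pval:>12.3g}"
            )
        het = self.heterogeneity
        lines.append("-" * 78)
        lines.append(
            f"Cochran Q = {het.Q:.3f} (df={het.df}, p={het.pval:.3g}), I2 = {het.i2:.1f}%"
        )
        if self.egger_intercept is not None:
            pi = self.egger_intercept
            lines.append(
                f"Egger intercept = {pi.intercept:.4g} (se {pi.se:.3g}, p = {pi.pval:.3g})"
            )
        st = self.steiger
        lines.append(
            f"Steiger: r2_exp = {st.r2_exposure:.4g}, r2_out = {st.r2_outcome:.4g}, "
            f"direction {'exposure->outcome' if st.direction_correct else 'REVERSED'} "
            f"(p = {st.pval:.3g})"
        )
        if self.presso is not None:
            pr = self.presso
            lines.append(
                f"PRESSO: global p = {pr.global_pval:.4g} (floor {pr.pval_floor:.3g}), "
                f"outliers = {len(pr.outlier_ids)}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    # ---------------------------------------------------------------- plots
    def plot_scatter(self, ax=None):
        """Per-SNP effects with fitted IVW (and Egger, if run) slopes."""
        import matplotlib.pyplot as plt

        h = self.data
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        sign = np.where(h.gamma < 0, -1.0, 1.0)
        x, y = h.gamma * sign, h.Gamma * sign
        ax.errorbar(x, y, xerr=h.se_x, yerr=h.se_y, fmt="o", ms=4, alpha=0.7, lw=0.8)
        xs = np.linspace(0, x.max() * 1.05, 20)
        ax.plot(xs, self.ivw.beta * xs, label=f"IVW ({self.ivw.beta:.3f})")
        if self.egger is not None and self.egger_intercept is not None:
            ax.plot(
                xs,
                self.egger_intercept.intercept + self.egger.beta * xs,
                "--",
                label=f"Egger ({self.egger.beta:.3f})",
            )
        ax.set_xlabel("SNP effect on exposure")
        ax.set_ylabel("SNP effect on outcome")
        ax.set_title(f"{h.exposure_id} -> {h.outcome_id}")
        ax.legend(fontsize=8)
        return ax

    def plot_funnel(self, ax=None):
        """Funnel plot: Wald ratio vs. its precision."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ratios, ses = est.wald_ratios(self.data)
        ax.scatter(ratios, 1.0 / ses, s=16, alpha=0.7)
        ax.axvline(self.ivw.beta, color="k", lw=1)
        ax.set_xlabel("Wald ratio")
        ax.set_ylabel("1 / SE")
        return ax

    def plot_leave_one_out(self, ax=None):
        """Forest of leave-one-out IVW estimates."""
        import matplotlib.pyplot as plt

        if self.leave_one_out is None:
            raise ValueError("leave-one-out not available (k < 3)")
        loo = self.leave_one_out
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.25 * len(loo) + 1.5))
        ys = np.arange(len(loo))
        ax.errorbar(
            loo["beta"], ys,
            xerr=[loo["beta"] - loo["ci_low"], loo["ci_high"] - loo["beta"]],
            fmt="o", ms=3, lw=0.8,
        )
        ax.axvline(self.ivw.beta, color="k", lw=1)
        ax.set_yticks(ys)
        ax.set_yticklabels(loo["dropped_snp"], fontsize=6)
        ax.set_xlabel("IVW estimate without SNP")
        return ax
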
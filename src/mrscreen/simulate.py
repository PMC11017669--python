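"""Synthetic GWAS summary statistics with known causal ground truth.

The generator realizes the standard two-sample MR data model on standardized
scales: per-SNP exposure effects gamma_j with sampling SE ~ 1/sqrt(n_exp),
outcome effects Gamma_j = beta * gamma_j + alpha_j with SE ~ 1/sqrt(n_out),
where alpha_j is a horizontal-pleiotropy term (absent, balanced around zero,
or directional).  Defaults emulate a metabolite-GWAS exposure (n ~ 7,824,
instruments explaining a few percent of variance so F statistics sit above
10) against a biobank-scale outcome (n ~ 460,000).

Optional structure exercises every pipeline stage: LD blocks of correlated
companions around each index SNP (so clumping has work to do), palindromic
allele pairs (excluded at harmonization), confounder-associated SNPs (for
the blacklist), and outlier SNPs whose outcome effect is displaced by a
stated multiple of its SE (for PRESSO).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import LDMatrix, write_ld_matrix
from .sumstats import HarmonizedSet, SummaryStatTable, VariantRecord, write_sumstats

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclasses.dataclass
class ScenarioTruth:
    """Ground-truth record for one simulated exposure-outcome pair.

    ``outlier_ids`` are indices (into the index-SNP list) of instruments whose
    outcome effect is displaced by ``outlier_displacement`` outcome-SEs.
    ``ld_block_spec`` entries ``(block_size, within_r)`` attach
    ``block_size - 1`` correlated companions to successive index SNPs.
    ``noise_scale`` multiplies the sampling noise only (the reported SE
    columns stay nominal); 0 gives the noiseless limit.  ``noise_scale_x`` /
    ``noise_scale_y`` override it per side: estimator calibration studies set
    ``noise_scale_x=0`` to study the estimators under their own sampling
    theory, which treats instrument-exposure effects as known (NOME).
    """

    causal_beta: float = 0.0
    k_snps: int = 30
    n_exp: int = 7824
    n_out: int = 460000
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violated
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_fraction: float = 1.0
    orient_positive: bool = False
    outlier_ids: list[int] = dataclasses.field(default_factory=list)
    outlier_displacement: float = 8.0
    ld_block_spec: list[tuple[int, float]] = dataclasses.field(default_factory=list)
    palindromic_fraction: float = 0.0
    confounder_snp_ids: list[str] = dataclasses.field(default_factory=list)
    target_r2: float = 0.08
    noise_scale: float = 1.0
    noise_scale_x: float | None = None
    noise_scale_y: float | None = None
    seed: int = 0
    exposure_id: str = "metabolite"
    outcome_id: str = "trait"
    snp_prefix: str = "rs"
    # realized ground truth, populated by the generator on its returned copy
    true_gamma: np.ndarray | None = None
    true_Gamma: np.ndarray | None = None
    outlier_snp_ids: list[str] | None = None

    def __post_init__(self):
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if self.n_exp < 10 or self.n_out < 10:
            raise ValueError("sample sizes must be >= 10")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ValueError("pleiotropy_fraction must be in [0,1]")
        if not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must be in (0,1)")
        if self.pleiotropy_mode not in (
            "none", "balanced", "directional", "inside_violated"
        ):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if any(i < 0 or i >= self.k_snps for i in self.outlier_ids):
            raise ValueError("outlier index out of range")

    @property
    def nsx(self) -> float:
        return self.noise_scale if self.noise_scale_x is None else self.noise_scale_x

    @property
    def nsy(self) -> float:
        return self.noise_scale if self.noise_scale_y is None else self.noise_scale_y


def _true_gammas(truth: ScenarioTruth, rng: np.random.Generator) -> np.ndarray:
    """True index-SNP exposure effects: random signs, magnitudes spread over
    [0.7, 1.3] of the common scale, rescaled so the summed variance explained
    equals ``target_r2`` (per-SNP r^2 ~ gamma^2 on standardized scales)."""
    mag = rng.uniform(0.7, 1.3, size=truth.k_snps)
    if truth.orient_positive:
        sign = np.ones(truth.k_snps)
    else:
        sign = rng.choice([-1.0, 1.0], size=truth.k_snps)
    g = mag * sign
    scale = np.sqrt(truth.target_r2 / np.sum(g**2))
    if truth.target_r2 >= 1.0:
        raise ValueError("variance-explained target unreachable")
    return g * scale


def _pleiotropy(truth: ScenarioTruth, gamma: np.ndarray, rng: np.random.Generator):
    if truth.pleiotropy_mode == "none":
        return np.zeros_like(gamma)
    z = rng.normal(size=gamma.size)
    if truth.pleiotropy_mode == "balanced":
        alpha = truth.pleiotropy_sd * z
    elif truth.pleiotropy_mode == "directional":
        alpha = truth.pleiotropy_mean + truth.pleiotropy_sd * z
    else:
        # inside_violated: direct effects correlated with instrument strength
        g_std = gamma / np.std(gamma) if np.std(gamma) > 0 else gamma
        alpha = truth.pleiotropy_mean + truth.pleiotropy_sd * (0.8 * g_std + 0.6 * z)
    if truth.pleiotropy_fraction < 1.0:
        m = int(round(truth.pleiotropy_fraction * gamma.size))
        mask = np.zeros(gamma.size)
        mask[rng.choice(gamma.size, size=m, replace=False)] = 1.0
        alpha = alpha * mask
    return alpha


def simulate_harmonized(truth: ScenarioTruth) -> tuple[HarmonizedSet, ScenarioTruth]:
    """Fast path: generate an already-harmonized instrument set (independent
    index SNPs only — no LD companions, palindromes or allele bookkeeping).

    This is the generator used by estimator calibration studies, where the
    selection and harmonization stages are not under study.
    """
    rng = np.random.default_rng(truth.seed)
    gamma = _true_gammas(truth, rng)
    alpha = _pleiotropy(truth, gamma, rng)
    se_x = np.full(truth.k_snps, 1.0 / np.sqrt(truth.n_exp))
    se_y = np.full(truth.k_snps, 1.0 / np.sqrt(truth.n_out))
    Gamma = truth.causal_beta * gamma + alpha
    for i in truth.outlier_ids:
        Gamma[i] += truth.outlier_displacement * se_y[i]
    g_obs = gamma + truth.nsx * se_x * rng.normal(size=truth.k_snps)
    G_obs = Gamma + truth.nsy * se_y * rng.normal(size=truth.k_snps)
    snp_ids = [f"{truth.snp_prefix}{i + 1:05d}" for i in range(truth.k_snps)]
    eaf = rng.uniform(0.01, 0.5, size=truth.k_snps)
    h = HarmonizedSet(
        truth.exposure_id, truth.outcome_id, snp_ids,
        g_obs, se_x, G_obs, se_y, eaf, truth.n_exp, truth.n_out,
    )
    realized = dataclasses.replace(
        truth,
        true_gamma=gamma,
        true_Gamma=Gamma,
        outlier_snp_ids=[snp_ids[i] for i in truth.outlier_ids],
    )
    return h, realized


def _block_chol(size: int, r: float) -> np.ndarray:
    """Cholesky factor of an equicorrelated block."""
    m = np.full((size, size), r)
    np.fill_diagonal(m, 1.0)
    return np.linalg.cholesky(m)


def simulate_pair(
    truth: ScenarioTruth,
) -> tuple[SummaryStatTable, SummaryStatTable, LDMatrix, ScenarioTruth]:
    """Generate a full exposure/outcome summary-statistics pair with LD.

    Index SNPs are spaced 1 Mb apart; LD-block companions sit within 50 kb of
    their index SNP with equicorrelated r (their true effects and sampling
    noise share that correlation, so the index SNP usually carries the
    smallest p-value and survives clumping).  Palindromic allele pairs are
    assigned to a random ``palindromic_fraction`` of SNPs.
    """
    rng = np.random.default_rng(truth.seed)
    gamma_idx = _true_gammas(truth, rng)
    alpha_idx = _pleiotropy(truth, gamma_idx, rng)
    Gamma_idx = truth.causal_beta * gamma_idx + alpha_idx

    # expand index SNPs into LD blocks
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    gamma_true: list[float] = []
    Gamma_true: list[float] = []
    block_members: list[list[int]] = []
    block_r: list[float] = []
    se_y_scalar = 1.0 / np.sqrt(truth.n_out)
    for j in range(truth.k_snps):
        size, r = (1, 0.0)
        if j < len(truth.ld_block_spec):
            size, r = truth.ld_block_spec[j]
        base_pos = 1_000_000 * (j + 1)
        chrom = str(j % 22 + 1)
        members = []
        for m in range(size):
            idx = len(snp_ids)
            members.append(idx)
            snp_ids.append(f"{truth.snp_prefix}{j + 1:03d}{m:02d}")
            chroms.append(chrom)
            positions.append(base_pos + m * 10_000)
            corr = 1.0 if m == 0 else r
            g = gamma_idx[j] * corr
            gamma_true.append(g)
            G = truth.causal_beta * g + alpha_idx[j] * corr
            if j in truth.outlier_ids:
                G += truth.outlier_displacement * se_y_scalar * corr
            Gamma_true.append(G)
        block_members.append(members)
        block_r.append(r)

    k_total = len(snp_ids)
    gamma_true = np.asarray(gamma_true)
    Gamma_true = np.asarray(Gamma_true)
    se_x = np.full(k_total, 1.0 / np.sqrt(truth.n_exp))
    se_y = np.full(k_total, se_y_scalar)

    # block-correlated sampling noise
    eps_x = np.empty(k_total)
    eps_y = np.empty(k_total)
    for members, r in zip(block_members, block_r):
        L = _block_chol(len(members), r) if len(members) > 1 else np.ones((1, 1))
        eps_x[members] = L @ rng.normal(size=len(members))
        eps_y[members] = L @ rng.normal(size=len(members))
    g_obs = gamma_true + truth.nsx * se_x * eps_x
    G_obs = Gamma_true + truth.nsy * se_y * eps_y

    eaf = rng.uniform(0.01, 0.5, size=k_total)
    n_pal = int(round(truth.palindromic_fraction * k_total))
    pal_idx = set(rng.choice(k_total, size=n_pal, replace=False)) if n_pal else set()
    alleles = []
    for i in range(k_total):
        pool = _PALINDROMIC_PAIRS if i in pal_idx else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])

    def _table(trait_id, role, betas, ses, n):
        z = betas / ses
        from scipy import stats as _st

        pvals = np.clip(2 * _st.norm.sf(np.abs(z)), 1e-300, 1.0)
        recs = [
            VariantRecord(
                snp_ids[i], chroms[i], positions[i],
                alleles[i][0], alleles[i][1],
                float(eaf[i]), float(betas[i]), float(ses[i]),
                float(pvals[i]), n,
            )
            for i in range(k_total)
        ]
        return SummaryStatTable.from_records(trait_id, role, recs)

    exposure = _table(truth.exposure_id, "exposure", g_obs, se_x, truth.n_exp)
    outcome = _table(truth.outcome_id, "outcome", G_obs, se_y, truth.n_out)

    r_mat = np.eye(k_total)
    for members, r in zip(block_members, block_r):
        for a in members:
            for b in members:
                if a != b:
                    r_mat[a, b] = r
    ld = LDMatrix(
        list(snp_ids), r_mat,
        {snp_ids[i]: (chroms[i], positions[i]) for i in range(k_total)},
    )
    realized = dataclasses.replace(
        truth,
        true_gamma=gamma_true,
        true_Gamma=Gamma_true,
        outlier_snp_ids=[snp_ids[block_members[j][0]] for j in truth.outlier_ids],
    )
    return exposure, outcome, ld, realized


def simulate_screen(
    out_dir: str | Path,
    n_exposures: int = 10,
    n_true_effects: int = 3,
    effect_size: float = 0.3,
    seed: int = 0,
    truth_defaults: ScenarioTruth | None = None,
    n_confounder_snps: int = 0,
) -> pd.DataFrame:
    """Write a complete screen input bundle and return the truth manifest.

    A random subset of ``n_true_effects`` exposures gets causal effect
    ``effect_size`` on the single shared outcome; the rest are null.  Each
    exposure owns a disjoint set of loci; one outcome table, one
    block-diagonal LD matrix and one blacklist cover them all.  Per-exposure
    sub-seeds derive deterministically from ``seed``.

    Files written: ``exposure_<id>.tsv`` per exposure, ``outcome.tsv``,
    ``ld_matrix.tsv``, ``ld_pos.tsv``, ``blacklist.txt``,
    ``truth_manifest.tsv``.
    """
    if n_true_effects > n_exposures:
        raise ValueError("n_true_effects cannot exceed n_exposures")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    true_set = set(master.choice(n_exposures, size=n_true_effects, replace=False).tolist())

    base = truth_defaults or ScenarioTruth()
    manifest_rows = []
    out_frames = []
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    ld_pos: dict[str, tuple[str, int]] = {}
    all_snp_ids: list[str] = []
    for e in range(n_exposures):
        beta = effect_size if e in true_set else 0.0
        truth = dataclasses.replace(
            base,
            causal_beta=beta,
            seed=int(seed) * 10_000 + e,  # fixed arithmetic sub-seed
            exposure_id=f"met{e + 1:03d}",
            snp_prefix=f"rs{e + 1:02d}",
            outcome_id="outcome",
        )
        exp_tab, out_tab, ld, truth = simulate_pair(truth)
        write_sumstats(exp_tab, out_dir / f"exposure_{truth.exposure_id}.tsv")
        out_frames.append(out_tab.df)
        ld_ids.extend(ld.snp_ids)
        ld_blocks.append(ld.r)
        ld_pos.update(ld.pos)
        all_snp_ids.extend(ld.snp_ids)
        manifest_rows.append(
            {
                "exposure_id": truth.exposure_id,
                "causal_beta": beta,
                "is_true_positive": beta != 0.0,
                "k_snps": truth.k_snps,
                "seed": truth.seed,
            }
        )

    out_df = pd.concat(out_frames, ignore_index=True)
    outcome = SummaryStatTable("outcome", "outcome", out_df)
    write_sumstats(outcome, out_dir / "outcome.tsv")

    # block-diagonal LD over all exposures; per-exposure position patterns
    # repeat, so offset each exposure by 100 Mb (variant IDs are disjoint
    # anyway, but distinct positions keep the map unambiguous)
    k_all = len(ld_ids)
    r_all = np.eye(k_all)
    ofs = 0
    for e, block in enumerate(ld_blocks):
        m = block.shape[0]
        r_all[ofs : ofs + m, ofs : ofs + m] = block
        for snp in ld_ids[ofs : ofs + m]:
            chrom, pos = ld_pos[snp]
            ld_pos[snp] = (chrom, pos + 100_000_000 * e)
        ofs += m
    ld_all = LDMatrix(ld_ids, r_all, ld_pos)
    write_ld_matrix(ld_all, out_dir / "ld_matrix.tsv", out_dir / "ld_pos.tsv")

    rng_bl = np.random.default_rng(int(seed) + 777)
    blacklist = (
        rng_bl.choice(ld_ids, size=min(n_confounder_snps, k_all), replace=False).tolist()
        if n_confounder_snps
        else []
    )
    (out_dir / "blacklist.txt").write_text("\n".join(blacklist) + ("\n" if blacklist else ""))

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "truth_manifest.tsv", sep="\t", index=False)
    return manifest
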
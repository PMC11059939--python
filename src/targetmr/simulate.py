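"""Synthetic GWAS/eQTL summary statistics under explicit causal models.

These generators exist so every pipeline stage — instrument selection,
harmonization, the MR estimators, SMR/HEIDI, colocalization, and the
drug-target screen — can be exercised end-to-end without external data.

Two-sample scenarios draw independent instruments with per-SNP standard
errors ``se = (2 maf (1-maf) n)^(-1/2)`` (standardized-trait scale) and an
outcome model ``beta_Y = theta * beta_X + alpha`` where ``alpha`` encodes
horizontal pleiotropy (absent, balanced, or directional, on a configurable
fraction of instruments).

Region scenarios place one or two causal variants on an AR(1) LD backbone
(``r_ij = rho^|i-j|``) and draw observed marginal betas from
``MVN(R b_joint, R/n)`` with ``se = n^(-1/2)`` — the standardized-genotype
scale keeps the marginal-truth identity exact. The architecture enum
(null / trait1_only / trait2_only / shared_variant / distinct_variants)
maps onto the colocalization hypotheses H0-H4 and the HEIDI linkage
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, RegionPanel, SumstatsTable

ARCHITECTURES = ("null", "trait1_only", "trait2_only",
                 "distinct_variants", "shared_variant")


@dataclass
class MRScenarioConfig:
    """Generative settings for a two-sample MR scenario.

    ``h2_exposure`` is the total exposure variance explained, split equally
    across instruments; ``pleiotropy_frac`` is the fraction of instruments
    carrying the pleiotropic effect ``alpha ~ N(mean, sd)`` (mean forced to
    zero for balanced pleiotropy).
    """

    n_instruments: int = 50
    theta: float = 0.5
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.03
    pleiotropy_frac: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.45)
    h2_exposure: float = 0.05
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode: {self.pleiotropy}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must lie in [0, 1]")


@dataclass
class RegionScenarioConfig:
    """Generative settings for a cis-region pair (e.g. eQTL vs GWAS)."""

    n_snps: int = 120
    ld_rho: float = 0.9
    architecture: str = "shared_variant"
    causal_idx: tuple[int, ...] = (60,)
    effect_sizes: tuple[float, float] = (12.0, 12.0)  # per-trait z targets
    n1: int = 30_000
    n2: int = 80_000
    trait1_type: str = "quantitative"
    trait2_type: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture: {self.architecture}")
        idx = tuple(self.causal_idx)
        if self.architecture == "distinct_variants":
            if len(idx) != 2 or idx[0] == idx[1]:
                raise ValueError("distinct_variants needs two distinct indices")
        elif self.architecture != "null" and len(idx) < 1:
            raise ValueError("architecture requires a causal index")
        if any(i < 0 or i >= self.n_snps for i in idx):
            raise ValueError("causal index out of range")
        self.causal_idx = idx


def simulate_ld(n_snps: int, rho: float, chrom: str = "1",
                start_pos: int = 1_000_000, spacing_bp: int = 1000
                ) -> tuple[LDMatrix, np.ndarray]:
    """AR(1) LD matrix ``r_ij = rho^|i-j|`` with SNP IDs snp_1..snp_n and
    positions spaced ``spacing_bp`` apart. Returns (LDMatrix, positions)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    snp_ids = [f"snp_{i + 1}" for i in idx]
    pos = start_pos + idx * spacing_bp
    return LDMatrix(snp_ids, r), pos


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta / se))


def _sumstats_frame(snp, chrom, pos, eaf, beta, se, n) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos, "a1": "A", "a2": "G",
        "eaf": eaf, "beta": beta, "se": se, "p": _pvals(beta, se), "n": n,
    })


def simulate_two_sample(config: MRScenarioConfig
                        ) -> tuple[SumstatsTable, SumstatsTable, dict]:
    """Independent-instrument exposure and outcome tables plus the latent
    truth record (true betas, pleiotropy effects, invalid-instrument mask)."""
    rng = np.random.default_rng(config.seed)
    m = config.n_instruments
    maf = rng.uniform(*config.maf_range, size=m)
    var_g = 2.0 * maf * (1.0 - maf)
    h2_per = config.h2_exposure / m
    sign = rng.choice([-1.0, 1.0], size=m)
    beta_x_true = sign * np.sqrt(h2_per / var_g)
    se_x = 1.0 / np.sqrt(var_g * config.n_exposure)
    se_y = 1.0 / np.sqrt(var_g * config.n_outcome)

    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    if config.pleiotropy != "none" and config.pleiotropy_frac > 0:
        k = int(round(config.pleiotropy_frac * m))
        which = rng.choice(m, size=k, replace=False)
        invalid[which] = True
        mean = 0.0 if config.pleiotropy == "balanced" else config.pleiotropy_mean
        alpha[which] = rng.normal(mean, config.pleiotropy_sd, size=k)
    # directional pleiotropy acts relative to the exposure-increasing allele
    beta_y_true = config.theta * beta_x_true + np.sign(beta_x_true) * alpha

    beta_x = rng.normal(beta_x_true, se_x)
    beta_y = rng.normal(beta_y_true, se_y)

    snp = [f"rs{i + 1}" for i in range(m)]
    chrom = [str(i % 22 + 1) for i in range(m)]
    pos = [10_000_000 + (i // 22) * 20_000_000 for i in range(m)]
    exposure = SumstatsTable(
        "exposure_sim", "quantitative",
        _sumstats_frame(snp, chrom, pos, maf, beta_x, se_x, config.n_exposure))
    outcome = SumstatsTable(
        "outcome_sim", "binary",
        _sumstats_frame(snp, chrom, pos, maf, beta_y, se_y, config.n_outcome))
    truth = {
        "theta": config.theta, "beta_x_true": beta_x_true,
        "beta_y_true": beta_y_true, "alpha": alpha, "invalid": invalid,
        "maf": maf, "se_x": se_x, "se_y": se_y,
    }
    return exposure, outcome, truth


def simulate_region_pair(config: RegionScenarioConfig,
                         ld: LDMatrix | None = None,
                         chrom: str = "1", start_pos: int = 1_000_000
                         ) -> tuple[RegionPanel, RegionPanel, LDMatrix]:
    """Correlated region panels for two traits under one causal architecture."""
    if ld is None:
        ld, pos = simulate_ld(config.n_snps, config.ld_rho, chrom=chrom,
                              start_pos=start_pos)
    else:
        pos = start_pos + np.arange(len(ld.snp_ids)) * 1000
    R = ld.r
    m = len(ld.snp_ids)
    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(m))

    z1, z2 = config.effect_sizes
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    arch = config.architecture
    if arch in ("trait1_only", "shared_variant", "distinct_variants"):
        b1[config.causal_idx[0]] = z1 / np.sqrt(config.n1)
    if arch == "shared_variant":
        b2[config.causal_idx[0]] = z2 / np.sqrt(config.n2)
    elif arch == "trait2_only":
        b2[config.causal_idx[0]] = z2 / np.sqrt(config.n2)
    elif arch == "distinct_variants":
        b2[config.causal_idx[1]] = z2 / np.sqrt(config.n2)

    eaf = rng.uniform(0.1, 0.5, size=m)

    def draw(b_joint, n):
        mu = R @ b_joint
        noise = chol @ rng.standard_normal(m) / np.sqrt(n)
        return mu + noise, np.full(m, 1.0 / np.sqrt(n))

    beta1, se1 = draw(b1, config.n1)
    beta2, se2 = draw(b2, config.n2)
    common = dict(snp_ids=list(ld.snp_ids), eaf=eaf,
                  effect_allele=np.array(["A"] * m),
                  other_allele=np.array(["G"] * m),
                  pos=np.asarray(pos), chrom=chrom)
    panel1 = RegionPanel(trait_id="trait1", trait_type=config.trait1_type,
                         beta=beta1, se=se1, n=config.n1, **common)
    panel2 = RegionPanel(trait_id="trait2", trait_type=config.trait2_type,
                         beta=beta2, se=se2, n=config.n2, **common)
    return panel1, panel2, ld


@dataclass
class TargetStudyFixture:
    """A desk-scale drug-target screen: gene tables, panels, LD, and truth."""

    interaction_table: pd.DataFrame   # columns: gene, drug
    connectivity_table: pd.DataFrame  # columns: gene, score
    gene_regions: dict[str, tuple[str, int, int]]
    eqtl_panels: dict[str, dict[str, RegionPanel]]   # gene -> tissue -> panel
    outcome_panels: dict[str, RegionPanel]           # gene -> outcome panel
    ld: dict[str, LDMatrix]
    causal_genes: list[str] = field(default_factory=list)
    no_eqtl_genes: list[str] = field(default_factory=list)


def simulate_target_study(n_genes: int = 10, n_causal: int = 1,
                          fraction_no_eqtl: float = 0.15, seed: int = 0,
                          n_snps: int = 120, ld_rho: float = 0.9,
                          z_eqtl: float = 30.0, z_gwas: float = 10.0,
                          n_eqtl: int = 30_000, n_gwas: int = 80_000,
                          tissue: str = "blood") -> TargetStudyFixture:
    """Generate a full drug-target screening fixture.

    Causal genes get a shared-variant architecture linking expression and
    outcome (protective direction: higher expression, lower risk); other
    genes get an eQTL-only architecture; a Bernoulli(``fraction_no_eqtl``)
    subset of non-causal genes has no eQTL panel at all, exercising the
    exclusion path. Connectivity scores are drawn so all study genes pass
    |score| > 90 while decoy genes do not.
    """
    if n_causal > n_genes:
        raise ValueError("n_causal cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    causal = list(rng.choice(genes, size=n_causal, replace=False))
    no_eqtl = [g for g in genes if g not in causal
               and rng.random() < fraction_no_eqtl]

    # source tables: half via drug-gene interaction db, half via connectivity
    half = n_genes // 2
    interaction = pd.DataFrame({
        "gene": genes[:half],
        "drug": ["varenicline" if i % 2 == 0 else "bupropion"
                 for i in range(half)],
    })
    conn_genes = genes[half:]
    scores = rng.uniform(91.0, 100.0, size=len(conn_genes))
    scores *= rng.choice([-1.0, 1.0], size=len(conn_genes))
    decoys = pd.DataFrame({
        "gene": [f"DECOY{i + 1:03d}" for i in range(5)],
        "score": rng.uniform(-89.0, 89.0, size=5),
    })
    connectivity = pd.concat([
        pd.DataFrame({"gene": conn_genes, "score": scores}), decoys,
    ], ignore_index=True)

    gene_regions, eqtl_panels, outcome_panels, ld_map = {}, {}, {}, {}
    for i, gene in enumerate(genes):
        chrom = str(i % 22 + 1)
        start = 1_000_000 + (i // 22) * 10_000_000
        gene_regions[gene] = (chrom, start + 40_000, start + 80_000)
        if gene in no_eqtl:
            continue
        if gene in causal:
            arch, z2 = "shared_variant", -abs(z_gwas)
        else:
            arch, z2 = "trait1_only", abs(z_gwas)
        cfg = RegionScenarioConfig(
            n_snps=n_snps, ld_rho=ld_rho, architecture=arch,
            causal_idx=(n_snps // 2,), effect_sizes=(z_eqtl, z2),
            n1=n_eqtl, n2=n_gwas, seed=int(rng.integers(2**31 - 1)))
        eq, gw, ld = simulate_region_pair(cfg, chrom=chrom, start_pos=start)
        eq.trait_id = gene
        gw.trait_id = "outcome"
        eqtl_panels[gene] = {tissue: eq}
        outcome_panels[gene] = gw
        ld_map[gene] = ld
    return TargetStudyFixture(
        interaction_table=interaction, connectivity_table=connectivity,
        gene_regions=gene_regions, eqtl_panels=eqtl_panels,
        outcome_panels=outcome_panels, ld=ld_map,
        causal_genes=causal, no_eqtl_genes=no_eqtl)


@dataclass
class MediationFixture:
    """Mediator and outcome GWAS with a focal gene locus, for the
    locus-dependence test."""

    mediator: SumstatsTable
    outcome: SumstatsTable
    focal_snp: str
    gene_region: tuple[str, int, int]
    ld: LDMatrix
    truth: dict


def simulate_mediation_study(scenario: str = "full_mediation",
                             theta: float = 0.5, n_background: int = 30,
                             z_focal: float = 30.0, z_background: float = 10.0,
                             n_sample: int = 100_000, seed: int = 0
                             ) -> MediationFixture:
    """Mediator->outcome GWAS pair with a strong focal locus.

    Under ``full_mediation`` the focal variant affects the outcome only
    through the mediator (Wald at the focal SNP estimates theta); under
    ``direct_effect`` the locus carries an additional direct outcome effect
    of equal size, doubling the focal Wald ratio while leaving the
    locus-excluded IVW at theta.
    """
    if scenario not in ("full_mediation", "direct_effect"):
        raise ValueError(f"unknown scenario: {scenario}")
    rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(0.5 * n_sample)  # maf 0.5 standardized scale

    # focal locus: the focal SNP plus 4 tight LD partners inside the gene
    chrom = "15"
    gene_region = (chrom, 78_000_000, 78_060_000)
    n_locus = 5
    locus_ld, _ = simulate_ld(n_locus, 0.95, chrom=chrom,
                              start_pos=78_010_000, spacing_bp=10_000)
    locus_snps = [f"locus_{i + 1}" for i in range(n_locus)]
    locus_ld.snp_ids = locus_snps
    locus_ld._index = {s: i for i, s in enumerate(locus_snps)}
    focal = locus_snps[2]
    locus_pos = 78_010_000 + np.arange(n_locus) * 10_000

    bM_focal = z_focal * se
    bM_locus_joint = np.zeros(n_locus)
    bM_locus_joint[2] = bM_focal
    mu_M_locus = locus_ld.r @ bM_locus_joint
    direct = theta * bM_focal if scenario == "direct_effect" else 0.0
    bY_locus_joint = np.zeros(n_locus)
    bY_locus_joint[2] = theta * bM_focal + direct
    mu_Y_locus = locus_ld.r @ bY_locus_joint
    chol = np.linalg.cholesky(locus_ld.r + 1e-10 * np.eye(n_locus))
    bM_locus = mu_M_locus + chol @ rng.standard_normal(n_locus) * se
    bY_locus = mu_Y_locus + chol @ rng.standard_normal(n_locus) * se

    # independent background instruments elsewhere in the genome
    sign = rng.choice([-1.0, 1.0], size=n_background)
    bM_bg_true = sign * z_background * se
    bY_bg_true = theta * bM_bg_true
    bM_bg = rng.normal(bM_bg_true, se)
    bY_bg = rng.normal(bY_bg_true, se)
    bg_snps = [f"bg_{i + 1}" for i in range(n_background)]
    bg_chrom = [str(i % 14 + 1) for i in range(n_background)]
    bg_pos = [10_000_000 + (i // 14) * 20_000_000 for i in range(n_background)]

    snp = locus_snps + bg_snps
    chroms = [chrom] * n_locus + bg_chrom
    pos = list(locus_pos) + bg_pos
    eaf = np.full(len(snp), 0.5 - 1e-6)  # standardized scale; A/G so unambiguous
    n_col = n_sample
    mediator = SumstatsTable("mediator_sim", "quantitative", _sumstats_frame(
        snp, chroms, pos, eaf, np.concatenate([bM_locus, bM_bg]), se, n_col))
    outcome = SumstatsTable("outcome_sim", "binary", _sumstats_frame(
        snp, chroms, pos, eaf, np.concatenate([bY_locus, bY_bg]), se, n_col))
    truth = {"theta": theta, "direct": direct, "scenario": scenario,
             "wald_focal_true": theta + (direct / bM_focal if bM_focal else 0.0)}
    return MediationFixture(mediator=mediator, outcome=outcome,
                            focal_snp=focal, gene_region=gene_region,
                            ld=locus_ld, truth=truth)


@dataclass
class ConfounderFixture:
    """Gene eQTL locus plus one confounder GWAS and the outcome GWAS."""

    eqtl_panel: RegionPanel
    confounder: SumstatsTable
    outcome: SumstatsTable
    gene_region: tuple[str, int, int]
    ld: LDMatrix
    truth: dict


def simulate_confounder_study(kind: str = "mediator", theta: float = 0.4,
                              n_background: int = 30, n_snps: int = 80,
                              ld_rho: float = 0.9, z_eqtl: float = 30.0,
                              z_conf: float = 12.0, z_outcome: float = 10.0,
                              n_sample: int = 100_000, seed: int = 0
                              ) -> ConfounderFixture:
    """A locus where gene expression, a candidate confounder phenotype and
    the outcome share one causal variant.

    ``kind='mediator'`` gives the confounder a genuine downstream effect
    ``theta`` on the outcome (its background instruments transmit it);
    ``kind='null_confounder'`` colocalizes at the locus but has no
    confounder->outcome effect, so it fails the IVW gate.
    """
    if kind not in ("mediator", "null_confounder"):
        raise ValueError(f"unknown kind: {kind}")
    rng = np.random.default_rng(seed)
    chrom = "15"
    start = 78_000_000
    gene_region = (chrom, start + 20_000, start + 60_000)
    ld, pos = simulate_ld(n_snps, ld_rho, chrom=chrom, start_pos=start,
                          spacing_bp=1000)
    c = n_snps // 2
    R = ld.r
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
    eaf = rng.uniform(0.1, 0.5, size=n_snps)

    def draw_panel(z_target, n):
        b = np.zeros(n_snps)
        b[c] = z_target / np.sqrt(n)
        beta = R @ b + chol @ rng.standard_normal(n_snps) / np.sqrt(n)
        return beta, np.full(n_snps, 1.0 / np.sqrt(n))

    beta_e, se_e = draw_panel(z_eqtl, 30_000)
    eqtl_panel = RegionPanel(
        trait_id="GENE_X", trait_type="quantitative", snp_ids=list(ld.snp_ids),
        beta=beta_e, se=se_e, eaf=eaf, n=30_000,
        effect_allele=np.array(["A"] * n_snps),
        other_allele=np.array(["G"] * n_snps), pos=np.asarray(pos), chrom=chrom)

    beta_c, se_c = draw_panel(z_conf, n_sample)
    beta_o, se_o = draw_panel(z_outcome, n_sample)

    se_bg = 1.0 / np.sqrt(0.5 * n_sample)
    sign = rng.choice([-1.0, 1.0], size=n_background)
    bC_bg_true = sign * 10.0 * se_bg
    theta_eff = theta if kind == "mediator" else 0.0
    bC_bg = rng.normal(bC_bg_true, se_bg)
    bO_bg = rng.normal(theta_eff * bC_bg_true, se_bg)
    bg_snps = [f"bg_{i + 1}" for i in range(n_background)]
    bg_chrom = [str(i % 14 + 1) for i in range(n_background)]
    bg_pos = [10_000_000 + (i // 14) * 20_000_000 for i in range(n_background)]

    snp = list(ld.snp_ids) + bg_snps
    chroms = [chrom] * n_snps + bg_chrom
    all_pos = list(pos) + bg_pos
    all_eaf = np.concatenate([eaf, np.full(n_background, 0.5 - 1e-6)])
    confounder = SumstatsTable("confounder_sim", "quantitative", _sumstats_frame(
        snp, chroms, all_pos, all_eaf,
        np.concatenate([beta_c, bC_bg]),
        np.concatenate([se_c, np.full(n_background, se_bg)]), n_sample))
    outcome = SumstatsTable("outcome_sim", "binary", _sumstats_frame(
        snp, chroms, all_pos, all_eaf,
        np.concatenate([beta_o, bO_bg]),
        np.concatenate([se_o, np.full(n_background, se_bg)]), n_sample))
    truth = {"kind": kind, "theta": theta_eff, "causal_snp": ld.snp_ids[c]}
    return ConfounderFixture(eqtl_panel=eqtl_panel, confounder=confounder,
                             outcome=outcome, gene_region=gene_region,
                             ld=ld, truth=truth)
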
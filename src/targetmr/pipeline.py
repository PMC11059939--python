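"""Drug-target screening and phenotype-MR orchestration.

Two analyses are wired together here. Analysis 1 is classic two-sample MR
of an exposure phenotype on the outcome: genome-wide-significant instrument
selection, LD clumping, allele harmonization, then the full estimator
suite. Analysis 2 screens candidate drug-target genes: each gene x tissue
cis-eQTL panel is tested against the outcome GWAS by SMR, and genes passing
the Bonferroni gate are taken through HEIDI (linkage check) and Bayesian
colocalization (shared-variant check). A hit must clear all three gates.

The module also implements the locus-dependence (mediation) contrast — a
Wald estimate through a single focal variant versus an IVW estimate with
the gene locus excluded — and the confounder-assessment loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import mr, smr
from .sumstats import (HarmonizedInstrumentSet, LDMatrix, RegionPanel,
                       SumstatsTable, cis_window, clump, harmonize,
                       select_instruments)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds shared across the pipeline (defaults follow the study
    protocol: p<5e-8 instruments, MAF>1%, clump r2 0.001 within 10000 kb,
    cis +/-1 Mb, coloc +/-100 kb with priors 1e-4/1e-4/1e-5, PP.H4>0.9)."""

    p_threshold: float = 5e-8
    maf_threshold: float = 0.01
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    cis_kb: float = 1_000
    coloc_kb: float = 100
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    pph4_threshold: float = 0.9
    heidi_alpha: float = 0.05
    alpha: float = 0.05
    palindrome_band: float = 0.08
    ivw_mode: str = "multiplicative_random"
    bonferroni_all_genes: bool = True
    n_boot: int = 1000
    seed: int = 0


@dataclass
class DrugTargetGene:
    """A gene interacting with a smoking-cessation medication."""

    gene_id: str
    source: str  # interaction_db | connectivity_up | connectivity_down
    connectivity_score: float | None = None
    has_eqtl: bool = True
    tissues: list[str] = field(default_factory=list)


@dataclass
class DependenceTestResult:
    """Focal-variant Wald vs locus-excluded IVW for the mediation contrast."""

    focal_snp: str
    estimate_focal: mr.CausalEstimate
    estimate_excluding: mr.CausalEstimate
    ci_overlap: bool
    ratio_of_effects: float


def select_drug_targets(interaction_table: pd.DataFrame,
                        connectivity_table: pd.DataFrame,
                        score_threshold: float = 90.0,
                        cap_per_direction: int = 20) -> list[DrugTargetGene]:
    """Union of interaction-database genes and connectivity-map genes with
    |score| above the threshold, capped per direction by |score| rank.
    Duplicates resolve to the interaction-database source."""
    out: dict[str, DrugTargetGene] = {}
    for gene in interaction_table["gene"]:
        out[str(gene)] = DrugTargetGene(gene_id=str(gene), source="interaction_db")
    conn = connectivity_table.copy()
    conn["score"] = pd.to_numeric(conn["score"])
    for direction, name in ((1, "connectivity_up"), (-1, "connectivity_down")):
        sub = conn[direction * conn["score"] > score_threshold]
        sub = sub.reindex(sub["score"].abs().sort_values(ascending=False).index)
        for _, row in sub.head(cap_per_direction).iterrows():
            g = str(row["gene"])
            if g not in out:
                out[g] = DrugTargetGene(gene_id=g, source=name,
                                        connectivity_score=float(row["score"]))
    return list(out.values())


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise threshold alpha/m (e.g. 0.05/88 = 5.68e-4)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    thr = alpha / m_tests
    logger.info("Bonferroni threshold: %.3g (alpha=%g, m=%d)", thr, alpha, m_tests)
    return thr


def region_panel_from_table(table: SumstatsTable, predicate,
                            trait_id: str | None = None) -> RegionPanel:
    """Restrict a summary-statistics table to a region predicate and view it
    as a :class:`RegionPanel` (sorted by position)."""
    mask = [predicate(str(c), int(p))
            for c, p in zip(table.df["chr"], table.df["pos"])]
    sub = table.df[mask].sort_values("pos")
    if sub.empty:
        raise ValueError("empty region")
    return RegionPanel(
        trait_id=trait_id or table.trait_id, trait_type=table.trait_type,
        snp_ids=sub["snp"].tolist(), beta=sub["beta"].to_numpy(),
        se=sub["se"].to_numpy(), eaf=sub["eaf"].to_numpy(),
        n=int(sub["n"].median()) if sub["n"].notna().any() else 0,
        effect_allele=sub["a1"].to_numpy(), other_allele=sub["a2"].to_numpy(),
        pos=sub["pos"].to_numpy(), chrom=str(sub["chr"].iloc[0]))


def build_instrument_set(exposure: SumstatsTable, outcome: SumstatsTable,
                         ld: LDMatrix | None, config: AnalysisConfig
                         ) -> HarmonizedInstrumentSet:
    """Analysis-1 front end: select, clump, harmonize."""
    candidates = select_instruments(exposure, config.p_threshold,
                                    config.maf_threshold)
    table = exposure.restrict(candidates)
    kept = clump(table, ld, r2_threshold=config.clump_r2,
                 window_kb=config.clump_kb) if len(table) else []
    return harmonize(exposure, outcome, kept,
                     palindrome_eaf_band=config.palindrome_band)


def run_phenotype_mr(exposure: SumstatsTable, outcome: SumstatsTable,
                     ld: LDMatrix | None = None,
                     config: AnalysisConfig | None = None) -> dict:
    """Analysis-1 driver for one exposure phenotype: instrument selection ->
    clumping -> harmonization -> the full MR suite (OR scale for binary
    outcomes)."""
    config = config or AnalysisConfig()
    hset = build_instrument_set(exposure, outcome, ld, config)
    if hset.n_snp == 0:
        raise ValueError(
            f"zero instruments for {exposure.trait_id} after selection/harmonization")
    suite = mr.run_mr_suite(hset, seed=config.seed, n_boot=config.n_boot,
                            ivw_mode=config.ivw_mode,
                            binary=outcome.trait_type == "binary")
    suite["instrument_set"] = hset
    return suite


def run_phenotype_mr_batch(exposures: dict[str, SumstatsTable],
                           outcome: SumstatsTable,
                           ld: LDMatrix | None = None,
                           config: AnalysisConfig | None = None) -> dict:
    """Run Analysis 1 for several exposure phenotypes; a failing phenotype is
    recorded and does not abort the rest."""
    results, failures = {}, {}
    for name, table in exposures.items():
        try:
            results[name] = run_phenotype_mr(table, outcome, ld, config)
        except (ValueError, KeyError) as exc:
            failures[name] = str(exc)
            logger.warning("phenotype %s failed: %s", name, exc)
    return {"results": results, "failures": failures}


def screen_targets(genes: list[DrugTargetGene],
                   eqtl_panels: dict[str, dict[str, RegionPanel]],
                   outcome_panels: dict[str, RegionPanel],
                   ld: dict[str, LDMatrix],
                   gene_regions: dict[str, tuple[str, int, int]] | None = None,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analysis-2 driver: SMR -> HEIDI -> colocalization per gene x tissue.

    Every input gene appears in the report with an explicit status. The SMR
    Bonferroni denominator is the number of selected genes (including those
    without eQTL data) when ``config.bonferroni_all_genes`` is true,
    otherwise the number of genes with at least one valid instrument. A hit
    needs p_smr below the threshold, HEIDI not rejecting (p >= heidi_alpha,
    or not computable), and PP.H4 above the threshold in a +/-coloc_kb
    window around the top SNP.
    """
    config = config or AnalysisConfig()
    m_all = len(genes)
    rows = []
    for gene in genes:
        tissues = eqtl_panels.get(gene.gene_id, {})
        if not gene.has_eqtl or not tissues:
            rows.append({"gene": gene.gene_id, "tissue": None,
                         "status": "no_eqtl"})
            continue
        for tissue, eq_panel in tissues.items():
            row = {"gene": gene.gene_id, "tissue": tissue}
            gw_panel = outcome_panels.get(gene.gene_id)
            if gw_panel is None:
                row["status"] = "no_outcome_panel"
                rows.append(row)
                continue
            try:
                res = smr.smr_test(eq_panel, gw_panel, gene_id=gene.gene_id,
                                   tissue=tissue,
                                   p_instrument=config.p_threshold)
            except smr.NoInstrumentError:
                row["status"] = "no_instrument"
                rows.append(row)
                continue
            row.update({"status": "tested", "top_snp": res.top_snp,
                        "b_xy": res.b_xy, "se_xy": res.se_xy,
                        "p_smr": res.p_smr})
            rows.append(row)
    report = pd.DataFrame(rows)

    tested = report["status"] == "tested" if len(report) else pd.Series(dtype=bool)
    m_valid = report.loc[tested, "gene"].nunique() if len(report) else 0
    m = m_all if config.bonferroni_all_genes else max(m_valid, 1)
    threshold = bonferroni_threshold(config.alpha, max(m, 1))
    report["m_tests"] = m
    report["p_smr_threshold"] = threshold

    for col in ("p_heidi", "n_heidi_snps", "pp_h4"):
        report[col] = np.nan
    report["coloc_top_snp"] = pd.Series([None] * len(report), dtype="object")
    report["smr_pass"] = False
    report["heidi_pass"] = False
    report["coloc_pass"] = False
    for i, row in report.iterrows():
        if row.get("status") != "tested" or not (row["p_smr"] < threshold):
            continue
        report.loc[i, "smr_pass"] = True
        gene_id, tissue = row["gene"], row["tissue"]
        eq_panel = eqtl_panels[gene_id][tissue]
        gw_panel = outcome_panels[gene_id]
        gene_ld = ld.get(gene_id)
        if gene_ld is not None:
            p_heidi, n_heidi = smr.heidi_test(eq_panel, gw_panel, gene_ld)
            report.loc[i, "p_heidi"] = p_heidi if p_heidi is not None else np.nan
            report.loc[i, "n_heidi_snps"] = n_heidi
            heidi_pass = p_heidi is None or p_heidi >= config.heidi_alpha
        else:
            heidi_pass = True
        report.loc[i, "heidi_pass"] = heidi_pass
        # colocalization in a +/-coloc_kb window around the SMR top SNP
        eq_c, gw_c = eq_panel, gw_panel
        if eq_panel.pos is not None:
            top_idx = eq_panel.snp_ids.index(row["top_snp"])
            center = int(np.asarray(eq_panel.pos)[top_idx])
            half = int(config.coloc_kb * 1000)
            keep = [j for j, p in enumerate(np.asarray(eq_panel.pos))
                    if abs(int(p) - center) <= half]
            eq_c, gw_c = eq_panel.subset(keep), gw_panel
        post = coloc_mod.coloc_abf(eq_c, gw_c, p1=config.p1, p2=config.p2,
                                   p12=config.p12, min_snps_warn=0)
        report.loc[i, "pp_h4"] = post.pp_h4
        report.loc[i, "coloc_top_snp"] = post.top_shared_snp
        report.loc[i, "coloc_pass"] = post.pp_h4 > config.pph4_threshold
    report["hit"] = report["smr_pass"] & report["heidi_pass"] & report["coloc_pass"]
    return report


def dependence_test(mediator_gwas: SumstatsTable, outcome_gwas: SumstatsTable,
                    focal_snp: str, gene_region: tuple[str, int, int],
                    flank_bp: int = 100_000, ld: LDMatrix | None = None,
                    config: AnalysisConfig | None = None
                    ) -> DependenceTestResult:
    """Locus-dependence contrast: Wald through the focal variant vs IVW on
    the mediator with all SNPs in ``gene_region +/- flank_bp`` removed
    before clumping. Overlapping 95% CIs are consistent with the locus
    acting through the mediator."""
    config = config or AnalysisConfig()
    binary = outcome_gwas.trait_type == "binary"
    try:
        med = mediator_gwas.get(focal_snp)
    except KeyError:
        raise ValueError(f"focal SNP {focal_snp} absent from mediator GWAS")
    focal_set = harmonize(mediator_gwas, outcome_gwas, [focal_snp],
                          palindrome_eaf_band=config.palindrome_band)
    if focal_set.n_snp == 0:
        reason = focal_set.dropped[0][1] if focal_set.dropped else "unknown"
        raise ValueError(f"focal SNP {focal_snp} unusable in outcome ({reason})")
    inst = focal_set.instruments[0]
    estimate_focal = mr.wald_ratio(inst.beta_exposure, inst.se_exposure,
                                   inst.beta_outcome, inst.se_outcome,
                                   binary=binary)

    predicate = cis_window(gene_region, flank_bp)
    reduced = mediator_gwas.exclude_region(predicate)
    hset = build_instrument_set(reduced, outcome_gwas, ld, config)
    if hset.n_snp < 2:
        raise ValueError("fewer than 2 instruments remain after locus exclusion")
    estimate_excl = mr.ivw(hset, mode=config.ivw_mode, binary=binary)

    overlap = (estimate_focal.ci_low <= estimate_excl.ci_high
               and estimate_excl.ci_low <= estimate_focal.ci_high)
    ratio = (estimate_focal.beta / estimate_excl.beta
             if estimate_excl.beta != 0 else np.inf)
    return DependenceTestResult(
        focal_snp=focal_snp, estimate_focal=estimate_focal,
        estimate_excluding=estimate_excl, ci_overlap=bool(overlap),
        ratio_of_effects=float(ratio))


def single_instrument_mode(eqtl_panel: RegionPanel,
                           mediator_gwas: SumstatsTable,
                           outcome_gwas: SumstatsTable, snp: str,
                           config: AnalysisConfig | None = None
                           ) -> dict[str, mr.CausalEstimate]:
    """Wald ratios of expression->outcome and mediator->outcome through one
    shared instrument (the single-variant pipeline mode)."""
    config = config or AnalysisConfig()
    binary = outcome_gwas.trait_type == "binary"
    if snp not in eqtl_panel.snp_ids:
        raise ValueError(f"SNP {snp} absent from eQTL panel")
    i = eqtl_panel.snp_ids.index(snp)
    try:
        out = outcome_gwas.get(snp)
    except KeyError:
        raise ValueError(f"SNP {snp} absent from outcome GWAS")
    beta_out, se_out = out.beta, out.se
    if eqtl_panel.effect_allele is not None:
        a1 = str(np.asarray(eqtl_panel.effect_allele)[i])
        a2 = str(np.asarray(eqtl_panel.other_allele)[i])
        if (out.effect_allele, out.other_allele) == (a2, a1):
            beta_out = -beta_out
        elif (out.effect_allele, out.other_allele) != (a1, a2):
            raise ValueError(f"SNP {snp}: irreconcilable alleles")
    expr_est = mr.wald_ratio(float(eqtl_panel.beta[i]), float(eqtl_panel.se[i]),
                             beta_out, se_out, binary=binary)
    med_set = harmonize(mediator_gwas, outcome_gwas, [snp],
                        palindrome_eaf_band=config.palindrome_band)
    if med_set.n_snp == 0:
        raise ValueError(f"SNP {snp} unusable for mediator->outcome")
    m0 = med_set.instruments[0]
    med_est = mr.wald_ratio(m0.beta_exposure, m0.se_exposure,
                            m0.beta_outcome, m0.se_outcome, binary=binary)
    return {"expression_on_outcome": expr_est, "mediator_on_outcome": med_est}


def run_confounder_analysis(gene_region: tuple[str, int, int],
                            confounders: dict[str, SumstatsTable],
                            outcome_gwas: SumstatsTable,
                            eqtl_panel: RegionPanel,
                            ld: LDMatrix | None = None,
                            config: AnalysisConfig | None = None
                            ) -> pd.DataFrame:
    """Confounder assessment at a gene locus.

    Per confounder phenotype: colocalization with the outcome at the locus,
    colocalization with the gene's eQTL, SMR of expression on the
    confounder, and genome-wide IVW of the confounder on the outcome. A
    candidate mediator must colocalize with both (PP.H4 above threshold)
    and show IVW p < alpha. Failures are isolated per confounder.
    """
    config = config or AnalysisConfig()
    predicate = cis_window(gene_region, int(config.coloc_kb * 1000))
    rows = []
    for name, table in confounders.items():
        row: dict = {"confounder": name}
        try:
            conf_panel = region_panel_from_table(table, predicate)
            out_panel = region_panel_from_table(outcome_gwas, predicate)
            pp_out = coloc_mod.coloc_abf(conf_panel, out_panel, p1=config.p1,
                                         p2=config.p2, p12=config.p12,
                                         min_snps_warn=0).pp_h4
            pp_gene = coloc_mod.coloc_abf(conf_panel, eqtl_panel, p1=config.p1,
                                          p2=config.p2, p12=config.p12,
                                          min_snps_warn=0).pp_h4
            smr_res = smr.smr_test(eqtl_panel, conf_panel,
                                   gene_id=eqtl_panel.trait_id, tissue="",
                                   p_instrument=config.p_threshold)
            ivw_suite = run_phenotype_mr(table, outcome_gwas, ld, config)
            primary = ivw_suite["estimates"].get("ivw") or ivw_suite["estimates"].get("wald")
            row.update({
                "pp_h4_outcome": pp_out, "pp_h4_gene": pp_gene,
                "p_smr_gene_on_confounder": smr_res.p_smr,
                "ivw_beta": primary.beta, "ivw_p": primary.pval,
                "candidate_mediator": bool(
                    pp_out > config.pph4_threshold
                    and pp_gene > config.pph4_threshold
                    and primary.pval < config.alpha),
                "status": "ok",
            })
        except (ValueError, smr.NoInstrumentError) as exc:
            row.update({"status": f"failed: {exc}", "candidate_mediator": False})
        rows.append(row)
    return pd.DataFrame(rows)
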
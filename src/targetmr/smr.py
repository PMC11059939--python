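"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR tests whether a gene's expression mediates a GWAS signal via the ratio
b_xy = beta_GWAS / beta_eQTL at the top cis-eQTL, with the statistic

    T_SMR = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2)  ~  chi-square(1).

HEIDI (heterogeneity in dependent instruments) asks whether b_xy is constant
across SNPs in LD with the top eQTL: under a single shared causal variant
every SNP estimates the same b_xy, whereas under linkage (distinct causal
variants) the per-SNP estimates diverge. The test statistic is the sum of
squared standardized deviations d_i = b_xy(i) - b_xy(top), referred to a
weighted sum of 1-df chi-squares whose weights are the eigenvalues of the
correlation matrix of the d's (Imhof numerical integration, Satterthwaite
fallback). A small HEIDI p flags linkage rather than causality/pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .sumstats import LDMatrix, RegionPanel

logger = logging.getLogger(__name__)

#: default HEIDI SNP-selection parameters (chi-square > 10 on the eQTL,
#: LD r^2 to the top SNP within [0.05, 0.9], at most 20 SNPs)
HEIDI_P_EQTL_MAX = stats.chi2.sf(10.0, 1)  # ~1.57e-3
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20


class NoInstrumentError(ValueError):
    """Raised when a gene has no genome-wide-significant eQTL instrument."""


@dataclass
class SMRResult:
    """Gene-level SMR/HEIDI summary for one tissue."""

    gene_id: str
    tissue: str
    top_snp: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0

    @property
    def or_scale(self) -> tuple[float, float, float]:
        lo = self.b_xy - stats.norm.ppf(0.975) * self.se_xy
        hi = self.b_xy + stats.norm.ppf(0.975) * self.se_xy
        return (float(np.exp(self.b_xy)), float(np.exp(lo)), float(np.exp(hi)))


def align_panels(p1: RegionPanel, p2: RegionPanel
                 ) -> tuple[RegionPanel, RegionPanel]:
    """Intersect two panels on snp_id and align p2's betas to p1's effect
    alleles (sign flip + eaf flip on swapped alleles; mismatches dropped)."""
    index2 = {s: i for i, s in enumerate(p2.snp_ids)}
    keep1, keep2, flip = [], [], []
    for i, snp in enumerate(p1.snp_ids):
        j = index2.get(snp)
        if j is None:
            continue
        f = 1.0
        if p1.effect_allele is not None and p2.effect_allele is not None:
            a1, a2 = p1.effect_allele[i], p1.other_allele[i]
            b1, b2 = p2.effect_allele[j], p2.other_allele[j]
            if (b1, b2) == (a1, a2):
                f = 1.0
            elif (b1, b2) == (a2, a1):
                f = -1.0
            else:
                continue
        keep1.append(i)
        keep2.append(j)
        flip.append(f)
    q1 = p1.subset(keep1)
    q2 = p2.subset(keep2)
    flip_a = np.asarray(flip)
    q2.beta = q2.beta * flip_a
    q2.eaf = np.where(flip_a < 0, 1.0 - q2.eaf, q2.eaf)
    if q2.effect_allele is not None and q1.effect_allele is not None:
        q2.effect_allele = np.asarray(q1.effect_allele).copy()
        q2.other_allele = np.asarray(q1.other_allele).copy()
    return q1, q2


def smr_statistic(z_eqtl: float, z_gwas: float) -> float:
    """T_SMR = z_g^2 z_e^2 / (z_g^2 + z_e^2); 0 when either z is 0."""
    ze2, zg2 = z_eqtl**2, z_gwas**2
    if ze2 + zg2 == 0:
        return 0.0
    return float(zg2 * ze2 / (zg2 + ze2))


def smr_test(eqtl_region: RegionPanel, gwas_region: RegionPanel,
             gene_id: str = "", tissue: str = "",
             p_instrument: float = 5e-8) -> SMRResult:
    """SMR at the top cis-eQTL of the region.

    Raises :class:`NoInstrumentError` when no SNP reaches ``p_instrument``
    on the eQTL side (the gene is then skipped as having no valid
    instrument). Panels are intersected/allele-aligned first.
    """
    eq, gw = align_panels(eqtl_region, gwas_region)
    if len(eq) == 0:
        raise NoInstrumentError("no valid instrument")
    p_eq = eq.pval
    top = int(np.argmin(p_eq))
    if not (p_eq[top] < p_instrument):
        raise NoInstrumentError("no valid instrument")
    z_e = float(eq.z[top])
    z_g = float(gw.z[top])
    t_smr = smr_statistic(z_e, z_g)
    p_smr = float(stats.chi2.sf(t_smr, 1))
    b_xy = float(gw.beta[top] / eq.beta[top])
    se_xy = abs(b_xy) / np.sqrt(t_smr) if t_smr > 0 else np.inf
    return SMRResult(gene_id=gene_id or eq.trait_id, tissue=tissue,
                     top_snp=eq.snp_ids[top], b_xy=b_xy, se_xy=float(se_xy),
                     p_smr=p_smr)


def select_heidi_snps(eqtl_region: RegionPanel, ld: LDMatrix,
                      p_eqtl_max: float = HEIDI_P_EQTL_MAX,
                      r2_min: float = HEIDI_R2_MIN,
                      r2_max: float = HEIDI_R2_MAX,
                      max_snps: int = HEIDI_MAX_SNPS) -> list[str]:
    """SNPs eligible for HEIDI: eQTL p below ``p_eqtl_max`` and r² to the
    top SNP within [r2_min, r2_max]; capped at ``max_snps`` by eQTL p rank.
    The top SNP itself is always included (first)."""
    p_eq = eqtl_region.pval
    top = int(np.argmin(p_eq))
    top_snp = eqtl_region.snp_ids[top]
    candidates = []
    for i, snp in enumerate(eqtl_region.snp_ids):
        if i == top:
            continue
        if not (p_eq[i] < p_eqtl_max):
            continue
        r = ld.r_value(snp, top_snp)
        if r is None:
            continue
        r2 = r * r
        if r2_min <= r2 <= r2_max:
            candidates.append((p_eq[i], snp))
    candidates.sort()
    kept = [snp for _, snp in candidates[: max(0, max_snps - 1)]]
    return [top_snp] + kept


def imhof_pvalue(t: float, lambdas: np.ndarray) -> float:
    """P(sum_k lambda_k chi2_1k > t) by Imhof's integral.

    Returns a value in [0, 1]; raises RuntimeError if the quadrature does
    not behave (caller falls back to Satterthwaite).
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0:
        return 1.0
    if np.allclose(lam, lam[0]):
        # equal weights: exactly a scaled chi-square
        return float(stats.chi2.sf(t / lam[0], lam.size))

    def integrand(x):
        # u = x/(1-x) maps (0,1) onto (0, inf)
        u = x / (1.0 - x)
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho) / (1.0 - x) ** 2

    import warnings
    with warnings.catch_warnings():
        # accuracy is checked via the returned error estimate below
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, 1.0, limit=500)
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-4:
        raise RuntimeError("Imhof integration did not converge")
    return float(min(max(p, 0.0), 1.0))


def satterthwaite_pvalue(t: float, lambdas: np.ndarray) -> float:
    """Scaled chi-square approximation to a weighted chi-square sum."""
    lam = np.asarray(lambdas, dtype=float)
    s1, s2 = float(np.sum(lam)), float(np.sum(lam**2))
    if s2 <= 0:
        return 1.0
    scale = s2 / s1
    df = s1**2 / s2
    return float(stats.chi2.sf(t / scale, df))


def heidi_test(eqtl_region: RegionPanel, gwas_region: RegionPanel,
               ld: LDMatrix,
               p_eqtl_max: float = HEIDI_P_EQTL_MAX,
               r2_min: float = HEIDI_R2_MIN,
               r2_max: float = HEIDI_R2_MAX,
               max_snps: int = HEIDI_MAX_SNPS,
               method: str = "imhof") -> tuple[float | None, int]:
    """HEIDI p-value for one region pair; ``(None, n)`` if < 3 eligible SNPs.

    Cross-trait covariance is taken as zero (non-overlapping studies);
    within-trait covariances of the betas follow cov(b_i, b_j) ~
    r_ij se_i se_j.
    """
    eq, gw = align_panels(eqtl_region, gwas_region)
    if len(eq) == 0:
        return None, 0
    snps = select_heidi_snps(eq, ld, p_eqtl_max=p_eqtl_max,
                             r2_min=r2_min, r2_max=r2_max, max_snps=max_snps)
    if len(snps) < 3:
        logger.info("HEIDI not computed: only %d eligible SNPs", len(snps))
        return None, len(snps)
    idx = [eq.snp_ids.index(s) for s in snps]
    eq_s, gw_s = eq.subset(idx), gw.subset(idx)
    R = ld.submatrix(snps).r
    m = len(snps)

    bE, sE = eq_s.beta, eq_s.se
    bG, sG = gw_s.beta, gw_s.se
    b = bG / bE  # b[0] is the top SNP's ratio

    # delta-method covariance of the ratio vector: independence across traits
    VG = R * np.outer(sG, sG)
    VE = R * np.outer(sE, sE)
    inv_bE = 1.0 / bE
    Cb = np.outer(inv_bE, inv_bE) * VG + np.outer(bG * inv_bE**2, bG * inv_bE**2) * VE

    # covariance of d_i = b_i - b_0, i = 1..m-1
    d = b[1:] - b[0]
    Cd = (Cb[1:, 1:] - Cb[1:, [0]] - Cb[[0], 1:] + Cb[0, 0])
    var_d = np.clip(np.diag(Cd), 0.0, None)
    sd = np.sqrt(var_d)
    # perfect-LD noise-free copies have var(d)=0 and d=0: contribute nothing
    ok = sd > 0
    if not np.any(ok):
        return 1.0, m
    z = np.where(ok, d / np.where(ok, sd, 1.0), 0.0)
    t_heidi = float(np.sum(z**2))
    Cd = Cd[np.ix_(ok, ok)]
    sd = sd[ok]
    corr = Cd / np.outer(sd, sd)
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    if method == "imhof":
        try:
            p = imhof_pvalue(t_heidi, lam)
        except RuntimeError:
            p = satterthwaite_pvalue(t_heidi, lam)
    elif method == "satterthwaite":
        p = satterthwaite_pvalue(t_heidi, lam)
    else:
        raise ValueError(f"unknown HEIDI p-value method: {method}")
    return float(min(max(p, 0.0), 1.0)), m


def smr_with_heidi(eqtl_region: RegionPanel, gwas_region: RegionPanel,
                   ld: LDMatrix, gene_id: str = "", tissue: str = "",
                   p_instrument: float = 5e-8, **heidi_kwargs) -> SMRResult:
    """SMR test followed by HEIDI on the same aligned region pair."""
    res = smr_test(eqtl_region, gwas_region, gene_id=gene_id, tissue=tissue,
                   p_instrument=p_instrument)
    p_heidi, n_heidi = heidi_test(eqtl_region, gwas_region, ld, **heidi_kwargs)
    res.p_heidi = p_heidi
    res.n_heidi_snps = n_heidi
    return res
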
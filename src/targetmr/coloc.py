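"""Enumeration-based Bayesian colocalization of two traits in a region.

Under the assumption of at most one causal variant per trait, every SNP
configuration falls into five hypotheses: H0 (no association), H1/H2 (one
trait only), H3 (both traits, distinct variants), H4 (a shared variant).
Per-SNP evidence uses Wakefield's approximate Bayes factor

    lABF = 0.5 * [ ln(1 - r) + z^2 r ],   r = w / (w + se^2),

with prior effect variance w (sd 0.2 for binary, 0.15 for quantitative
traits). Hypothesis posteriors combine per-SNP ABFs with priors p1, p2
(single-trait causal) and p12 (shared causal); all sums are done in log
space, so |z| up to 100 is safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import RegionPanel, cis_window
from .smr import align_panels

#: coloc default priors: per-SNP causal for each trait, and shared
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: prior standard deviation of the true effect, per trait type
PRIOR_SD = {"binary": 0.2, "quantitative": 0.15}

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass
class ColocPosterior:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]
    n_snps: int
    top_shared_snp: str

    @property
    def pp_h4(self) -> float:
        return self.pp["pp_h4"]

    def as_array(self) -> np.ndarray:
        return np.array([self.pp[h] for h in HYPOTHESES])


def wakefield_labf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for one association (vectorized)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + z**2 * r)


def coloc_abf(region1: RegionPanel, region2: RegionPanel,
              p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
              p12: float = DEFAULT_P12,
              min_snps_warn: int = 50) -> ColocPosterior:
    """Colocalization posteriors for two region panels.

    Panels are intersected and allele-aligned first; zero common SNPs is an
    error, and fewer than ``min_snps_warn`` triggers a low-power warning.
    """
    r1, r2 = align_panels(region1, region2)
    n = len(r1)
    if n == 0:
        raise ValueError("no common SNPs between the two panels")
    if n < min_snps_warn:
        warnings.warn(
            f"colocalization on only {n} SNPs: limited power to resolve "
            "hypotheses", stacklevel=2)
    l1 = wakefield_labf(r1.beta, r1.se, PRIOR_SD[r1.trait_type])
    l2 = wakefield_labf(r2.beta, r2.se, PRIOR_SD[r2.trait_type])

    lsum1 = logsumexp(l1)                # sum_i ABF1_i
    lsum2 = logsumexp(l2)                # sum_j ABF2_j
    lsum12 = logsumexp(l1 + l2)          # sum_i ABF1_i ABF2_i
    # sum_{i != j} ABF1_i ABF2_j = S1*S2 - S12, computed stably in log space
    lcross = lsum1 + lsum2
    with np.errstate(divide="ignore"):
        diff = lsum12 - lcross
        l_h3 = lcross + np.log1p(-min(np.exp(diff), 1.0)) if diff < 0 else -np.inf

    logpost = np.array([
        0.0,
        np.log(p1) + lsum1,
        np.log(p2) + lsum2,
        np.log(p1) + np.log(p2) + l_h3,
        np.log(p12) + lsum12,
    ])
    logpost -= logsumexp(logpost)
    pp = np.exp(logpost)
    pp /= pp.sum()
    top = r1.snp_ids[int(np.argmax(l1 + l2))]
    return ColocPosterior(pp=dict(zip(HYPOTHESES, pp.tolist())),
                          n_snps=n, top_shared_snp=top)


def define_coloc_region(center: tuple, flank_bp: int = 100_000):
    """Region predicate around a gene interval or single variant position.

    ``center`` is ``(chrom, start, end)`` or ``(chrom, pos)``; the default
    flank is 100 kb either side, boundary positions included.
    """
    if len(center) == 2:
        chrom, pos = center
        return cis_window((chrom, int(pos), int(pos)), flank_bp)
    return cis_window(tuple(center), flank_bp)
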
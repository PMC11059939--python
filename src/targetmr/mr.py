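"""Two-sample Mendelian-randomization estimators and sensitivity diagnostics.

All estimators consume a :class:`~targetmr.sumstats.HarmonizedInstrumentSet`
and return :class:`CausalEstimate` objects on the outcome beta scale
(log-odds for a binary outcome; the OR-scale triple is attached when
requested). The inverse-variance-weighted (IVW) estimator is the primary
method; MR-Egger, weighted median, simple/weighted mode, Cochran's Q and
MR-PRESSO probe the instrument-validity assumptions.

Conventions: IVW and Wald p-values use the normal distribution; MR-Egger
uses t with n-2 degrees of freedom. The default IVW variant is
multiplicative random effects with the overdispersion scale floored at 1.
Every bootstrap- or simulation-based quantity takes a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CausalEstimate:
    """A method-labelled causal-effect estimate with CI and p-value."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_scale: tuple[float, float, float] | None = None

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snp: int,
                     dist: str = "norm", df: int | None = None,
                     binary: bool = False) -> "CausalEstimate":
        if se > 0 and np.isfinite(se):
            z = beta / se
            if dist == "t":
                pval = 2.0 * stats.t.sf(abs(z), df)
            else:
                pval = 2.0 * stats.norm.sf(abs(z))
        else:
            pval = 1.0
        lo, hi = beta - Z95 * se, beta + Z95 * se
        or_scale = (np.exp(beta), np.exp(lo), np.exp(hi)) if binary else None
        return cls(method=method, beta=float(beta), se=float(se),
                   ci_low=float(lo), ci_high=float(hi),
                   pval=float(max(min(pval, 1.0), 5e-324)), n_snp=int(n_snp),
                   or_scale=or_scale)


@dataclass
class HeterogeneityReport:
    """Cochran's Q, the Egger intercept, and MR-PRESSO outputs."""

    q: float
    df: int
    pval: float
    egger_intercept: CausalEstimate | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)


def _ratios(hset: HarmonizedInstrumentSet):
    bx, sx, by, sy = hset.arrays()
    if np.any(bx == 0):
        raise ValueError("null instrument")
    b = by / bx
    # first-order delta-method variance of each ratio
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    return b, var, (bx, sx, by, sy)


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               binary: bool = False) -> CausalEstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if beta_x == 0:
        raise ValueError("null instrument")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return CausalEstimate.from_beta_se("wald", beta, se, 1, binary=binary)


def ivw(hset: HarmonizedInstrumentSet, mode: str = "multiplicative_random",
        binary: bool = False) -> CausalEstimate:
    """Inverse-variance-weighted estimate: WLS of beta_Y on beta_X through
    the origin with weights 1/se_Y^2.

    ``multiplicative_random`` multiplies the fixed-effect SE by
    ``max(1, sqrt(Q/(n-1)))``; with a single instrument it reduces exactly
    to the Wald ratio.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode: {mode}")
    bx, sx, by, sy = hset.arrays()
    n = len(bx)
    if n == 0:
        raise ValueError("empty instrument set")
    if np.any(bx == 0):
        raise ValueError("null instrument")
    w = sy**-2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    if mode == "multiplicative_random" and n >= 2:
        q = float(np.sum((bx**2 / sy**2) * (by / bx - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (n - 1)))
    return CausalEstimate.from_beta_se("ivw", beta, se, n, binary=binary)


def _orient(bx, by):
    """Flip instrument signs so every beta_exposure is non-negative."""
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def mr_egger(hset: HarmonizedInstrumentSet, binary: bool = False
             ) -> tuple[CausalEstimate, CausalEstimate]:
    """MR-Egger WLS with intercept; the intercept tests directional pleiotropy.

    Instruments are oriented so all beta_exposure >= 0 before fitting
    (the intercept is not orientation-invariant). SEs carry a multiplicative
    overdispersion factor floored at 1; p-values use t with n-2 df.
    """
    bx, sx, by, sy = hset.arrays()
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, by = _orient(bx, by)
    w = sy**-2
    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    cov_unit = np.linalg.inv(XtW @ X)
    coef = cov_unit @ (XtW @ by)
    resid = by - X @ coef
    scale = float(np.sum(w * resid**2)) / (n - 2)
    cov = cov_unit * max(1.0, scale)
    se = np.sqrt(np.diag(cov))
    slope = CausalEstimate.from_beta_se("egger_slope", coef[1], se[1], n,
                                        dist="t", df=n - 2, binary=binary)
    intercept = CausalEstimate.from_beta_se("egger_intercept", coef[0], se[0], n,
                                            dist="t", df=n - 2)
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation between order
    statistics (cumulative weight centred on each observation)."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed: int = 0, binary: bool = False) -> CausalEstimate:
    """Weighted-median estimator; consistent when valid instruments carry
    more than half the total inverse-variance weight. SE by parametric
    bootstrap of the per-SNP betas."""
    b, var, (bx, sx, by, sy) = _ratios(hset)
    n = len(b)
    if n < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    w = 1.0 / var
    est = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
        b_s = by_s / bx_s
        w_s = 1.0 / (sy**2 / bx_s**2 + by_s**2 * sx**2 / bx_s**4)
        boots[k] = _weighted_median(b_s, w_s)
    se = float(np.std(boots, ddof=1))
    return CausalEstimate.from_beta_se("weighted_median", est, se, n, binary=binary)


def _mode_point(b: np.ndarray, w: np.ndarray, h: float) -> float:
    """Argmax of a weighted normal-kernel density on a 512-point grid."""
    if h <= 0:
        return float(b[0])
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 512)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(hset: HarmonizedInstrumentSet, kind: str = "weighted",
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0, binary: bool = False) -> CausalEstimate:
    """Mode-based estimate: the argmax of a kernel density over per-SNP
    ratios (inverse-variance weighted for ``kind='weighted'``), with
    Silverman-style bandwidth ``factor * 0.9 * min(sd, IQR/1.349) * n^-0.2``.
    """
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown mode kind: {kind}")
    b, var, (bx, sx, by, sy) = _ratios(hset)
    n = len(b)
    if n < 3:
        raise ValueError("mode estimator requires at least 3 instruments")

    def bandwidth(vals: np.ndarray) -> float:
        sd = float(np.std(vals, ddof=1))
        iqr = float(np.subtract(*np.percentile(vals, [75, 25])))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        return bandwidth_factor * 0.9 * spread * len(vals) ** (-0.2)

    def weights(variances: np.ndarray) -> np.ndarray:
        return 1.0 / variances if kind == "weighted" else np.ones_like(variances)

    est = _mode_point(b, weights(var), bandwidth(b))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
        b_s = by_s / bx_s
        var_s = sy**2 / bx_s**2 + by_s**2 * sx**2 / bx_s**4
        boots[k] = _mode_point(b_s, weights(var_s), bandwidth(b_s))
    se = float(np.std(boots, ddof=1))
    method = "simple_mode" if kind == "simple" else "weighted_mode"
    return CausalEstimate.from_beta_se(method, est, se, n, binary=binary)


def cochran_q(hset: HarmonizedInstrumentSet) -> HeterogeneityReport:
    """Cochran's Q over per-SNP ratios around the fixed-effect IVW estimate,
    with weights beta_X^2/se_Y^2 and a chi-square(n-1) reference."""
    bx, sx, by, sy = hset.arrays()
    n = len(bx)
    if n < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    if np.any(bx == 0):
        raise ValueError("null instrument")
    w = bx**2 / sy**2
    b = by / bx
    b_ivw = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_ivw) ** 2))
    pval = float(stats.chi2.sf(q, n - 1))
    return HeterogeneityReport(q=q, df=n - 1, pval=pval)


def mr_presso(hset: HarmonizedInstrumentSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> tuple[float, list[str]]:
    """MR-PRESSO global and outlier tests.

    The observed statistic is the inverse-variance-weighted residual sum of
    squares of each SNP's outcome beta around its leave-one-out IVW
    prediction; its null distribution comes from ``n_sim`` parametric
    simulations under the fitted model. Per-SNP outliers are flagged by
    simulated residual exceedance with Bonferroni correction.
    """
    bx, sx, by, sy = hset.arrays()
    n = len(bx)
    if n < 4:
        raise ValueError("insufficient instruments for MR-PRESSO")
    w = sy**-2

    def loo_slopes(bxa, bya):
        s1 = np.sum(w * bxa * bya)
        s2 = np.sum(w * bxa**2)
        return (s1 - w * bxa * bya) / (s2 - w * bxa**2)

    b_loo = loo_slopes(bx, by)
    resid2 = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(resid2))

    rng = np.random.default_rng(seed)
    exceed_global = 0
    exceed_snp = np.zeros(n)
    for _ in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(b_loo * bx, sy)
        b_loo_s = loo_slopes(bx_s, by_s)
        r2_s = w * (by_s - b_loo_s * bx_s) ** 2
        if np.sum(r2_s) >= rss_obs:
            exceed_global += 1
        exceed_snp += r2_s >= resid2
    global_p = (1 + exceed_global) / (n_sim + 1)
    p_snp = exceed_snp / n_sim
    cutoff = outlier_alpha / n
    outliers = [hset.instruments[i].snp_id for i in range(n) if p_snp[i] < cutoff]
    return float(global_p), outliers


def run_mr_suite(hset: HarmonizedInstrumentSet, seed: int = 0,
                 n_boot: int = 1000, n_presso: int = 1000,
                 ivw_mode: str = "multiplicative_random",
                 binary: bool = False) -> dict:
    """Run every applicable estimator and diagnostic on one instrument set.

    Degrades gracefully: a single instrument yields only the Wald ratio;
    methods whose preconditions fail are recorded as ``not computed`` with
    the reason, and never abort the suite. ``direction_concordant`` is true
    iff every computed point estimate shares the IVW (or Wald) sign.
    """
    n = hset.n_snp
    estimates: dict[str, CausalEstimate] = {}
    not_computed: dict[str, str] = {}

    def attempt(name, fn):
        try:
            estimates[name] = fn()
        except (ValueError, np.linalg.LinAlgError) as exc:
            not_computed[name] = str(exc)

    if n == 0:
        raise ValueError("empty instrument set")
    if n == 1:
        i = hset.instruments[0]
        attempt("wald", lambda: wald_ratio(i.beta_exposure, i.se_exposure,
                                           i.beta_outcome, i.se_outcome, binary=binary))
        primary = estimates.get("wald")
    else:
        attempt("ivw", lambda: ivw(hset, mode=ivw_mode, binary=binary))
        primary = estimates.get("ivw")

    het = None
    egger_intercept = None
    if n >= 2:
        try:
            het = cochran_q(hset)
        except ValueError as exc:
            not_computed["cochran_q"] = str(exc)
    if n >= 3:
        def egger():
            nonlocal egger_intercept
            slope, egger_intercept = mr_egger(hset, binary=binary)
            return slope
        attempt("egger_slope", egger)
        attempt("weighted_median",
                lambda: weighted_median(hset, n_boot=n_boot, seed=seed, binary=binary))
        attempt("simple_mode",
                lambda: mode_estimate(hset, kind="simple", n_boot=n_boot,
                                      seed=seed + 1, binary=binary))
        attempt("weighted_mode",
                lambda: mode_estimate(hset, kind="weighted", n_boot=n_boot,
                                      seed=seed + 2, binary=binary))
    presso_p, presso_out = None, []
    if n >= 4:
        try:
            presso_p, presso_out = mr_presso(hset, n_sim=n_presso, seed=seed + 3)
        except ValueError as exc:
            not_computed["mr_presso"] = str(exc)
    if het is not None:
        het.egger_intercept = egger_intercept
        het.presso_global_p = presso_p
        het.presso_outliers = presso_out

    concordant = None
    if primary is not None:
        ref = np.sign(primary.beta)
        concordant = all(np.sign(e.beta) == ref or e.beta == 0
                         for e in estimates.values())
    return {
        "estimates": estimates,
        "heterogeneity": het,
        "egger_intercept": egger_intercept,
        "not_computed": not_computed,
        "direction_concordant": concordant,
        "n_snp": n,
    }
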
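"""GWAS/eQTL summary-statistic data model, I/O, harmonization, and LD clumping.

The central objects are :class:`SumstatsTable` (one trait's per-SNP marginal
effects), :class:`LDMatrix` (pairwise correlations for a region or panel),
:class:`RegionPanel` (one trait's statistics over an ordered SNP window, the
input to SMR/HEIDI and colocalization) and :class:`HarmonizedInstrumentSet`
(exposure/outcome effects aligned to a common effect allele, the input to the
MR estimators).

Conventions: coordinates are 1-based with closed intervals; betas are
log-odds for binary traits and trait-SD or expression units otherwise;
thresholds are strict (``pval < p_threshold``, ``maf > maf_threshold``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the tab-separated summary-statistic format
CANONICAL_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n"]

#: columns that must be present (directly or via a dialect map)
MANDATORY_COLUMNS = ["snp", "a1", "a2", "beta", "se", "p"]

#: relative tolerance for the p-value vs |beta/se| consistency check
PVAL_RTOL = 0.10


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's marginal summary statistic for one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty means valid)."""
        out = []
        if self.effect_allele == self.other_allele:
            out.append("identical-alleles")
        if not (self.se > 0):
            out.append("nonpositive-se")
        if np.isfinite(self.eaf) and not (0.0 < self.eaf < 1.0):
            out.append("eaf-out-of-range")
        if not (0.0 < self.pval <= 1.0):
            out.append("pval-out-of-range")
        elif self.se > 0 and np.isfinite(self.beta):
            expected = 2.0 * stats.norm.sf(abs(self.beta / self.se))
            # compare only where the normal p is representable; 10% relative
            if expected > 1e-290 and self.pval > 1e-290:
                if abs(self.pval - expected) > PVAL_RTOL * expected:
                    out.append("pval-inconsistent")
        return out


@dataclass
class SumstatsTable:
    """Per-SNP summary statistics for a single trait, unique by snp_id."""

    trait_id: str
    trait_type: str  # "binary" or "quantitative"
    df: pd.DataFrame  # canonical columns, one row per SNP
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type: {self.trait_type}")
        if self.df["snp"].duplicated().any():
            dupes = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp_id: {dupes[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def get(self, snp_id: str) -> VariantAssociation:
        sub = self.df[self.df["snp"] == snp_id]
        if sub.empty:
            raise KeyError(snp_id)
        r = sub.iloc[0]
        return VariantAssociation(
            snp_id=r["snp"], chrom=str(r["chr"]), pos=int(r["pos"]),
            effect_allele=r["a1"], other_allele=r["a2"], eaf=float(r["eaf"]),
            beta=float(r["beta"]), se=float(r["se"]), pval=float(r["p"]),
            n=int(r["n"]),
        )

    def restrict(self, snp_ids: Iterable[str]) -> "SumstatsTable":
        keep = set(snp_ids)
        return SumstatsTable(self.trait_id, self.trait_type,
                             self.df[self.df["snp"].isin(keep)].copy())

    def exclude_region(self, predicate: Callable[[str, int], bool]) -> "SumstatsTable":
        """Drop all SNPs for which ``predicate(chrom, pos)`` is true."""
        mask = [
            not predicate(str(c), int(p))
            for c, p in zip(self.df["chr"], self.df["pos"])
        ]
        return SumstatsTable(self.trait_id, self.trait_type, self.df[mask].copy())


class Instrument(NamedTuple):
    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects aligned to a common effect allele per SNP."""

    exposure_id: str
    outcome_id: str
    instruments: list[Instrument]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exposure, se_exposure, beta_outcome, se_outcome)."""
        a = np.array([[i.beta_exposure, i.se_exposure, i.beta_outcome, i.se_outcome]
                      for i in self.instruments], dtype=float)
        if a.size == 0:
            a = a.reshape(0, 4)
        return a[:, 0], a[:, 1], a[:, 2], a[:, 3]

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        keep = set(snp_ids)
        return HarmonizedInstrumentSet(
            self.exposure_id, self.outcome_id,
            [i for i in self.instruments if i.snp_id in keep], list(self.dropped))


@dataclass
class LDMatrix:
    """Pairwise LD correlations (signed r) over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        w = np.linalg.eigvalsh((self.r + self.r.T) / 2.0)
        if w.min() < -1e-8:
            raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r_value(self, a: str, b: str) -> float | None:
        """Signed correlation between two SNPs; None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib])

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


@dataclass
class RegionPanel:
    """One trait's summary statistics over an ordered window of SNPs.

    Units: ``beta``/``se`` on the trait scale (log-odds for binary traits);
    ``n`` is the study sample size. Alleles and positions are optional but
    required for cross-panel harmonization and region predicates.
    """

    trait_id: str
    trait_type: str
    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    eaf: np.ndarray
    n: int
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    pos: np.ndarray | None = None
    chrom: str | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        k = len(self.snp_ids)
        if not (len(self.beta) == len(self.se) == len(self.eaf) == k):
            raise ValueError("RegionPanel vector lengths differ")
        if np.any(self.se <= 0):
            raise ValueError("RegionPanel requires se > 0 elementwise")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pval(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def subset(self, indices: Sequence[int]) -> "RegionPanel":
        idx = np.asarray(indices, dtype=int)
        return RegionPanel(
            trait_id=self.trait_id, trait_type=self.trait_type,
            snp_ids=[self.snp_ids[i] for i in idx],
            beta=self.beta[idx], se=self.se[idx], eaf=self.eaf[idx], n=self.n,
            effect_allele=None if self.effect_allele is None else np.asarray(self.effect_allele)[idx],
            other_allele=None if self.other_allele is None else np.asarray(self.other_allele)[idx],
            pos=None if self.pos is None else np.asarray(self.pos)[idx],
            chrom=self.chrom)

    def to_sumstats(self) -> SumstatsTable:
        df = pd.DataFrame({
            "snp": self.snp_ids,
            "chr": self.chrom if self.chrom is not None else "1",
            "pos": self.pos if self.pos is not None else np.arange(1, len(self) + 1),
            "a1": self.effect_allele if self.effect_allele is not None else "A",
            "a2": self.other_allele if self.other_allele is not None else "G",
            "eaf": self.eaf, "beta": self.beta, "se": self.se,
            "p": self.pval, "n": self.n,
        })
        return SumstatsTable(self.trait_id, self.trait_type, df)


# ---------------------------------------------------------------------------
# file I/O


def _open(path, mode="rt"):
    p = str(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


def read_sumstats(path, trait_type: str, dialect: dict | None = None,
                  trait_id: str | None = None) -> SumstatsTable:
    """Read a tab-separated summary-statistic file into a :class:`SumstatsTable`.

    ``dialect`` maps canonical column names (``snp``, ``chr``, ``pos``, ``a1``,
    ``a2``, ``eaf``, ``beta``, ``se``, ``p``, ``n``) to the file's header
    names. Mandatory columns missing from the header raise; rows that fail a
    per-variant invariant (or do not parse numerically) are dropped and
    counted by reason.
    """
    dialect = dialect or {}
    with _open(path) as fh:
        raw = pd.read_csv(fh, sep="\t", dtype=str)
    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing column: {col}")
    for col in CANONICAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[CANONICAL_COLUMNS]

    numeric = ["pos", "eaf", "beta", "se", "p", "n"]
    parsed = raw.copy()
    for col in numeric:
        parsed[col] = pd.to_numeric(parsed[col], errors="coerce")
    parsed["a1"] = parsed["a1"].astype(str).str.upper()
    parsed["a2"] = parsed["a2"].astype(str).str.upper()
    parsed["chr"] = parsed["chr"].astype(str)
    parsed["pos"] = parsed["pos"].fillna(0).astype(np.int64)
    parsed["n"] = parsed["n"].fillna(0).astype(np.int64)
    parsed["eaf"] = parsed["eaf"].fillna(np.nan)

    reasons: dict[str, int] = {}
    keep = np.ones(len(parsed), dtype=bool)
    for i, row in parsed.iterrows():
        if not (np.isfinite(row["beta"]) and np.isfinite(row["se"])
                and np.isfinite(row["p"])):
            keep[i] = False
            reasons["unparseable-numeric"] = reasons.get("unparseable-numeric", 0) + 1
            continue
        va = VariantAssociation(
            snp_id=row["snp"], chrom=row["chr"], pos=int(row["pos"]),
            effect_allele=row["a1"], other_allele=row["a2"],
            eaf=float(row["eaf"]) if np.isfinite(row["eaf"]) else np.nan,
            beta=float(row["beta"]), se=float(row["se"]),
            pval=float(row["p"]), n=int(row["n"]))
        viol = va.violations()
        if viol:
            keep[i] = False
            for v in viol:
                reasons[v] = reasons.get(v, 0) + 1
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d rows (%s)", path, dropped, reasons)
    table = SumstatsTable(
        trait_id=trait_id or str(path), trait_type=trait_type,
        df=parsed[keep].reset_index(drop=True),
        n_dropped=dropped, drop_reasons=reasons)
    return table


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write the canonical tab-separated layout (full float precision)."""
    df = table.df[CANONICAL_COLUMNS].copy()
    with _open(path, "wt") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fields = [
                str(row.snp), str(row.chr), str(int(row.pos)),
                str(row.a1), str(row.a2), _fmt(row.eaf), _fmt(row.beta),
                _fmt(row.se), _fmt(row.p), str(int(row.n)),
            ]
            fh.write("\t".join(fields) + "\n")


def _fmt(x: float) -> str:
    return "nan" if not np.isfinite(x) else repr(float(x))


def read_ld_matrix(path) -> LDMatrix:
    """Read the LD format: first line SNP IDs, then the square matrix."""
    with _open(path) as fh:
        header = fh.readline().split()
        rows = [list(map(float, line.split())) for line in fh if line.strip()]
    return LDMatrix(header, np.array(rows, dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with _open(path, "wt") as fh:
        fh.write(" ".join(ld.snp_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# instrument selection / clumping / windows


def select_instruments(table: SumstatsTable, p_threshold: float = 5e-8,
                       maf_threshold: float = 0.01) -> list[str]:
    """SNPs with ``pval < p_threshold`` and ``min(eaf, 1-eaf) > maf_threshold``."""
    if not (0 < p_threshold < 1) or not (0 < maf_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    df = table.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    mask = (df["p"] < p_threshold) & (maf > maf_threshold)
    return df.loc[mask.fillna(False), "snp"].tolist()


def clump(table: SumstatsTable, ld: LDMatrix | None,
          r2_threshold: float = 0.001, window_kb: float = 10000) -> list[str]:
    """Greedy p-value clumping.

    Candidates are visited in ascending p (ties broken by chrom, pos, snp_id);
    a SNP is accepted iff no already-accepted SNP on the same chromosome lies
    within ``window_kb`` kilobases *and* has r² above ``r2_threshold`` with it.
    SNPs absent from the LD matrix are treated as independent (and logged).
    """
    df = table.df.sort_values(["p", "chr", "pos", "snp"], kind="mergesort")
    window_bp = window_kb * 1000.0
    accepted: list[tuple[str, str, int]] = []  # (snp, chrom, pos)
    missing_ld = []
    for row in df.itertuples(index=False):
        ok = True
        for snp_a, chr_a, pos_a in accepted:
            if str(row.chr) != chr_a or abs(int(row.pos) - pos_a) > window_bp:
                continue
            r = None if ld is None else ld.r_value(row.snp, snp_a)
            if r is None:
                missing_ld.append(row.snp)
                continue
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            accepted.append((row.snp, str(row.chr), int(row.pos)))
    if missing_ld:
        logger.info("clump: %d SNP pairs lacked LD entries; treated as independent",
                    len(missing_ld))
    return [a[0] for a in accepted]


def cis_window(gene_pos: tuple[str, int, int], flank_bp: int = 1_000_000
               ) -> Callable[[str, int], bool]:
    """Closed-interval cis predicate: same chrom, pos in [start-flank, end+flank]."""
    chrom, start, end = gene_pos
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    if start > end:
        raise ValueError("gene start exceeds end")
    lo, hi = start - flank_bp, end + flank_bp

    def predicate(snp_chrom: str, snp_pos: int) -> bool:
        return str(snp_chrom) == str(chrom) and lo <= snp_pos <= hi

    return predicate


# ---------------------------------------------------------------------------
# allele harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(exposure: SumstatsTable, outcome: SumstatsTable,
              snps: Sequence[str], palindrome_eaf_band: float = 0.08
              ) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele per instrument.

    Swapped alleles negate the outcome beta (and flip its eaf); strand flips
    (A<->T, C<->G complements) are resolved before the swap rule. Palindromic
    SNPs are kept only when both traits' eaf lie outside
    ``[0.5-band, 0.5+band]`` and on the same side of 0.5; otherwise dropped
    as ``palindromic-ambiguous``. Irreconcilable alleles or missing outcome
    rows are dropped with reasons; the union of kept and dropped equals the
    requested SNP list.
    """
    if not (0.0 <= palindrome_eaf_band < 0.5):
        raise ValueError("palindrome_eaf_band must lie in [0, 0.5)")
    out_idx = outcome.df.set_index("snp")
    exp_idx = exposure.df.set_index("snp")
    instruments: list[Instrument] = []
    dropped: list[tuple[str, str]] = []
    for snp in snps:
        if snp not in exp_idx.index:
            dropped.append((snp, "missing-exposure"))
            continue
        if snp not in out_idx.index:
            dropped.append((snp, "missing-outcome"))
            continue
        e = exp_idx.loc[snp]
        o = out_idx.loc[snp]
        ea1, ea2 = str(e["a1"]), str(e["a2"])
        ob1, ob2 = str(o["a1"]), str(o["a2"])
        o_beta, o_eaf, o_se = float(o["beta"]), float(o["eaf"]), float(o["se"])
        if o_se <= 0 or float(e["se"]) <= 0:
            dropped.append((snp, "nonpositive-se"))
            continue
        pal = _is_palindromic(ea1, ea2)
        if not pal:
            cb1, cb2 = COMPLEMENT.get(ob1), COMPLEMENT.get(ob2)
            if (ob1, ob2) == (ea1, ea2):
                pass
            elif (ob1, ob2) == (ea2, ea1):
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
            elif (cb1, cb2) == (ea1, ea2):
                pass  # strand flip only
            elif (cb1, cb2) == (ea2, ea1):
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
            else:
                dropped.append((snp, "allele-mismatch"))
                continue
        else:
            if {ob1, ob2} != {ea1, ea2}:
                dropped.append((snp, "allele-mismatch"))
                continue
            if (ob1, ob2) == (ea2, ea1):
                o_beta, o_eaf = -o_beta, 1.0 - o_eaf
            e_eaf = float(e["eaf"])
            lo, hi = 0.5 - palindrome_eaf_band, 0.5 + palindrome_eaf_band
            inside = (lo <= e_eaf <= hi) or (lo <= o_eaf <= hi)
            same_side = (e_eaf - 0.5) * (o_eaf - 0.5) > 0
            if inside or not same_side or not np.isfinite(e_eaf) or not np.isfinite(o_eaf):
                dropped.append((snp, "palindromic-ambiguous"))
                continue
        instruments.append(Instrument(
            snp_id=snp, beta_exposure=float(e["beta"]), se_exposure=float(e["se"]),
            beta_outcome=o_beta, se_outcome=o_se, eaf=float(e["eaf"])))
    return HarmonizedInstrumentSet(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        instruments=instruments, dropped=dropped)
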
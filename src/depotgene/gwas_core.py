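"""Common-variant association core.

Variant QC (array and imputed modes), covariate-adjusted least-squares
association scanning of inverse-normal-transformed traits, greedy LD
clumping of summary statistics into loci, novelty flagging against a
catalog, the genomic-control inflation factor, sequential Bonferroni
thresholds, and directional replication concordance.

The association engine is covariate-adjusted OLS: with unrelated
individuals (as produced by the synthetic cohort generator) this is the
statistical equivalent of a mixed-model scan, without the random effect
machinery that only matters under relatedness or strong structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DataError, InsufficientDataError

log = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

SUMSTAT_COLUMNS = [
    "CHR", "BP", "SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "TRAIT", "STRATUM",
]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value from hard genotype counts.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the conditional probabilities no larger than that of
    the observed configuration (two-sided exact test).  Computed with a
    stable recurrence so the far tail (thresholds as extreme as 1e-15)
    is meaningful.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise DataError("negative genotype count")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0 or rare == 0:
        return 1.0

    # unnormalized log-probabilities over het counts of the right parity
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    valid = homc >= 0
    hets, homr, homc = hets[valid], homr[valid], homc[valid]
    logp = (
        hets * math.log(2.0)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        - gammaln(hets + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_from_dosages(dos: np.ndarray) -> float:
    hard = np.rint(dos).astype(int)
    return hwe_exact_pvalue(
        int((hard == 1).sum()), int((hard == 0).sum()), int((hard == 2).sum())
    )


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------


def variant_qc_common(
    genotypes: pd.DataFrame,
    mode: str = "array",
    info: pd.Series | None = None,
    maf_min_array: float = 0.01,
    hwe_min: float = 1e-15,
    call_rate_min: float = 0.99,
    maf_min_imputed: float = 0.005,
    info_min: float = 0.3,
) -> pd.DataFrame:
    """Per-variant QC over a (samples x variants) dosage frame.

    Array mode keeps variants with MAF >= 1%, HWE exact p > 1e-15 (on
    hard-called counts) and call rate >= 99%.  Imputed mode drops
    variants with MAF < 0.005 or INFO < 0.3.  Returns a per-variant
    report with a ``keep`` flag and the reason for any drop.
    """
    if mode not in ("array", "imputed"):
        raise ValueError(f"unknown QC mode {mode!r}")
    rows = []
    for snp in genotypes.columns:
        dos = genotypes[snp].to_numpy(float)
        present = np.isfinite(dos)
        d = dos[present]
        if d.size and (d.min() < 0 or d.max() > 2):
            raise DataError(f"dosage outside [0, 2] for {snp}")
        call_rate = present.mean() if dos.size else 0.0
        af = d.mean() / 2.0 if d.size else np.nan
        maf = min(af, 1 - af) if np.isfinite(af) else 0.0
        reason = ""
        if mode == "array":
            hwe_p = _hwe_from_dosages(d) if d.size else 1.0
            if maf < maf_min_array:
                reason = "maf"
            elif hwe_p <= hwe_min:
                reason = "hwe"
            elif call_rate < call_rate_min:
                reason = "call_rate"
        else:
            hwe_p = np.nan
            snp_info = info.get(snp, np.nan) if info is not None else np.nan
            if maf < maf_min_imputed:
                reason = "maf"
            elif np.isfinite(snp_info) and snp_info < info_min:
                reason = "info"
        rows.append(
            {
                "SNP": snp,
                "maf": maf,
                "call_rate": call_rate,
                "hwe_p": hwe_p,
                "keep": reason == "",
                "drop_reason": reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------


def association_scan(
    genotypes: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    snp_info: pd.DataFrame | None = None,
    trait_name: str = "trait",
    stratum: str = "combined",
    chunk_size: int = 4096,
) -> pd.DataFrame:
    """Per-variant least-squares association of an INT trait.

    For each variant, fits trait ~ 1 + dosage + covariates and reports
    the dosage coefficient (BETA), its SE and the two-sided t-test P.
    Missing dosages are mean-imputed per variant; variants monomorphic
    after imputation are skipped with a log entry.  Implemented via
    projection onto the covariate complement, so the scan is a pair of
    matrix products per chunk.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n < 30:
        raise InsufficientDataError("need >= 30 individuals")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    p_cov = Q.shape[1]
    y_r = y - Q @ (Q.T @ y)
    df_resid = n - p_cov - 1

    snp_ids = list(genotypes.columns)
    out = {k: [] for k in ("SNP", "EAF", "BETA", "SE", "P", "degenerate")}
    skipped: list[str] = []
    for start in range(0, len(snp_ids), chunk_size):
        G = genotypes.iloc[:, start : start + chunk_size].to_numpy(
            dtype=float, na_value=np.nan
        )
        miss = np.isnan(G)
        if miss.any():
            col_mean = np.nanmean(G, axis=0)
            G[miss] = np.take(col_mean, np.nonzero(miss)[1])
        eaf = G.mean(axis=0) / 2.0
        G_r = G - Q @ (Q.T @ G)
        gg = (G_r * G_r).sum(axis=0)
        gy = G_r.T @ y_r
        ok = gg > 1e-12
        beta = np.full(gg.shape, np.nan)
        beta[ok] = gy[ok] / gg[ok]
        rss = (y_r @ y_r) - beta**2 * gg
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df_resid
        se = np.sqrt(np.where(ok, sigma2 / np.where(ok, gg, 1.0), np.nan))
        degenerate = ok & (sigma2 <= 1e-12 * max(y_r @ y_r / n, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        for j, snp in enumerate(snp_ids[start : start + chunk_size]):
            if not ok[j]:
                skipped.append(snp)
                continue
            out["SNP"].append(snp)
            out["EAF"].append(eaf[j])
            out["BETA"].append(beta[j])
            out["SE"].append(se[j])
            out["P"].append(min(pvals[j], 1.0) if np.isfinite(pvals[j]) else np.nan)
            out["degenerate"].append(bool(degenerate[j]))
    if skipped:
        log.warning("skipped %d zero-variance variants: %s ...", len(skipped), skipped[:5])

    res = pd.DataFrame(out)
    res["N"] = n
    res["TRAIT"] = trait_name
    res["STRATUM"] = stratum
    if snp_info is not None:
        res = res.merge(
            snp_info[[c for c in ("SNP", "CHR", "BP", "EA", "OA") if c in snp_info]],
            on="SNP",
            how="left",
        )
    return res


# ---------------------------------------------------------------------------
# LD lookup + clumping
# ---------------------------------------------------------------------------


class LdTable:
    """Symmetric r² lookup.

    Built from a long table (snp_a, snp_b, r2) or a square DataFrame.
    Missing pairs are treated as r² = 0 (warned once); ``knows`` tells
    whether a SNP appears in the table at all.
    """

    def __init__(self, pairs: dict[tuple[str, str], float], ids: set[str]):
        self._pairs = pairs
        self._ids = ids
        self._warned = False

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "LdTable":
        pairs: dict[tuple[str, str], float] = {}
        ids: set[str] = set()
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
            key = (a, b) if a <= b else (b, a)
            pairs[key] = float(r2)
            ids.add(a)
            ids.add(b)
        return cls(pairs, ids)

    @classmethod
    def from_square(cls, df: pd.DataFrame) -> "LdTable":
        long = df.stack().reset_index()
        long.columns = ["snp_a", "snp_b", "r2"]
        return cls.from_long(long[long["snp_a"] != long["snp_b"]])

    def knows(self, snp: str) -> bool:
        return snp in self._ids

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        val = self._pairs.get(key)
        if val is None:
            if not self._warned:
                log.warning("missing LD entry (e.g. %s-%s); treating as r2=0", a, b)
                self._warned = True
            return 0.0
        return val


@dataclass(frozen=True)
class ClumpConfig:
    """PLINK-style clumping parameters."""

    p1: float = 5e-8
    p2: float = 5e-6
    r2: float = 0.1
    window_kb: float = 1000.0

    def __post_init__(self):
        if self.p1 > self.p2:
            raise ValueError("p1 must be <= p2")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")


@dataclass
class Locus:
    """A lead SNP and the correlated variants assigned to it."""

    lead: pd.Series
    members: list[str] = field(default_factory=list)
    trait: str | None = None
    stratum: str | None = None
    novel: bool | None = None


def ld_clump(stats_df: pd.DataFrame, ld: LdTable, cfg: ClumpConfig = ClumpConfig()) -> list[Locus]:
    """Greedy LD clumping of summary statistics into loci.

    Repeatedly takes the lowest-p unassigned SNP with p < p1 as a lead,
    assigning to it every unassigned SNP with p < p2, within the window,
    and r² > the threshold with the lead.  Ties in p are broken by
    (CHR, BP) ascending, so output is deterministic.
    """
    df = stats_df.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    assigned: set[str] = set()
    loci: list[Locus] = []
    for _, row in df.iterrows():
        if row["P"] >= cfg.p1:
            break
        if row["SNP"] in assigned:
            continue
        assigned.add(row["SNP"])
        members = []
        near = df[
            (df["CHR"] == row["CHR"])
            & ((df["BP"] - row["BP"]).abs() <= cfg.window_kb * 1000)
            & (df["P"] < cfg.p2)
        ]
        for _, cand in near.iterrows():
            if cand["SNP"] in assigned:
                continue
            if ld.r2(row["SNP"], cand["SNP"]) > cfg.r2:
                members.append(cand["SNP"])
                assigned.add(cand["SNP"])
        loci.append(
            Locus(
                lead=row,
                members=members,
                trait=row.get("TRAIT"),
                stratum=row.get("STRATUM"),
            )
        )
    return loci


def flag_novel_loci(
    leads: list[str] | list[Locus], catalog_snps: list[str], ld: LdTable, r2_known: float = 0.1
) -> pd.DataFrame:
    """Flag lead SNPs not in LD with any catalog SNP as novel.

    A lead is novel iff its maximum r² with every catalog SNP is
    strictly below 0.1; exactly 0.1 counts as known.  Leads absent from
    the LD lookup are flagged indeterminate, never novel.
    """
    rows = []
    for lead in leads:
        snp = lead.lead["SNP"] if isinstance(lead, Locus) else lead
        if not ld.knows(snp):
            status = "indeterminate"
            max_r2 = np.nan
        else:
            max_r2 = max((ld.r2(snp, c) for c in catalog_snps), default=0.0)
            status = "novel" if max_r2 < r2_known else "known"
        rows.append({"SNP": snp, "max_catalog_r2": max_r2, "status": status})
        if isinstance(lead, Locus):
            lead.novel = status == "novel"
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics + thresholds + replication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasDiagnostics:
    lambda_gc: float
    n_tested: int


def genomic_inflation(pvals) -> GwasDiagnostics:
    """Genomic-control inflation factor from association p-values.

    Converts p-values to 1-df chi-square quantiles and divides their
    median by the null chi-square median (~0.4549).
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise InsufficientDataError("need >= 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return GwasDiagnostics(float(np.median(chi2) / CHI2_1_MEDIAN), int(p.size))


@dataclass(frozen=True)
class BonferroniThreshold:
    value: float  # unrounded
    display: float  # rounded to 2 significant figures

    def __float__(self):
        return self.value


def bonferroni_threshold(alpha: float, counts: list[int]) -> BonferroniThreshold:
    """Sequential Bonferroni division of alpha by each count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    value = alpha
    for c in counts:
        if int(c) <= 0:
            raise ValueError("counts must be positive")
        value /= c
    return BonferroniThreshold(value, float(f"{value:.1e}"))


def replication_concordance(pairs: pd.DataFrame) -> tuple[int, int, float]:
    """Directional concordance of effects against an external study.

    ``pairs`` has columns beta_this and beta_external, already aligned
    to the same effect allele.  Pairs with a zero beta in either source
    are excluded (logged).  Returns (n_concordant, n_total, p) with the
    two-sided exact binomial p against 0.5:
    ``min(1, 2 * P(X >= max(k, n - k)))``.
    """
    b1 = pairs["beta_this"].to_numpy(float)
    b2 = pairs["beta_external"].to_numpy(float)
    nonzero = (b1 != 0) & (b2 != 0)
    if (~nonzero).any():
        log.warning("excluding %d pairs with a zero beta", int((~nonzero).sum()))
    b1, b2 = b1[nonzero], b2[nonzero]
    n = b1.size
    k = int((np.sign(b1) == np.sign(b2)).sum())
    m = max(k, n - k)
    p = min(1.0, 2.0 * stats.binom.sf(m - 1, n, 0.5))
    return k, n, float(p)
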
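"""Rare-variant burden testing with weighted gene masks.

Exome genotype calls pass a per-call filter (read depth, genotype
quality, allele balance, Phred likelihoods), variants pass a
region/HWE/call-rate filter, and rare (cohort MAF < 0.1%) qualifying
variants are aggregated per gene into a capped weighted burden score.

Two masks are used: pLoF (high-confidence predicted loss-of-function,
weight 1) and pLoF + damaging missense, where missense variants carry a
gene-specific weight derived from the ratio of the two masks'
cumulative allele frequencies,

    w_missense = min(1, sqrt( f_L (1 - f_L) / ( f_M (1 - f_M) ) )),

with w = 1 when a gene has no high-confidence pLoF variants.  An
individual's gene score is the weighted dosage sum over qualifying
variants, capped at one, and the burden test is a covariate-adjusted
least-squares regression of the INT phenotype on the score, restricted
to genes with at least ten carriers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InvalidValueError
from .gwas_core import bonferroni_threshold, hwe_exact_pvalue

log = logging.getLogger(__name__)

MASK_PLOF = "pLoF"
MASK_PLOF_MISSENSE = "pLoF+missense"
CLASS_PLOF = "pLoF_HC"
CLASS_MISSENSE = "missense_5of5"


# ---------------------------------------------------------------------------
# genotype-call filter
# ---------------------------------------------------------------------------


def genotype_call_filter(calls: pd.DataFrame) -> pd.Series:
    """Per-call verdicts: ``keep`` or ``set_missing``.

    ``calls`` columns: genotype (hom_ref/het/hom_alt/missing), DP, GQ,
    alt_ratio, PL_ref.  A call is set missing if DP <= 10 or DP >= 200;
    if hom_ref with GQ <= 20 or alt allele balance > 0.1; if het with
    balance < 0.2 or PL of the reference allele < 20; if hom_alt with
    balance < 0.9 or PL_ref < 20.  Rows with missing quality fields are
    set missing (logged).  Total function; idempotent on its output.
    """
    g = calls["genotype"]
    dp = pd.to_numeric(calls["DP"], errors="coerce")
    gq = pd.to_numeric(calls.get("GQ"), errors="coerce")
    ab = pd.to_numeric(calls.get("alt_ratio"), errors="coerce")
    pl = pd.to_numeric(calls.get("PL_ref"), errors="coerce")

    missing_fields = dp.isna() | (
        g.map({"hom_ref": 0, "het": 1, "hom_alt": 2}).notna()
        & (
            (g.eq("hom_ref") & (gq.isna() | ab.isna()))
            | (g.eq("het") & (ab.isna() | pl.isna()))
            | (g.eq("hom_alt") & (ab.isna() | pl.isna()))
        )
    )
    if missing_fields.any():
        log.warning("%d calls with missing quality fields set to missing", int(missing_fields.sum()))

    bad = (
        missing_fields
        | g.eq("missing")
        | (dp <= 10)
        | (dp >= 200)
        | (g.eq("hom_ref") & ((gq <= 20) | (ab > 0.1)))
        | (g.eq("het") & ((ab < 0.2) | (pl < 20)))
        | (g.eq("hom_alt") & ((ab < 0.9) | (pl < 20)))
    )
    return pd.Series(np.where(bad, "set_missing", "keep"), index=calls.index, name="verdict")


# ---------------------------------------------------------------------------
# variant-level QC
# ---------------------------------------------------------------------------


def _in_regions(chrom, pos, regions: pd.DataFrame) -> bool:
    sub = regions[regions["chrom"].astype(str) == str(chrom)]
    # BED half-open [start, end)
    return bool(((sub["start"] < pos + 1) & (pos < sub["end"])).any())


def rare_variant_qc(
    variant_stats: pd.DataFrame, exclusion_regions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Variant keep/drop decisions after the genotype-call filter.

    ``variant_stats`` columns: variant_id, chrom, pos (1-based), and
    post-filter counts n_hom_ref, n_het, n_hom_alt, n_missing.  Drops
    variants overlapping an exclusion region (BED frame with chrom,
    start, end), with HWE exact p < 1e-15, call rate < 90%, or
    monomorphic after call filtering.
    """
    if exclusion_regions is not None:
        for col in ("chrom", "start", "end"):
            if col not in exclusion_regions.columns:
                raise DataError(f"exclusion regions missing column {col!r}")
    rows = []
    for _, v in variant_stats.iterrows():
        n_called = v["n_hom_ref"] + v["n_het"] + v["n_hom_alt"]
        total = n_called + v["n_missing"]
        call_rate = n_called / total if total else 0.0
        alt = v["n_het"] + 2 * v["n_hom_alt"]
        reason = ""
        if exclusion_regions is not None and _in_regions(v["chrom"], v["pos"], exclusion_regions):
            reason = "excluded_region"
        elif hwe_exact_pvalue(v["n_het"], v["n_hom_ref"], v["n_hom_alt"]) < 1e-15:
            reason = "hwe"
        elif call_rate < 0.90:
            reason = "call_rate"
        elif alt == 0 or alt == 2 * n_called:
            reason = "monomorphic"
        rows.append({"variant_id": v["variant_id"], "keep": reason == "", "drop_reason": reason})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Eq-style missense weight and burden scores
# ---------------------------------------------------------------------------


def missense_weight(f_lof: float, f_mis: float, has_missense: bool = True) -> float:
    """Gene-specific weight for damaging-missense variants.

    ``min(1, sqrt(f_L (1 - f_L) / (f_M (1 - f_M))))``; 1.0 when the
    gene has no high-confidence pLoF variants (f_L = 0).  ``f_M = 0``
    while missense variants are claimed is an inconsistency.
    """
    if not (0 <= f_lof < 1) or not (0 <= f_mis < 1):
        raise InvalidValueError("cumulative frequencies must lie in [0, 1)")
    if f_lof == 0:
        return 1.0
    if f_mis == 0:
        if has_missense:
            raise InvalidValueError("f_M = 0 but missense variants claimed")
        return 1.0
    return float(min(1.0, np.sqrt((f_lof * (1 - f_lof)) / (f_mis * (1 - f_mis)))))


@dataclass
class GeneBurdenSet:
    """Per-sample burden scores plus per-gene mask bookkeeping."""

    scores: pd.DataFrame  # samples x genes, values in [0, 1]
    gene_info: pd.DataFrame  # gene, f_lof, f_mis, weight_missense, n_carriers
    mask: str


def gene_burden_matrix(
    genotypes: pd.DataFrame,
    annotations: pd.DataFrame,
    mask: str = MASK_PLOF_MISSENSE,
    maf_max: float = 0.001,
) -> GeneBurdenSet:
    """Capped weighted per-gene burden scores.

    ``genotypes`` is samples x variants rare-allele dosages (NaN =
    missing call; missing contributes 0 but the sample is retained);
    ``annotations`` maps variant_id to gene and class (pLoF_HC /
    missense_5of5).  Variants are restricted to cohort MAF < 0.1%
    (computed over non-missing calls); cumulative mask frequencies and
    the missense weight are computed per gene, and each sample's score
    is ``min(1, sum dosage x weight)``.
    """
    if mask not in (MASK_PLOF, MASK_PLOF_MISSENSE):
        raise ValueError(f"unknown mask {mask!r}")
    unknown = set(annotations["variant_id"]) - set(genotypes.columns)
    if unknown:
        raise DataError(f"annotated variants absent from genotypes: {sorted(unknown)[:5]}")

    G = genotypes.to_numpy(dtype=float, na_value=np.nan)
    af = np.nanmean(G, axis=0) / 2.0
    af = pd.Series(af, index=genotypes.columns)
    maf = np.minimum(af, 1 - af)

    scores = {}
    info_rows = []
    for gene, ann in annotations.groupby("gene"):
        # monomorphic-in-cohort variants carry no carriers (and would be
        # dropped by variant QC); exclude them from the mask frequencies
        ann = ann[
            (ann["variant_id"].map(maf) < maf_max) & (ann["variant_id"].map(af) > 0)
        ]
        lof_ids = list(ann.loc[ann["class"] == CLASS_PLOF, "variant_id"])
        mis_ids = list(ann.loc[ann["class"] == CLASS_MISSENSE, "variant_id"])
        f_lof = float(af[lof_ids].sum()) if lof_ids else 0.0
        f_mis = float(af[mis_ids].sum()) if mis_ids else 0.0
        w_mis = missense_weight(f_lof, f_mis, has_missense=bool(mis_ids)) if mis_ids else 1.0

        use = lof_ids if mask == MASK_PLOF else lof_ids + mis_ids
        if not use:
            continue
        weights = np.array([1.0 if v in lof_ids else w_mis for v in use])
        dose = genotypes[use].to_numpy(dtype=float, na_value=np.nan)
        dose = np.nan_to_num(dose, nan=0.0)
        score = np.minimum(dose @ weights, 1.0)
        scores[gene] = score
        info_rows.append(
            {
                "gene": gene,
                "f_lof": f_lof,
                "f_mis": f_mis,
                "weight_missense": w_mis,
                "n_carriers": int((score > 0).sum()),
            }
        )
    return GeneBurdenSet(
        scores=pd.DataFrame(scores, index=genotypes.index),
        gene_info=pd.DataFrame(info_rows),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# burden association
# ---------------------------------------------------------------------------


def burden_association(
    burden: GeneBurdenSet,
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    min_carriers: int = 10,
    n_analyses: int = 27,
) -> pd.DataFrame:
    """Covariate-adjusted least-squares burden test per gene.

    Genes with fewer than ``min_carriers`` carriers are excluded before
    multiplicity accounting.  Emits per-gene BETA, SE, P plus the
    exome-wide (0.05 / n tested genes) and study-wide (further / number
    of analyses) thresholds.  Genes whose carriers all fall in a single
    covariate cell are reported with an ``unstable`` warning flag.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    df_resid = n - Q.shape[1] - 1

    info = burden.gene_info.set_index("gene")
    rows = []
    for gene in burden.scores.columns:
        n_carriers = int(info.loc[gene, "n_carriers"])
        if n_carriers < min_carriers:
            continue
        s = burden.scores[gene].to_numpy(float)
        s_r = s - Q @ (Q.T @ s)
        ss = float(s_r @ s_r)
        if ss <= 1e-12:
            log.warning("gene %s: burden score fully explained by covariates; flagged unstable", gene)
            rows.append({"gene": gene, "n_carriers": n_carriers, "BETA": np.nan,
                         "SE": np.nan, "P": np.nan, "unstable": True})
            continue
        beta = float(s_r @ y_r) / ss
        rss = max(float(y_r @ y_r) - beta**2 * ss, 0.0)
        se = np.sqrt(rss / df_resid / ss)
        t = beta / se if se > 0 else np.inf
        p = float(min(2.0 * stats.t.sf(abs(t), df_resid), 1.0))
        rows.append({"gene": gene, "n_carriers": n_carriers, "BETA": beta,
                     "SE": se, "P": p, "unstable": False})
    out = pd.DataFrame(rows)
    n_tested = len(out)
    if n_tested:
        out.attrs["exome_wide_threshold"] = bonferroni_threshold(0.05, [n_tested])
        out.attrs["study_wide_threshold"] = bonferroni_threshold(0.05, [n_tested, n_analyses])
    return out
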
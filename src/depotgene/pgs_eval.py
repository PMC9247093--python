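"""Polygenic-score application and tail-enrichment evaluation.

Externally trained per-SNP weights are applied to genotype dosages with
allele alignment, the resulting score is residualized against genetic
principal components, and the evaluation mirrors the downstream
analyses of a depot-specific score: a 2x2 tail-enrichment odds ratio
(is an individual in the phenotype tail also in the score tail?) and
regressions of outcomes on indicators for the extreme score
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, InsufficientDataError, InvalidValueError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# score application + residualization
# ---------------------------------------------------------------------------


def apply_score(
    genotypes: pd.DataFrame,
    geno_alleles: pd.DataFrame,
    weights: pd.DataFrame,
) -> tuple[pd.Series, int]:
    """Weighted allele-dosage score with allele alignment.

    ``genotypes`` holds dosages of each variant's counted allele;
    ``geno_alleles`` gives that counted allele (A1) and the other (A2)
    per SNP; ``weights`` has columns SNP, EA, OA, WEIGHT.  When the
    weight's effect allele is the genotype's other allele the dosage is
    flipped (2 - d).  Unresolvable allele pairs are skipped and
    counted; missing dosages are mean-imputed per variant.

    Returns (scores, n_skipped).
    """
    alle = geno_alleles.set_index("SNP")
    score = np.zeros(len(genotypes))
    skipped = 0
    for _, w in weights.iterrows():
        snp = w["SNP"]
        if snp not in genotypes.columns or snp not in alle.index:
            skipped += 1
            continue
        a1, a2 = alle.loc[snp, "A1"], alle.loc[snp, "A2"]
        d = genotypes[snp].to_numpy(float)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        if (w["EA"], w["OA"]) == (a1, a2):
            eff = d
        elif (w["EA"], w["OA"]) == (a2, a1):
            eff = 2.0 - d
        else:
            skipped += 1
            continue
        score += w["WEIGHT"] * eff
    if skipped:
        log.warning("skipped %d weight rows with unresolvable variants/alleles", skipped)
    return pd.Series(score, index=genotypes.index, name="score"), skipped


def residualize_score(scores: pd.Series, pcs: pd.DataFrame | np.ndarray) -> pd.Series:
    """Residual of the raw score on {1, PCs} — removes ancestry gradients."""
    y = scores.to_numpy(float)
    X = np.column_stack([np.ones(y.size), np.asarray(pcs, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=scores.index, name="score_resid")


def percentile_ranks(scores: pd.Series, seed: int = 0) -> pd.Series:
    """Percentile rank in (0, 1]; boundary ties broken by a seeded shuffle."""
    y = scores.to_numpy(float)
    if np.ptp(y) == 0:
        raise InvalidValueError("constant score: percentiles undefined")
    rng = np.random.default_rng(seed)
    order = rng.permutation(y.size)
    ranks = np.empty(y.size)
    # stable sort of the shuffled values gives random tie order
    idx = order[np.argsort(y[order], kind="stable")]
    ranks[idx] = np.arange(1, y.size + 1)
    return pd.Series(ranks / y.size, index=scores.index, name="percentile")


# ---------------------------------------------------------------------------
# tail enrichment
# ---------------------------------------------------------------------------


@dataclass
class TailEnrichment:
    counts: tuple  # (a, b, c, d): (both tails, trait only, score only, neither)
    odds_ratio: float
    ci_low: float
    ci_high: float
    trait_q: float
    score_q: float
    corrected: bool  # Haldane 0.5 applied to a zero cell


def _tail_mask(values: np.ndarray, q: float, upper: bool) -> np.ndarray:
    if upper:
        return values > np.quantile(values, 1.0 - q)
    return values < np.quantile(values, q)


def tail_enrichment(
    trait: pd.Series | np.ndarray,
    score: pd.Series | np.ndarray,
    trait_q: float = 0.05,
    score_q: float = 0.05,
    upper: bool = True,
) -> TailEnrichment:
    """Odds ratio linking phenotype-tail and score-tail membership.

    Tails are empirical-quantile based (strictly beyond the type-7
    quantile).  OR = ad/bc with a Woolf log-normal 95% CI; any zero
    cell triggers the Haldane 0.5 continuity correction (logged).
    ``upper=False`` evaluates the bottom tails instead.
    """
    t = np.asarray(trait, dtype=float)
    s = np.asarray(score, dtype=float)
    if t.size != s.size:
        raise DataError("trait and score must cover the same samples")
    if t.size < 200:
        raise InsufficientDataError("need n >= 200 for tail analysis")
    in_t = _tail_mask(t, trait_q, upper)
    in_s = _tail_mask(s, score_q, upper)
    if in_t.sum() < 5 or in_s.sum() < 5:
        raise InsufficientDataError("tail smaller than 5 individuals")
    a = int((in_t & in_s).sum())
    b = int((in_t & ~in_s).sum())
    c = int((~in_t & in_s).sum())
    d = int((~in_t & ~in_s).sum())
    corrected = 0 in (a, b, c, d)
    if corrected:
        log.warning("zero cell in 2x2 table; applying Haldane 0.5 correction")
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    or_ = (aa * dd) / (bb * cc)
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return TailEnrichment(
        counts=(a, b, c, d),
        odds_ratio=float(or_),
        ci_low=float(np.exp(np.log(or_) - 1.96 * se_log)),
        ci_high=float(np.exp(np.log(or_) + 1.96 * se_log)),
        trait_q=trait_q,
        score_q=score_q,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# extreme-percentile outcome models
# ---------------------------------------------------------------------------


def extreme_score_outcome_association(
    score_resid: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
    q: float = 0.05,
    binary: dict[str, bool] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Regress outcomes on indicators for the extreme score percentiles.

    Builds top-``q`` and bottom-``q`` indicator variables from the
    residualized score's percentile ranks, and fits, per outcome, a
    linear model (continuous) or logistic model (binary) adjusted for
    the supplied covariates.  An outcome is treated as binary when its
    non-missing values are all 0/1 unless overridden via ``binary``.
    Binary outcomes with zero events in a tail are reported
    non-estimable.
    """
    ranks = percentile_ranks(score_resid, seed=seed)
    top = (ranks > 1.0 - q).astype(float)
    bottom = (ranks <= q).astype(float)
    n = len(score_resid)
    C = (
        np.column_stack([np.asarray(covariates, dtype=float)])
        if covariates is not None
        else np.empty((n, 0))
    )

    rows = []
    for name in outcomes.columns:
        y = outcomes[name].to_numpy(float)
        is_bin = (
            binary[name]
            if binary is not None and name in binary
            else bool(np.isin(y[~np.isnan(y)], [0.0, 1.0]).all())
        )
        for tail, ind in (("top", top), ("bottom", bottom)):
            X = sm.add_constant(np.column_stack([ind.to_numpy(), C]))
            if is_bin and (y[ind.to_numpy(bool)].sum() == 0):
                rows.append({"outcome": name, "tail": tail, "estimate": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "type": "logistic", "estimable": False})
                continue
            if is_bin:
                fit = sm.Logit(y, X).fit(disp=0)
                est = float(np.exp(fit.params[1]))
                lo, hi = np.exp(fit.conf_int()[1])
                typ = "logistic"
            else:
                fit = sm.OLS(y, X).fit()
                est = float(fit.params[1])
                lo, hi = fit.conf_int()[1]
                typ = "linear"
            rows.append({"outcome": name, "tail": tail, "estimate": est,
                         "ci_low": float(lo), "ci_high": float(hi),
                         "p": float(fit.pvalues[1]), "type": typ, "estimable": True})
    return pd.DataFrame(rows)


def split_samples(
    sample_ids, fractions=(0.7, 0.1, 0.2), seed: int = 0
) -> dict[str, np.ndarray]:
    """Seeded train/validate/test partition of sample ids."""
    if not np.isclose(sum(fractions), 1.0):
        raise InvalidValueError("fractions must sum to 1")
    ids = np.asarray(sample_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    n_train = int(round(fractions[0] * ids.size))
    n_val = int(round(fractions[1] * ids.size))
    return {
        "train": ids[perm[:n_train]],
        "validate": ids[perm[n_train : n_train + n_val]],
        "test": ids[perm[n_train + n_val :]],
    }
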
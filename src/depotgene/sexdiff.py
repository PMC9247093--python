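"""Sex-heterogeneity testing of association effects.

For a SNP with sex-stratified effect estimates, the dimorphism statistic
is

    t = (beta_m - beta_f) / sqrt(se_m^2 + se_f^2 - 2 r se_m se_f)

where ``r`` is the genome-wide Spearman rank correlation between male
and female effect estimates of the trait — it absorbs the correlation
the two estimates share (partial sample overlap, shared controls).  At
biobank sample sizes the statistic is referred to the standard normal,
so ``p_diff = 2 Phi(-|t|)``.

Loci are classified combined / male-only / female-only from the three
strata's significance: male-only means genome-wide significant in males
but in neither females nor the sex-combined scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InsufficientDataError, InvalidValueError
from .gwas_core import bonferroni_threshold


def _aligned(male: pd.DataFrame, female: pd.DataFrame) -> pd.DataFrame:
    m = male.set_index("SNP")
    f = female.set_index("SNP")
    shared = m.index.intersection(f.index)
    if {"EA", "OA"}.issubset(m.columns) and {"EA", "OA"}.issubset(f.columns):
        mism = (m.loc[shared, "EA"] != f.loc[shared, "EA"]) | (
            m.loc[shared, "OA"] != f.loc[shared, "OA"]
        )
        if mism.any():
            raise AlignmentError(
                f"allele mismatch between strata for {list(shared[mism])[:5]}"
            )
    return pd.DataFrame(
        {
            "SNP": shared,
            "beta_male": m.loc[shared, "BETA"].to_numpy(float),
            "se_male": m.loc[shared, "SE"].to_numpy(float),
            "beta_female": f.loc[shared, "BETA"].to_numpy(float),
            "se_female": f.loc[shared, "SE"].to_numpy(float),
        }
    )


def effect_rank_correlation(male: pd.DataFrame, female: pd.DataFrame) -> float:
    """Genome-wide Spearman correlation of male vs female effect sizes.

    Computed over all shared, allele-aligned SNPs of a trait (not a
    pruned subset).  Requires at least 10 shared SNPs.
    """
    merged = _aligned(male, female)
    if len(merged) < 10:
        raise InsufficientDataError(f"only {len(merged)} shared SNPs; need >= 10")
    rho = stats.spearmanr(merged["beta_male"], merged["beta_female"]).statistic
    return float(rho)


def sex_heterogeneity_test(
    beta_male, se_male, beta_female, se_female, r: float
) -> pd.DataFrame:
    """Dimorphism t-statistic and two-sided normal p for each SNP.

    Accepts scalars or aligned arrays.  The variance term
    ``se_m^2 + se_f^2 - 2 r se_m se_f`` must be positive (it can only
    degenerate as r -> 1 with equal SEs).
    """
    bm = np.atleast_1d(np.asarray(beta_male, dtype=float))
    bf = np.atleast_1d(np.asarray(beta_female, dtype=float))
    sm = np.broadcast_to(np.asarray(se_male, dtype=float), bm.shape).astype(float)
    sf = np.broadcast_to(np.asarray(se_female, dtype=float), bf.shape).astype(float)
    if not -1.0 < r < 1.0:
        raise InvalidValueError("r must lie strictly inside (-1, 1)")
    if np.any(sm <= 0) or np.any(sf <= 0):
        raise InvalidValueError("standard errors must be positive")
    var = sm**2 + sf**2 - 2.0 * r * sm * sf
    if np.any(var <= 0):
        raise InvalidValueError("non-positive variance term in dimorphism test")
    t = (bm - bf) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(t))
    return pd.DataFrame(
        {
            "beta_male": bm,
            "se_male": sm,
            "beta_female": bf,
            "se_female": sf,
            "r": r,
            "t": t,
            "p_diff": np.minimum(p, 1.0),
        }
    )


def dimorphism_threshold(n_locus_trait_pairs: int, alpha: float = 0.05):
    """Bonferroni p_diff threshold over the tested locus-trait pairs."""
    return bonferroni_threshold(alpha, [n_locus_trait_pairs])


def classify_sex_specific_loci(
    combined: pd.DataFrame,
    male: pd.DataFrame,
    female: pd.DataFrame,
    threshold: float = 5e-8,
) -> pd.DataFrame:
    """Classify loci as combined / male_only / female_only.

    A locus is ``combined`` if genome-wide significant in the
    sex-combined scan; ``male_only`` if significant in males but in
    neither females nor combined (``female_only`` symmetrically);
    ``other`` if it clears the threshold nowhere or in both sexes only.
    Each input frame needs columns SNP and P covering every locus.
    """
    c = combined.set_index("SNP")["P"]
    m = male.set_index("SNP")["P"]
    f = female.set_index("SNP")["P"]
    rows = []
    for snp in c.index.union(m.index).union(f.index):
        if snp not in c.index or snp not in m.index or snp not in f.index:
            raise InsufficientDataError(f"locus {snp} missing a stratum")
        sig_c, sig_m, sig_f = c[snp] < threshold, m[snp] < threshold, f[snp] < threshold
        if sig_c:
            cls = "combined"
        elif sig_m and not sig_f:
            cls = "male_only"
        elif sig_f and not sig_m:
            cls = "female_only"
        else:
            cls = "other"
        rows.append({"SNP": snp, "class": cls})
    return pd.DataFrame(rows)
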
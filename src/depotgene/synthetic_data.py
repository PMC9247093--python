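"""Synthetic cohorts, summary statistics and rare-variant data.

Every downstream stage (trait derivation, association scanning, the
sex-heterogeneity test, bNMF clustering, burden testing, polygenic-score
evaluation) is exercised on data from this module, so the generators
emulate the statistical structure those stages assume:

* a cohort generator with sex-specific depot volume distributions
  (male/female mean VAT 5.0/2.6 L, ASAT 5.9/7.9 L, GFAT 9.3/11.3 L), a
  latent shared-adiposity factor that induces the observed strong
  depot-BMI correlation, and planted per-SNP effects (optionally
  sex-specific);
* a multi-trait z-score generator with planted non-negative cluster
  structure, ``z = A_true @ B_true + noise``, emitted as (beta, se)
  records with ``se = 1/sqrt(N)``;
* a sex-stratified effect generator with correlated male/female
  estimation noise and an optional truly dimorphic subset;
* a rare-variant generator with per-gene pLoF and damaging-missense
  variants at specified cumulative allele frequencies and planted gene
  effects on an INT-scale phenotype;
* a block-LD scenario generator for exercising LD clumping (exchangeable
  r-squared within a block, zero across blocks).

Depot volumes and BMI are drawn lognormal (volumes are strictly positive
and right-skewed) with the latent normal scores sharing a common factor;
the requested means and SDs are matched exactly by moment inversion.
All draws flow from a single ``numpy`` Generator seeded per invocation,
and each generator records its spec and seed in the returned metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpecError

__all__ = [
    "CohortSimSpec",
    "ClusterSimSpec",
    "BurdenSimSpec",
    "simulate_cohort",
    "simulate_summary_stats",
    "simulate_sex_stratified_effects",
    "simulate_gene_burden_data",
    "simulate_clump_scenario",
]


# ---------------------------------------------------------------------------
# cohort + genotypes
# ---------------------------------------------------------------------------

#: per-sex (male, female) depot volume means in litres
DEPOT_MEANS = {"vat": (5.0, 2.6), "asat": (5.9, 7.9), "gfat": (9.3, 11.3)}
#: per-sex (male, female) depot volume SDs in litres
DEPOT_SDS = {"vat": (2.5, 1.5), "asat": (2.2, 2.8), "gfat": (2.1, 2.6)}


@dataclass
class CohortSimSpec:
    """Parameters of the cohort generator.

    ``shared_adiposity_frac`` is the fraction of each latent depot
    score's variance carried by the common adiposity factor; the default
    was tuned once so that the pooled depot-BMI Pearson correlations of
    a default cohort land inside the observed 0.77-0.88 band.
    """

    n_individuals: int = 20_000
    sex_fraction_female: float = 0.51
    depot_means: dict = field(default_factory=lambda: dict(DEPOT_MEANS))
    depot_sds: dict = field(default_factory=lambda: dict(DEPOT_SDS))
    bmi_mean: tuple = (27.4, 27.1)
    bmi_sd: tuple = (4.2, 5.1)
    height_mean: tuple = (176.5, 163.1)
    height_sd: tuple = (6.8, 6.2)
    age_mean: float = 65.0
    age_sd: float = 7.5
    age_range: tuple = (45.0, 82.0)
    #: per-depot fraction of latent variance on the shared factor; VAT needs
    #: a higher loading because its large between-sex mean gap dilutes the
    #: pooled correlation with BMI
    shared_adiposity_frac: dict = field(
        default_factory=lambda: {"vat": 0.99, "asat": 0.93, "gfat": 0.93}
    )
    bmi_shared_frac: float = 0.97
    n_snps: int = 0
    maf_range: tuple = (0.05, 0.5)
    #: rows (snp, trait, stratum, beta): per-allele effect in litres on a
    #: raw depot ("vat"/"asat"/"gfat"), applied to centered dosage
    effects: pd.DataFrame | None = None
    n_centers: int = 3
    n_pcs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise SpecError("sex_fraction_female must be in [0, 1]")
        for d, (sm, sf) in self.depot_sds.items():
            if sm <= 0 or sf <= 0:
                raise SpecError(f"non-positive SD for depot {d!r}")
        if self.effects is not None:
            traits = set(DEPOT_MEANS)
            if not set(self.effects["trait"]).issubset(traits):
                raise SpecError("effect table references unknown trait")
            if not set(self.effects["stratum"]).issubset({"combined", "male", "female"}):
                raise SpecError("effect stratum must be combined/male/female")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    var = sd**2
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_cohort(spec: CohortSimSpec):
    """Draw a cohort table plus genotype dosages.

    Returns ``(cohort, genotypes, snp_info, meta)``: the cohort table in
    the format :func:`depotgene.traits.derive_local_adiposity` consumes,
    an (individuals x SNPs) int8 dosage DataFrame, per-SNP info (CHR,
    BP, MAF, alleles) and a metadata dict recording the spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals

    female = rng.random(n) < spec.sex_fraction_female
    sexidx = female.astype(int)  # 0 = male, 1 = female
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range)
    height = rng.normal(
        np.asarray(spec.height_mean)[sexidx], np.asarray(spec.height_sd)[sexidx]
    )

    # latent shared-adiposity factor ties BMI and the depots together
    factor = rng.standard_normal(n)
    fb = spec.bmi_shared_frac
    bmi_latent = np.sqrt(fb) * factor + np.sqrt(1 - fb) * rng.standard_normal(n)
    mu_b = np.empty(n)
    sg_b = np.empty(n)
    for s in (0, 1):
        mu, sg = _lognormal_params(spec.bmi_mean[s], spec.bmi_sd[s])
        mu_b[sexidx == s], sg_b[sexidx == s] = mu, sg
    bmi = np.exp(mu_b + sg_b * bmi_latent)

    # genotypes first so planted effects can enter the depots
    geno = None
    snp_info = None
    if spec.n_snps > 0:
        maf = rng.uniform(*spec.maf_range, spec.n_snps)
        geno = rng.binomial(2, maf, size=(n, spec.n_snps)).astype(np.int8)
        snp_ids = [f"rs{i + 1}" for i in range(spec.n_snps)]
        snp_info = pd.DataFrame(
            {
                "SNP": snp_ids,
                "CHR": 1 + np.arange(spec.n_snps) % 22,
                "BP": 1_000_000 + 10_000 * np.arange(spec.n_snps),
                "EA": "A",
                "OA": "G",
                "MAF": maf,
            }
        )

    depots = {}
    for depot in ("vat", "asat", "gfat"):
        fd = spec.shared_adiposity_frac[depot]
        latent = np.sqrt(fd) * factor + np.sqrt(1 - fd) * rng.standard_normal(n)
        mu_d = np.empty(n)
        sg_d = np.empty(n)
        for s in (0, 1):
            mu, sg = _lognormal_params(spec.depot_means[depot][s], spec.depot_sds[depot][s])
            mu_d[sexidx == s], sg_d[sexidx == s] = mu, sg
        vol = np.exp(mu_d + sg_d * latent)
        if spec.effects is not None and geno is not None:
            rows = spec.effects[spec.effects["trait"] == depot]
            ids = list(snp_info["SNP"])
            for _, row in rows.iterrows():
                if row["snp"] not in ids:
                    raise SpecError(f"effect table references unknown SNP {row['snp']!r}")
                j = ids.index(row["snp"])
                centered = geno[:, j] - 2 * maf[j]
                if row["stratum"] == "combined":
                    vol = vol + row["beta"] * centered
                else:
                    in_stratum = female if row["stratum"] == "female" else ~female
                    vol = vol + np.where(in_stratum, row["beta"] * centered, 0.0)
        depots[depot] = np.maximum(vol, 0.01)

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "sex": np.where(female, "female", "male"),
            "age": age,
            "bmi": bmi,
            "height": height,
            "vat": depots["vat"],
            "asat": depots["asat"],
            "gfat": depots["gfat"],
            "center": rng.integers(0, spec.n_centers, n),
            "array": rng.integers(0, 2, n),
        }
    )
    for k in range(spec.n_pcs):
        cohort[f"pc{k + 1}"] = rng.standard_normal(n)

    geno_df = None
    if geno is not None:
        geno_df = pd.DataFrame(geno, index=cohort["sample_id"], columns=snp_info["SNP"])

    meta = {"seed": spec.seed, "spec": _spec_to_meta(spec)}
    return cohort, geno_df, snp_info, meta


def _spec_to_meta(spec) -> dict:
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, pd.DataFrame):
            d[k] = v.to_dict("records")
    return d


# ---------------------------------------------------------------------------
# multi-trait z-scores with planted cluster structure
# ---------------------------------------------------------------------------


@dataclass
class ClusterSimSpec:
    """Planted-structure spec for the multi-trait z-score generator.

    If ``a_true`` / ``b_true`` are omitted, variants are assigned to the
    ``k_true`` clusters cyclically; each variant loads U(4, 8) on its own
    cluster, and each cluster weights a disjoint block of traits U(0.5,
    1.5) — giving signal entries comfortably above the unit noise SD.
    """

    n_variants: int = 100
    n_traits: int = 20
    k_true: int = 3
    a_true: np.ndarray | None = None  # variants x K, >= 0
    b_true: np.ndarray | None = None  # K x traits, >= 0
    sample_sizes: np.ndarray | None = None  # per trait
    default_n: int = 30_000
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_true > min(self.n_variants, self.n_traits):
            raise SpecError("k_true exceeds min(n_variants, n_traits)")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be > 0")
        for m in (self.a_true, self.b_true):
            if m is not None and np.any(np.asarray(m) < 0):
                raise SpecError("a_true/b_true must be elementwise non-negative")


def simulate_summary_stats(spec: ClusterSimSpec):
    """Emit per-trait summary statistics with planted cluster structure.

    Returns ``(z, stats, labels, meta)``: the signed z matrix (variants x
    traits), a long DataFrame of (SNP, TRAIT, BETA, SE, P, N) records
    with ``se = 1/sqrt(N)`` and ``beta = z * se``, the true cluster label
    per variant, and metadata.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    N, M, K = spec.n_variants, spec.n_traits, spec.k_true

    if spec.a_true is None:
        labels = np.arange(N) % K
        A = np.zeros((N, K))
        A[np.arange(N), labels] = rng.uniform(4.0, 8.0, N)
    else:
        A = np.asarray(spec.a_true, dtype=float)
        labels = A.argmax(axis=1)
    if spec.b_true is None:
        B = np.zeros((K, M))
        for k in range(K):
            block = np.arange(M)[np.arange(M) % K == k]
            B[k, block] = rng.uniform(0.5, 1.5, block.size)
    else:
        B = np.asarray(spec.b_true, dtype=float)

    z = A @ B + rng.normal(0.0, spec.noise_sd, size=(N, M))
    nn = (
        np.asarray(spec.sample_sizes, dtype=float)
        if spec.sample_sizes is not None
        else np.full(M, float(spec.default_n))
    )
    se = 1.0 / np.sqrt(nn)

    snp_ids = [f"rs{i + 1}" for i in range(N)]
    trait_names = [f"trait{j + 1}" for j in range(M)]
    recs = []
    for j, t in enumerate(trait_names):
        recs.append(
            pd.DataFrame(
                {
                    "SNP": snp_ids,
                    "TRAIT": t,
                    "BETA": z[:, j] * se[j],
                    "SE": se[j],
                    "P": 2.0 * stats.norm.sf(np.abs(z[:, j])),
                    "N": nn[j],
                }
            )
        )
    zdf = pd.DataFrame(z, index=snp_ids, columns=trait_names)
    meta = {"seed": spec.seed, "a_true": A, "b_true": B}
    return zdf, pd.concat(recs, ignore_index=True), labels, meta


def simulate_sex_stratified_effects(
    n_snps: int,
    se_male: float = 0.02,
    se_female: float = 0.02,
    est_correlation: float = 0.3,
    n_dimorphic: int = 0,
    dimorphic_delta: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Male/female effect estimates with correlated estimation noise.

    Under the null the true effect is identical in both sexes (zero);
    the estimates share correlation ``est_correlation`` as arises from
    partial sample overlap.  The first ``n_dimorphic`` SNPs get a true
    male-female effect difference of ``dimorphic_delta``.
    """
    rng = np.random.default_rng(seed)
    r = est_correlation
    cov = np.array(
        [[se_male**2, r * se_male * se_female], [r * se_male * se_female, se_female**2]]
    )
    noise = rng.multivariate_normal([0.0, 0.0], cov, size=n_snps)
    beta_m = noise[:, 0].copy()
    beta_f = noise[:, 1].copy()
    dimorphic = np.zeros(n_snps, dtype=bool)
    if n_dimorphic:
        dimorphic[:n_dimorphic] = True
        beta_m[:n_dimorphic] += dimorphic_delta
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_snps)],
            "EA": "A",
            "OA": "G",
            "beta_male": beta_m,
            "se_male": se_male,
            "beta_female": beta_f,
            "se_female": se_female,
            "true_dimorphic": dimorphic,
        }
    )


# ---------------------------------------------------------------------------
# rare-variant carrier data
# ---------------------------------------------------------------------------


@dataclass
class BurdenSimSpec:
    """Per-gene rare-variant spec.

    ``genes`` has columns gene, f_lof, f_mis (cumulative allele
    frequencies of the pLoF and damaging-missense masks) and effect (the
    planted per-unit-score effect on the INT-scale phenotype).
    """

    genes: pd.DataFrame = None
    n_individuals: int = 10_000
    variants_per_mask: int = 6
    seed: int = 0

    def validate(self) -> None:
        g = self.genes
        if g is None or g.empty:
            raise SpecError("genes table required")
        if ((g["f_lof"] < 0) | (g["f_lof"] >= 0.5)).any():
            raise SpecError("f_lof must be in [0, 0.5)")
        if ((g["f_mis"] < 0) | (g["f_mis"] >= 0.5)).any():
            raise SpecError("f_mis must be in [0, 0.5)")
        if ((g["f_lof"] + g["f_mis"]) >= 0.5).any():
            raise SpecError("f_lof + f_mis must be < 0.5 per gene")


def simulate_gene_burden_data(spec: BurdenSimSpec):
    """Draw rare-variant carriers and a phenotype with planted gene effects.

    Each gene's mask frequency is split over ``variants_per_mask``
    variants; carrier dosages are Binomial(2, freq) per variant.  The
    phenotype is standard normal noise plus, per gene, the planted
    effect times the capped weighted burden score (missense weight from
    the pLoF/missense cumulative-frequency ratio, computed from the spec
    frequencies).  Genes with at least ten realized carriers are flagged
    testable.

    Returns ``(annotations, genotypes, phenotype, gene_info, meta)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals

    ann_rows = []
    geno_cols = {}
    score_total = np.zeros(n)
    gene_rows = []
    for _, g in spec.genes.iterrows():
        gene = g["gene"]
        # spec-level missense weight used for planting the effect
        if g["f_lof"] == 0 or g["f_mis"] == 0:
            w_mis = 1.0
        else:
            w_mis = min(
                1.0,
                np.sqrt(
                    (g["f_lof"] * (1 - g["f_lof"])) / (g["f_mis"] * (1 - g["f_mis"]))
                ),
            )
        score = np.zeros(n)
        for cls, ftot, w in (
            ("pLoF_HC", g["f_lof"], 1.0),
            ("missense_5of5", g["f_mis"], w_mis),
        ):
            if ftot <= 0:
                continue
            k = spec.variants_per_mask
            # mildly concentrated split keeps per-variant frequencies well
            # under the rare-variant MAF cap
            fracs = rng.dirichlet(np.full(k, 3.0))
            for v in range(k):
                vid = f"{gene}:{cls}:{v + 1}"
                freq = ftot * fracs[v]
                dos = rng.binomial(2, freq, n).astype(np.int8)
                geno_cols[vid] = dos
                ann_rows.append({"variant_id": vid, "gene": gene, "class": cls})
                score += w * dos
        score = np.minimum(score, 1.0)
        carriers = int((score > 0).sum())
        score_total += g["effect"] * score
        gene_rows.append(
            {
                "gene": gene,
                "f_lof": g["f_lof"],
                "f_mis": g["f_mis"],
                "planted_effect": g["effect"],
                "n_carriers": carriers,
                "testable": carriers >= 10,
            }
        )

    sample_ids = [f"S{i:06d}" for i in range(n)]
    genotypes = pd.DataFrame(geno_cols, index=sample_ids)
    phenotype = pd.Series(
        score_total + rng.standard_normal(n), index=sample_ids, name="trait"
    )
    annotations = pd.DataFrame(ann_rows)
    gene_info = pd.DataFrame(gene_rows)
    meta = {"seed": spec.seed, "spec": _spec_to_meta(spec)}
    return annotations, genotypes, phenotype, gene_info, meta


# ---------------------------------------------------------------------------
# block-LD clumping scenarios
# ---------------------------------------------------------------------------


def simulate_clump_scenario(
    n_snps: int = 200,
    block_size: int = 10,
    frac_significant: float = 0.15,
    seed: int = 0,
):
    """Summary statistics plus a block-diagonal LD table.

    SNPs fall into blocks of ``block_size``; within a block every pair
    shares an exchangeable r-squared drawn U(0, 1), across blocks r² is
    exactly zero.  Physical gaps between adjacent SNPs are drawn from a
    heavy-tailed mix so some within-block pairs exceed a 1 Mb window.
    A fraction of SNPs receives genome-wide significant p-values.

    Returns ``(stats, ld_long)`` with the LD table in long format
    (snp_a, snp_b, r2).
    """
    rng = np.random.default_rng(seed)
    snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    gaps = rng.choice([5_000, 50_000, 400_000, 1_500_000], size=n_snps, p=[0.55, 0.3, 0.1, 0.05])
    bp = 1_000_000 + np.cumsum(gaps)
    chrom = np.ones(n_snps, dtype=int)

    sig = rng.random(n_snps) < frac_significant
    logp = np.where(
        sig, rng.uniform(8.2, 14.0, n_snps), rng.uniform(0.3, 7.8, n_snps)
    )
    pvals = 10.0**-logp

    stats_df = pd.DataFrame(
        {"CHR": chrom, "BP": bp, "SNP": snp_ids, "P": pvals}
    )

    rows = []
    for start in range(0, n_snps, block_size):
        idx = range(start, min(start + block_size, n_snps))
        r2 = rng.uniform(0.0, 1.0)
        for i in idx:
            for j in idx:
                if i < j:
                    rows.append({"snp_a": snp_ids[i], "snp_b": snp_ids[j], "r2": r2})
    return stats_df, pd.DataFrame(rows)
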
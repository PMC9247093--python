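"""Bayesian NMF with automatic relevance determination for locus clustering.

Lead SNPs associated with a primary trait are summarised by a matrix of
standardized multi-trait effects: per variant and trait, z = beta / se,
rescaled by sqrt(median N / N_trait) so traits with different GWAS
sample sizes are comparable, sign-aligned so every variant increases
the primary trait, and split by sign into non-negative column pairs
(trait_pos, trait_neg).  The resulting X (N variants by 2M split
traits) is factored as X ~ (W H)^T with W (2M x K) and H (K x N) both
non-negative.

The fit minimises a penalised Frobenius objective

    F = 1/2 ||X^T - W H||_F^2
        + sum_k (1/2 ||w_k||^2 + 1/2 ||h_k||^2 + b) / lambda_k
        + C sum_k log lambda_k,        C = (2M + N)/2 + a + 1,

the negative log-posterior under half-normal priors on W and H whose
per-component scales lambda_k carry inverse-gamma(a, b) hyperpriors.
Alternating multiplicative updates (monotone majorise-minimise steps)
are interleaved with the closed-form lambda update; components whose
relevance collapses are pruned, which is how the model selects K.  The
procedure is restarted from many random initialisations and the modal
K across restarts, with the best-objective solution among modal-K
restarts, is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, InvalidValueError
from .gwas_core import LdTable


# ---------------------------------------------------------------------------
# signed z matrix construction
# ---------------------------------------------------------------------------


@dataclass
class SignedZMatrix:
    """Non-negative variants x split-traits matrix plus provenance."""

    X: pd.DataFrame  # variants x 2M, columns "<trait>_pos"/"<trait>_neg"
    z: pd.DataFrame  # signed scaled z, variants x retained traits
    sample_sizes: dict
    median_n: float
    primary_trait: str


def build_signed_z_matrix(
    leads: list[str],
    trait_stats: dict[str, pd.DataFrame],
    primary_trait: str,
    ld: LdTable | None = None,
    n_snps_for_bonferroni: int | None = None,
    nominal_p: float = 0.05,
    prune_r2: float = 0.1,
    corr_cutoff: float = 0.85,
) -> SignedZMatrix:
    """Assemble the non-negative association matrix for clustering.

    ``trait_stats`` maps trait name to a frame with columns SNP, BETA,
    SE, P, N covering every lead (missing entries are an error — panels
    must be complete).  Pipeline: keep leads nominally associated
    (p < 0.05) with the primary trait; LD-prune at r² = 0.1 keeping the
    lower primary p; z = beta/se scaled by sqrt(median N / N_trait);
    flip each variant's sign vector so its primary-trait z is positive;
    drop traits with no |z| above the Bonferroni normal quantile for
    0.05 / n_variants; among trait pairs with |Pearson corr| > 0.85 on
    the signed columns drop the trait with the larger minimum p; split
    each signed column into a (pos, neg) non-negative pair.
    """
    if primary_trait not in trait_stats:
        raise KeyError(f"no summary statistics for primary trait {primary_trait!r}")
    indexed = {t: df.set_index("SNP") for t, df in trait_stats.items()}
    prim = indexed[primary_trait]

    missing = [s for s in leads if s not in prim.index]
    if missing:
        raise InvalidValueError(f"leads missing from primary-trait stats: {missing[:5]}")

    # (1) nominal association with the primary trait
    kept = [s for s in leads if prim.loc[s, "P"] < nominal_p]
    zero_beta = [s for s in kept if prim.loc[s, "BETA"] == 0]
    if zero_beta:
        kept = [s for s in kept if s not in zero_beta]

    # (2) LD-prune, keeping the variant with the lower primary p
    if ld is not None:
        order = sorted(kept, key=lambda s: (prim.loc[s, "P"], s))
        pruned: list[str] = []
        for s in order:
            if all(ld.r2(s, t) <= prune_r2 for t in pruned):
                pruned.append(s)
        kept = [s for s in kept if s in set(pruned)]
    if not kept:
        raise InvalidValueError("no leads survive primary-trait filtering")

    # (3)-(4) standardize and sample-size scale; the primary trait defines
    # selection and orientation but is not itself a clustering column
    traits = [t for t in trait_stats if t != primary_trait]
    nn = {}
    for t in traits:
        sub = indexed[t]
        absent = [s for s in kept if s not in sub.index]
        if absent:
            raise InvalidValueError(f"trait {t!r} missing stats for {absent[:5]}")
        nn[t] = float(np.median(sub.loc[kept, "N"]))
    median_n = float(np.median(list(nn.values())))
    z = pd.DataFrame(index=kept, columns=traits, dtype=float)
    for t in traits:
        sub = indexed[t].loc[kept]
        z[t] = (sub["BETA"] / sub["SE"]) * np.sqrt(median_n / nn[t])

    # (5) align every variant to the primary-trait increasing direction
    flip = np.sign(prim.loc[kept, "BETA"].to_numpy())
    z = z.mul(flip, axis=0)

    # (6) drop traits with no |z| above the Bonferroni quantile
    n_var = n_snps_for_bonferroni or len(kept)
    z_thresh = stats.norm.isf((0.05 / n_var) / 2.0)
    z = z.loc[:, (z.abs() >= z_thresh).any(axis=0)]

    # (7) collapse highly correlated trait pairs, keeping lower min p
    min_p = {t: float(indexed[t].loc[kept, "P"].min()) for t in z.columns}
    drop: set[str] = set()
    cols = list(z.columns)
    corr = z.corr()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in drop or b in drop:
                continue
            if abs(corr.loc[a, b]) > corr_cutoff:
                drop.add(a if min_p[a] > min_p[b] else b)
    z = z.drop(columns=sorted(drop))

    # (8) split signed columns into non-negative pos/neg pairs
    parts = {}
    for t in z.columns:
        col = z[t].to_numpy()
        parts[f"{t}_pos"] = np.clip(col, 0, None)
        parts[f"{t}_neg"] = np.clip(-col, 0, None)
    X = pd.DataFrame(parts, index=z.index)
    return SignedZMatrix(X=X, z=z, sample_sizes=nn, median_n=median_n, primary_trait=primary_trait)


# ---------------------------------------------------------------------------
# ARD-regularized NMF
# ---------------------------------------------------------------------------


@dataclass
class BnmfSolution:
    K: int
    W: np.ndarray  # 2M x K
    H: np.ndarray  # K x N
    lambdas: np.ndarray
    objective: float
    n_iter: int
    seed: int
    converged: bool
    #: rows (iteration, active K, objective); populated when tracing is on.
    #: The objective is comparable (and non-increasing) within stretches of
    #: constant K; pruning a component removes its penalty terms and so
    #: re-bases the trace.
    trace: list | None = None


@dataclass
class BnmfResult:
    solutions: list[BnmfSolution]
    modal_k: int
    modal_fraction: float
    best: BnmfSolution


def _objective(V, W, H, lam, b, C):
    resid = V - W @ H
    fit = 0.5 * float((resid * resid).sum())
    norms = 0.5 * (W * W).sum(axis=0) + 0.5 * (H * H).sum(axis=1)
    return fit + float(((norms + b) / lam).sum() + C * np.log(lam).sum())


def _fit_single(V, k0, rng_seed, a, b, tol, max_iter, prune_tol, eps=1e-12, trace=False):
    rng = np.random.default_rng(rng_seed)
    n_rows, n_cols = V.shape
    scale = np.sqrt(V.mean() / k0)
    W = rng.uniform(0.0, 1.0, (n_rows, k0)) * scale + eps
    H = rng.uniform(0.0, 1.0, (k0, n_cols)) * scale + eps
    C = (n_rows + n_cols) / 2.0 + a + 1.0

    lam = (0.5 * (W * W).sum(axis=0) + 0.5 * (H * H).sum(axis=1) + b) / C
    obj = _objective(V, W, H, lam, b, C)
    history: list | None = [] if trace else None
    # convergence needs the active component count stable and the relative
    # objective change below tol across a patience window, otherwise slow
    # component die-offs masquerade as plateaus
    check_every, window = 10, 10
    checkpoints: list[tuple[int, float]] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + H / lam[:, None] + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + W / lam[None, :] + eps)
        lam = (0.5 * (W * W).sum(axis=0) + 0.5 * (H * H).sum(axis=1) + b) / C

        if trace:
            history.append((it, W.shape[1], _objective(V, W, H, lam, b, C)))

        # prune components whose relative energy has collapsed
        energy = np.sqrt((W * W).sum(axis=0) * (H * H).sum(axis=1))
        keep = energy > prune_tol * max(energy.sum(), eps)
        if keep.sum() == 0:
            keep = energy == energy.max()
        if not keep.all():
            W, H, lam = W[:, keep], H[keep, :], lam[keep]

        if it % check_every == 0 or it == max_iter:
            obj = _objective(V, W, H, lam, b, C)
            checkpoints.append((W.shape[1], obj))
            if len(checkpoints) > window:
                k_then, obj_then = checkpoints[-1 - window]
                if k_then == W.shape[1] and abs(obj_then - obj) <= tol * abs(obj):
                    converged = True
                    break
    return BnmfSolution(
        K=W.shape[1],
        W=W,
        H=H,
        lambdas=lam,
        objective=obj,
        n_iter=it,
        seed=rng_seed,
        converged=converged,
        trace=history,
    )


def fit_bnmf_ard(
    X,
    k0: int = 20,
    n_restarts: int = 100,
    seed: int = 0,
    a: float = 10.0,
    b: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    prune_tol: float = 1e-8,
    trace: bool = False,
    refit: bool = True,
) -> BnmfResult:
    """Fit ARD-regularised NMF over random restarts and pick modal K.

    ``X`` is the non-negative variants x split-traits matrix (a
    :class:`SignedZMatrix` or array); its transpose is factored so W is
    split-traits x K.  ``a`` and ``b`` are the inverse-gamma hyperprior
    shape and scale on the component relevances; by default ``b`` is
    matched to the data scale, ``b = sqrt(mean(X^2)) * (a - 1) / k0``,
    so the prior mean relevance sits near the per-component share of
    the data energy.  Restart r uses child seed ``seed + r``; results
    are reproducible bit-for-bit for a fixed master seed.
    """
    V = np.asarray(X.X if isinstance(X, SignedZMatrix) else X, dtype=float).T
    if np.any(V < 0):
        raise InvalidValueError("X must be elementwise non-negative")
    if np.any((V.sum(axis=0) == 0)):
        raise InvalidValueError("X contains an all-zero row (variant)")
    if b is None:
        b = float(np.sqrt((V**2).mean()) * (a - 1.0) / k0)

    sols = [
        _fit_single(V, k0, seed + r, a, b, tol, max_iter, prune_tol, trace=trace)
        for r in range(n_restarts)
    ]
    if not any(s.converged for s in sols):
        raise ConvergenceError(
            f"no restart converged within {max_iter} iterations at tol {tol}"
        )
    ks = np.array([s.K for s in sols])
    vals, counts = np.unique(ks, return_counts=True)
    modal_k = int(vals[counts.argmax()])
    modal_fraction = float(counts.max() / len(sols))
    best = min((s for s in sols if s.K == modal_k), key=lambda s: s.objective)
    if refit:
        # unpenalized polish of the selected factors: ARD picked K, the
        # plain multiplicative updates remove the prior's shrinkage bias
        W, H = best.W.copy(), best.H.copy()
        prev = float(((V - W @ H) ** 2).sum())
        for _ in range(1000):
            H *= (W.T @ V) / (W.T @ W @ H + 1e-12)
            W *= (V @ H.T) / (W @ (H @ H.T) + 1e-12)
            cur = float(((V - W @ H) ** 2).sum())
            if abs(prev - cur) <= tol * max(prev, 1e-30):
                break
            prev = cur
        best.W, best.H = W, H
    return BnmfResult(solutions=sols, modal_k=modal_k, modal_fraction=modal_fraction, best=best)


# ---------------------------------------------------------------------------
# cluster summaries
# ---------------------------------------------------------------------------


@dataclass
class ClusterSummary:
    k: int
    trait_rankings: list[pd.Series]  # per cluster, weights ordered desc
    variant_rankings: list[pd.Series]  # per cluster, loadings ordered desc
    assignments: pd.Series  # variant -> cluster index
    modal_fraction: float | None = None


def summarize_clusters(
    solution: BnmfSolution,
    trait_labels: list[str],
    variant_ids: list[str],
    modal_fraction: float | None = None,
) -> ClusterSummary:
    """Rank traits and variants per cluster and hard-assign variants.

    Traits are ordered by their W-column weight, variants by their H-row
    loading.  Each variant is assigned to its max-loading cluster; ties
    go to the lowest cluster index.
    """
    W, H = solution.W, solution.H
    trait_rankings = [
        pd.Series(W[:, k], index=trait_labels).sort_values(ascending=False, kind="mergesort")
        for k in range(solution.K)
    ]
    variant_rankings = [
        pd.Series(H[k, :], index=variant_ids).sort_values(ascending=False, kind="mergesort")
        for k in range(solution.K)
    ]
    assignments = pd.Series(H.argmax(axis=0), index=variant_ids, name="cluster")
    return ClusterSummary(
        k=solution.K,
        trait_rankings=trait_rankings,
        variant_rankings=variant_rankings,
        assignments=assignments,
        modal_fraction=modal_fraction,
    )
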
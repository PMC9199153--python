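"""Normalization and quasi-negative-binomial differential tests.

Counts are depth-normalized by median-of-ratios size factors and modelled
per gene with a log-linear quasi-NB model

    Var(y) = b * mu + alpha_g * mu**2

where ``alpha_g`` is the per-gene biological overdispersion (moment estimate
shrunk toward a mean-dispersion trend) and ``b`` is a single technical
coefficient estimated from the same trend (``b`` is 1 for Poisson shot noise
at unit depth). Estimating ``b`` from the data rather than pinning it to 1
makes every reported statistic exactly invariant to rescaling any sample's
counts: the normalized matrix changes only by a global factor, and the pair
(b, alpha) is equivariant under that factor, so Wald z-scores are unchanged.

Three tests are exposed: a per-assay condition shift (mRNA or footprints), and
a translation-efficiency (TE) shift, formalized as the assay x condition
interaction of a two-factor model — the interaction coefficient is
log2FC(TE) = log2FC(ribo) - log2FC(rna). Models are fitted by iteratively
reweighted least squares, vectorized across genes (all genes share the design
matrix); Wald p-values are BH-adjusted over tested, converged genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ASSAY_RIBO, ASSAY_RNA, CountMatrix

RESULT_COLUMNS = ("log2fc", "se", "p", "fdr", "tested", "converged")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene expressed in every sample, the ratio of each sample's count
    to the gene's across-sample geometric mean is formed; a sample's factor is
    the median of its ratios.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    values = mat.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; apply the background filter first"
        )
    logs = np.log(values[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    log_factors = np.median(log_ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by their per-sample size factors."""
    if factors is None:
        factors = size_factors(counts)
    return counts.counts / factors


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    """Per-gene overdispersion plus the shared variance-trend parameters.

    ``alpha`` is the shrunk per-gene estimate used by the tests, ``alpha_raw``
    the unshrunk moment estimate, ``alpha_trend`` the across-gene trend value
    and ``b`` the technical (linear) variance coefficient.
    """

    alpha: pd.Series
    alpha_raw: pd.Series
    alpha_trend: float
    b: float
    residual_df: int


def estimate_dispersion(
    norm: pd.DataFrame,
    groups: list[list[str]],
    prior_df: float = 20.0,
) -> DispersionEstimates:
    """Moment-based dispersion estimation with shrinkage toward a trend.

    ``groups`` lists the replicate sample ids of each experimental cell; the
    pooled within-group variance of each gene is decomposed as
    ``b * mean + alpha * mean**2`` by an across-gene regression, and per-gene
    moment estimates of ``alpha`` are shrunk toward the trend intercept with
    prior weight ``prior_df`` (in residual degrees of freedom).
    """
    sizes = np.array([len(g) for g in groups])
    df = int((sizes - 1).sum())
    if df < 1:
        raise ValueError("dispersion estimation needs >= 2 replicates in at least one group")

    t = np.zeros(len(norm))  # pooled within-group variance
    m1 = np.zeros(len(norm))  # df-weighted mean of group means
    m2 = np.zeros(len(norm))  # df-weighted mean of squared group means
    for g, n_g in zip(groups, sizes):
        if n_g < 2:
            continue
        block = norm[list(g)].to_numpy(dtype=float)
        mean_g = block.mean(axis=1)
        var_g = block.var(axis=1, ddof=1)
        w = (n_g - 1) / df
        t += w * var_g
        m1 += w * mean_g
        m2 += w * mean_g**2

    usable = m2 > 0
    if not usable.any():
        raise ValueError("all genes are zero in the tested samples")
    x = m1[usable] / m2[usable]  # ~ 1/mean
    r = t[usable] / m2[usable]  # ~ CV^2 = b/mean + alpha
    slope, intercept = np.polyfit(x, r, 1)
    b = float(max(slope, 0.0))
    if b == 0.0:
        # variance grows at least quadratically; attribute it all to alpha
        alpha_trend = float(max(np.median(r), 0.0))
    else:
        alpha_trend = float(max(intercept, 0.0))

    alpha_raw = np.full(len(norm), np.nan)
    alpha_raw[usable] = np.maximum(0.0, (t[usable] - b * m1[usable]) / m2[usable])
    alpha = (df * alpha_raw + prior_df * alpha_trend) / (df + prior_df)
    alpha[~usable] = alpha_trend  # genes without usable replicate variance
    return DispersionEstimates(
        alpha=pd.Series(alpha, index=norm.index, name="alpha"),
        alpha_raw=pd.Series(alpha_raw, index=norm.index, name="alpha_raw"),
        alpha_trend=alpha_trend,
        b=b,
        residual_df=df,
    )


# ---------------------------------------------------------------------------
# Vectorized IRLS for the quasi-NB log-linear model
# ---------------------------------------------------------------------------


def nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    alpha: np.ndarray,
    b: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Fit ``log mu = X beta`` with ``Var = b*mu + alpha*mu^2`` per gene.

    ``y`` is genes x samples (non-negative, need not be integer), ``design``
    samples x p shared across genes, ``alpha`` per-gene. Returns coefficient
    and standard-error matrices (genes x p), fitted means and a per-gene
    convergence flag. Non-converged genes keep their last iterate.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n_genes, n_samples = y.shape
    p = design.shape[1]

    # per-gene degenerate guard: zero variance function would make weights 0/0
    b_gene = np.full(n_genes, float(b))
    if b == 0.0:
        b_gene[alpha == 0.0] = 1.0

    eta = np.log(np.clip(y, 0.5, None))
    beta = np.zeros((n_genes, p))
    # initialize by unweighted least squares on log counts
    beta[:] = np.linalg.lstsq(design, eta.T, rcond=None)[0].T
    eta = np.clip(beta @ design.T, -30.0, 30.0)
    converged = np.zeros(n_genes, dtype=bool)

    for _ in range(max_iter):
        mu = np.exp(eta)
        w = mu / (b_gene[:, None] + alpha[:, None] * mu)
        z = eta + (y - mu) / mu
        xtwx = np.einsum("gs,sp,sq->gpq", w, design, design, optimize=True)
        xtwz = np.einsum("gs,gs,sp->gp", w, z, design, optimize=True)
        try:
            beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ridge = 1e-10 * np.eye(p)
            beta_new = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        delta = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        eta = np.clip(beta @ design.T, -30.0, 30.0)
        converged = delta < tol
        if converged.all():
            break

    mu = np.exp(eta)
    w = mu / (b_gene[:, None] + alpha[:, None] * mu)
    xtwx = np.einsum("gs,sp,sq->gpq", w, design, design, optimize=True)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(xtwx + 1e-10 * np.eye(p))
    se = np.sqrt(np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, None))
    return {"beta": beta, "se": se, "mu": mu, "converged": converged}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Contrast tests
# ---------------------------------------------------------------------------


def _wald_table(
    norm_used: pd.DataFrame,
    design: np.ndarray,
    coef: int,
    disp: DispersionEstimates,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    y = norm_used.to_numpy(dtype=float)
    tested = y.sum(axis=1) > 0
    log2fc = np.full(len(y), np.nan)
    se = np.full(len(y), np.nan)
    p = np.full(len(y), np.nan)
    converged = np.zeros(len(y), dtype=bool)

    if tested.any():
        alpha = disp.alpha.to_numpy()[tested]
        fit = nb_glm(y[tested], design, alpha, b=disp.b, max_iter=max_iter, tol=tol)
        ln2 = np.log(2.0)
        log2fc[tested] = fit["beta"][:, coef] / ln2
        se[tested] = fit["se"][:, coef] / ln2
        z = fit["beta"][:, coef] / np.where(fit["se"][:, coef] > 0, fit["se"][:, coef], np.nan)
        p[tested] = 2.0 * stats.norm.sf(np.abs(z))
        converged[tested] = fit["converged"]

    fdr = np.full(len(y), np.nan)
    ok = tested & converged & ~np.isnan(p)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "fdr": fdr,
            "tested": tested,
            "converged": converged,
        },
        index=norm_used.index,
    )


def _check_condition(cm: CountMatrix, cond: str) -> None:
    if cond not in set(cm.samples["condition"]):
        raise ValueError(f"condition {cond!r} not present in the sample sheet")


def test_assay_shift(
    cm: CountMatrix,
    assay: str,
    cond_a: str,
    cond_b: str,
    factors: pd.Series | None = None,
    prior_df: float = 20.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene test of a condition shift within one assay.

    log2FC is reported for ``cond_b`` versus ``cond_a``. Size factors default
    to median-of-ratios over the full matrix.
    """
    _check_condition(cm, cond_a)
    _check_condition(cm, cond_b)
    ids_a = cm.sample_ids(assay=assay, condition=cond_a)
    ids_b = cm.sample_ids(assay=assay, condition=cond_b)
    if not ids_a or not ids_b:
        raise ValueError(f"assay {assay!r} missing replicates in one of the conditions")
    norm = normalized_counts(cm, factors)
    used = norm[ids_a + ids_b]
    design = np.column_stack(
        [np.ones(len(ids_a) + len(ids_b)), np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]]
    )
    disp = estimate_dispersion(used, [ids_a, ids_b], prior_df=prior_df)
    return _wald_table(used, design, coef=1, disp=disp, max_iter=max_iter, tol=tol)


def test_te_shift(
    cm: CountMatrix,
    cond_a: str,
    cond_b: str,
    factors: pd.Series | None = None,
    prior_df: float = 20.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene test of a translation-efficiency shift between two conditions.

    Fits ``log mu = b0 + b1*ribo + b2*condB + b3*(ribo x condB)``; ``b3`` is
    the log fold change of TE (footprint change minus mRNA change) and is
    Wald-tested.
    """
    _check_condition(cm, cond_a)
    _check_condition(cm, cond_b)
    cells: list[list[str]] = []
    rows: list[tuple[float, float]] = []  # (is_ribo, is_cond_b) per sample
    for cond, cond_flag in ((cond_a, 0.0), (cond_b, 1.0)):
        for assay, ribo_flag in ((ASSAY_RNA, 0.0), (ASSAY_RIBO, 1.0)):
            ids = cm.sample_ids(assay=assay, condition=cond)
            if not ids:
                raise ValueError(f"assay {assay!r} missing in condition {cond!r}")
            cells.append(ids)
            rows.extend([(ribo_flag, cond_flag)] * len(ids))
    ordered = [s for cell in cells for s in cell]
    norm = normalized_counts(cm, factors)
    used = norm[ordered]
    flags = np.array(rows)
    design = np.column_stack(
        [np.ones(len(flags)), flags[:, 0], flags[:, 1], flags[:, 0] * flags[:, 1]]
    )
    disp = estimate_dispersion(used, cells, prior_df=prior_df)
    return _wald_table(used, design, coef=3, disp=disp, max_iter=max_iter, tol=tol)
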
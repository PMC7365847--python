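"""Moderated differential-expression statistics and the s ranking score.

One ordinary-least-squares linear model is fitted per gene on log-cpm
values, with a group mean per (arm, time) cell and an optional additive
donor blocking factor. Gene-wise residual variances are shrunk toward an
ensemble prior estimated by moment matching of log s_g^2 against its
theoretical scaled-F distribution (the empirical-Bayes moderation of
limma), giving moderated t statistics per contrast and a moderated F
across a set of contrasts. P-values are Benjamini–Hochberg adjusted, and
genes are ranked by the signed score

    s = -log10(q) * log2(FC)

whose iso-|s| curves are the hyperbolae separating the top-K genes on a
volcano plot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "build_design_matrix",
    "fit_gene_models",
    "moderate_statistics",
    "moderated_t",
    "moderated_f",
    "bh_adjust",
    "s_score",
    "top_k_by_s",
    "gene_zscore_matrix",
    "run_contrast",
    "divergence_f_table",
    "GeneFit",
    "ModeratedFit",
]

Q_FLOOR = 1e-300  # keeps -log10(q), hence s, finite


def group_label(arm: str, time_h: float) -> str:
    return f"{arm}{int(time_h)}"


def build_design_matrix(design: pd.DataFrame, blocking: str | None = "donor") -> pd.DataFrame:
    """Cell-means design matrix: one column per (arm, time) group, plus an
    optional treatment-coded blocking factor (first level dropped).

    Raises on rank deficiency, naming the aliased columns.
    """
    design = design.reset_index() if design.index.name == "sample_id" else design
    groups = [group_label(a, t) for a, t in zip(design["arm"], design["time_h"])]
    x = pd.get_dummies(pd.Series(groups, name="group"), dtype=float)
    if blocking is not None:
        block = pd.get_dummies(design[blocking], prefix=blocking, dtype=float)
        x = pd.concat([x, block.iloc[:, 1:]], axis=1)
    x.index = design["sample_id"].to_numpy()
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        aliased = _aliased_columns(x.to_numpy(), list(x.columns))
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return x


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[i] for i in np.where(diag < tol)[0]]


@dataclass
class GeneFit:
    """Per-gene OLS results shared across a common design matrix."""

    coef: pd.DataFrame        # genes x coefficients
    sigma2: pd.Series         # residual variances s_g^2
    df_resid: int
    xtx_inv: np.ndarray
    design_columns: list[str]


@dataclass
class ModeratedFit:
    fit: GeneFit
    d0: float                 # prior degrees of freedom (may be inf)
    s0_2: float               # prior variance
    post_var: pd.Series       # posterior (moderated) variances


def fit_gene_models(logcpm: pd.DataFrame, x: pd.DataFrame) -> GeneFit:
    """OLS per gene: Y (genes x n) against a shared design matrix (n x p)."""
    if list(x.index) != list(logcpm.columns):
        x = x.loc[logcpm.columns]
    xm = x.to_numpy(dtype=float)
    n, p = xm.shape
    rank = np.linalg.matrix_rank(xm)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient; aliased columns: "
            f"{_aliased_columns(xm, list(x.columns))}"
        )
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    y = logcpm.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(xm.T @ xm)
    beta = y @ xm @ xtx_inv
    resid = y - beta @ xm.T
    sigma2 = (resid**2).sum(axis=1) / df_resid
    return GeneFit(
        pd.DataFrame(beta, index=logcpm.index, columns=x.columns),
        pd.Series(sigma2, index=logcpm.index, name="sigma2"),
        df_resid,
        xtx_inv,
        list(x.columns),
    )


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            return x
    raise RuntimeError("trigamma inversion did not converge")


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s_g^2 to its scaled-F distribution -> (d0, s0^2).

    Genes with zero residual variance are excluded from estimation. A
    non-positive excess variance means no evidence of variance spread
    beyond sampling noise: d0 = inf (complete shrinkage to s0^2).
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        logger.warning("no excess variance in log s^2; using d0 = inf")
        return np.inf, float(np.exp(e_mean))
    try:
        d0 = 2.0 * _trigamma_inverse(excess)
    except RuntimeError:
        logger.warning("trigamma inversion failed; falling back to d0 = inf")
        return np.inf, float(np.exp(e_mean))
    s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def moderate_statistics(fit: GeneFit, d0: float | None = None, s0_2: float | None = None) -> ModeratedFit:
    """Shrink residual variances: s~_g^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g)."""
    if d0 is None or s0_2 is None:
        d0, s0_2 = estimate_prior(fit.sigma2.to_numpy(), fit.df_resid)
    if np.isinf(d0):
        post = np.full(len(fit.sigma2), s0_2)
    else:
        post = (d0 * s0_2 + fit.df_resid * fit.sigma2.to_numpy()) / (d0 + fit.df_resid)
    return ModeratedFit(fit, d0, s0_2, pd.Series(post, index=fit.sigma2.index))


def _contrast_vector(columns: list[str], contrast: dict[str, float]) -> np.ndarray:
    unknown = set(contrast) - set(columns)
    if unknown:
        raise ValueError(f"contrast refers to unknown columns: {sorted(unknown)}")
    c = np.zeros(len(columns))
    for name, wgt in contrast.items():
        c[columns.index(name)] = wgt
    return c


def moderated_t(mfit: ModeratedFit, contrast: dict[str, float]) -> pd.DataFrame:
    """Moderated t for one contrast: columns log2fc, stat, p."""
    fit = mfit.fit
    c = _contrast_vector(fit.design_columns, contrast)
    effect = fit.coef.to_numpy() @ c
    se_mult = float(np.sqrt(c @ fit.xtx_inv @ c))
    se = np.sqrt(mfit.post_var.to_numpy()) * se_mult
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    df_total = mfit.d0 + fit.df_resid
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"log2fc": effect, "stat": t, "p": p}, index=fit.coef.index
    )


def moderated_f(mfit: ModeratedFit, contrasts: list[dict[str, float]]) -> pd.DataFrame:
    """Moderated F over a set of contrasts (joint any-difference test)."""
    fit = mfit.fit
    cmat = np.stack([_contrast_vector(fit.design_columns, c) for c in contrasts])
    k = cmat.shape[0]
    cov = cmat @ fit.xtx_inv @ cmat.T
    cov_inv = np.linalg.inv(cov)
    effects = fit.coef.to_numpy() @ cmat.T  # genes x k
    quad = np.einsum("gi,ij,gj->g", effects, cov_inv, effects)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mfit.post_var > 0, quad / (k * mfit.post_var.to_numpy()), 0.0)
    df2 = mfit.d0 + fit.df_resid
    if np.isinf(df2):
        p = stats.chi2.sf(k * f, k)
    else:
        p = stats.f.sf(f, k, df2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"stat": f, "p": p}, index=fit.coef.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def s_score(q, log2fc) -> np.ndarray:
    """Signed ranking score s = -log10(q) * log2(FC); q floored at 1e-300."""
    q = np.asarray(q, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if np.any(q <= 0) or np.any(q > 1):
        raise ValueError("q must lie in (0, 1]")
    if np.any(~np.isfinite(log2fc)):
        raise ValueError("log2fc must be finite")
    out = -np.log10(np.maximum(q, Q_FLOOR)) * log2fc
    return float(out) if out.ndim == 0 else out


def top_k_by_s(table: pd.DataFrame, k: int = 750) -> tuple[list[str], float]:
    """The k genes of largest |s| plus the iso-|s| hyperbola threshold.

    Ties at the k-th position break deterministically: larger |log2fc|
    first, then lexicographic gene id.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    gene_ids = (
        table["gene_id"].to_numpy()
        if "gene_id" in table.columns
        else table.index.to_numpy()
    )
    abs_s = table["s"].abs().to_numpy()
    abs_fc = table["log2fc"].abs().to_numpy()
    # lexsort: last key is primary
    order = np.lexsort((gene_ids, -abs_fc, -abs_s))
    top = order[:k]
    threshold = float(abs_s[top[-1]])
    return [str(g) for g in gene_ids[top]], threshold


def gene_zscore_matrix(logcpm: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Gene-wise z-scores across samples (sample sd, ddof=1).

    Zero-variance genes come back as all-zero rows with a warning.
    """
    sub = logcpm.loc[genes] if genes is not None else logcpm
    x = sub.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes z-scored to 0", RuntimeWarning
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def run_contrast(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    group_a: tuple[str, float],
    group_b: tuple[str, float],
    blocking: str | None = None,
) -> pd.DataFrame:
    """Full DE table (log2fc, stat, p, q, s) for group_a minus group_b.

    Groups are (arm, time_h) cells of the design; log-cpm differences are
    log2 fold changes directly. Donor blocking is optional and off by
    default: the critical between-arm contrasts compare cells with
    disjoint donor sets, where a donor factor cannot cancel any donor
    effect but doubles the contrast variance; unblocked fits let donor
    variability act as replicate noise instead.
    """
    x = build_design_matrix(design, blocking=blocking)
    fit = fit_gene_models(logcpm, x)
    mfit = moderate_statistics(fit)
    contrast = {group_label(*group_a): 1.0, group_label(*group_b): -1.0}
    table = moderated_t(mfit, contrast)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["s"] = s_score(table["q"].to_numpy(), table["log2fc"].to_numpy())
    table.index.name = "gene_id"
    return table


def divergence_f_table(
    logcpm: pd.DataFrame,
    design: pd.DataFrame,
    pairs: list[tuple[tuple[str, float], tuple[str, float]]] | None = None,
    blocking: str | None = None,
) -> pd.DataFrame:
    """Moderated-F table for between-arm divergence at matched time points.

    Default pairs compare the arms at the shared times 4/14/24 h and pair
    the two endpoints (persistent 96 h vs. resolving 48 h). Returns
    stat (F), p and q per gene, ordered as the input.
    """
    if pairs is None:
        pairs = [
            (("persistent", 4.0), ("resolving", 4.0)),
            (("persistent", 14.0), ("resolving", 14.0)),
            (("persistent", 24.0), ("resolving", 24.0)),
            (("persistent", 96.0), ("resolving", 48.0)),
        ]
    x = build_design_matrix(design, blocking=blocking)
    fit = fit_gene_models(logcpm, x)
    mfit = moderate_statistics(fit)
    contrasts = [
        {group_label(*a): 1.0, group_label(*b): -1.0} for a, b in pairs
    ]
    table = moderated_f(mfit, contrasts)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table.index.name = "gene_id"
    return table
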
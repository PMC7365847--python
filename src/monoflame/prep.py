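"""Count-matrix preparation: imputation, TMM, log-cpm, filtering, PCA.

The preparation chain mirrors a standard bulk RNA-seq workflow on a
genes-by-samples count matrix: a bespoke replicate-imputation rule for
missing cells, trimmed-mean-of-M-values (TMM) between-sample normalization,
the offset log2 counts-per-million transform, an expression filter keeping
genes with cpm > 1 in at least 4 samples, and gene-centered PCA of the
resulting log-cpm matrix. Imputation runs before normalization and
filtering; TMM factors are computed on the full matrix and the expression
filter is applied afterwards.

Counts are handled as pandas DataFrames (index = gene ids, columns =
sample ids); missing cells are NaN until imputation.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_counts",
    "write_counts",
    "impute_missing_replicates",
    "tmm_factors",
    "log_cpm",
    "cpm",
    "filter_by_cpm",
    "pca_scores",
    "ExprMatrix",
    "PCAResult",
]


class ExprMatrix(NamedTuple):
    """Normalized expression: log-cpm values with the factors that made them."""

    logcpm: pd.DataFrame
    norm_factors: pd.Series
    lib_sizes: pd.Series


class PCAResult(NamedTuple):
    scores: pd.DataFrame          # samples x components
    variance_explained: np.ndarray
    loadings: pd.DataFrame        # genes x components


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV (gene_id + one column per sample).

    Blank or NA cells mark missing replicate measurements and come back as
    NaN. Duplicate gene ids or non-numeric/negative entries are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric entries in count matrix: {err}") from err
    if (df < 0).any().any():
        raise ValueError("negative counts")
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write counts as TSV; missing cells become empty fields.

    Integral values are written without a decimal point so that
    write -> read round-trips losslessly.
    """
    out = counts.copy()
    if bool((out.dropna() == out.dropna().round()).all().all()):
        out = out.astype("Int64")  # nullable int keeps NaN as blank
    out.to_csv(path, sep="\t", index_label="gene_id")


def impute_missing_replicates(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells within (arm, time) replicate groups.

    Per gene and group: exactly one missing value is set to the mean of
    the observed replicates (rounded to the nearest count); if two or more
    are missing but at least one replicate was observed, the missing ones
    are set to zero; a fully missing group is an error. Observed cells are
    never modified. The rule is stated for 3-replicate groups and
    generalizes to other group sizes as mean-of-observed.
    """
    design = design.set_index("sample_id") if "sample_id" in design.columns else design
    missing_samples = set(counts.columns) - set(design.index)
    if missing_samples:
        raise ValueError(f"samples absent from design: {sorted(missing_samples)[:5]}")
    out = counts.copy()
    for (_, _), group in design.loc[list(counts.columns)].groupby(
        ["arm", "time_h"], sort=False
    ):
        cols = [s for s in counts.columns if s in group.index]
        block = out[cols].to_numpy(dtype=float)
        isna = np.isnan(block)
        n_miss = isna.sum(axis=1)
        if np.any(n_miss == len(cols)):
            bad = out.index[n_miss == len(cols)][:5].tolist()
            raise ValueError(f"all replicates missing in a group for genes {bad}")
        one = n_miss == 1
        if one.any():
            means = np.rint(np.nanmean(block[one], axis=1))
            rows = np.where(one)[0]
            block[rows, :] = np.where(isna[rows], means[:, None], block[rows])
        many = n_miss > 1
        if many.any():
            rows = np.where(many)[0]
            block[rows, :] = np.where(isna[rows], 0.0, block[rows])
        out[cols] = block
    return out


def _quantile_libnorm(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts / lib, p, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    ref: str | None = None,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors (weighted trimmed mean of M-values).

    For each sample against a reference, gene-wise log2 expression ratios
    (M) are trimmed by 30% on M and 5% on average abundance (A), weighted
    by the inverse asymptotic binomial variance, and averaged; the factor
    is 2 to that mean. The reference defaults to the sample whose
    upper-quartile count fraction is closest to the mean. Factors are
    renormalized to geometric mean 1.
    """
    if counts.isna().any().any():
        raise ValueError("counts contain missing values; impute first")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    if ref is None:
        f75 = _quantile_libnorm(x, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref)

    refc, nref = x[:, ref_idx], lib[ref_idx]
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            x[:, j], refc, lib[j], nref, log_ratio_trim, abundance_trim
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(obs, refc, nobs, nref, log_ratio_trim, abundance_trim) -> float:
    pos = (obs > 0) & (refc > 0)
    obs, refc = obs[pos], refc[pos]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / nobs) / (refc / nref))
    a = 0.5 * np.log2((obs / nobs) * (refc / nref))
    w = (nobs - obs) / (nobs * obs) + (nref - refc) / (nref * refc)
    if np.max(np.abs(m)) < 1e-6:  # samples identical after scaling
        return 1.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    log_f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(log_f) or abs(log_f) < 1e-6:
        return 1.0
    return float(2.0**log_f)


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective (TMM-scaled) library sizes."""
    lib = counts.sum(axis=0)
    eff = lib * factors.reindex(counts.columns) if factors is not None else lib
    return counts / eff * 1e6


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> ExprMatrix:
    """Offset log2-cpm: log2((count + 0.5) / (effective libsize + 1) * 1e6)."""
    if counts.isna().any().any():
        raise ValueError("counts contain missing values; impute first")
    lib = counts.sum(axis=0)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib * factors.reindex(counts.columns)
    logcpm = np.log2((counts + 0.5) / (eff + 1.0) * 1e6)
    return ExprMatrix(logcpm, factors, lib)


def filter_by_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    threshold: float = 1.0,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Keep genes with cpm strictly above ``threshold`` in >= ``min_samples``.

    Gene order is preserved; the retained set does not depend on sample
    order.
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {counts.shape[1]}"
        )
    c = cpm(counts, factors)
    keep = (c > threshold).sum(axis=1) >= min_samples
    return counts.loc[keep]


def pca_scores(expr: ExprMatrix | pd.DataFrame, k: int = 2) -> PCAResult:
    """Gene-centered PCA of the log-cpm matrix via SVD.

    Samples are the observations. The sign of each component is fixed so
    that its largest-magnitude gene loading is positive. Variance-explained
    fractions are non-increasing and sum to <= 1.
    """
    logcpm = expr.logcpm if isinstance(expr, ExprMatrix) else expr
    n_genes, n_samples = logcpm.shape
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min matrix dimension")
    x = logcpm.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(k):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] *= -1.0
            vt[j, :] *= -1.0
    scores = (vt[:k].T * s[:k])
    var_explained = s[:k] ** 2 / np.sum(s**2)
    return PCAResult(
        pd.DataFrame(
            scores, index=logcpm.columns, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        var_explained,
        pd.DataFrame(
            u[:, :k], index=logcpm.index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
    )
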
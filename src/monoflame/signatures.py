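"""M1/M2 polarization signature scoring and sample clustering.

The analysis takes two signed gene lists as opaque inputs — 98 genes
modulated in monocyte-to-M1 differentiation and 107 in monocyte-to-M2 —
and uses them to score and cluster samples along the time course. The
score is direction-aware: the mean gene-wise z-score of the up genes
minus the mean gene-wise z-score of the down genes, so a sample enriched
for the polarized state scores positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import gene_zscore_matrix

__all__ = [
    "SignatureSet",
    "read_signature",
    "signature_score",
    "cluster_samples",
]


@dataclass(frozen=True)
class SignatureSet:
    """A signed signature: genes up or down in the polarized state."""

    name: str
    up_genes: frozenset
    down_genes: frozenset

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValueError("up and down gene sets overlap")
        if not (self.up_genes | self.down_genes):
            raise ValueError("empty signature")


def read_signature(path, name: str) -> SignatureSet:
    """Read a signature TSV with columns gene_id and direction (up/down)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "direction"} <= set(df.columns):
        raise ValueError("signature file needs columns gene_id, direction")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"unknown directions: {sorted(bad)}")
    return SignatureSet(
        name,
        frozenset(df.loc[df["direction"] == "up", "gene_id"]),
        frozenset(df.loc[df["direction"] == "down", "gene_id"]),
    )


def signature_score(logcpm: pd.DataFrame, sig: SignatureSet) -> pd.Series:
    """Per-sample signature score: mean z of up genes minus mean z of down.

    Genes absent from the matrix are dropped with a warning naming them;
    the score is invariant to adding a constant to all samples of a gene.
    """
    present_up = sorted(sig.up_genes & set(logcpm.index))
    present_down = sorted(sig.down_genes & set(logcpm.index))
    missing = (sig.up_genes | sig.down_genes) - set(logcpm.index)
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from matrix: "
            f"{sorted(missing)[:10]}",
            RuntimeWarning,
        )
    if not present_up and not present_down:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes -> z=0
        z = gene_zscore_matrix(logcpm, present_up + present_down)
    up = z.loc[present_up].mean(axis=0) if present_up else 0.0
    down = z.loc[present_down].mean(axis=0) if present_down else 0.0
    score = up - down
    score.name = sig.name
    return score


def cluster_samples(
    logcpm: pd.DataFrame,
    genes=None,
    method: str = "average",
    metric: str = "correlation",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of samples on a gene subset.

    Distance is 1 - Pearson correlation by default, with average linkage.
    Constant genes are removed first. Samples are canonically ordered by
    id before clustering, so the leaf order is stable under input
    permutation. Returns (leaf-ordered sample ids, scipy linkage matrix).
    """
    sub = logcpm.loc[[g for g in genes if g in logcpm.index]] if genes is not None else logcpm
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples to cluster")
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.empty:
        raise ValueError("all selected genes are constant; nothing to cluster")
    sub = sub[sorted(sub.columns)]
    d = pdist(sub.to_numpy().T, metric=metric)
    link = hierarchy.linkage(d, method=method)
    order = hierarchy.leaves_list(link)
    return [sub.columns[i] for i in order], link
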
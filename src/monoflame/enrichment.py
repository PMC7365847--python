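"""Dual pathway enrichment: GSEA + hypergeometric ORA fused by rank product.

Two complementary enrichment statistics are computed for every gene set:
a weighted Kolmogorov–Smirnov running-sum GSEA on the full signed ranking
(the s score), with a gene-label permutation null, and an upper-tail
hypergeometric over-representation test on the top-750 gene selection.
The two per-set rankings are fused by the rank product (their geometric
mean). Results across comparisons are summarized as an enrichment map:
nodes are top pathways, edges connect pairs whose overlap coefficient
|X∩Y| / min(|X|,|Y|) reaches a threshold (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "filter_sets",
    "gsea_es",
    "gsea",
    "ora",
    "enrich_table",
    "rank_product_integrate",
    "overlap_coefficient",
    "enrichment_map",
    "write_edge_list",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional provenance label."""

    sets: dict[str, frozenset]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members; tab-separated).

    Duplicate genes within a set are collapsed; a line with fewer than
    three fields is an error reported with its line number.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets, source or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source, *sorted(members)]) + "\n")


def filter_sets(
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect sets with the expression universe and keep sizes in
    [min_size, max_size] (both inclusive)."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    kept = {}
    for name, members in collection.sets.items():
        inter = members & universe
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
    return GeneSetCollection(kept, collection.source)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _sorted_metric(metric: pd.Series) -> pd.Series:
    """Descending by metric, ties broken by gene id for determinism."""
    order = np.lexsort((metric.index.to_numpy(), -metric.to_numpy()))
    return metric.iloc[order]


def _es_from_positions(weights: np.ndarray, positions: np.ndarray, n: int) -> float:
    """Enrichment score given sorted |metric| weights and hit positions.

    The running sum increments by w/sum(w) at hits and decrements by
    1/(N-K) at misses; extremes occur immediately before/after hits, so
    only those 2K candidate deviations are evaluated.
    """
    positions = np.sort(positions)
    k = positions.size
    w = weights[positions]
    total = w.sum()
    if total <= 0:
        raise ValueError("gene set has zero total metric weight")
    cum_hit = np.cumsum(w) / total
    miss_step = 1.0 / (n - k) if n > k else 0.0
    idx = np.arange(k)
    dev_after = cum_hit - (positions - idx) * miss_step
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - (positions - idx) * miss_step
    hi = dev_after.max()
    lo = dev_before.min()
    return float(hi if hi >= -lo else lo)


def gsea_es(metric: pd.Series, gene_set) -> float:
    """Weighted KS enrichment score (weight = |metric|^1) for one set."""
    ranked = _sorted_metric(metric)
    members = frozenset(gene_set) & frozenset(ranked.index)
    n = len(ranked)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    weights = np.abs(ranked.to_numpy())
    pos = np.flatnonzero(ranked.index.isin(members))
    return _es_from_positions(weights, pos, n)


def gsea(
    metric: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """GSEA enrichment score and gene-label permutation p-value.

    The null redraws the set membership uniformly over the ranked universe
    (equivalent to permuting gene labels); p is the add-one-smoothed
    fraction of permutations with |ES_perm| >= |ES_obs|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = _sorted_metric(metric)
    members = frozenset(gene_set) & frozenset(ranked.index)
    n = len(ranked)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    weights = np.abs(ranked.to_numpy())
    pos = np.flatnonzero(ranked.index.isin(members))
    es_obs = _es_from_positions(weights, pos, n)

    rng = np.random.default_rng(seed)
    k = pos.size
    # vectorized sampling of n_perm random k-subsets via random keys
    keys = rng.random((n_perm, n))
    perm_pos = np.argpartition(keys, k - 1, axis=1)[:, :k]
    exceed = 0
    for row in perm_pos:
        if weights[row].sum() <= 0:
            continue
        if abs(_es_from_positions(weights, row, n)) >= abs(es_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return es_obs, p


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def ora(selected, gene_set, universe) -> tuple[float, int]:
    """Upper-tail hypergeometric P(X >= overlap) and the overlap itself.

    N = |universe|, K = |set ∩ universe|, n = |selected|.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = frozenset(selected) & universe
    members = frozenset(gene_set) & universe
    overlap = len(selected & members)
    n_total, n_set, n_sel = len(universe), len(members), len(selected)
    p = float(stats.hypergeom.sf(overlap - 1, n_total, n_set, n_sel))
    return min(p, 1.0), overlap


# ---------------------------------------------------------------------------
# rank-product fusion
# ---------------------------------------------------------------------------

def _average_ranks(keys: list[tuple]) -> np.ndarray:
    """Ranks 1..n for lexicographic keys, averaging exact-tie groups."""
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = np.empty(len(keys))
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and keys[order[j + 1]] == keys[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def rank_product_integrate(rows: pd.DataFrame) -> pd.DataFrame:
    """Fuse GSEA and ORA orderings by the rank product (geometric mean).

    GSEA ranks by p then |ES| (larger first); ORA ranks by p then overlap
    (larger first); exact ties receive average ranks. The returned table
    is sorted ascending by rank_product (ties by set name).
    """
    required = {"set_name", "es", "gsea_p", "ora_p", "overlap"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if rows[["gsea_p", "ora_p"]].isna().any().any():
        raise ValueError("missing rank inputs (NaN p-values)")
    out = rows.copy()
    gsea_keys = [(p, -abs(e)) for p, e in zip(out["gsea_p"], out["es"])]
    ora_keys = [(p, -o) for p, o in zip(out["ora_p"], out["overlap"])]
    out["gsea_rank"] = _average_ranks(gsea_keys)
    out["ora_rank"] = _average_ranks(ora_keys)
    out["rank_product"] = np.sqrt(out["gsea_rank"] * out["ora_rank"])
    return out.sort_values(
        by=["rank_product", "set_name"], kind="mergesort"
    ).reset_index(drop=True)


def enrich_table(
    metric: pd.Series,
    selected,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run GSEA + ORA on every set of a (pre-filtered) collection and fuse.

    ``metric`` is the signed s score over the expression universe;
    ``selected`` is the top-|s| gene selection feeding ORA. Each set gets
    a deterministic per-set permutation seed derived from ``seed``.
    """
    universe = frozenset(metric.index)
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(collection.sets))
    for (name, members), child in zip(sorted(collection.sets.items()), children):
        set_seed = int(child.generate_state(1)[0] % (2**31))
        es, gp = gsea(metric, members, n_perm=n_perm, seed=set_seed)
        op, overlap = ora(selected, members, universe)
        rows.append(
            {
                "set_name": name,
                "size": len(frozenset(members) & universe),
                "es": es,
                "gsea_p": gp,
                "ora_p": op,
                "overlap": overlap,
            }
        )
    return rank_product_integrate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# enrichment map
# ---------------------------------------------------------------------------

def overlap_coefficient(x, y) -> float:
    """O(X, Y) = |X∩Y| / min(|X|, |Y|), in [0, 1]."""
    x, y = frozenset(x), frozenset(y)
    if not x or not y:
        return 0.0
    return len(x & y) / min(len(x), len(y))


def enrichment_map(
    results: dict[str, pd.DataFrame],
    collection: GeneSetCollection,
    threshold: float = 0.7,
    top_n: int = 500,
) -> nx.Graph:
    """Overlap-coefficient graph over each comparison's top pathways.

    Nodes are the union of the top ``top_n`` sets (by fused rank) of each
    comparison, annotated with size and a category: the comparison name
    for exclusive sets, ``"both"`` for shared ones. Edges connect pairs
    with overlap coefficient >= threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if not results:
        raise ValueError("need at least one comparison")
    membership: dict[str, set[str]] = {}
    for comparison, table in results.items():
        top = table.nsmallest(min(top_n, len(table)), "rank_product")["set_name"]
        for name in top:
            membership.setdefault(name, set()).add(comparison)
    g = nx.Graph()
    for name, comps in membership.items():
        category = "both" if len(comps) > 1 else next(iter(comps))
        g.add_node(
            name,
            category=category,
            comparisons=",".join(sorted(comps)),
            size=len(collection.sets.get(name, frozenset())),
        )
    nodes = sorted(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            o = overlap_coefficient(
                collection.sets.get(a, frozenset()), collection.sets.get(b, frozenset())
            )
            if o >= threshold:
                g.add_edge(a, b, overlap=o)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"set_a": a, "set_b": b, "overlap": d["overlap"]}
        for a, b, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["set_a", "set_b", "overlap"]).to_csv(
        path, sep="\t", index=False
    )
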
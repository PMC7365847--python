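"""End-to-end orchestration: configuration, staging, demo run, manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__, cytokines, differential, enrichment, prep, signatures, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "run_demo"]

DEFAULT_CONTRASTS = [
    ["P24_vs_R24", "persistent", 24.0, "resolving", 24.0],
    ["P96_vs_R48", "persistent", 96.0, "resolving", 48.0],
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full pipeline run.

    Threshold defaults are the analysis constants of the study design:
    expression filter cpm > 1 in >= 4 samples, top 750 genes by |s| for
    ORA, gene sets of 10–500 members, enrichment-map overlap >= 0.7.
    """

    counts: str = ""
    design: str = ""
    out_dir: str = "monoflame_out"
    gmt: str | None = None
    signatures: dict[str, str] = field(default_factory=dict)  # name -> TSV path
    panel: str | None = None
    cpm_threshold: float = 1.0
    min_samples: int = 4
    top_k: int = 750
    set_min: int = 10
    set_max: int = 500
    map_threshold: float = 0.7
    map_top_n: int = 500
    n_perm: int = 1000
    seed: int = 7
    contrasts: list = field(default_factory=lambda: [list(c) for c in DEFAULT_CONTRASTS])
    blocking: str | None = None
    enrichment_enabled: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("cpm_threshold", "top_k", "set_min", "set_max", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.map_threshold <= 1.0:
            raise ValueError("map_threshold must be in [0, 1]")
        if not self.counts or not self.design:
            raise ValueError("counts and design paths are required")
        if self.enrichment_enabled and self.gmt is None:
            raise ValueError("enrichment is enabled but no GMT path is configured")
        for p in filter(None, [self.counts, self.design, self.gmt, self.panel]):
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        for p in self.signatures.values():
            if not Path(p).exists():
                raise ValueError(f"signature path does not exist: {p}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, fn, manifest: dict):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, err) from err
    manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
    logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write a report bundle + manifest.

    Outputs under ``config.out_dir``: filtered log-cpm TSV, PCA scores,
    one DE table per contrast, enrichment tables and GraphML/edge-list
    map, signature scores, cytokine results, and ``manifest.json`` with
    all parameter values, seeds and row counts. Identical config and seed
    give identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("signatures",)
        },
        "stages": {},
        "tables": {},
    }

    design = _stage(
        "read_design", lambda: pd.read_csv(config.design, sep="\t"), manifest
    )
    counts = _stage("read_counts", lambda: prep.read_counts(config.counts), manifest)
    counts = _stage(
        "impute", lambda: prep.impute_missing_replicates(counts, design), manifest
    )
    factors = _stage("tmm", lambda: prep.tmm_factors(counts), manifest)
    filtered = _stage(
        "filter",
        lambda: prep.filter_by_cpm(
            counts, factors, config.cpm_threshold, config.min_samples
        ),
        manifest,
    )
    expr = _stage("log_cpm", lambda: prep.log_cpm(filtered, factors), manifest)
    expr.logcpm.to_csv(out / "logcpm.tsv", sep="\t")
    manifest["tables"]["logcpm"] = list(expr.logcpm.shape)

    pca = _stage("pca", lambda: prep.pca_scores(expr, k=2), manifest)
    pca_out = pca.scores.copy()
    pca_out.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    manifest["tables"]["pca_variance_explained"] = [
        float(v) for v in pca.variance_explained
    ]

    de_tables: dict[str, pd.DataFrame] = {}
    for name, arm_a, t_a, arm_b, t_b in config.contrasts:
        table = _stage(
            f"de_{name}",
            lambda a=arm_a, ta=t_a, b=arm_b, tb=t_b: differential.run_contrast(
                expr.logcpm, design, (a, float(ta)), (b, float(tb)), config.blocking
            ),
            manifest,
        )
        table.to_csv(out / f"de_{name}.tsv", sep="\t")
        de_tables[name] = table
        manifest["tables"][f"de_{name}"] = len(table)

    if config.enrichment_enabled:
        collection = _stage(
            "read_gmt", lambda: enrichment.read_gmt(config.gmt), manifest
        )
        universe = expr.logcpm.index
        filtered_sets = _stage(
            "filter_sets",
            lambda: enrichment.filter_sets(
                collection, universe, config.set_min, config.set_max
            ),
            manifest,
        )
        enr_results: dict[str, pd.DataFrame] = {}
        for name, table in de_tables.items():
            selected, threshold = differential.top_k_by_s(
                table, min(config.top_k, len(table))
            )
            enr = _stage(
                f"enrich_{name}",
                lambda t=table, sel=selected: enrichment.enrich_table(
                    t["s"], sel, filtered_sets, n_perm=config.n_perm, seed=config.seed
                ),
                manifest,
            )
            enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
            enr_results[name] = enr
            manifest["tables"][f"enrichment_{name}"] = len(enr)
            manifest["tables"][f"s_threshold_{name}"] = threshold
        graph = _stage(
            "enrichment_map",
            lambda: enrichment.enrichment_map(
                enr_results, filtered_sets, config.map_threshold, config.map_top_n
            ),
            manifest,
        )
        nx.write_graphml(graph, out / "enrichment_map.graphml")
        enrichment.write_edge_list(graph, out / "enrichment_map_edges.tsv")
        manifest["tables"]["enrichment_map"] = [
            graph.number_of_nodes(),
            graph.number_of_edges(),
        ]

    if config.signatures:
        scores = {}
        for name, path in sorted(config.signatures.items()):
            sig = signatures.read_signature(path, name)
            scores[name] = _stage(
                f"signature_{name}",
                lambda s=sig: signatures.signature_score(expr.logcpm, s),
                manifest,
            )
        score_df = pd.DataFrame(scores)
        score_df.to_csv(out / "signature_scores.tsv", sep="\t", index_label="sample_id")
        manifest["tables"]["signature_scores"] = list(score_df.shape)

    if config.panel:
        panel = _stage("read_panel", lambda: cytokines.read_panel(config.panel), manifest)
        cyto = _stage(
            "cytokine_equilibrium", lambda: cytokines.analyze_panel(panel), manifest
        )
        cyto.to_csv(out / "cytokine_results.csv", index=False)
        manifest["tables"]["cytokine_results"] = len(cyto)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class DemoParams:
    """Problem sizes for the self-contained demo run."""

    n_genes: int = 6000
    n_gene_sets: int = 40
    n_archetype_sets: int = 10


def run_demo(
    seed: int = 1,
    out_dir: str = "monoflame_demo",
    params: DemoParams | None = None,
    dry_run: bool = False,
) -> dict:
    """Generate synthetic inputs emulating the 36-sample design and run
    the full pipeline on them.

    With ``dry_run`` the planned stages are returned (and printed via the
    CLI) but nothing is written.
    """
    params = params or DemoParams()
    if dry_run:
        return {
            "plan": [
                "simulate_design (36 samples)",
                f"simulate_counts ({params.n_genes} genes)",
                "simulate_cytokine_panel",
                "prep: impute -> TMM -> filter -> log-cpm -> PCA",
                "differential: P24_vs_R24, P96_vs_R48",
                "enrichment: GSEA + ORA -> rank product -> map",
                "signatures: M1, M2",
                "cytokines: rates, free IL-1b/IL-18, active index",
            ],
            "out_dir": out_dir,
            "seed": seed,
        }
    out = Path(out_dir)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    design = synthetic.make_design()
    counts, truth = synthetic.simulate_counts(
        design, synthetic.CountSimParams(n_genes=params.n_genes), seed=seed
    )
    panel, _ = synthetic.simulate_cytokine_panel(seed=seed + 1)
    gene_sets = synthetic.make_gene_sets(
        truth,
        n_random_sets=params.n_gene_sets,
        n_archetype_sets=params.n_archetype_sets,
        seed=seed + 2,
    )
    sigs = synthetic.make_signature_lists(truth, seed=seed + 3)

    synthetic.write_design(design, inputs / "design.tsv")
    prep.write_counts(counts, inputs / "counts.tsv")
    synthetic.write_truth(truth, inputs / "truth.tsv")
    cytokines.write_panel(panel, inputs / "panel.csv")
    enrichment.write_gmt(
        enrichment.GeneSetCollection(
            {k: frozenset(v) for k, v in gene_sets.items()}, "synthetic"
        ),
        inputs / "gene_sets.gmt",
    )
    sig_paths = {}
    for name, df in sigs.items():
        p = inputs / f"signature_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        sig_paths[name] = str(p)

    config = PipelineConfig(
        counts=str(inputs / "counts.tsv"),
        design=str(inputs / "design.tsv"),
        gmt=str(inputs / "gene_sets.gmt"),
        signatures=sig_paths,
        panel=str(inputs / "panel.csv"),
        out_dir=str(out / "results"),
        n_perm=200,
        seed=seed,
    )
    return run_pipeline(config)
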
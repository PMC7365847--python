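"""Synthetic data emulating the two-arm monocyte inflammation study design.

The generators reproduce the *structure* of the study — 36 RNA-seq samples
(6 donors at time 0, 3 at 2 h, then 3 donors per arm over the resolving
time course 4/14/24/48 h and the persistent course 4/14/24/72/96 h),
negative-binomial counts with donor effects and arm-divergent temporal
archetypes after 14 h, and cytokine trajectories that peak at 4–14 h with
soluble-inhibitor excess at late time points — together with ground-truth
tables so downstream estimates can be scored against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cytokines import (
    BindingParams,
    free_il1b_two_site,
    free_ligand_single,
    pg_per_ml_to_pM,
)

RESOLVING_TIMES: tuple[float, ...] = (4.0, 14.0, 24.0, 48.0)
PERSISTENT_TIMES: tuple[float, ...] = (4.0, 14.0, 24.0, 72.0, 96.0)
BASELINE_TIMES: tuple[float, ...] = (0.0, 2.0)

ARCHETYPES = ("null", "transient_up", "resolving_up", "persistent_up", "persistent_down")

#: fraction of the nominal effect size each archetype carries per (arm, time).
#: transient genes pulse at 4–14 h in both arms; resolving_up genes return to
#: baseline by 24–48 h only in the resolving arm; persistent_up/down genes
#: diverge between arms from 24 h on.
_ARCHETYPE_PROFILE: dict[str, dict[str, dict[float, float]]] = {
    "null": {},
    "transient_up": {
        "baseline": {2.0: 0.5},
        "resolving": {4.0: 1.0, 14.0: 1.0, 24.0: 0.25},
        "persistent": {4.0: 1.0, 14.0: 1.0, 24.0: 0.25},
    },
    "resolving_up": {
        "baseline": {2.0: 0.25},
        "resolving": {4.0: 1.0, 14.0: 1.0, 24.0: 0.5, 48.0: 0.0},
        "persistent": {4.0: 1.0, 14.0: 1.0, 24.0: 1.0, 72.0: 1.0, 96.0: 1.0},
    },
    "persistent_up": {
        "baseline": {},
        "resolving": {},
        "persistent": {24.0: 1.0, 72.0: 1.0, 96.0: 1.0},
    },
    "persistent_down": {
        "baseline": {},
        "resolving": {},
        "persistent": {24.0: -1.0, 72.0: -1.0, 96.0: -1.0},
    },
}

#: the two critical between-arm comparisons of the study
DEFAULT_CONTRASTS = ("P24_vs_R24", "P96_vs_R48")
_CONTRAST_CELLS = {
    "P24_vs_R24": (("persistent", 24.0), ("resolving", 24.0)),
    "P96_vs_R48": (("persistent", 96.0), ("resolving", 48.0)),
}


def archetype_log2fc(archetype: str, arm: str, time_h: float, effect: float) -> float:
    """True log2 fold change vs. time 0 for one archetype at one (arm, time)."""
    if archetype not in _ARCHETYPE_PROFILE:
        raise ValueError(f"unknown archetype {archetype!r}")
    return effect * _ARCHETYPE_PROFILE[archetype].get(arm, {}).get(time_h, 0.0)


def make_design(
    n_donors_per_arm: int = 3,
    arms: Sequence[str] = ("resolving", "persistent"),
    n_baseline_donors: int = 6,
    n_t2_donors: int = 3,
    donor_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the sample sheet of the two-arm kinetic design.

    Defaults reproduce the deposited study layout: 6 donors at time 0 and 3
    at 2 h (shared pre-divergence baseline), then 3 donors through the
    resolving course (4, 14, 24, 48 h) and 3 through the persistent course
    (4, 14, 24, 72, 96 h) — 36 samples in total.

    Returns a DataFrame with columns ``sample_id, donor, arm, time_h``.
    """
    if n_donors_per_arm < 1:
        raise ValueError("n_donors_per_arm must be >= 1")
    arms = list(arms)
    valid_arms = {"resolving", "persistent"}
    for a in arms:
        if a not in valid_arms:
            raise ValueError(f"unknown arm {a!r}; expected one of {sorted(valid_arms)}")
    if len(set(arms)) != len(arms):
        raise ValueError("duplicate arm names")

    n_donors = max(n_baseline_donors, n_t2_donors, n_donors_per_arm * len(arms))
    if donor_ids is None:
        donor_ids = [f"D{i + 1}" for i in range(n_donors)]
    donor_ids = list(donor_ids)
    if len(set(donor_ids)) != len(donor_ids):
        raise ValueError("duplicate donor ids requested")
    if len(donor_ids) < n_donors:
        raise ValueError(f"need at least {n_donors} donor ids, got {len(donor_ids)}")

    rows: list[tuple[str, str, str, float]] = []
    for d in donor_ids[:n_baseline_donors]:
        rows.append((f"{d}_T0", d, "baseline", 0.0))
    for d in donor_ids[:n_t2_donors]:
        rows.append((f"{d}_T2", d, "baseline", 2.0))
    arm_times = {"resolving": RESOLVING_TIMES, "persistent": PERSISTENT_TIMES}
    arm_code = {"resolving": "R", "persistent": "P"}
    for i, arm in enumerate(arms):
        arm_donors = donor_ids[i * n_donors_per_arm : (i + 1) * n_donors_per_arm]
        for t in arm_times[arm]:
            for d in arm_donors:
                rows.append((f"{d}_{arm_code[arm]}{int(t)}", d, arm, t))
    design = pd.DataFrame(rows, columns=["sample_id", "donor", "arm", "time_h"])
    if design["sample_id"].duplicated().any():
        raise ValueError("sample ids are not unique")
    return design


@dataclass
class CountSimParams:
    """Settings for the negative-binomial count simulator.

    The NB model is mean–dispersion: Var = mu + phi * mu^2 with gene-wise
    dispersion phi drawn lognormal. Donor effects are additive on the log2
    mean and shared across a donor's time points. Effect sizes and archetype
    fractions are free parameters of the generator, not estimates of the
    study.
    """

    n_genes: int = 10_000
    archetype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.90,
            "transient_up": 0.025,
            "resolving_up": 0.025,
            "persistent_up": 0.025,
            "persistent_down": 0.025,
        }
    )
    effect_log2fc: float = 1.5
    dispersion_log_mean: float = math.log(0.1)
    dispersion_log_sd: float = 0.5
    donor_sd: float = 0.2
    libsize_range: tuple[float, float] = (5e6, 15e6)
    base_log2_sd: float = 2.0

    def validate(self) -> None:
        fr = dict(self.archetype_fractions)
        unknown = set(fr) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("archetype fractions must be non-negative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        if self.dispersion_log_sd < 0 or self.donor_sd < 0:
            raise ValueError("dispersion/donor SDs must be non-negative")
        lo, hi = self.libsize_range
        if not (0 < lo < hi):
            raise ValueError("libsize_range must be increasing and positive")


def simulate_counts(
    design: pd.DataFrame,
    params: CountSimParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix plus its ground-truth table.

    Returns ``(counts, truth)``: counts is a genes x samples integer
    DataFrame (index gene_id, columns sample_id); truth holds each gene's
    archetype and true log2FC for the two critical between-arm contrasts.
    Same seed, same inputs => bit-identical output.
    """
    params = params or CountSimParams()
    params.validate()
    rng = np.random.default_rng(seed)

    n_genes = params.n_genes
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)])

    # archetype assignment with exact proportions (largest-remainder rounding)
    fracs = {a: params.archetype_fractions.get(a, 0.0) for a in ARCHETYPES}
    counts_per = {a: int(math.floor(f * n_genes)) for a, f in fracs.items()}
    remainder = n_genes - sum(counts_per.values())
    by_frac = sorted(ARCHETYPES, key=lambda a: -(fracs[a] * n_genes - counts_per[a]))
    for a in by_frac[:remainder]:
        counts_per[a] += 1
    archetypes = np.repeat(
        [a for a in ARCHETYPES for _ in range(1)],
        [counts_per[a] for a in ARCHETYPES],
    )
    rng.shuffle(archetypes)

    base_log2 = rng.normal(0.0, params.base_log2_sd, size=n_genes)
    phi = np.exp(rng.normal(params.dispersion_log_mean, params.dispersion_log_sd, n_genes))

    donors = design["donor"].unique()
    donor_effect = {
        d: rng.normal(0.0, params.donor_sd, size=n_genes) for d in donors
    }

    lo, hi = params.libsize_range
    span = hi - lo
    # target library sizes drawn from the middle of the range so that the
    # realized NB totals stay inside the configured bounds
    targets = rng.uniform(lo + 0.15 * span, hi - 0.15 * span, size=len(design))

    lfc_cache: dict[tuple[str, float], np.ndarray] = {}
    for (arm, t) in design[["arm", "time_h"]].drop_duplicates().itertuples(index=False):
        lfc = np.array(
            [archetype_log2fc(a, arm, t, params.effect_log2fc) for a in ARCHETYPES]
        )
        arch_idx = {a: i for i, a in enumerate(ARCHETYPES)}
        lfc_cache[(arm, t)] = lfc[[arch_idx[a] for a in archetypes]]

    counts = np.empty((n_genes, len(design)), dtype=np.int64)
    for j, row in enumerate(design.itertuples(index=False)):
        log2_mu = base_log2 + lfc_cache[(row.arm, row.time_h)] + donor_effect[row.donor]
        w = np.exp2(log2_mu)
        mu = w / w.sum() * targets[j]
        # NB(mean mu, var mu + phi mu^2): n = 1/phi, p = 1/(1 + phi*mu)
        n_param = 1.0 / phi
        p_param = 1.0 / (1.0 + phi * mu)
        counts[:, j] = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"].to_numpy())
    counts_df.index.name = "gene_id"

    truth = pd.DataFrame({"gene_id": gene_ids, "archetype": archetypes})
    for name, ((arm_a, t_a), (arm_b, t_b)) in _CONTRAST_CELLS.items():
        truth[f"true_log2fc_{name}"] = [
            archetype_log2fc(a, arm_a, t_a, params.effect_log2fc)
            - archetype_log2fc(a, arm_b, t_b, params.effect_log2fc)
            for a in archetypes
        ]
    truth = truth.set_index("gene_id")
    return counts_df, truth


# ---------------------------------------------------------------------------
# cytokine panel
# ---------------------------------------------------------------------------

@dataclass
class AnalyteParams:
    """Gamma-pulse trajectory for one analyte: rise, peak, decay, plateau."""

    name: str
    mw_kda: float
    peak_time_h: float
    peak_pg_ml: float
    shape: float = 2.0
    late_plateau_pg_ml: float = 0.0  # residual late-time level (inhibitors)

    def total_pg_ml(self, t: float) -> float:
        if t <= 0:
            return 0.0
        x = t / self.peak_time_h
        pulse = self.peak_pg_ml * x**self.shape * math.exp(self.shape * (1.0 - x))
        plateau = self.late_plateau_pg_ml * (1.0 - math.exp(-t / 30.0))
        return pulse + plateau


def _default_analytes() -> list[AnalyteParams]:
    # peak at 4-14 h for the agonist cytokines; soluble inhibitors keep a
    # late plateau so that they are in molar excess at 72-96 h
    return [
        AnalyteParams("IL-1b", 17.0, 14.0, 2000.0),
        AnalyteParams("IL-18", 18.0, 4.0, 150.0),
        AnalyteParams("IL-1Ra", 17.0, 14.0, 20000.0, late_plateau_pg_ml=2000.0),
        AnalyteParams("sIL-1R2", 47.0, 24.0, 600.0, late_plateau_pg_ml=400.0),
        AnalyteParams("sIL-1R3", 47.0, 24.0, 300.0, late_plateau_pg_ml=200.0),
        AnalyteParams("IL-18BP", 40.0, 24.0, 2000.0, late_plateau_pg_ml=1500.0),
    ]


@dataclass
class CytokineSimParams:
    """Settings for the cytokine panel simulator.

    Cultures start at 5e6 cells in 2 ml; supernatants are replaced at each
    medium change, so measured totals accumulate from the previous change.
    Default viability stays above 80% at 48 h and above 50% at 96 h.
    """

    analytes: list[AnalyteParams] = field(default_factory=_default_analytes)
    time_points_h: tuple[float, ...] = (2.0, 4.0, 14.0, 24.0, 72.0, 96.0)
    media_changes_h: tuple[float, ...] = (0.0, 2.0, 7.0, 24.0, 72.0)
    volume_ml: float = 2.0
    cells_plated: float = 5e6
    measurement_cv: float = 0.1
    viability_curve: Mapping[float, float] = field(
        default_factory=lambda: {0.0: 1.0, 24.0: 0.95, 48.0: 0.85, 96.0: 0.55}
    )
    binding: BindingParams = field(default_factory=BindingParams)

    def validate(self) -> None:
        if self.measurement_cv < 0:
            raise ValueError("measurement CV must be >= 0")
        if self.volume_ml <= 0 or self.cells_plated <= 0:
            raise ValueError("volume and cell number must be positive")
        if not self.analytes:
            raise ValueError("at least one analyte required")

    def viable_fraction(self, t: float) -> float:
        ts = sorted(self.viability_curve)
        vs = [self.viability_curve[x] for x in ts]
        return float(np.interp(t, ts, vs))

    def last_media_change(self, t: float) -> float:
        before = [c for c in self.media_changes_h if c < t]
        return max(before) if before else 0.0


def simulate_cytokine_panel(
    params: CytokineSimParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a measured cytokine panel plus its noise-free truth.

    Returns ``(panel, truth)``. The panel has one row per (analyte, time):
    ``analyte, time_h, conc_pg_ml, volume_ml, viable_cells,
    last_media_change_h``; measured totals are the truth multiplied by
    lognormal noise with the configured CV. The truth table carries total,
    inhibitor and free concentrations in pM, where free is computed by the
    equilibrium solver (two-site for IL-1b, single-site for IL-18) and
    therefore satisfies the mass-action isotherm exactly.
    """
    params = params or CytokineSimParams()
    params.validate()
    rng = np.random.default_rng(seed)

    by_name = {a.name: a for a in params.analytes}
    sigma = math.sqrt(math.log1p(params.measurement_cv**2))

    panel_rows = []
    truth_rows = []
    for t in params.time_points_h:
        totals_pg = {a.name: a.total_pg_ml(t) for a in params.analytes}
        totals_pm = {
            name: pg_per_ml_to_pM(v, by_name[name].mw_kda) for name, v in totals_pg.items()
        }
        for a in params.analytes:
            noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            panel_rows.append(
                {
                    "analyte": a.name,
                    "time_h": t,
                    "conc_pg_ml": totals_pg[a.name] * noise,
                    "volume_ml": params.volume_ml,
                    "viable_cells": params.cells_plated * params.viable_fraction(t),
                    "last_media_change_h": params.last_media_change(t),
                }
            )
        il1b = totals_pm.get("IL-1b", 0.0)
        il18 = totals_pm.get("IL-18", 0.0)
        r2 = totals_pm.get("sIL-1R2", 0.0)
        r3 = totals_pm.get("sIL-1R3", 0.0)
        bp = totals_pm.get("IL-18BP", 0.0)
        if "IL-1b" in totals_pm:
            truth_rows.append(
                {
                    "analyte": "IL-1b",
                    "time_h": t,
                    "true_total_pM": il1b,
                    "true_inhibitor_pM": r2,
                    "true_free_pM": free_il1b_two_site(il1b, r2, r3, params.binding),
                }
            )
        if "IL-18" in totals_pm:
            truth_rows.append(
                {
                    "analyte": "IL-18",
                    "time_h": t,
                    "true_total_pM": il18,
                    "true_inhibitor_pM": bp,
                    "true_free_pM": free_ligand_single(il18, bp, params.binding.kd_il18_bp),
                }
            )
    panel = pd.DataFrame(panel_rows)
    truth = pd.DataFrame(truth_rows)
    return panel, truth


# ---------------------------------------------------------------------------
# auxiliary synthetic inputs for the demo pipeline
# ---------------------------------------------------------------------------

def make_gene_sets(
    truth: pd.DataFrame,
    n_random_sets: int = 40,
    set_size_range: tuple[int, int] = (15, 80),
    n_archetype_sets: int = 10,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic GMT-style collection over simulated genes.

    Random sets provide the null background; archetype-enriched sets (drawn
    mostly from one non-null archetype) give the enrichment stage signal.
    """
    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()
    sets: dict[str, set[str]] = {}
    lo, hi = set_size_range
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"RANDOM_{i + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    non_null = [a for a in ARCHETYPES if a != "null"]
    for i in range(n_archetype_sets):
        arch = non_null[i % len(non_null)]
        pool = truth.index[truth["archetype"] == arch].to_numpy()
        size = int(rng.integers(lo, hi + 1))
        n_sig = min(len(pool), int(0.7 * size))
        members = set(rng.choice(pool, size=n_sig, replace=False))
        members |= set(rng.choice(genes, size=size - n_sig, replace=False))
        sets[f"{arch.upper()}_SET_{i + 1:02d}"] = members
    return sets


def make_signature_lists(
    truth: pd.DataFrame,
    n_m1: int = 98,
    n_m2: int = 107,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Synthetic signed M1/M2 signature lists over simulated genes.

    The M1 list is built from early-pulse archetypes (up in the activated
    state), the M2 list from late-divergence archetypes, mirroring the
    98/107-gene signed lists the real analysis takes as input.
    """
    rng = np.random.default_rng(seed)
    early = truth.index[truth["archetype"].isin(["transient_up", "resolving_up"])]
    late_up = truth.index[truth["archetype"] == "persistent_up"]
    late_dn = truth.index[truth["archetype"] == "persistent_down"]
    nulls = truth.index[truth["archetype"] == "null"]

    def _pick(pool, n):
        pool = np.asarray(pool)
        n = min(n, len(pool))
        return rng.choice(pool, size=n, replace=False)

    m1_up = _pick(early, int(0.7 * n_m1))
    m1_dn = _pick(nulls, n_m1 - len(m1_up))
    m2_up = _pick(late_up, int(0.5 * n_m2))
    m2_dn = _pick(late_dn, n_m2 - len(m2_up))
    m1 = pd.DataFrame(
        {
            "gene_id": np.concatenate([m1_up, m1_dn]),
            "direction": ["up"] * len(m1_up) + ["down"] * len(m1_dn),
        }
    )
    m2 = pd.DataFrame(
        {
            "gene_id": np.concatenate([m2_up, m2_dn]),
            "direction": ["up"] * len(m2_up) + ["down"] * len(m2_dn),
        }
    )
    return {"M1": m1, "M2": m2}


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")
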
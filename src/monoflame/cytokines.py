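"""Free and active IL-1 family cytokines by the law of mass action.

Measured ELISA totals of IL-1beta and IL-18 overstate biological activity
because both cytokines circulate partly bound to soluble inhibitors: the
decoy receptor sIL-1R2 for IL-1beta (Kd 2700 pM, with a high-affinity
5.6 pM ternary pool when sIL-1R2 pairs with the accessory chain sIL-1R3)
and IL-18BP for IL-18 (Kd 400 pM). Under one-ligand/one-receptor specific
binding (Clark's theory) the free-ligand concentration has the closed form

    LF = ( -RT + LT - Kd + sqrt((RT - LT + Kd)^2 + 4*LT*Kd) ) / 2

with all quantities in pM. This module implements that formula, the
two-site extension for IL-1beta, the active-IL-1beta index
(free IL-1beta / IL-1Ra) * 1000, per-cell per-hour production-rate
normalization, and the one-way ANOVA + Tukey HSD comparisons used on the
rate profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BindingParams",
    "pg_per_ml_to_pM",
    "free_ligand_single",
    "free_il1b_two_site",
    "active_il1b",
    "production_rate",
    "anova_tukey",
    "read_panel",
    "analyze_panel",
]


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium constants (pM) and molecular weights (kDa).

    ``kd_il1ra_r2`` (the 25 uM sIL-1R2 affinity for IL-1Ra) is stored for
    documentation only: the equilibrium follows a one-ligand model in which
    IL-1Ra does not compete for the decoy receptor.
    """

    kd_il1b_r2: float = 2700.0
    kd_il18_bp: float = 400.0
    kd_ternary: float = 5.6
    kd_il1ra_r2: float = 25e6  # 25 uM in pM; documented, unused
    mw_kda: dict = field(
        default_factory=lambda: {
            "IL-1b": 17.0,
            "IL-18": 18.0,
            "sIL-1R2": 47.0,
            "IL-18BP": 40.0,
            "sIL-1R3": 47.0,
            "IL-1Ra": 17.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("kd_il1b_r2", "kd_il18_bp", "kd_ternary", "kd_il1ra_r2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pg_per_ml_to_pM(conc_pg_ml: float, mw_kda: float) -> float:
    """Convert a mass concentration to molarity: pM = (pg/ml) / (kDa).

    1 pg/ml = 1e-9 g/L; dividing by the molar mass in kDa (1e3 g/mol)
    gives 1e-12 mol/L per kDa.
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    conc = np.asarray(conc_pg_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    out = conc / mw_kda
    return float(out) if out.ndim == 0 else out


def free_ligand_single(LT: float, RT: float, Kd: float) -> float:
    """Free ligand for one ligand binding one soluble receptor/inhibitor.

    Closed-form root of the binding isotherm LT - LF = RT*LF/(Kd + LF);
    all concentrations in pM. Satisfies 0 <= LF <= LT.
    """
    if LT < 0 or RT < 0:
        raise ValueError("total concentrations must be non-negative")
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    b = RT - LT + Kd
    sqrt_disc = math.sqrt(b * b + 4.0 * LT * Kd)
    # algebraically identical forms; pick the one without cancellation
    lf = (sqrt_disc - b) / 2.0 if b <= 0 else 2.0 * LT * Kd / (sqrt_disc + b)
    return min(max(lf, 0.0), LT)


def free_il1b_two_site(
    LT: float,
    R2T: float,
    R3T: float,
    params: BindingParams | None = None,
    kd_r2_r3: float | None = None,
) -> float:
    """Free IL-1beta with sIL-1R2 split into binary and ternary pools.

    The fraction of sIL-1R2 engaged with sIL-1R3 forms a high-affinity
    (kd_ternary) pool; the remainder binds with the binary-complex Kd.
    By default the pairing is stoichiometric, C = min(R2T, R3T). If
    ``kd_r2_r3`` is given, C is instead the equilibrium R2:R3 complex at
    that dissociation constant (sensitivity analysis). LF is the bracketed
    root of

        LT = LF + (R2T - C)*LF/(Kd_binary + LF) + C*LF/(Kd_ternary + LF)

    and is monotone decreasing in both R2T and R3T.
    """
    params = params or BindingParams()
    if LT < 0 or R2T < 0 or R3T < 0:
        raise ValueError("total concentrations must be non-negative")
    if LT == 0:
        return 0.0
    if kd_r2_r3 is None:
        C = min(R2T, R3T)
    else:
        # R2 + R3 <-> R2:R3 at kd_r2_r3, same closed form with R3 as ligand
        bound_r3 = R3T - free_ligand_single(R3T, R2T, kd_r2_r3)
        C = min(bound_r3, R2T)
    binary = R2T - C

    def mass_balance(lf: float) -> float:
        return (
            lf
            + binary * lf / (params.kd_il1b_r2 + lf)
            + C * lf / (params.kd_ternary + lf)
            - LT
        )

    if mass_balance(LT) <= 0:  # no inhibitor at all
        return LT
    lf = optimize.brentq(mass_balance, 0.0, LT, xtol=1e-15, rtol=1e-14)
    return float(lf)


def active_il1b(free_il1b_conc: float, il1ra_conc: float) -> float:
    """Active-IL-1beta index: (free IL-1beta / IL-1Ra) * 1000.

    Both arguments must share units (pM here); the index is dimensionless.
    """
    if il1ra_conc <= 0:
        raise ValueError("IL-1Ra concentration must be positive (ratio undefined)")
    if free_il1b_conc < 0:
        raise ValueError("free IL-1beta must be non-negative")
    return free_il1b_conc / il1ra_conc * 1000.0


def production_rate(
    conc_pg_ml: float,
    volume_ml: float,
    viable_cells: float,
    time_h: float,
    last_media_change_h: float,
) -> float:
    """Cytokine production rate in pg per 10^6 viable cells per hour.

    The accumulation interval runs from the last medium change (supernatant
    replacement resets accumulation) to the harvest time.
    """
    interval = time_h - last_media_change_h
    if interval <= 0:
        raise ValueError("harvest must come after the last media change")
    if volume_ml <= 0 or viable_cells <= 0:
        raise ValueError("volume and viable cells must be positive")
    return (conc_pg_ml * volume_ml) / ((viable_cells / 1e6) * interval)


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    pairwise_p: np.ndarray  # groups x groups, Tukey HSD adjusted


def anova_tukey(groups: list[list[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey's HSD pairwise comparisons.

    Unequal group sizes use the Tukey–Kramer correction (scipy default).
    A configuration with zero within-group variance but unequal means is
    reported at the smallest positive float with a warning.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    within_var = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if within_var == 0:
        if np.ptp(means) == 0:
            return AnovaTukeyResult(0.0, 1.0, k - 1, n - k, np.ones((k, k)))
        warnings.warn(
            "zero within-group variance with unequal means; p reported below "
            "machine precision",
            RuntimeWarning,
        )
        tiny = np.finfo(float).tiny
        pw = np.full((k, k), tiny)
        np.fill_diagonal(pw, 1.0)
        return AnovaTukeyResult(math.inf, tiny, k - 1, n - k, pw)
    f_stat, p_value = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    return AnovaTukeyResult(
        float(f_stat), float(p_value), k - 1, n - k, np.asarray(hsd.pvalue)
    )


# ---------------------------------------------------------------------------
# panel I/O and end-to-end analysis
# ---------------------------------------------------------------------------

PANEL_COLUMNS = (
    "analyte",
    "time_h",
    "conc_pg_ml",
    "volume_ml",
    "viable_cells",
    "last_media_change_h",
)


def read_panel(path) -> pd.DataFrame:
    """Read a cytokine panel CSV and validate its schema."""
    panel = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    for analyte, sub in panel.groupby("analyte"):
        t = sub["time_h"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"time points not strictly increasing for {analyte!r}")
    if (panel["conc_pg_ml"] < 0).any():
        raise ValueError("negative concentrations in panel")
    if (panel["last_media_change_h"] >= panel["time_h"]).any():
        raise ValueError("last_media_change_h must precede time_h")
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def analyze_panel(
    panel: pd.DataFrame,
    params: BindingParams | None = None,
    ligand_il1b: str = "IL-1b",
    ligand_il18: str = "IL-18",
    inhibitor_r2: str = "sIL-1R2",
    inhibitor_r3: str = "sIL-1R3",
    inhibitor_bp: str = "IL-18BP",
    antagonist: str = "IL-1Ra",
) -> pd.DataFrame:
    """Per-analyte, per-time results: rate, pM totals, free and active levels.

    Free IL-18 uses the single-site closed form against IL-18BP; free
    IL-1beta uses the two-site solver against sIL-1R2/sIL-1R3. The active
    IL-1beta index divides free IL-1beta by IL-1Ra (both pM). Analytes
    without a configured inhibitor report free = total.
    """
    params = params or BindingParams()
    out = panel.copy()
    out["rate_pg_per_1e6_per_h"] = [
        production_rate(
            r.conc_pg_ml, r.volume_ml, r.viable_cells, r.time_h, r.last_media_change_h
        )
        for r in out.itertuples(index=False)
    ]
    out["conc_pM"] = [
        pg_per_ml_to_pM(r.conc_pg_ml, params.mw_kda.get(r.analyte, math.nan))
        if r.analyte in params.mw_kda
        else math.nan
        for r in out.itertuples(index=False)
    ]

    pm_by_time: dict[float, dict[str, float]] = {}
    for r in out.itertuples(index=False):
        pm_by_time.setdefault(r.time_h, {})[r.analyte] = r.conc_pM

    free = []
    active = []
    for r in out.itertuples(index=False):
        levels = pm_by_time[r.time_h]
        if r.analyte == ligand_il1b:
            lf = free_il1b_two_site(
                r.conc_pM,
                levels.get(inhibitor_r2, 0.0),
                levels.get(inhibitor_r3, 0.0),
                params,
            )
            ra = levels.get(antagonist, math.nan)
            act = active_il1b(lf, ra) if ra and ra > 0 else math.nan
        elif r.analyte == ligand_il18:
            lf = free_ligand_single(
                r.conc_pM, levels.get(inhibitor_bp, 0.0), params.kd_il18_bp
            )
            act = math.nan
        else:
            lf = r.conc_pM
            act = math.nan
        free.append(lf)
        active.append(act)
    out["free_pM"] = free
    out["active_index"] = active
    return out
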
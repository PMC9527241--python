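"""Ex vivo chemosensitivity metrics and highest-single-agent synergy.

Two viability readouts are supported, both normalized against same-sample
DMSO wells:

* CD138 loss — plasma cells shed CD138 while dying, so the printed
  formula ``%CD138+[drug] / %CD138+[DMSO]`` is a *survival* ratio; it is
  reported verbatim alongside the complementary death fraction
  ``max(0, 1 - ratio)``.
* Annexin-V positivity within CD138+ cells — specific apoptosis
  ``100 * (annexin[drug] - annexin[DMSO]) / (100 - annexin[DMSO])``.

Combination grids are scored by excess over the highest single agent
(HSA): positive excess = synergy, negative = antagonism.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChemoError",
    "CellDeath",
    "AnnexinSpecificApoptosis",
    "SynergyMatrix",
    "cell_death_eq2",
    "specific_apoptosis_annexin",
    "summarize_viability",
    "hsa_synergy",
    "synergy_from_viability",
    "correlate_profiling_sensitivity",
]


class ChemoError(ValueError):
    """Invalid chemosensitivity inputs."""


class CellDeath(NamedTuple):
    ratio_as_printed: float  # %CD138+[drug] / %CD138+[DMSO] (survival ratio)
    death_fraction: float    # max(0, 1 - ratio)


class AnnexinSpecificApoptosis(NamedTuple):
    raw: float
    clamped: float


def cell_death_eq2(pct_cd138_drug: float, pct_cd138_dmso: float) -> CellDeath:
    """CD138-loss viability readout.

    The printed formula is the CD138+ survival ratio drug/DMSO; both that
    ratio and the complementary death fraction are returned with explicit
    labels.  Ratios above 1 (drug > DMSO) are allowed; the death fraction is
    then floored at 0.
    """
    if pct_cd138_dmso <= 0:
        raise ChemoError("%CD138+[DMSO] must be positive")
    if pct_cd138_drug < 0:
        raise ChemoError("%CD138+[drug] must be nonnegative")
    ratio = pct_cd138_drug / pct_cd138_dmso
    return CellDeath(ratio_as_printed=ratio, death_fraction=max(0.0, 1.0 - ratio))


def specific_apoptosis_annexin(
    annexin_drug: float, annexin_dmso: float
) -> AnnexinSpecificApoptosis:
    """Annexin-V specific apoptosis within CD138+ cells, in percent."""
    for name, v in (("annexin_drug", annexin_drug), ("annexin_dmso", annexin_dmso)):
        if not 0.0 <= v <= 100.0:
            raise ChemoError(f"{name} must lie in [0, 100], got {v}")
    if annexin_dmso >= 100.0:
        raise ChemoError("%Annexin+[DMSO] = 100 leaves no dynamic range")
    raw = 100.0 * (annexin_drug - annexin_dmso) / (100.0 - annexin_dmso)
    return AnnexinSpecificApoptosis(raw=raw, clamped=float(np.clip(raw, 0.0, 100.0)))


def summarize_viability(wells: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged per-condition viability metrics for one or more samples.

    Well-level percentages are averaged within (sample, drug_a, dose_a,
    drug_b, dose_b) before normalization against the sample's DMSO mean.
    Returns one row per condition with the survival ratio, death fraction
    and Annexin-specific apoptosis (raw and clamped).
    """
    required = {"sample_id", "drug_a", "dose_a", "pct_cd138_pos", "pct_annexin_pos_in_cd138"}
    missing = required - set(wells.columns)
    if missing:
        raise ChemoError(f"viability table missing column(s): {sorted(missing)}")
    wells = wells.copy()
    if "drug_b" not in wells.columns:
        wells["drug_b"] = ""
        wells["dose_b"] = 0.0
    wells["drug_b"] = wells["drug_b"].fillna("")
    wells["dose_b"] = wells["dose_b"].fillna(0.0)

    keys = ["sample_id", "drug_a", "dose_a", "drug_b", "dose_b"]
    means = (
        wells.groupby(keys, sort=False)[["pct_cd138_pos", "pct_annexin_pos_in_cd138"]]
        .mean()
        .reset_index()
    )
    out_rows = []
    for sample_id, grp in means.groupby("sample_id", sort=False):
        dmso = grp[(grp["drug_a"] == "DMSO") & (grp["dose_a"] == 0.0)]
        if len(dmso) == 0:
            raise ChemoError(f"sample {sample_id!r} has no DMSO wells")
        cd138_dmso = float(dmso["pct_cd138_pos"].iloc[0])
        annexin_dmso = float(dmso["pct_annexin_pos_in_cd138"].iloc[0])
        for _, row in grp.iterrows():
            death = cell_death_eq2(float(row["pct_cd138_pos"]), cd138_dmso)
            sa = specific_apoptosis_annexin(
                float(row["pct_annexin_pos_in_cd138"]), annexin_dmso
            )
            out_rows.append(
                {
                    "sample_id": sample_id,
                    "drug_a": row["drug_a"],
                    "dose_a": float(row["dose_a"]),
                    "drug_b": row["drug_b"],
                    "dose_b": float(row["dose_b"]),
                    "cd138_survival_ratio": death.ratio_as_printed,
                    "death_fraction": death.death_fraction,
                    "annexin_specific_apoptosis_raw": sa.raw,
                    "annexin_specific_apoptosis": sa.clamped,
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# HSA synergy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyMatrix:
    """Excess-over-highest-single-agent surface for one drug pair.

    ``effect`` holds the observed % specific apoptosis on the dose_a x
    dose_b grid (margins included at dose 0); ``excess`` is defined on the
    interior cells only.  ``summary_mean_excess`` averages the interior
    excess (points); the max is also reported.
    """

    drug_a: str
    drug_b: str
    doses_a: tuple[float, ...]       # without 0
    doses_b: tuple[float, ...]
    effect: pd.DataFrame             # index doses incl. 0 (rows=A, cols=B)
    excess: pd.DataFrame             # interior cells only
    marginal_a: pd.Series
    marginal_b: pd.Series
    summary_mean_excess: float
    summary_max_excess: float

    def to_dict(self) -> dict:
        return {
            "drug_a": self.drug_a,
            "drug_b": self.drug_b,
            "doses_a": list(self.doses_a),
            "doses_b": list(self.doses_b),
            "effect": self.effect.to_numpy().tolist(),
            "excess": self.excess.to_numpy().tolist(),
            "marginal_a": self.marginal_a.to_list(),
            "marginal_b": self.marginal_b.to_list(),
            "summary_mean_excess": self.summary_mean_excess,
            "summary_max_excess": self.summary_max_excess,
        }


def hsa_synergy(
    combo: pd.DataFrame,
    drug_a: str = "A",
    drug_b: str = "B",
    effect_col: str = "effect",
) -> SynergyMatrix:
    """Score a combination surface by excess over the highest single agent.

    ``combo`` holds one row per grid cell with columns dose_a, dose_b and
    the effect (in % specific apoptosis); rows with dose_b == 0 are the
    drug-A margin and vice versa.  excess(a, b) = E(a, b) -
    max(E(a, 0), E(0, b)) on interior cells.
    """
    for col in ("dose_a", "dose_b", effect_col):
        if col not in combo.columns:
            raise ChemoError(f"combination table missing column {col!r}")
    grid = combo.groupby(["dose_a", "dose_b"], sort=True)[effect_col].mean().unstack()
    doses_a = [d for d in grid.index if d > 0]
    doses_b = [d for d in grid.columns if d > 0]
    if 0.0 not in grid.index or grid.loc[:, grid.columns == 0.0].isna().all().all():
        raise ChemoError(f"missing single-agent margin for {drug_b!r} (dose_a = 0 rows)")
    if 0.0 not in grid.columns:
        raise ChemoError(f"missing single-agent margin for {drug_a!r} (dose_b = 0 rows)")
    marginal_a = grid.loc[doses_a, 0.0]
    marginal_b = grid.loc[0.0, doses_b]
    if marginal_a.isna().any():
        raise ChemoError(f"missing single-agent margin for {drug_a!r} (dose_b = 0 rows)")
    if marginal_b.isna().any():
        raise ChemoError(f"missing single-agent margin for {drug_b!r} (dose_a = 0 rows)")
    if not doses_a or not doses_b:
        raise ChemoError("no interior combination cells in the grid")

    interior = grid.loc[doses_a, doses_b]
    if interior.isna().any().any():
        raise ChemoError("combination grid has missing interior cells")
    hsa_ref = np.maximum.outer(marginal_a.to_numpy(), marginal_b.to_numpy())
    excess = interior - hsa_ref
    return SynergyMatrix(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=tuple(doses_a),
        doses_b=tuple(doses_b),
        effect=grid,
        excess=excess,
        marginal_a=marginal_a,
        marginal_b=marginal_b,
        summary_mean_excess=float(excess.to_numpy().mean()),
        summary_max_excess=float(excess.to_numpy().max()),
    )


def synergy_from_viability(
    wells: pd.DataFrame, drug_a: str, drug_b: str
) -> SynergyMatrix:
    """HSA synergy from raw combination wells, on the Annexin scale.

    The wells must include DMSO, both single-agent margins and the interior
    combination cells for (drug_a, drug_b).
    """
    summary = summarize_viability(wells)
    mask = (
        summary["drug_a"].isin(["DMSO", drug_a])
        & summary["drug_b"].isin(["", drug_b])
    )
    sub = summary[mask]
    return hsa_synergy(
        sub,
        drug_a=drug_a,
        drug_b=drug_b,
        effect_col="annexin_specific_apoptosis",
    )


# ---------------------------------------------------------------------------
# Profiling vs sensitivity correlation
# ---------------------------------------------------------------------------

def correlate_profiling_sensitivity(x, y) -> dict:
    """Spearman rank correlation between paired per-sample metrics.

    Pairs with a missing value are dropped (the effective n is reported);
    ties receive average ranks; the p-value is two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ChemoError("x and y must be paired (equal length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ChemoError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ChemoError("correlation undefined: zero variance in an input vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": n}
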
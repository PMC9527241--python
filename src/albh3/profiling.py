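"""BH3-profiling metrics: specific apoptosis, dose-response AUC,
delta-priming and pro-survival dependency calls.

The central normalization converts per-well cytochrome-c release into
control-anchored %specific apoptosis,

    %SA = 100 * (release[peptide] - release[negative]) /
                (release[positive] - release[negative]),

with the negative control an inert exposure (DMSO or the non-interacting
PUMA2A peptide) and the positive control the BAX/BAK-independent
pore-former alamethicin.  Peptide titrations are summarized by the area
under the response over log10(dose), normalized by the log-dose span so a
constant response r has AUC = r (units: % specific apoptosis, 0-100).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecificApoptosis",
    "BH3Profile",
    "DependencyCall",
    "ProfileError",
    "DegenerateControlsError",
    "specific_apoptosis",
    "dose_response_auc",
    "profile_wells",
    "delta_priming",
    "call_dependencies",
]


class ProfileError(ValueError):
    """Invalid profiling inputs (missing peptides, mismatched grids, ...)."""


class DegenerateControlsError(ValueError):
    """Positive control does not exceed the negative control."""


class SpecificApoptosis(NamedTuple):
    raw: float      # can fall outside [0, 100] with noisy controls
    clamped: float  # min(100, max(0, raw))


def specific_apoptosis(
    pep_release: float, neg_release: float, pos_release: float
) -> SpecificApoptosis:
    """Control-normalized %specific apoptosis for one peptide well.

    All three inputs are %cytochrome-c release in [0, 100]; the positive
    control must exceed the negative control.  Both the raw value (which can
    leave [0, 100] under noise) and a clamped copy are returned.
    """
    for name, v in (("pep_release", pep_release), ("neg_release", neg_release),
                    ("pos_release", pos_release)):
        if not 0.0 <= v <= 100.0:
            raise ProfileError(f"{name} must lie in [0, 100], got {v}")
    if pos_release <= neg_release:
        raise DegenerateControlsError(
            f"positive-control release ({pos_release}) must exceed the "
            f"negative-control release ({neg_release})"
        )
    raw = 100.0 * (pep_release - neg_release) / (pos_release - neg_release)
    return SpecificApoptosis(raw=raw, clamped=float(np.clip(raw, 0.0, 100.0)))


def dose_response_auc(doses: Sequence[float], responses: Sequence[float]) -> float:
    """Normalized area under the response over log10(dose), in [0, 100].

    Trapezoidal integral of the response against log10(dose) divided by the
    log10-dose span, so a constant response r yields AUC = r.  Requires at
    least two distinct, strictly positive doses sorted ascending.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ProfileError("doses and responses must have equal length")
    if doses.size < 2 or np.unique(doses).size < 2:
        raise ProfileError(
            "need at least two distinct doses for an AUC; "
            "use the raw response for a single dose"
        )
    if (doses <= 0).any():
        raise ProfileError("doses must be strictly positive")
    if (np.diff(doses) <= 0).any():
        raise ProfileError("doses must be sorted strictly ascending")
    if ((responses < 0) | (responses > 100)).any():
        raise ProfileError("responses must lie in [0, 100]")
    x = np.log10(doses)
    return float(np.trapezoid(responses, x) / (x[-1] - x[0]))


@dataclass(frozen=True)
class BH3Profile:
    """Per-sample specific-apoptosis values on a (peptide, dose) grid.

    ``table`` has one row per peptide well with columns peptide, dose,
    raw_release, specific_apoptosis_raw, specific_apoptosis (clamped);
    ``auc`` maps each peptide with >= 2 doses to its normalized AUC.
    """

    sample_id: str
    table: pd.DataFrame
    auc: pd.Series
    controls_used: str          # "dmso" or "puma2a"
    neg_release: float
    pos_release: float
    auc_dose_scale: str = "log10"

    def response_at(self, peptide: str, dose: float) -> float:
        rows = self.table[(self.table["peptide"] == peptide) & (self.table["dose"] == dose)]
        if len(rows) != 1:
            raise ProfileError(
                f"expected exactly one well for ({peptide}, {dose}); found {len(rows)}"
            )
        return float(rows["specific_apoptosis"].iloc[0])

    def peptides(self) -> list[str]:
        return list(dict.fromkeys(self.table["peptide"]))


def profile_wells(
    well_stats: pd.DataFrame, control_preference: str = "puma2a"
) -> BH3Profile:
    """Build a BH3 profile for one sample from per-well release stats.

    ``well_stats`` is the output of :func:`albh3.cytometry.quantify_plate`
    restricted to a single sample: columns sample_id, condition, dose,
    control_type, pct_cytc_release.
    """
    samples = well_stats["sample_id"].unique()
    if len(samples) != 1:
        raise ProfileError(f"expected exactly one sample, got {list(samples)}")
    sample_id = str(samples[0])

    neg_type = "negative_puma2a" if control_preference == "puma2a" else "negative_dmso"
    neg = well_stats[well_stats["control_type"] == neg_type]
    if len(neg) == 0:  # fall back to whichever negative control exists
        neg = well_stats[well_stats["control_type"].str.startswith("negative")]
        if len(neg) == 0:
            raise ProfileError("no negative-control well in stats")
        neg_type = str(neg["control_type"].iloc[0])
    pos = well_stats[well_stats["control_type"] == "positive_alamethicin"]
    if len(pos) == 0:
        raise ProfileError("no alamethicin positive-control well in stats")

    neg_release = float(neg["pct_cytc_release"].iloc[0])
    pos_release = float(pos["pct_cytc_release"].iloc[0])

    peptide_rows = well_stats[well_stats["control_type"] == "none"]
    records = []
    for _, row in peptide_rows.iterrows():
        sa = specific_apoptosis(float(row["pct_cytc_release"]), neg_release, pos_release)
        records.append(
            {
                "peptide": row["condition"],
                "dose": float(row["dose"]),
                "raw_release": float(row["pct_cytc_release"]),
                "specific_apoptosis_raw": sa.raw,
                "specific_apoptosis": sa.clamped,
            }
        )
    table = pd.DataFrame(records).sort_values(["peptide", "dose"], kind="stable")
    table = table.reset_index(drop=True)

    aucs = {}
    for peptide, grp in table.groupby("peptide", sort=False):
        if grp["dose"].nunique() >= 2:
            grp = grp.sort_values("dose")
            aucs[peptide] = dose_response_auc(
                grp["dose"].to_numpy(), grp["specific_apoptosis"].to_numpy()
            )
    return BH3Profile(
        sample_id=sample_id,
        table=table,
        auc=pd.Series(aucs, dtype=float),
        controls_used="puma2a" if neg_type == "negative_puma2a" else "dmso",
        neg_release=neg_release,
        pos_release=pos_release,
    )


def delta_priming(treated: BH3Profile, untreated: BH3Profile) -> pd.DataFrame:
    """Treated-minus-untreated change in %specific apoptosis (clamped values).

    Both profiles must cover the same (peptide, dose) grid; a mismatch is an
    error listing the offending conditions, not a silent intersection.
    Returns one row per (peptide, dose) with the delta in percentage points.
    """
    key_t = set(zip(treated.table["peptide"], treated.table["dose"]))
    key_u = set(zip(untreated.table["peptide"], untreated.table["dose"]))
    if key_t != key_u:
        missing = sorted(key_t ^ key_u)
        raise ProfileError(f"peptide/dose grids differ; unmatched conditions: {missing}")
    t = treated.table.set_index(["peptide", "dose"])["specific_apoptosis"]
    u = untreated.table.set_index(["peptide", "dose"])["specific_apoptosis"]
    delta = (t - u).rename("delta").reset_index()
    return delta.sort_values(["peptide", "dose"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class DependencyCall:
    """Continuous pro-survival dependency scores plus thresholded flags.

    HRK (BCL-X_L-selective) reads out BCL-X_L; the BAD response minus the
    HRK response isolates the BCL-2 component of BAD's BCL-2/BCL-X_L/BCL-W
    reactivity; MS1 reads out MCL-1.
    """

    bcl2_score: float
    bclxl_score: float
    mcl1_score: float
    dependent_bcl2: bool
    dependent_bclxl: bool
    dependent_mcl1: bool
    threshold_used: float
    basis: str = "reference_dose"  # or "auc"


def call_dependencies(
    profile: BH3Profile,
    threshold: float = 20.0,
    reference_dose: float = 10.0,
    use_auc: bool = False,
) -> DependencyCall:
    """Score BCL-2 / BCL-X_L / MCL-1 dependence from selective peptides.

    Scores default to %specific apoptosis at the reference dose (10 uM);
    with ``use_auc`` the per-peptide AUC is scored instead.  A dependency is
    flagged when its score reaches ``threshold``.
    """
    needed = ("BAD", "HRK", "MS1")
    if use_auc:
        missing = [p for p in needed if p not in profile.auc.index]
        if missing:
            raise ProfileError(f"profile lacks AUC for peptide(s): {missing}")
        bad, hrk, ms1 = (float(profile.auc[p]) for p in needed)
        basis = "auc"
    else:
        have = set(zip(profile.table["peptide"], profile.table["dose"]))
        missing = [p for p in needed if (p, reference_dose) not in have]
        if missing:
            raise ProfileError(
                f"profile lacks peptide(s) {missing} at reference dose {reference_dose}"
            )
        bad, hrk, ms1 = (profile.response_at(p, reference_dose) for p in needed)
        basis = "reference_dose"

    bclxl_score = hrk
    bcl2_score = max(0.0, bad - hrk)
    mcl1_score = ms1
    return DependencyCall(
        bcl2_score=bcl2_score,
        bclxl_score=bclxl_score,
        mcl1_score=mcl1_score,
        dependent_bcl2=bcl2_score >= threshold,
        dependent_bclxl=bclxl_score >= threshold,
        dependent_mcl1=mcl1_score >= threshold,
        threshold_used=threshold,
        basis=basis,
    )
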
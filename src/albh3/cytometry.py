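"""Per-well cytometry: event-table IO, gating, light-chain calls and
cytochrome-c release quantification.

Event tables are tidy pandas DataFrames: one row per event, channel
intensity columns (CD38, CD138, kappa, lambda, cytc) plus well metadata
repeated per row (sample_id, well_id, condition, dose, control_type).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "METADATA_COLUMNS",
    "GateSpec",
    "PopulationStats",
    "EventTableError",
    "DegenerateControlsError",
    "read_event_table",
    "write_event_table",
    "validate_event_table",
    "gate_plasma_cells",
    "classify_light_chain_predominance",
    "percent_cytc_release",
    "default_gates",
    "quantify_plate",
]

CHANNELS = ("CD38", "CD138", "kappa", "lambda", "cytc")
METADATA_COLUMNS = ("sample_id", "well_id", "condition", "dose", "control_type")

CONTROL_TYPES = (
    "none",
    "negative_dmso",
    "negative_puma2a",
    "positive_alamethicin",
)


class EventTableError(ValueError):
    """Malformed event table (missing channels, bad dose field, ...)."""


class DegenerateControlsError(ValueError):
    """Control wells do not separate released from retained cytochrome c."""


@dataclass(frozen=True)
class GateSpec:
    """A fixed threshold gate on one channel."""

    channel: str
    threshold: float
    direction: str = "above"  # keep events above (or below) the threshold

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise EventTableError(f"gate direction must be above/below, got {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise EventTableError("gate threshold must be finite")

    def mask(self, events: pd.DataFrame) -> np.ndarray:
        values = events[self.channel].to_numpy(float)
        return values > self.threshold if self.direction == "above" else values < self.threshold


@dataclass(frozen=True)
class PopulationStats:
    """Release summary for one gated well population."""

    n_total: int
    n_gated: int
    pct_cytc_release: float
    cytc_threshold_used: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_gated <= self.n_total:
            raise EventTableError("0 <= n_gated <= n_total violated")
        if not 0.0 <= self.pct_cytc_release <= 100.0:
            raise EventTableError("pct_cytc_release outside [0, 100]")


def default_gates(cd38: float = 100.0, cd138: float = 100.0) -> tuple[GateSpec, ...]:
    """Plasma-cell gate: CD38 and CD138 double-positive above fixed thresholds."""
    return (GateSpec("CD38", cd38, "above"), GateSpec("CD138", cd138, "above"))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def validate_event_table(events: pd.DataFrame) -> None:
    missing = [c for c in CHANNELS if c not in events.columns]
    if missing:
        raise EventTableError(f"event table missing channel column(s): {missing}")
    for col in METADATA_COLUMNS:
        if col not in events.columns:
            raise EventTableError(f"event table missing metadata column: {col!r}")
    values = events[list(CHANNELS)].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise EventTableError("channel intensities must be finite")
    if (values < 0).any():
        raise EventTableError("channel intensities must be nonnegative")
    bad = set(events["control_type"].unique()) - set(CONTROL_TYPES)
    if bad:
        raise EventTableError(f"unknown control_type value(s): {sorted(bad)}")


def read_event_table(path: str) -> pd.DataFrame:
    """Read a tidy CSV event table (UTF-8, comma-separated, header row).

    Raises :class:`EventTableError` naming the first missing channel, or
    pointing at the first unparseable dose entry.
    """
    events = pd.read_csv(path, encoding="utf-8")
    if "dose" in events.columns:
        doses = pd.to_numeric(events["dose"], errors="coerce")
        bad = events.index[doses.isna() & events["dose"].notna()]
        if len(bad):
            raise EventTableError(f"unparseable dose field at row {int(bad[0])}")
        events["dose"] = doses.fillna(0.0)
    validate_event_table(events)
    return events


def write_event_table(events: pd.DataFrame, path: str) -> None:
    validate_event_table(events)
    events.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Gating and classification
# ---------------------------------------------------------------------------

def gate_plasma_cells(
    events: pd.DataFrame, gates: Iterable[GateSpec] | None = None
) -> pd.DataFrame:
    """Return the subset of events passing every gate (row order preserved).

    The default gate keeps CD38+/CD138+ double-positive events, the clonal
    plasma-cell compartment.
    """
    if gates is None:
        gates = default_gates()
    gates = tuple(gates)
    covered = {g.channel for g in gates}
    if not {"CD38", "CD138"} <= covered:
        raise EventTableError("gates must cover CD38 and CD138")
    mask = np.ones(len(events), dtype=bool)
    for gate in gates:
        if gate.channel not in events.columns:
            raise EventTableError(f"gate channel {gate.channel!r} not in event table")
        mask &= gate.mask(events)
    return events.loc[mask]


def classify_light_chain_predominance(
    events: pd.DataFrame, dominance_fraction: float = 0.7
) -> str:
    """Call kappa/lambda clonal predominance from gated plasma cells.

    Each event is assigned to the chain with the larger intensity; the
    sample is called for a chain when its event fraction reaches
    ``dominance_fraction``, else ``"indeterminate"``.
    """
    if not 0.5 < dominance_fraction <= 1.0:
        raise EventTableError("dominance_fraction must lie in (0.5, 1]")
    if len(events) == 0:
        raise EventTableError("no plasma cells: cannot classify light-chain predominance")
    kappa_frac = float((events["kappa"].to_numpy(float) > events["lambda"].to_numpy(float)).mean())
    if kappa_frac >= dominance_fraction:
        return "kappa"
    if 1.0 - kappa_frac >= dominance_fraction:
        return "lambda"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Cytochrome-c release
# ---------------------------------------------------------------------------

def percent_cytc_release(
    population: pd.DataFrame,
    negative_control: pd.DataFrame,
    positive_control: pd.DataFrame,
) -> PopulationStats:
    """Fraction of gated events that lost cytochrome c, in percent.

    Release lowers the retained cytochrome-c signal, so the positive-control
    (pore-former) median must sit below the negative-control median.  The
    threshold is the midpoint of the two control medians — a unit-free,
    control-anchored rule invariant to monotone channel rescaling of the
    medians' midpoint ordering.
    """
    if len(population) == 0:
        raise EventTableError("population is empty")
    med_neg = float(np.median(negative_control["cytc"].to_numpy(float)))
    med_pos = float(np.median(positive_control["cytc"].to_numpy(float)))
    if not med_pos < med_neg:
        raise DegenerateControlsError(
            f"positive-control median cytc ({med_pos:g}) must be below the "
            f"negative-control median ({med_neg:g})"
        )
    threshold = 0.5 * (med_pos + med_neg)
    released = population["cytc"].to_numpy(float) < threshold
    return PopulationStats(
        n_total=int(len(population)),
        n_gated=int(len(population)),
        pct_cytc_release=100.0 * float(released.mean()),
        cytc_threshold_used=threshold,
    )


def quantify_plate(
    events: pd.DataFrame,
    gates: Iterable[GateSpec] | None = None,
    control_preference: str = "puma2a",
) -> pd.DataFrame:
    """Gate every well of a plate and quantify cytochrome-c release.

    Controls are resolved per sample: the negative control is the PUMA2A
    well when present (configurable to prefer DMSO), the positive control
    the alamethicin well.  Returns one row per well with columns
    sample_id, condition, dose, control_type, n_total, n_gated,
    pct_cytc_release, cytc_threshold.
    """
    validate_event_table(events)
    if control_preference not in ("puma2a", "dmso"):
        raise EventTableError("control_preference must be 'puma2a' or 'dmso'")
    rows = []
    for sample_id, sample_events in events.groupby("sample_id", sort=False):
        gated = {
            well: gate_plasma_cells(well_events, gates)
            for well, well_events in sample_events.groupby("well_id", sort=False)
        }
        meta = (
            sample_events[["well_id", "condition", "dose", "control_type"]]
            .drop_duplicates("well_id")
            .set_index("well_id")
        )
        neg = _pick_negative(meta, control_preference)
        pos_candidates = meta.index[meta["control_type"] == "positive_alamethicin"]
        if len(pos_candidates) == 0:
            raise EventTableError(f"sample {sample_id!r} has no alamethicin positive-control well")
        pos_well = pos_candidates[0]
        for well_id, well_events in gated.items():
            stats = percent_cytc_release(well_events, gated[neg], gated[pos_well])
            rows.append(
                {
                    "sample_id": sample_id,
                    "condition": meta.loc[well_id, "condition"],
                    "dose": float(meta.loc[well_id, "dose"]),
                    "control_type": meta.loc[well_id, "control_type"],
                    "n_total": int(len(events[events["well_id"] == well_id])),
                    "n_gated": stats.n_gated,
                    "pct_cytc_release": stats.pct_cytc_release,
                    "cytc_threshold": stats.cytc_threshold_used,
                }
            )
    return pd.DataFrame(rows)


def _pick_negative(meta: pd.DataFrame, preference: str) -> str:
    order = (
        ("negative_puma2a", "negative_dmso")
        if preference == "puma2a"
        else ("negative_dmso", "negative_puma2a")
    )
    for ctype in order:
        wells = meta.index[meta["control_type"] == ctype]
        if len(wells):
            return wells[0]
    raise EventTableError("no negative-control well (DMSO or PUMA2A) on the plate")
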
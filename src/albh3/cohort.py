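"""Cohort bookkeeping: exclusion filters and subgroup summaries."""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ConfigError
from .simulate import CohortManifest

__all__ = ["CohortSummary", "apply_exclusion_filters", "summarize_cohort"]


@dataclass(frozen=True)
class CohortSummary:
    """Accrual and subgroup counts for a cohort.

    Invariants: included = collected - insufficient - no_predominance
    (the two exclusion flags are mutually exclusive by construction);
    naive + relapsed + on_treatment = included; kappa + lambda = included.
    """

    n_collected: int
    n_insufficient: int
    n_no_predominance: int
    n_included: int
    n_naive: int
    n_relapsed: int
    n_on_treatment: int
    n_kappa: int
    n_lambda: int
    n_t11_14: int

    def __post_init__(self) -> None:
        if self.n_included != self.n_collected - self.n_insufficient - self.n_no_predominance:
            raise ConfigError("included count inconsistent with exclusions")
        if self.n_naive + self.n_relapsed + self.n_on_treatment != self.n_included:
            raise ConfigError("treatment-status counts do not sum to included")
        if self.n_kappa + self.n_lambda != self.n_included:
            raise ConfigError("light-chain counts do not sum to included")

    def to_dict(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.__dict__.items()}


def apply_exclusion_filters(
    manifest: CohortManifest,
) -> tuple[CohortManifest, CohortSummary]:
    """Drop flagged records and tally the accrual arithmetic.

    Records flagged for insufficient plasma-cell yield or absent clonal
    predominance are excluded; the two flags must be mutually exclusive (a
    specimen that fails yield is never also assessed for predominance) and
    patient ids unique.
    """
    records = manifest.records
    dupes = records["patient_id"][records["patient_id"].duplicated()]
    if len(dupes):
        raise ConfigError(f"duplicate patient_id(s): {sorted(set(dupes))}")
    both = records["insufficient_yield"] & records["no_clonal_predominance"]
    if both.any():
        bad = records.loc[both, "patient_id"].tolist()
        raise ConfigError(f"exclusion flags must be mutually exclusive; both set for {bad}")

    included = records[~records["insufficient_yield"] & ~records["no_clonal_predominance"]]
    included_manifest = CohortManifest(included.reset_index(drop=True))
    summary = _summarize(
        included_manifest,
        n_collected=len(records),
        n_insufficient=int(records["insufficient_yield"].sum()),
        n_no_predominance=int(records["no_clonal_predominance"].sum()),
    )
    return included_manifest, summary


def summarize_cohort(included: CohortManifest) -> CohortSummary:
    """Subgroup counts (treatment status, light chain, t(11;14)) of an
    already-filtered cohort."""
    if included.records["insufficient_yield"].any() or included.records[
        "no_clonal_predominance"
    ].any():
        raise ConfigError("summarize_cohort expects an already-filtered manifest")
    return _summarize(included, n_collected=len(included), n_insufficient=0, n_no_predominance=0)


def _summarize(
    included: CohortManifest,
    n_collected: int,
    n_insufficient: int,
    n_no_predominance: int,
) -> CohortSummary:
    rec = included.records
    status_counts = rec["treatment_status"].value_counts()
    unknown = set(status_counts.index) - {"naive", "relapsed", "on_bortezomib"}
    if unknown:
        raise ConfigError(f"unknown treatment_status value(s): {sorted(unknown)}")
    chain_counts = rec["light_chain"].value_counts()
    unknown = set(chain_counts.index) - {"kappa", "lambda"}
    if unknown:
        raise ConfigError(f"unknown light_chain value(s): {sorted(unknown)}")
    return CohortSummary(
        n_collected=n_collected,
        n_insufficient=n_insufficient,
        n_no_predominance=n_no_predominance,
        n_included=len(rec),
        n_naive=int(status_counts.get("naive", 0)),
        n_relapsed=int(status_counts.get("relapsed", 0)),
        n_on_treatment=int(status_counts.get("on_bortezomib", 0)),
        n_kappa=int(chain_counts.get("kappa", 0)),
        n_lambda=int(chain_counts.get("lambda", 0)),
        n_t11_14=int(rec["t11_14"].sum()),
    )
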
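"""Configuration objects for simulation and pipeline runs.

All randomness in the package is controlled through the single ``seed``
carried by these configs; every simulated artifact is byte-reproducible
under a fixed seed and config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

# Default titration used for every BH3 peptide (micromolar).  The assay's
# published descriptions mention 0.1/1/10 uM exposures; the exact per-peptide
# panels are a configurable choice.
DEFAULT_PEPTIDE_DOSES_UM = (0.1, 1.0, 10.0)

DEFAULT_PEPTIDE_PANEL: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("BIM", DEFAULT_PEPTIDE_DOSES_UM),
    ("BID", DEFAULT_PEPTIDE_DOSES_UM),
    ("PUMA", DEFAULT_PEPTIDE_DOSES_UM),
    ("BAD", DEFAULT_PEPTIDE_DOSES_UM),
    ("HRK", DEFAULT_PEPTIDE_DOSES_UM),
    ("MS1", DEFAULT_PEPTIDE_DOSES_UM),
)

# Ex vivo drug titrations (nanomolar).
DEFAULT_DRUG_PANEL: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("ABT-199", (1.0, 10.0, 100.0, 1000.0)),
    ("ABT-263", (1.0, 10.0, 100.0, 1000.0)),
    ("S63845", (1.0, 10.0, 100.0, 1000.0)),
    ("WEHI-539", (10.0, 100.0, 1000.0, 10000.0)),
    ("bortezomib", (1.0, 3.0, 10.0, 30.0)),
    ("ixazomib", (3.0, 10.0, 30.0, 100.0)),
)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ProteomicsSimConfig:
    """Generative settings for the protein x sample time-course matrix.

    Each protein's log2 intensity follows
    ``y = b0 + b1*cellline + b2*time + b3*cellline*time + noise`` where
    ``cellline`` is 1 for the AL line (ALMC-1) and 0 for the myeloma line
    (ALMC-2), and ``time`` is treatment duration in hours.
    """

    n_proteins: int = 2000
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 12.0)
    fraction_nonnull: float = 0.2
    noise_sd: float = 0.25
    b0_mean: float = 12.0
    b0_sd: float = 1.5
    b1_mag: tuple[float, float] = (0.5, 2.0)
    b2_mag: tuple[float, float] = (0.05, 0.30)
    b3_mag: tuple[float, float] = (0.05, 0.30)

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if len(self.timepoints) < 2:
            raise ConfigError("need at least 2 timepoints")
        if not 0.0 <= self.fraction_nonnull <= 1.0:
            raise ConfigError("fraction_nonnull must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort and plate generator.

    The defaults describe a 40-patient untreated cohort (9 treatment-naive,
    31 relapsed/refractory) profiled at 5000 events per well, with naive
    patients more primed for apoptosis than relapsed ones by ``priming_gap``
    in expectation.  Use :meth:`full_cohort` for the 88-aspirate accrual with
    fixed-count exclusions.
    """

    seed: int = 0
    n_patients: int = 40
    events_per_well: int = 5000

    # --- cohort composition -------------------------------------------------
    # "fixed" mode flags exactly the given counts (mutually exclusive flags);
    # "rate" mode draws independent Bernoulli flags at the given rates.
    exclusion_mode: str = "fixed"
    n_insufficient: int = 0
    n_no_predominance: int = 0
    insufficient_rate: float = 0.09
    no_predominance_rate: float = 0.25
    n_naive: int | None = 9          # fixed count among included; None -> rate
    naive_fraction: float = 9 / 40
    n_kappa: int | None = None       # fixed count among included; None -> rate
    kappa_fraction: float = 11 / 58
    t11_14_rate: float = 0.2

    # --- latent priming / dependency model ----------------------------------
    priming_naive_mean: float = 0.75
    priming_gap: float = 0.25        # naive-minus-relapsed mean priming
    priming_sd: float = 0.12
    relapsed_dep_shift: float = 0.08  # relapsed: BCL-2 down / MCL-1 up by this
    bortezomib_shift: float = 0.30    # Noxa-mediated BCL-2 up / MCL-1 down

    # --- assay model ---------------------------------------------------------
    background_release: float = 0.05  # spontaneous release in negative wells
    hill_slope: float = 1.5
    noise_sd: float = 2.0             # well-level noise, percentage points
    plasma_fraction: float = 0.7      # plasma-cell fraction of simulated events
    n_replicates: int = 3             # chemosensitivity wells per condition

    peptide_panel: tuple[tuple[str, tuple[float, ...]], ...] = DEFAULT_PEPTIDE_PANEL
    drug_panel: tuple[tuple[str, tuple[float, ...]], ...] = DEFAULT_DRUG_PANEL

    proteomics: ProteomicsSimConfig = field(default_factory=ProteomicsSimConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        if self.events_per_well < 1:
            raise ConfigError("events_per_well must be positive")
        if self.exclusion_mode not in ("fixed", "rate"):
            raise ConfigError("exclusion_mode must be 'fixed' or 'rate'")
        if self.n_insufficient < 0 or self.n_no_predominance < 0:
            raise ConfigError("exclusion counts must be nonnegative")
        if self.n_insufficient + self.n_no_predominance > self.n_patients:
            raise ConfigError("exclusion counts exceed cohort size")
        if not 0.0 <= self.background_release < 1.0:
            raise ConfigError("background_release must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        for name, doses in self.peptide_panel:
            self._check_doses(name, doses)
        for name, doses in self.drug_panel:
            self._check_doses(name, doses)
        self.proteomics.validate()

    @staticmethod
    def _check_doses(name: str, doses: tuple[float, ...]) -> None:
        if any(d <= 0 for d in doses):
            raise ConfigError(f"doses for {name!r} must be strictly positive")
        if list(doses) != sorted(doses):
            raise ConfigError(f"doses for {name!r} must be sorted ascending")

    @classmethod
    def full_cohort(cls, seed: int = 0, **overrides: Any) -> "SimConfig":
        """The full 88-aspirate accrual with fixed-count exclusions.

        Eight specimens fail plasma-cell yield and twenty-two lack clonal
        predominance (disjoint flags), leaving 58 included samples of which
        14 are treatment-naive and 11 kappa-predominant.
        """
        params: dict[str, Any] = dict(
            seed=seed,
            n_patients=88,
            exclusion_mode="fixed",
            n_insufficient=8,
            n_no_predominance=22,
            n_naive=14,
            n_kappa=11,
        )
        params.update(overrides)
        return cls(**params)

    # --- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        data = dict(data)
        prot = data.pop("proteomics", None)
        if prot is not None and not isinstance(prot, ProteomicsSimConfig):
            prot = ProteomicsSimConfig(
                **{**prot, **_tupleize(prot, ("timepoints", "b1_mag", "b2_mag", "b3_mag"))}
            )
        kwargs = {
            k: v for k, v in data.items()
            if k in {f.name for f in dataclasses.fields(cls)}
        }
        for key in ("peptide_panel", "drug_panel"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple((str(n), tuple(float(d) for d in ds)) for n, ds in kwargs[key])
        if prot is not None:
            kwargs["proteomics"] = prot
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _tupleize(data: dict[str, Any], keys: tuple[str, ...]) -> dict[str, Any]:
    return {k: tuple(data[k]) for k in keys if k in data and data[k] is not None}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings (simulation + analysis stages)."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # cytometry gates (fluorescence thresholds, "above" direction)
    cd38_threshold: float = 100.0
    cd138_threshold: float = 100.0
    dominance_fraction: float = 0.7
    control_preference: str = "puma2a"      # negative-control choice when both exist
    dependency_threshold: float = 20.0      # % specific apoptosis
    dependency_reference_dose: float = 10.0  # uM
    synergy_pair: tuple[str, str] = ("ABT-199", "S63845")
    synergy_interaction: str = "bliss"       # or "hsa_null"
    n_profiled_patients: int | None = None   # cap for plate simulation; None = all
    cluster_cut: int = 9
    kmeans_k: int = 3

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sim = data.pop("sim", None)
        kwargs = {
            k: v for k, v in data.items()
            if k in {f.name for f in dataclasses.fields(cls)}
        }
        if "synergy_pair" in kwargs and kwargs["synergy_pair"] is not None:
            kwargs["synergy_pair"] = tuple(kwargs["synergy_pair"])
        if sim is not None:
            kwargs["sim"] = sim if isinstance(sim, SimConfig) else SimConfig.from_dict(sim)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
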
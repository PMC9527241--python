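"""Synthetic-data generator with recoverable ground truth.

Every input the analysis pipeline consumes — cohort manifests, per-well
cytometry event tables, ex vivo viability plates, treatment-shifted latents
and proteomics time courses — is generated here from explicit latent
parameters, so each downstream stage can be verified against known truth.

The mitochondrial-release model is deliberately simple: for a peptide (or
drug) whose targets carry combined dependency weight ``w`` in [0, 1], the
probability that a permeabilized plasma cell releases cytochrome c at dose
``d`` is

    p(d) = bg + (1 - bg) * theta * w * hill(d; EC50(w), slope)

where ``theta`` is the patient's apoptotic priming, ``bg`` the spontaneous
release fraction, and ``hill`` a 2-parameter Hill curve whose midpoint
tightens modestly with the dependency weight (EC50(w) = EC50_ref /
(0.25 + 0.75 w)).  Promiscuous activator/sensitizer peptides (BIM, BID,
PUMA) have w = 1 and differ only in potency, with BIM the most potent.
This is monotone in dose, priming and dependency, vanishes exactly when the
targeted dependency is absent, and saturates at the positive control when
theta = w = 1.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, ProteomicsSimConfig, SimConfig

__all__ = [
    "PatientLatent",
    "CohortManifest",
    "simulate_cohort",
    "simulate_bh3_plate",
    "simulate_chemo_plate",
    "simulate_combo_plate",
    "apply_treatment_shift",
    "simulate_proteomics",
    "release_probability",
    "drug_death_fraction",
    "hill",
    "PEPTIDE_TARGETS",
    "DRUG_TARGETS",
]

# ---------------------------------------------------------------------------
# Peptide / drug registries
# ---------------------------------------------------------------------------

# BH3 peptide -> pro-survival proteins it neutralizes.  None marks promiscuous
# activator/sensitizer peptides that report overall priming.
PEPTIDE_TARGETS: dict[str, tuple[str, ...] | None] = {
    "BIM": None,
    "BID": None,
    "PUMA": None,
    "BAD": ("bcl2", "bclxl"),   # BAD also binds BCL-W; BCL-2/X_L dominate here
    "HRK": ("bclxl",),
    "MS1": ("mcl1",),
}

# Reference EC50s in micromolar.  BIM is more potent than BID, reflecting the
# higher sensitivity of plasma cells to BIM observed in this assay class.
PEPTIDE_EC50_UM: dict[str, float] = {
    "BIM": 0.2,
    "BID": 0.8,
    "PUMA": 0.5,
    "BAD": 1.0,
    "HRK": 1.0,
    "MS1": 1.0,
}

# Drug -> dependency weight it probes.  "priming" marks proteasome inhibitors
# whose killing tracks overall apoptotic priming rather than a single
# pro-survival protein.
DRUG_TARGETS: dict[str, tuple[str, ...] | str] = {
    "ABT-199": ("bcl2",),
    "ABT-263": ("bcl2", "bclxl"),
    "S63845": ("mcl1",),
    "WEHI-539": ("bclxl",),
    "bortezomib": "priming",
    "ixazomib": "priming",
}

DRUG_EC50_NM: dict[str, float] = {
    "ABT-199": 50.0,
    "ABT-263": 60.0,
    "S63845": 30.0,
    "WEHI-539": 150.0,
    "bortezomib": 5.0,
    "ixazomib": 20.0,
}

NEGATIVE_CONTROLS = ("DMSO", "PUMA2A")
POSITIVE_CONTROL = "alamethicin"

TREATMENT_STATUSES = ("naive", "relapsed", "on_bortezomib")
LIGHT_CHAINS = ("kappa", "lambda")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientLatent:
    """Ground-truth priming and pro-survival dependency weights of a patient.

    ``priming_theta`` stands in for overall apoptotic priming; the three
    ``dep_*`` fractions weight reliance on BCL-2, BCL-X_L and MCL-1.
    """

    patient_id: str
    priming_theta: float
    dep_bcl2: float
    dep_bclxl: float
    dep_mcl1: float
    treatment_status: str = "naive"
    light_chain: str = "lambda"
    t11_14: bool = False

    def __post_init__(self) -> None:
        for name in ("priming_theta", "dep_bcl2", "dep_bclxl", "dep_mcl1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.treatment_status not in TREATMENT_STATUSES:
            raise ConfigError(f"unknown treatment_status {self.treatment_status!r}")
        if self.light_chain not in LIGHT_CHAINS:
            raise ConfigError(f"unknown light_chain {self.light_chain!r}")


@dataclass(frozen=True)
class CohortManifest:
    """Per-patient accrual record with exclusion flags.

    Records flagged ``insufficient_yield`` (too few plasma cells) or
    ``no_clonal_predominance`` are excluded from downstream analysis.
    """

    records: pd.DataFrame  # columns: patient_id, insufficient_yield,
    #          no_clonal_predominance, treatment_status, light_chain, t11_14

    COLUMNS = (
        "patient_id",
        "insufficient_yield",
        "no_clonal_predominance",
        "treatment_status",
        "light_chain",
        "t11_14",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ConfigError(f"manifest missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# RNG helpers
# ---------------------------------------------------------------------------

def _child_seed(seed: int, stream: int) -> int:
    """Derive a deterministic sub-seed below 2**31."""
    return (int(seed) * 1_000_003 + 7919 * int(stream) + 1) % (2**31)


def hill(dose: np.ndarray | float, ec50: float, slope: float) -> np.ndarray | float:
    """Two-parameter Hill response in [0, 1), increasing in dose."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        num = np.power(dose, slope)
    return num / (num + ec50**slope)


def _target_weight(latent: PatientLatent, targets: tuple[str, ...] | str | None) -> float:
    if targets is None or targets == "priming":
        return 1.0
    weights = {
        "bcl2": latent.dep_bcl2,
        "bclxl": latent.dep_bclxl,
        "mcl1": latent.dep_mcl1,
    }
    return max(weights[t] for t in targets)


def _effective_ec50(ec50_ref: float, weight: float) -> float:
    # Stronger dependency -> modestly more potent peptide/drug.
    return ec50_ref / (0.25 + 0.75 * weight)


def release_probability(
    latent: PatientLatent,
    peptide: str,
    dose_um: float,
    background: float = 0.05,
    slope: float = 1.5,
) -> float:
    """Expected cytochrome-c release fraction for one peptide well."""
    if peptide == POSITIVE_CONTROL:
        return 1.0
    if peptide in NEGATIVE_CONTROLS:
        return background
    if peptide not in PEPTIDE_TARGETS:
        known = sorted(PEPTIDE_TARGETS) + list(NEGATIVE_CONTROLS) + [POSITIVE_CONTROL]
        raise ConfigError(f"unknown peptide {peptide!r}; known: {known}")
    w = _target_weight(latent, PEPTIDE_TARGETS[peptide])
    ec50 = _effective_ec50(PEPTIDE_EC50_UM[peptide], w)
    frac = latent.priming_theta * w * float(hill(dose_um, ec50, slope))
    return background + (1.0 - background) * frac


def drug_death_fraction(
    latent: PatientLatent,
    drug: str,
    dose_nm: float,
    slope: float = 1.5,
    bortezomib_shift: float = 0.0,
) -> float:
    """Expected death fraction induced by a single agent ex vivo.

    Proteasome inhibitors optionally act on a transiently Noxa-shifted
    latent (``bortezomib_shift``), mirroring the treatment-induced
    MCL-1 neutralization / BCL-2 dependence gain used for dynamic profiling.
    """
    if drug not in DRUG_TARGETS:
        raise ConfigError(
            f"unknown drug {drug!r}; recognized drugs: {sorted(DRUG_TARGETS)}"
        )
    if dose_nm < 0:
        raise ConfigError("dose must be nonnegative")
    if dose_nm == 0:
        return 0.0
    targets = DRUG_TARGETS[drug]
    if targets == "priming" and bortezomib_shift > 0:
        latent = apply_treatment_shift(latent, bortezomib_shift)
    w = _target_weight(latent, targets)
    ec50 = _effective_ec50(DRUG_EC50_NM[drug], w)
    return latent.priming_theta * w * float(hill(dose_nm, ec50, slope))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_dependencies(rng: np.random.Generator, relapsed: bool, shift: float) -> tuple[float, float, float]:
    dep_bcl2 = rng.beta(4.0, 2.5)
    dep_bclxl = rng.beta(1.5, 8.0)
    dep_mcl1 = rng.beta(4.0, 2.5)
    if relapsed:
        # Relapsed disease trends toward lower BCL-2 and higher MCL-1 reliance.
        dep_bcl2 = max(0.0, dep_bcl2 - shift)
        dep_mcl1 = min(1.0, dep_mcl1 + shift)
    return dep_bcl2, dep_bclxl, dep_mcl1


def simulate_cohort(config: SimConfig) -> tuple[CohortManifest, list[PatientLatent]]:
    """Draw an accrual manifest and per-patient latent parameters.

    In fixed-count mode exactly ``n_insufficient`` and ``n_no_predominance``
    records carry (mutually exclusive) exclusion flags; among included
    patients the treatment-naive and kappa counts are likewise fixed when
    configured.  Naive patients are more primed than relapsed ones by
    ``priming_gap`` in expectation.
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(_child_seed(config.seed, 0))

    if n == 0:
        empty = pd.DataFrame(columns=list(CohortManifest.COLUMNS))
        return CohortManifest(empty.astype({"patient_id": str})), []

    patient_ids = [f"AL{idx + 1:03d}" for idx in range(n)]

    insufficient = np.zeros(n, dtype=bool)
    no_predominance = np.zeros(n, dtype=bool)
    if config.exclusion_mode == "fixed":
        order = rng.permutation(n)
        insufficient[order[: config.n_insufficient]] = True
        stop = config.n_insufficient + config.n_no_predominance
        no_predominance[order[config.n_insufficient : stop]] = True
    else:
        insufficient = rng.random(n) < config.insufficient_rate
        # flags kept mutually exclusive: yield failure preempts the
        # predominance assessment
        no_predominance = (~insufficient) & (rng.random(n) < config.no_predominance_rate)

    included_idx = np.flatnonzero(~insufficient & ~no_predominance)
    n_inc = included_idx.size

    status = np.array(["relapsed"] * n, dtype=object)
    if config.n_naive is not None:
        n_naive = min(config.n_naive, n_inc)
        naive_pick = rng.permutation(included_idx)[:n_naive]
    else:
        naive_pick = included_idx[rng.random(n_inc) < config.naive_fraction]
    status[naive_pick] = "naive"

    chain = np.array(["lambda"] * n, dtype=object)
    if config.n_kappa is not None:
        n_kappa = min(config.n_kappa, n_inc)
        kappa_pick = rng.permutation(included_idx)[:n_kappa]
    else:
        kappa_pick = np.flatnonzero(rng.random(n) < config.kappa_fraction)
    chain[kappa_pick] = "kappa"

    t11 = rng.random(n) < config.t11_14_rate

    latents: list[PatientLatent] = []
    for i in range(n):
        relapsed = status[i] == "relapsed"
        mean = config.priming_naive_mean - (config.priming_gap if relapsed else 0.0)
        theta = float(np.clip(rng.normal(mean, config.priming_sd), 0.02, 0.98))
        dep_bcl2, dep_bclxl, dep_mcl1 = _draw_dependencies(
            rng, relapsed, config.relapsed_dep_shift
        )
        latents.append(
            PatientLatent(
                patient_id=patient_ids[i],
                priming_theta=theta,
                dep_bcl2=dep_bcl2,
                dep_bclxl=dep_bclxl,
                dep_mcl1=dep_mcl1,
                treatment_status=str(status[i]),
                light_chain=str(chain[i]),
                t11_14=bool(t11[i]),
            )
        )

    records = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "insufficient_yield": insufficient,
            "no_clonal_predominance": no_predominance,
            "treatment_status": status,
            "light_chain": chain,
            "t11_14": t11,
        }
    )
    return CohortManifest(records), latents


# ---------------------------------------------------------------------------
# Cytometry plate simulation
# ---------------------------------------------------------------------------

_CHANNELS = ("CD38", "CD138", "kappa", "lambda", "cytc")

# Log-space locations of the simulated fluorescence populations (arbitrary
# units).  Populations are well separated so fixed default gates recover the
# plasma-cell compartment essentially exactly.
_MARKER_HI = (np.log(500.0), 0.35)
_MARKER_LO = (np.log(20.0), 0.45)
_CYTC_RETAINED = (np.log(500.0), 0.30)
_CYTC_RELEASED = (np.log(30.0), 0.40)
_CLONAL_PURITY = 0.97   # fraction of plasma events positive for the clonal chain


def _panel_conditions(
    panel: Sequence[tuple[str, Sequence[float]]]
) -> list[tuple[str, float, str]]:
    """Expand a panel into (condition, dose, control_type) wells."""
    wells: list[tuple[str, float, str]] = []
    names = {name for name, _ in panel}
    for name, doses in panel:
        if name in NEGATIVE_CONTROLS:
            ctype = "negative_dmso" if name == "DMSO" else "negative_puma2a"
            wells.append((name, 0.0, ctype))
        elif name == POSITIVE_CONTROL:
            wells.append((name, 0.0, "positive_alamethicin"))
        else:
            for d in doses:
                wells.append((name, float(d), "none"))
    if not names & set(NEGATIVE_CONTROLS):
        raise ConfigError(
            "panel is missing a negative-control well (DMSO or PUMA2A)"
        )
    if POSITIVE_CONTROL not in names:
        raise ConfigError("panel is missing the alamethicin positive-control well")
    return wells


def _with_controls(
    panel: Sequence[tuple[str, Sequence[float]]]
) -> list[tuple[str, tuple[float, ...]]]:
    """Append any missing control wells to a peptide panel."""
    out = [(n, tuple(d)) for n, d in panel]
    names = {n for n, _ in out}
    for ctl in ("DMSO", "PUMA2A", POSITIVE_CONTROL):
        if ctl not in names:
            out.append((ctl, ()))
    return out


def simulate_bh3_plate(
    latent: PatientLatent,
    panel: Sequence[tuple[str, Sequence[float]]] | None = None,
    events_per_well: int = 5000,
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate one BH3-profiling plate as a tidy per-event table.

    Each well exposes permeabilized cells to one peptide dose (or a control);
    events carry surface-marker, light-chain and cytochrome-c intensities.
    The returned frame has one row per event with well metadata repeated.
    """
    cfg = config or SimConfig()
    if panel is None:
        panel = [(n, d) for n, d in cfg.peptide_panel]
    wells = _panel_conditions(_with_controls(panel))
    rng = np.random.default_rng(_child_seed(seed, 1))

    frames = []
    for well_idx, (condition, dose, ctype) in enumerate(wells):
        p_release = release_probability(
            latent,
            condition,
            dose,
            background=cfg.background_release,
            slope=cfg.hill_slope,
        )
        frames.append(
            _simulate_well_events(
                rng,
                latent,
                n_events=events_per_well,
                p_release=p_release,
                plasma_fraction=cfg.plasma_fraction,
                background=cfg.background_release,
                sample_id=latent.patient_id,
                condition=condition,
                dose=dose,
                control_type=ctype,
                well_id=f"{latent.patient_id}-W{well_idx:02d}",
            )
        )
    return pd.concat(frames, ignore_index=True)


def _simulate_well_events(
    rng: np.random.Generator,
    latent: PatientLatent,
    n_events: int,
    p_release: float,
    plasma_fraction: float,
    background: float,
    sample_id: str,
    condition: str,
    dose: float,
    control_type: str,
    well_id: str,
) -> pd.DataFrame:
    is_plasma = rng.random(n_events) < plasma_fraction

    def lognorm(loc_sd: tuple[float, float], size: int) -> np.ndarray:
        loc, sd = loc_sd
        return np.exp(rng.normal(loc, sd, size))

    cd38 = np.where(is_plasma, lognorm(_MARKER_HI, n_events), lognorm(_MARKER_LO, n_events))
    cd138 = np.where(is_plasma, lognorm(_MARKER_HI, n_events), lognorm(_MARKER_LO, n_events))

    clonal_pos = rng.random(n_events) < _CLONAL_PURITY
    pos_chain = np.where(is_plasma & clonal_pos, lognorm(_MARKER_HI, n_events), lognorm(_MARKER_LO, n_events))
    neg_chain = lognorm(_MARKER_LO, n_events)
    if latent.light_chain == "kappa":
        kappa, lam = pos_chain, neg_chain
    else:
        kappa, lam = neg_chain, pos_chain

    # Non-plasma bystanders release only at the spontaneous background rate.
    p_event = np.where(is_plasma, p_release, background)
    released = rng.random(n_events) < p_event
    cytc = np.where(released, lognorm(_CYTC_RELEASED, n_events), lognorm(_CYTC_RETAINED, n_events))

    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "well_id": well_id,
            "condition": condition,
            "dose": dose,
            "control_type": control_type,
            "CD38": cd38,
            "CD138": cd138,
            "kappa": kappa,
            "lambda": lam,
            "cytc": cytc,
        }
    )


# ---------------------------------------------------------------------------
# Ex vivo chemosensitivity simulation
# ---------------------------------------------------------------------------

_CD138_BASELINE = 30.0   # % CD138+ of mononuclear cells in DMSO wells
_ANNEXIN_BASELINE = 8.0  # % Annexin+ within CD138+ in DMSO wells


def _viability_well(
    rng: np.random.Generator,
    death: float,
    noise_sd: float,
) -> tuple[float, float]:
    cd138 = _CD138_BASELINE * (1.0 - death) + rng.normal(0.0, noise_sd)
    annexin = _ANNEXIN_BASELINE + (100.0 - _ANNEXIN_BASELINE) * death + rng.normal(0.0, noise_sd)
    return float(np.clip(cd138, 0.0, 100.0)), float(np.clip(annexin, 0.0, 100.0))


def simulate_chemo_plate(
    latent: PatientLatent,
    drugs: Sequence[tuple[str, Sequence[float]]] | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate single-agent ex vivo viability wells (tidy, with replicates).

    Columns: sample_id, drug_a, dose_a, drug_b, dose_b, replicate,
    pct_cd138_pos, pct_annexin_pos_in_cd138.  DMSO wells carry drug_a="DMSO",
    dose_a=0.
    """
    cfg = config or SimConfig()
    if drugs is None:
        drugs = [(n, d) for n, d in cfg.drug_panel]
    for name, _doses in drugs:
        if name != "DMSO" and name not in DRUG_TARGETS:
            raise ConfigError(
                f"unknown drug {name!r}; recognized drugs: {sorted(DRUG_TARGETS)}"
            )
    rng = np.random.default_rng(_child_seed(seed, 2))

    rows = []
    conditions: list[tuple[str, float]] = [("DMSO", 0.0)]
    for name, doses in drugs:
        if name == "DMSO":
            continue
        conditions.extend((name, float(d)) for d in doses)
    for drug, dose in conditions:
        death = (
            0.0
            if drug == "DMSO"
            else drug_death_fraction(
                latent, drug, dose, slope=cfg.hill_slope,
                bortezomib_shift=cfg.bortezomib_shift,
            )
        )
        for rep in range(cfg.n_replicates):
            cd138, annexin = _viability_well(rng, death, cfg.noise_sd)
            rows.append(
                {
                    "sample_id": latent.patient_id,
                    "drug_a": drug,
                    "dose_a": dose,
                    "drug_b": "",
                    "dose_b": 0.0,
                    "replicate": rep,
                    "pct_cd138_pos": cd138,
                    "pct_annexin_pos_in_cd138": annexin,
                }
            )
    return pd.DataFrame(rows)


def simulate_combo_plate(
    latent: PatientLatent,
    drug_a: str,
    drug_b: str,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    interaction: str = "bliss",
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Simulate a combination dose grid including single-agent margins.

    ``interaction`` sets the combination surface: "hsa_null" makes the
    combined death exactly the max of the single agents (zero excess over
    highest single agent by construction) while "bliss" uses independent
    action, which exceeds the best single agent wherever both act.
    """
    if interaction not in ("bliss", "hsa_null"):
        raise ConfigError("interaction must be 'bliss' or 'hsa_null'")
    cfg = config or SimConfig()
    rng = np.random.default_rng(_child_seed(seed, 3))

    grid_a = [0.0] + [float(d) for d in doses_a]
    grid_b = [0.0] + [float(d) for d in doses_b]
    rows = []
    for da in grid_a:
        ea = drug_death_fraction(latent, drug_a, da, slope=cfg.hill_slope)
        for db in grid_b:
            eb = drug_death_fraction(latent, drug_b, db, slope=cfg.hill_slope)
            if interaction == "bliss":
                death = 1.0 - (1.0 - ea) * (1.0 - eb)
            else:
                death = max(ea, eb)
            for rep in range(cfg.n_replicates):
                cd138, annexin = _viability_well(rng, death, cfg.noise_sd)
                rows.append(
                    {
                        "sample_id": latent.patient_id,
                        "drug_a": drug_a if da > 0 else "DMSO",
                        "dose_a": da,
                        "drug_b": drug_b if db > 0 else "",
                        "dose_b": db,
                        "replicate": rep,
                        "pct_cd138_pos": cd138,
                        "pct_annexin_pos_in_cd138": annexin,
                    }
                )
    out = pd.DataFrame(rows)
    # the (0, 0) cell is the DMSO baseline
    out.loc[(out.dose_a == 0) & (out.dose_b == 0), "drug_a"] = "DMSO"
    return out


# ---------------------------------------------------------------------------
# Treatment shift (dynamic profiling ground truth)
# ---------------------------------------------------------------------------

def apply_treatment_shift(latent: PatientLatent, shift: float) -> PatientLatent:
    """Proteasome-inhibitor-induced dependency shift.

    Bortezomib upregulates Noxa, which neutralizes MCL-1 and pushes the cell
    onto BCL-2: dep_bcl2 rises by ``shift`` (capped at 1), dep_mcl1 falls by
    ``shift`` (floored at 0), and the status becomes ``on_bortezomib``.  The
    input latent is unchanged.
    """
    if shift < 0:
        raise ConfigError("shift must be nonnegative")
    return dataclasses.replace(
        latent,
        dep_bcl2=min(1.0, latent.dep_bcl2 + shift),
        dep_mcl1=max(0.0, latent.dep_mcl1 - shift),
        treatment_status="on_bortezomib",
    )


# ---------------------------------------------------------------------------
# Proteomics time-course simulation
# ---------------------------------------------------------------------------

def simulate_proteomics(
    config: SimConfig | ProteomicsSimConfig,
    seed: int = 0,
) -> tuple["ProteomicsMatrix", pd.DataFrame]:
    """Simulate a protein x sample log2-intensity time course with truth.

    Samples form a 2 cell line (ALMC1 = AL line, ALMC2 = myeloma line) x
    timepoint design with one sample per condition.  Per protein,
    ``y = b0 + b1*cellline + b2*time + b3*cellline*time + noise`` where the
    cell-line indicator is 1 for ALMC1.  Exactly
    ``floor(fraction_nonnull * n_proteins)`` proteins carry any nonzero
    b1/b2/b3.  Returns the matrix and a ground-truth frame indexed by
    protein with columns b0..b3 and ``nonnull``.
    """
    from .proteomics import ProteomicsMatrix  # local import to avoid a cycle

    pcfg = config.proteomics if isinstance(config, SimConfig) else config
    pcfg.validate()
    rng = np.random.default_rng(_child_seed(seed, 4))

    times = np.asarray(pcfg.timepoints, dtype=float)
    cell_lines = ["ALMC1", "ALMC2"]
    sample_ids = [f"{cl}_t{t:g}" for cl in cell_lines for t in times]
    meta = pd.DataFrame(
        {
            "cell_line": [cl for cl in cell_lines for _ in times],
            "time_h": np.concatenate([times, times]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    n_samples = len(meta)
    if n_samples < 5:
        raise ConfigError("need at least 5 samples to identify 4 coefficients")

    n = pcfg.n_proteins
    n_nonnull = int(np.floor(pcfg.fraction_nonnull * n))
    nonnull = np.zeros(n, dtype=bool)
    nonnull[rng.permutation(n)[:n_nonnull]] = True

    def draw_mag(lohi: tuple[float, float], size: int) -> np.ndarray:
        lo, hi = lohi
        return rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)

    b0 = rng.normal(pcfg.b0_mean, pcfg.b0_sd, n)
    b1 = np.where(nonnull, draw_mag(pcfg.b1_mag, n), 0.0)
    b2 = np.where(nonnull, draw_mag(pcfg.b2_mag, n), 0.0)
    b3 = np.where(nonnull, draw_mag(pcfg.b3_mag, n), 0.0)

    cl = (meta["cell_line"] == "ALMC1").to_numpy(float)
    t = meta["time_h"].to_numpy(float)
    design = np.column_stack([np.ones(n_samples), cl, t, cl * t])
    coeffs = np.column_stack([b0, b1, b2, b3])
    values = coeffs @ design.T + rng.normal(0.0, pcfg.noise_sd, (n, n_samples))

    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    matrix = ProteomicsMatrix(
        values=pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                            columns=meta.index),
        samples=meta,
    )
    truth = pd.DataFrame(
        {"b0": b0, "b1": b1, "b2": b2, "b3": b3, "nonnull": nonnull},
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return matrix, truth
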
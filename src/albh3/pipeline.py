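"""End-to-end orchestration: simulate -> gate -> profile -> chemo ->
synergy -> proteomics -> report.

Each stage reads and writes tidy TSV/CSV/JSON files inside a working
directory so stages can be run individually (see :mod:`albh3.cli`) or as a
single :func:`run_pipeline` call.  Outputs contain no timestamps; a bundle
produced twice from the same config and seed is byte-identical.
"""
from __future__ import annotations

import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemosensitivity as chemo
from . import cytometry, profiling, proteomics, simulate
from .cohort import apply_exclusion_filters
from .config import ConfigError, RunConfig

log = logging.getLogger("albh3.pipeline")

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "gate", "profile", "chemo", "synergy", "proteomics", "report")


def _version() -> str:
    try:
        return metadata.version("albh3")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir: Path) -> None:
    """Generate every synthetic input the downstream stages consume."""
    sim = config.sim
    manifest, latents = simulate.simulate_cohort(sim)
    manifest.records.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    with open(out_dir / "latents.json", "w") as fh:
        json.dump([vars(l) for l in latents], fh, indent=1, sort_keys=True)

    included, _ = apply_exclusion_filters(manifest)
    keep = set(included.records["patient_id"])
    profiled = [l for l in latents if l.patient_id in keep]
    if config.n_profiled_patients is not None:
        profiled = profiled[: config.n_profiled_patients]

    events = []
    chemo_wells = []
    for i, latent in enumerate(profiled):
        events.append(
            simulate.simulate_bh3_plate(
                latent,
                events_per_well=sim.events_per_well,
                seed=simulate._child_seed(sim.seed, 100 + i),
                config=sim,
            )
        )
        chemo_wells.append(
            simulate.simulate_chemo_plate(
                latent, seed=simulate._child_seed(sim.seed, 200 + i), config=sim
            )
        )
    if events:
        cytometry.write_event_table(pd.concat(events, ignore_index=True),
                                    str(out_dir / "events.csv"))
        pd.concat(chemo_wells, ignore_index=True).to_csv(
            out_dir / "chemo.csv", index=False
        )
        drug_a, drug_b = config.synergy_pair
        combo = simulate.simulate_combo_plate(
            profiled[0],
            drug_a,
            drug_b,
            doses_a=dict(sim.drug_panel)[drug_a],
            doses_b=dict(sim.drug_panel)[drug_b],
            interaction=config.synergy_interaction,
            seed=simulate._child_seed(sim.seed, 300),
            config=sim,
        )
        combo.to_csv(out_dir / "combo.csv", index=False)

    matrix, truth = simulate.simulate_proteomics(sim, seed=sim.seed)
    matrix.write_tsv(str(out_dir / "proteomics.tsv"), str(out_dir / "proteomics_samples.tsv"))
    truth.reset_index().to_json(out_dir / "proteomics_truth.json", orient="records", indent=1)
    log.info("simulate: %d patients, %d profiled, %d proteins",
             len(latents), len(profiled), matrix.n_proteins)


def stage_gate(config: RunConfig, out_dir: Path) -> None:
    """Gate plasma cells and quantify cytochrome-c release per well."""
    events = cytometry.read_event_table(str(out_dir / "events.csv"))
    gates = cytometry.default_gates(config.cd38_threshold, config.cd138_threshold)
    stats = cytometry.quantify_plate(events, gates, config.control_preference)
    stats.to_csv(out_dir / "well_stats.tsv", sep="\t", index=False)
    log.info("gate: %d events in, %d wells out", len(events), len(stats))


def stage_profile(config: RunConfig, out_dir: Path) -> None:
    """Specific apoptosis, AUC summaries and dependency calls per sample."""
    stats = pd.read_csv(out_dir / "well_stats.tsv", sep="\t")
    tables, aucs, calls = [], [], []
    for sample_id, grp in stats.groupby("sample_id", sort=False):
        prof = profiling.profile_wells(grp, config.control_preference)
        t = prof.table.copy()
        t.insert(0, "sample_id", sample_id)
        tables.append(t)
        for peptide, value in prof.auc.items():
            aucs.append({"sample_id": sample_id, "peptide": peptide, "auc": value,
                         "dose_scale": prof.auc_dose_scale})
        call = profiling.call_dependencies(
            prof,
            threshold=config.dependency_threshold,
            reference_dose=config.dependency_reference_dose,
        )
        calls.append({"sample_id": sample_id, **vars(call)})
    pd.concat(tables, ignore_index=True).to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
    pd.DataFrame(aucs).to_csv(out_dir / "auc.tsv", sep="\t", index=False)
    pd.DataFrame(calls).to_csv(out_dir / "dependency_calls.tsv", sep="\t", index=False)
    log.info("profile: %d samples", stats["sample_id"].nunique())


def stage_chemo(config: RunConfig, out_dir: Path) -> None:
    """Viability normalization plus profiling-vs-sensitivity correlations."""
    wells = pd.read_csv(out_dir / "chemo.csv")
    summary = chemo.summarize_viability(wells)
    summary.to_csv(out_dir / "chemo_summary.tsv", sep="\t", index=False)

    correlations = {}
    profiles_path = out_dir / "profiles.tsv"
    if profiles_path.exists():
        profiles = pd.read_csv(profiles_path, sep="\t")
        ref_dose = config.dependency_reference_dose
        pairs = (
            ("BAD", "ABT-263"),
            ("MS1", "S63845"),
            ("BIM", "bortezomib"),
        )
        for peptide, drug in pairs:
            merged = _paired_metrics(profiles, summary, peptide, ref_dose, drug)
            if len(merged) >= 3:
                try:
                    correlations[f"{peptide}_vs_{drug}"] = chemo.correlate_profiling_sensitivity(
                        merged["specific_apoptosis"], merged["death_fraction"]
                    )
                except chemo.ChemoError as exc:
                    correlations[f"{peptide}_vs_{drug}"] = {"error": str(exc)}
    with open(out_dir / "correlations.json", "w") as fh:
        json.dump(correlations, fh, indent=1, sort_keys=True)
    log.info("chemo: %d wells in, %d conditions out", len(wells), len(summary))


def _paired_metrics(profiles: pd.DataFrame, summary: pd.DataFrame,
                    peptide: str, dose: float, drug: str) -> pd.DataFrame:
    x = profiles[(profiles["peptide"] == peptide) & (profiles["dose"] == dose)]
    drug_rows = summary[summary["drug_a"] == drug]
    if len(drug_rows) == 0:
        return pd.DataFrame()
    top = drug_rows["dose_a"].max()
    y = drug_rows[drug_rows["dose_a"] == top]
    return x.merge(y, on="sample_id")[["sample_id", "specific_apoptosis", "death_fraction"]]


def stage_synergy(config: RunConfig, out_dir: Path) -> None:
    """HSA excess surface for the configured drug pair."""
    combo = pd.read_csv(out_dir / "combo.csv")
    drug_a, drug_b = config.synergy_pair
    matrix = chemo.synergy_from_viability(combo, drug_a, drug_b)
    with open(out_dir / "synergy.json", "w") as fh:
        json.dump(matrix.to_dict(), fh, indent=1, sort_keys=True)
    log.info("synergy: %s + %s mean excess %.2f points",
             drug_a, drug_b, matrix.summary_mean_excess)


def stage_proteomics(config: RunConfig, out_dir: Path) -> None:
    """Standardize, regress, rank, project and cluster the protein matrix."""
    matrix = proteomics.read_proteomics_tsv(
        str(out_dir / "proteomics.tsv"), str(out_dir / "proteomics_samples.tsv")
    )
    std, info = proteomics.bistandardize(matrix)
    results = proteomics.fit_protein_regressions(std)
    results.to_csv(out_dir / "regression.tsv", sep="\t")

    comp = pca_components = min(5, std.n_samples, std.n_proteins)
    projection = proteomics.pca(std, pca_components)
    with open(out_dir / "pca.json", "w") as fh:
        json.dump(
            {
                "variance_explained": projection["variance_explained"].tolist(),
                "scores": projection["scores"].round(6).to_dict(orient="index"),
                "bistandardize_iterations": info["n_iter"],
            },
            fh, indent=1, sort_keys=True,
        )
    clusters = proteomics.cluster_two_stage(
        std, n_clusters=min(config.cluster_cut, std.n_proteins),
        k=config.kmeans_k, seed=config.seed,
    )
    clusters.to_csv(out_dir / "clusters.tsv", sep="\t")
    log.info("proteomics: %d proteins, %d samples, %d PCs",
             std.n_proteins, std.n_samples, comp)


def stage_report(config: RunConfig, out_dir: Path) -> None:
    """Cohort summary and run manifest."""
    records = pd.read_csv(out_dir / "cohort.tsv", sep="\t")
    manifest = simulate.CohortManifest(records)
    _, summary = apply_exclusion_filters(manifest)
    sections = {
        "cohort": "cohort.tsv",
        "profiling": "profiles.tsv",
        "chemosensitivity": "chemo_summary.tsv",
        "synergy": "synergy.json",
        "proteomics": "regression.tsv",
    }
    present = {k: v for k, v in sections.items() if (out_dir / v).exists()}
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": _version(),
        "cohort_summary": summary.to_dict(),
        "sections": present,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("report: %d/%d sections present", len(present), len(sections))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gate": stage_gate,
    "profile": stage_profile,
    "chemo": stage_chemo,
    "synergy": stage_synergy,
    "proteomics": stage_proteomics,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the configured stages in order, returning the report manifest.

    Raises with the failing stage named; a completed run leaves a
    ``report.json`` whose sections list every stage output present.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    config.to_yaml(str(out / "run_config.yaml"))
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report_path = out / "report.json"
    if report_path.exists():
        with open(report_path) as fh:
            return json.load(fh)
    return {}
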
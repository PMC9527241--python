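# Methods

`albh3` implements the desk analysis of a BH3-profiling study of clonal
plasma cells in AL amyloidosis: functional measurement of apoptotic priming
and pro-survival protein dependence, ex vivo drug-response normalization and
synergy scoring, and protein-level time-course statistics for an isogenic
AL-vs-myeloma cell-line pair. Because primary patient material cannot be
redistributed, the package ships a synthetic-data generator with explicit
latent ground truth; every analysis stage is validated by recovering that
truth.

## The assay model

BH3 profiling exposes permeabilized cells to pro-apoptotic BH3-domain
peptides and reads out mitochondrial outer membrane permeabilization (MOMP)
as loss of intracellular cytochrome c by flow cytometry. Promiscuous
peptides (BIM, BID, PUMA) measure overall apoptotic priming; selective
peptides measure dependence on individual pro-survival proteins: BAD
(BCL-2/BCL-X_L/BCL-W), HRK (BCL-X_L), MS1 (MCL-1).

Per-well release is normalized against same-sample controls
(Eq. "specific apoptosis"):

    %SA = 100 * (release[peptide] - release[negative]) /
                (release[positive] - release[negative])

with DMSO or the inert PUMA2A peptide as the negative control and the
pore-former alamethicin as the positive control. Raw values can leave
[0, 100] with noisy controls; both raw and clamped values are retained and
downstream consumers default to the clamped copy. When both negative
controls are present the PUMA2A well is preferred (sequence-matched inert
peptide); this is configurable.

Titrations are summarized by the **dose-response AUC**: the trapezoidal
integral of %SA over log10(dose), divided by the log10-dose span, so a
constant response r yields AUC = r and the statistic stays on the 0-100 %SA
scale. Log dose was chosen because titrations span decades; the scale is
recorded in output metadata. A single-dose series has no AUC — the raw
response is used instead.

**Dependency calls** isolate protein-specific signal: BCL-X_L score = HRK
response; BCL-2 score = max(0, BAD - HRK), subtracting the BCL-X_L
component of BAD's reactivity; MCL-1 score = MS1 response. Scores default
to %SA at the 10 µM reference dose (AUC basis behind a flag) and are
thresholded at 20 %SA — a documented, configurable cutoff reported
alongside the continuous scores, since no canonical threshold exists.

**Delta priming** (dynamic BH3 profiling) is the treated-minus-untreated
difference of clamped %SA on an identical (peptide, dose) grid; grid
mismatches are an error rather than a silent intersection.

## Cytometry

Event tables are tidy CSV (UTF-8, header row, one event per row, well
metadata repeated). Gating uses fixed per-channel thresholds from
configuration (default CD38+/CD138+ double-positive above 100 AU); fixed
gates are deterministic and testable, and automated mixture-based gating is
deliberately out of scope. Light-chain predominance assigns each gated
event to the brighter chain channel and calls a sample kappa/lambda when
that fraction reaches the dominance cutoff (default 0.7, configurable;
below it the call is "indeterminate").

The cytochrome-c release threshold is the midpoint of the positive- and
negative-control medians of the same sample, with per-sample (not
per-plate) controls. This rule is unit-free in the sense of being invariant
to joint affine (gain/offset) rescaling of the cytc channel, which is the
property the tests assert; it is *not* invariant to arbitrary nonlinear
monotone transforms, a stronger property no midpoint-type rule can have.
Controls must separate (positive median strictly below negative median,
since release lowers the retained signal) or a degenerate-controls error is
raised.

## Ex vivo chemosensitivity

Two readouts, both normalized against same-sample DMSO wells after
averaging replicate wells within (sample, drug, dose):

* CD138 loss. Apoptotic plasma cells shed CD138, so the printed formula
  `%CD138+[drug] / %CD138+[DMSO]` is a survival ratio despite its "%cell
  death" name. Both the verbatim ratio and the complementary death fraction
  `max(0, 1 - ratio)` are emitted under explicit labels.
* Annexin-V positivity within CD138+ cells:
  `100 * (annexin[drug] - annexin[DMSO]) / (100 - annexin[DMSO])`.

**HSA synergy.** For a dose grid of two agents, excess(a, b) =
E(a, b) - max(E(a, 0), E(0, b)) on interior cells, with effects on the
Annexin specific-apoptosis scale (the CD138 scale is available through the
same summary table). The surface summary is the mean interior excess
(robust to single-cell noise); the max is also reported. Doses are matched
exactly — no interpolation between grids. Bliss/Loewe/ZIP models and IC50
fitting are out of scope.

**Correlation.** Profiling-vs-sensitivity association uses Spearman rank
correlation with average ranks for ties and a two-sided p; incomplete pairs
are dropped and the effective n reported; fewer than 3 pairs or a
zero-variance vector is an error.

## Proteomics time course

The design is 2 isogenic cell lines (ALMC1, the AL line; ALMC2, the
relapsed-myeloma line) × 5 treatment durations (0, 2, 4, 6, 12 h), one
sample per condition.

* **Bi-standardization:** alternate row (protein) and column (sample)
  centering/scaling to mean 0, population variance 1, iterated until all
  moments are within `tol` (default 1e-6) or `max_iter` sweeps; population
  variance and row-then-column order are the documented choices (the target
  moments only say "approximately zero mean and common variance").
  Constant rows/columns are an error naming the offender.
* **Per-protein regression:** OLS on [1, cellline, time, cellline×time]
  with cellline = 1 for ALMC1, so positive cell-line coefficients mean
  higher abundance in the AL line; time is continuous hours. t-tests use
  n − 4 df. Bonferroni and BH are applied per coefficient family (the set
  of proteins, separately for b1/b2/b3); ranking defaults to ascending BH q
  of the cell-line coefficient, configurable.
* **Adjustments:** Bonferroni min(1, m·p); BH step-up; Holm-Šidák
  step-down (adj_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1), capped at 1).
  Computed via `statsmodels.stats.multitest`; tests cross-check brute-force
  implementations of the definitions.
* **PCA:** samples are observations, proteins features, column-centered;
  SVD with the sign convention that each component's largest-magnitude
  loading is positive. Run on the standardized matrix by default.
* **Two-stage clustering:** complete-linkage agglomeration on Euclidean
  distances, tree cut at 9 clusters by default, then per-cluster k-means
  (k-means++ init, default k = 3, fixed seed). Both counts are
  configurable; defaults mirror the analysis this reproduces, where
  sub-cluster numbering reached 9 without stated parameters.
* **ORA:** hypergeometric upper tail of the query/set overlap within the
  universe, sets filtered to [3, 5000] members after intersection with the
  universe, BH across sets.
* **Permutation GSEA:** weighted Kolmogorov–Smirnov running sum with
  weight exponent 1 on the descending score ranking; null from gene-label
  permutations (same-size random member sets) because the design has one
  sample per condition; p = (1 + #{same-direction permutations at least as
  extreme}) / (n_perm + 1); NES = ES / mean(|ES_perm|) over same-sign
  permutations; leading edge = members at or before (after, for negative
  ES) the running-sum peak. Default n_perm = 1000.

## The synthetic generator

The generator's defaults *are* the study conditions the analysis is
validated under; they are not tuned per run.

* **Cohort.** The default config draws 40 patients (9 treatment-naive, 31
  relapsed), matching the untreated-patient subset analyzed for priming;
  `SimConfig.full_cohort()` draws the 88-aspirate accrual with fixed-count,
  mutually exclusive exclusions (8 insufficient yield, 22 no clonal
  predominance → 58 included; 14 naive / 44 relapsed; 11 kappa / 47
  lambda). Exclusion flags also support a Bernoulli "rate" mode.
* **Latents.** Priming θ ~ Normal(0.75, 0.12) for naive patients, mean
  lower by the configured gap (default 0.25) for relapsed, clipped to
  [0.02, 0.98]. Dependencies: BCL-2, MCL-1 ~ Beta(4, 2.5) (mean ≈ 0.62),
  BCL-X_L ~ Beta(1.5, 8) (mean ≈ 0.16, reflecting its consistently weaker
  readout); relapsed patients shift BCL-2 down / MCL-1 up by 0.08.
* **Release model.** p(d) = bg + (1 − bg)·θ·w·hill(d; EC50(w), 1.5) with
  background bg = 5% (keeps normalization denominators nondegenerate),
  w the max dependency weight over the peptide's targets (1 for promiscuous
  peptides), and EC50(w) = EC50_ref/(0.25 + 0.75w). The amplitude carries
  the dependency weight as well as the EC50 because potency-only coupling
  cannot make a zero-dependency response collapse exactly to background —
  a property both the contracts and the nulls rely on. BIM (EC50 0.2 µM)
  is more potent than BID (0.8 µM), so simulated cohorts reproduce the
  BIM > BID sensitivity ordering by construction.
* **Events.** Each well draws `events_per_well` events, 70% plasma cells;
  marker and cytochrome-c intensities are well-separated lognormals, the
  cytc channel bimodal (retained around 500 AU, released around 30 AU);
  non-plasma bystanders release only at background. Alamethicin wells
  release completely; negative-control wells at background.
* **Drugs.** Single-agent death = θ·w·hill(dose; EC50(w)) with targets
  ABT-199→BCL-2, ABT-263→max(BCL-2, BCL-X_L), WEHI-539→BCL-X_L,
  S63845→MCL-1, and proteasome inhibitors tracking overall priming (with a
  transient Noxa-mediated dependency shift, default 0.3, for dynamic
  profiling). Combination surfaces are either exactly the max of the
  margins ("hsa_null", zero HSA excess by construction) or Bliss
  independent action ("bliss", supra-HSA wherever both agents act). Wells
  add Gaussian noise (SD 2 percentage points) and 3 replicates.
* **Proteomics.** Per protein, y = b0 + b1·cellline + b2·t + b3·cellline·t
  + N(0, σ); exactly ⌊fraction_nonnull·n⌋ proteins carry any nonzero
  b1/b2/b3, with magnitudes ~ U(0.5, 2) for the cell-line offset and
  U(0.05, 0.3) per hour for slopes/interactions and random signs;
  σ = 0.25 by default.

What the generator does **not** emulate: fluorescence spillover and
compensation, doublets, acquisition drift, plate effects, peptide
cross-reactivity beyond the target map, correlated protein co-regulation,
or missing proteomics values. Passing tests therefore demonstrate that the
statistics are implemented correctly and recover truth under an idealized
but structurally faithful data model — not that the pipeline is robust to
every artifact of real cytometry or mass spectrometry.

## Numerical and design choices

* All randomness flows from a single integer seed through deterministic
  sub-streams; every generator output and the whole pipeline bundle are
  byte-reproducible under a fixed config + seed.
* Replicate wells are averaged (arithmetic mean of percentages) before
  normalization — the simplest unbiased choice where ordering is unstated.
* The peptide titration defaults to {0.1, 1, 10} µM; exact per-patient
  panels are a configuration choice, not a fixed fact of the assay.
* Degenerate inputs fail loudly and early: inverted controls, saturated
  Annexin baselines, rank-deficient designs, constant rows, mismatched
  delta-priming grids, unknown drugs/peptides all raise typed errors naming
  the offender.
* FCS ingestion is not included; event tables are CSV. The tidy CSV dialect
  round-trips losslessly and is the generator's native output format.
* Problem sizes used by the validation suite and the reproduction script —
  40 patients × 5000 events/well for recovery, 30 patients for
  correlations, 2000 proteins for null calibration, 100 replicates of 50
  proteins for family-wise error — were chosen as the smallest scales at
  which the targeted statistical properties are sharply testable.

## Known limitations

* Dependency scores conflate priming and dependence (both scale the
  response); the calls are comparative, not absolute binding measurements.
* The HSA summary is a mean over interior cells and will dilute a synergy
  confined to one dose combination; the max-excess summary is reported for
  that case.
* Gene-label permutation GSEA tests set concentration against a fixed
  ranking; with one sample per condition it cannot propagate
  sample-level variance, and its p-values should be read accordingly.
* Fixed-threshold gating assumes well-separated marker populations, as the
  generator produces; real cytometry may require compensation and manual
  gate review first.
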
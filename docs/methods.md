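# Methods

This note records the models, conventions and numerical choices behind
`pvniche`, and what the synthetic validation does and does not
demonstrate.

## Data model and coordinate conventions

A study is a manifest (tumor → treatment {untreated, NAC} × 3-year
outcome {DF, Mets}), per-ROI cell tables and per-ROI geometry. Cells are
points: continuous µm coordinates, origin at the ROI's top-left corner, y
increasing downward (image convention), with one boolean call per marker
(PanCK, CD31, CD3, CD4, CD8, FOXP3, PD-1, PD-L1, TIM-3, LAG-3, CD163).
Cell footprints are ignored throughout: a cell is "inside" a region iff
its centroid is. Geometry comes in two interchangeable dialects — polygon
sets in µm, or uint8 label masks (0 stroma, 1 TCI, 2 vessel) with a
stated pixel size. Raster pixel (i, j) covers the half-open square
[j·s, (j+1)·s) × [i·s, (i+1)·s) and is labeled by its center. Where TCI
and vessel regions would overlap, the vessel wins.

Upstream steps — segmentation, marker positivity calling, TCI/stroma
region classification from fluorescence — are out of scope; the package
consumes their output.

## Phenotype gating

Gating is a total, deterministic function of the marker booleans,
resolved by a fixed priority order: CD31+ → endothelial; else CD163+ →
TAM; else CD3+CD8+ → CD8 T cell; else CD3+CD4+FOXP3+ → Treg; else
CD3+CD4+ → CD4 T cell; else PanCK+ → cancer; else other. The order makes
conflicts (CD163+CD3+, CD3+CD4+CD8+) explicit and auditable: each
ambiguous pattern is counted in a QC tally (CD4/CD8 double positives,
CD8+FOXP3+ cells, LAG-3+PD-1− T cells). CD8 gating does not condition on
CD4, so CD3+CD4+CD8+ cells gate CD8; FOXP3 defines Tregs only within
CD4. T-cell activation: PD-1− ⇒ naïve (regardless of LAG-3, which alone
is not interpreted; such cells are tallied), PD-1+LAG-3− ⇒ active,
PD-1+LAG-3+ ⇒ exhausted. TAMs carry their PD-L1 and TIM-3 booleans as
subset attributes, so the four PD-L1±/TIM-3± subsets partition the TAM
population exactly. Rules live in a YAML/JSON `GatingConfig`
(required-positive / required-negative marker lists in priority order),
so a different panel can be gated without code changes.

## Compartments and the perivascular band

Five mutually exclusive labels partition each ROI: stroma/TCI crossed
with PV/non-PV, plus `VESSEL_EXCLUDED` for points inside a vessel region
(CD31+ wall and lumen are one region, excluded from all analysis
compartments). PV means Euclidean distance from the point to the nearest
vessel *boundary* ≤ the threshold (default 50 µm); a distance of exactly
50 µm is PV ("within 50 µm" is inclusive, "non-PV" is strictly beyond).
With no vessels the distance is +∞ and nothing is PV. Distances are
2-D — section-plane only; 3-D vessel geometry is unknowable from thin
sections.

Two computation routes exist, used according to the input dialect:

* **vector** — exact point-to-polygon distances; the PV band for area
  integration is the offset polygon `vessel.buffer(threshold)`
  (64 segments per quarter circle) minus the vessels;
* **raster** — label lookup plus a Euclidean distance transform of the
  vessel mask, in µm.

Both are tested to agree except within one pixel of a boundary. Area
integration always happens on a raster at the stated pixel size, counting
pixel centers, so the five classes partition the ROI area exactly. The
raster distance-transform area has a bias of order s/2 per band edge
(distance is measured to the nearest vessel *pixel center*), which is why
its error at the analytic annulus π(60²−10²) µm² shrinks roughly linearly
with pixel size (≈0.9% at 1 µm, ≈0.3% at 0.5 µm, ≈0.16% at 0.25 µm); the
vector route is fluctuation-limited and an order of magnitude more
accurate at the same grid.

## Densities and cohort aggregation

Density = cell count / compartment area (cells/mm²) per ROI, phenotype
selector and compartment. A compartment with zero realized area yields NA
— absence of the compartment, not absence of cells — and NA ROIs are
dropped from, not zero-filled into, the tumor mean. Aggregation is
two-level: tumor value = unweighted mean over that tumor's ROIs (so every
tumor contributes equally to its group no matter how many ROIs it has);
group value = mean ± SEM (sd/√n, ddof = 1) over tumor values. A pooled
mode (pooled counts / pooled area per tumor) is available for sensitivity
analysis. Subset proportions (%-of-parent, e.g. the TIM-3+ fraction of
TAMs) default to compartment-stratified computation, with tumor-wide
available by choosing the strata.

Phenotype selectors are a tiny conjunction language
(`TAM & tam_tim3 & !tam_pdl1`, `CD8_T & activation==NAIVE`) evaluated on
the labeled cell table; disjoint selectors are additive in density by
construction.

## 3-cell clusters

The object of interest is a mutually contacting triple {one TAM, one
CD4+ or CD8+ T cell, one Treg}. Contact is operationalized as centroid
distance ≤ 12 µm by default — about two touching 6 µm-radius leukocytes —
because membrane masks are not part of the data model; the threshold is a
parameter of every entry point. The contact graph is built with a KD-tree
but is defined (and tested) as identical to the all-pairs computation.
Default cluster = triangle (all three pairwise contacts); a relaxed
"path" mode (any connected triple) exists as an option. Every unique
id-triple is reported, so one cell can appear in several triples; a
greedy vertex-disjoint count (most compact triple first) is provided
because the counting convention for overlapping triples is a free
methodological choice. A cluster's compartment is its centroid's
compartment. Composition tables report, per stratum, the activation-state
fractions of the T-cell member (summing to 1), the TAM PD-L1± fractions
(summing to 1), and the TIM-3+:TIM-3− ratio among PD-L1− TAMs.

## Statistics

Group comparisons use the two-sided Mann-Whitney U-test: exact
enumeration p when n₁+n₂ ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. Multiplicity is
handled by Bonferroni within *explicitly declared* families — a contrast
plan names blocks of contrasts and the family size is the block size;
nothing is corrected implicitly, because the "right" family is an
analysis-level decision. Pearson correlation uses the t-transform with
n−2 df and treats zero variance as an error, not NaN. ROC curves are
computed over all score thresholds with trapezoidal AUC; the p-value
against AUC = 0.5 comes from the exact equivalence AUC·n₁n₂ = U rather
than an asymptotic variance formula, and an AUC below 0.5 is reported
as-is with an orientation flag, never silently flipped. AUC bands follow
the common convention (>0.7 good, ≤0.5 uninformative). A blinding helper
recodes group labels to opaque codes and returns the unblinding key
separately.

## The synthetic generator

The generator emulates the tissue structure the analysis assumes, with
known ground truth for every downstream estimate.

**Geometry.** TCI blobs are Fourier-perturbed ellipses (harmonics 2–5,
amplitudes ≤ 0.15, rescaled to an exact nominal area) placed without
mutual overlap until their ROI-clipped total reaches the target areal
fraction (±20% enforced; the last blob is sized to the remaining
deficit). Vessels are circles placed fully inside the ROI, in stroma,
non-overlapping. Real TCIs are more irregular and real vessels are not
circular, but compartment logic depends only on boundaries and distances,
which these shapes exercise fully.

**Cells.** Within each of the four analysis compartments the point
process is homogeneous Poisson with intensity
base(phenotype, stroma|TCI) × ρ(phenotype) inside the PV band ×
group effect. Counts are Poisson(intensity × realized area); positions
are uniform over the compartment's raster pixels with in-pixel jitter,
and any jittered point whose exact (vector) compartment differs from the
intended one is resampled — so the recorded ground truth is leakage-free
by construction. Markers follow the phenotype deterministically (a Treg
is CD3+CD4+FOXP3+, etc.) plus independent co-expression draws:
P(PD-L1+|TAM), P(TIM-3+|TAM), P(PD-1+|T), P(LAG-3+|PD-1+). Seeded
clusters place TAM/T/Treg triples on a small equilateral triangle
(circumradius = threshold/3, so all pairwise distances ≈ 0.58 × threshold)
at random perivascular stromal locations, every member verified to be PV
stroma with a 0.5 µm margin.

**Defaults (the simulated study conditions).** 600×600 µm ROIs at
0.5 µm/px, 20 ROIs/tumor, 2×2 design (untreated/NAC × DF/Mets), TCI
fraction 0.35; stromal intensities TAM 250, CD4 150, CD8 150, Treg 50
cells/mm² with TCI intensities 10× lower (immune exclusion) and cancer
2000/mm² in TCIs; PV enrichment ρ = 2 for TAMs, CD4 T cells and Tregs,
ρ = 1 for CD8 T cells (perivascular accumulation of the first three,
even stromal distribution of CD8); co-expression P(PD-L1+|TAM) = 0.22
(most TAMs lack PD-L1), P(TIM-3+|TAM) = 0.30, P(PD-1+|T) = 0.5 and
P(LAG-3+|PD-1+) = 0.2, giving a 0.5/0.4/0.1 naïve/active/exhausted T-cell
mix. Group effects default to 1 (a null cohort) and are supplied
explicitly when an effect is wanted. Vessel count (3/ROI) and radius
(8 µm) are *unconstrained by any measurement* — tissue vessel statistics
vary widely — and are simply plausible round numbers; treat them as free
parameters.

**Determinism.** One `SeedSequence` per cohort, one spawned child per
ROI: identical configs give byte-identical study directories (masks are
written as uncompressed TIFF without volatile tags).

**What it does not emulate.** No fluorescence rendering, no segmentation
or positivity-calling errors, no spatial clustering beyond the explicit
seeded triples, no marker co-expression correlations beyond the
conditional structure above — and, importantly, no between-tumor
biological variance: tumors within a group differ only by Poisson
sampling noise. Validation against this generator therefore demonstrates
the *correctness of the estimators and tests*, not their operating
characteristics on real tissue, where between-patient variance is far
larger and power correspondingly lower. The measured power of the
Mann-Whitney/Bonferroni procedure for a 2× effect at 10 tumors/arm is a
property of the generator's noise level, not a claim about patient
cohorts.

## Validation design and problem sizes

The acceptance suite checks properties, each against an independent
oracle:

1. classification vs from-first-principles ray casting + per-segment
   distances (1,000 random cells, 20 random geometries, 100% agreement);
2. raster PV-annulus area vs the closed form, error strictly decreasing
   at 1.0/0.5/0.25 µm/px and < 2% at 0.5;
3. triangle detection vs exhaustive C(n,3) scans (50 ROIs up to 300
   cells) and monotonicity in the contact threshold;
4. phenotype round-trip (exact) and group-density recovery within
   ±3 SEM of ground truth on a 4 × 8-tumor × 4-ROI cohort for ≥95% of
   the estimate grid. The grid includes every (group, compartment,
   phenotype) with expected events ≥ ~2 per tumor plus all
   zero-expectation cells (which verify absence of leakage); below ~2
   expected events the tumor values are almost all zero and the
   empirical SEM degenerates, leaving the band undefined;
5. seeded-cluster recall (100%) with the surplus of detections bounded
   by a permutation null that shuffles non-seeded phenotype labels
   within compartments while holding seeded labels fixed — the
   exchangeability the generator actually has;
6. Mann-Whitney exact p vs full enumeration, the AUC·n₁n₂ = U identity,
   Bonferroni clipping, Pearson ±1 on exact linear data;
7. calibration: familywise error ≤ 0.05 (plus two binomial SEs) over
   1,000 null replicates, and power ≥ 80% for a 2× effect at 10
   tumors/arm, both on a fixed-geometry 300×300 µm two-arm cohort with
   cells resampled per replicate;
8. bit-identical tables, results JSON and reports across two full runs
   from one seed (the provenance file, which records the run's own
   paths, is compared excluded).

Simulation sizes in tests (300–400 µm ROIs at 1 µm/px, 2–8 tumors per
group) were chosen so each check has adequate statistical resolution;
estimator correctness does not depend on them.

## Known limitations

* Cells are centroids: contact and compartment membership ignore cell
  size and shape.
* The PV band is a pure distance criterion; no distinction between
  functional vessel subtypes.
* Bonferroni is the only multiplicity method, by design fidelity; it is
  conservative for correlated contrasts.
* The exact Mann-Whitney path is limited to n₁+n₂ ≤ 12 without ties;
  identical-value samples therefore get the (slightly <1) corrected
  normal p rather than the exact 1.0.
* The raster area error bound assumes region boundaries are resolved at
  the stated pixel size; masks coarser than ~2 µm/px will visibly bias
  PV-band areas.
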
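# Methods

`ielquant` quantifies CD3⁺ intraepithelial lymphocytes (IELs) and
subepithelial band thickness on brightfield images and validates the whole
chain on a synthetic generator with exact ground truth. This note records
the models, the parameters that matter, and the design decisions taken
where the problem was genuinely open.

## Synthetic mucosa generator

The generator emulates a 20×-scanned colon/ileum biopsy fragment at a
default pixel pitch of 0.5 µm/px (a typical 20× scan; configurable).
Geometry is schematic rather than photorealistic:

- **Lumen** above an undulating boundary (two superimposed sinusoids with
  random phases, default amplitude 5 µm) — label 0 (background).
- **Surface epithelium**: a band of constant thickness (default 30 µm,
  about one columnar cell height) following the boundary — label 1.
- **Lamina propria**: everything below — label 3.
- **Crypts**: vertical elliptical annuli (outer radius ≈ 18 µm horizontally,
  1.2–1.6× vertically; wall 6 µm) embedded in lamina propria with bounded
  rejection sampling; the annulus is label 2, the crypt lumen label 0.
  Crypts never touch the top lumen or each other. No branching — the
  morphology corresponds to well-oriented biopsies with crypts cut
  perpendicular to the surface, the only orientation in which these
  metrics are read.
- **Subepithelial band**: the first `band_thickness_um` of lamina propria
  directly beneath the epithelium, tracked in its own binary mask (the
  compartment label stays lamina propria).

**Nuclei.** Epithelial nuclei are 1.5 µm-radius discs placed along the
surface-band midline and each crypt mid-wall at a fixed arc-length spacing
(default 4.5 µm). Each epithelial nucleus is independently CD3⁺ with
probability `rate/(100+rate)`, which makes the configured rate the
expected value of the measured statistic 100·pos/neg. Lamina propria
receives CD3⁺ lymphocytes and CD3⁻ stromal nuclei as homogeneous Poisson
point processes (defaults 300 and 600 /mm²; normal colonic mucosa carries
a few hundred CD3⁺ cells per mm²), thinned by a minimum centre-to-centre
distance. The minimum separation (default 4.5 µm) deliberately exceeds one
nucleus diameter plus the rendered 1-px DAB halo so that distinct ground-
truth nuclei remain resolvable objects; without that packing constraint
"exact recovery" would be ill-posed at the image level.

**Rendering.** Transmitted intensity follows Beer–Lambert per channel,
`I = I0·10^(−Σ c_s A_s)`, with unit-norm stain OD vectors `A_s`
(Ruifrok–Johnston values for hematoxylin, eosin and DAB; plausible
synthetic vectors for the Van Gieson, Masson Trichrome and
Weigert-Alcian-Sirius chromogens). Structure recipes per profile:
nuclei get hematoxylin 0.70 with ±10 % per-cell jitter; CD3⁺ cells add
DAB 0.80 over the nucleus disc plus a 1-px halo (a simplification of the
membranous CD3 pattern that keeps positivity a per-nucleus mean-OD
decision); stroma gets a light counterstain; the band adds chromogen 0.70
under the connective stains and nothing under H&E or CD3 — so a thin band
is visible on special stains and invisible on H&E, the dissociation the
band analysis exists to capture. Noise is additive Gaussian in intensity
(default sd 2/255), the smallest model that makes thresholding
non-trivial. A master seed spawns independent substreams for geometry,
nuclei and rendering, so stages are independently reproducible and
re-rendering the same truth under another stain changes nothing else.

What the generator does **not** model: eosinophils and plasma cells,
stain batch variation, tissue folds/artefacts, 3-D effects, truly
pseudostratified epithelium, lymphocyte aggregates. Passing tests
therefore demonstrate correctness of the measurement chain under the
stated image model, not clinical performance on scanner data.

## Stain separation

OD conversion uses `OD = −log10(max(I, ε)/I0)` with ε = 1/255 so
saturated-dark pixels stay finite. Unmixing is the least-squares
projection onto the stain basis (pseudo-inverse), with negative
concentrations clipped to zero — stain amounts are physical. Bases with
condition number above 10³ are rejected with the number reported.

## Tissue segmentation

A four-class pixel classifier runs at a working scale of 1/4 (standing in
for training at 5× on 20× material). Features per working-scale pixel:
raw and σ=2-smoothed OD per channel, multi-scale smoothed total OD
(σ = 1, 2, 4, 8), gradient magnitude, local OD standard deviation,
binarized-nucleus packing density at σ = 2 and 6 (so a strongly stained
isolated lymphocyte is not confused with a contiguous epithelial nuclear
band), relative row position, and distance into tissue. The classifier is
a seeded random forest (60 trees, depth ≤ 16): deterministic, trains on
one CPU in seconds at fixture scale, and supports the retrain-with-
corrective-ROIs loop by keeping its training set. The relative-row and
distance features encode the generator's top-lumen geometry; they are
part of the recorded training config and would need rethinking for
arbitrarily oriented real slides.

Predictions are upsampled to native resolution and cleaned with a
majority filter (radius 2) and minimum-region relabelling (64 px at
native scale, ties to the surrounding majority; equal class scores break
to the lowest class index by the forest's argmax). A coarse prediction
alone places boundaries only to about the scale factor (4 px ≈ 2 µm),
which biases centroid-based compartment assignment — lamina propria
lymphocytes sitting just under the epithelium leak into the surface
count. Segmentation is therefore coarse-to-fine: a second forest,
trained on native-scale samples near class boundaries, re-classifies a
±6 px zone around every compartment boundary of the upsampled
prediction, bringing boundary error down to ~1–2 px. The band sampler
still searches ±4 px around the nominal epithelial lower boundary to
absorb the residual.

The 0.90 held-out pixel-accuracy floor used in the 12-train/22-validation
experiment is this package's own acceptance bar for "comparable to manual
labelling"; the floor is evaluated on unseen synthetic images.

## Cell detection and positivity

Detection operates on the unmixed hematoxylin concentration: every
nucleus carries the counterstain, whereas including DAB would let the
halo of a CD3⁺ cell fuse neighbouring blobs into shapes no watershed
criterion can split reliably. The chain is Gaussian smoothing (σ = 1),
fixed threshold (0.35 — midway between stroma ≈ 0.1 and nuclei ≈ 0.7),
distance-transform watershed (markers = distance maxima with minimum
separation 3 px, ties by scan order), and an area filter (8–500 px). Centroids are intensity-weighted.
A cell is CD3⁺ iff its mean DAB OD over the nucleus region + 1-px halo
(mirroring the renderer) **strictly** exceeds the threshold; ties are
negative. The threshold is calibrated as the midpoint of the two
class-conditional mean-OD means on labelled material — the simplest
reproducible realisation of "a threshold based on staining intensity of
the cohort". Compartment assignment is by the centroid pixel's label;
whether a boundary-straddling cell is intraepithelial is genuinely
ambiguous and the centroid rule is this package's convention.
Detection metrics use greedy nearest-first one-to-one matching within a
radius — deterministic and adequate at these densities.

## Quantification

- `iel_per_100` = 100 · (CD3⁺ in compartment) / (CD3⁻ in compartment).
  The denominator is the CD3⁻ epithelial nuclei: on a CD3 stain they are
  the only countable proxy for "epithelial cells". A config toggle
  (`denominator="pos_plus_neg"`) divides by all epithelial nuclei instead,
  since either convention is defensible. An empty denominator raises —
  the ratio is undefined, not 0 or ∞.
- `lp_density` = CD3⁺ count / lamina propria area, with area counted from
  label-3 pixels × (µm/px)²/10⁶.
- `hotspot_count` emulates manual hotspot reading: the maximum per-100
  over sliding windows of exactly W consecutive CD3⁻ cells (default
  W = 100) along the surface path, where window *i* counts the positives
  strictly between the neighbouring negatives *i−1* and *i+W* (extended
  at the sequence ends). Under this open-edge rule the window maximum is
  provably ≥ the whole-compartment value whenever the number of negatives
  N ≥ W(W+1) (a disjoint chain of windows covers every positive, then
  pigeonhole); for pathological edge-clustered configurations below that
  size the ordering can fail for *any* exactly-W window rule, so the
  property suite exercises the provable regime, which is also the
  realistic one (hundreds of cells per compartment). Fewer than W
  negatives falls back to the global value, flagged.
- `band_thickness`: perpendicular depth of band evidence (ground-truth
  mask or thresholded connective-chromogen concentration, threshold 0.4)
  sampled below every 4th surface column; the representative value is the
  **median** of samples (robust to local aggregates), rounded half-up to
  integer µm.
- `classify_mc`: lymphocytic axis LC iff IELs > 20, LCi for [10, 20];
  collagenous axis CC iff band > 10 µm, CCi for [5, 10]. "Exceeding" is
  read strictly and "between" inclusively, so exact boundary values fall
  to the incomplete category; the call is monotone by construction.

## Statistics

Summaries are mean, two-sided 95 % t-interval and range (n = 1 flags the
CI undefined). The paired t-test uses the closed form with n−1 df;
identical pairs return t = 0, p = 1, while a constant non-zero difference
raises (the statistic is undefined). The Wilcoxon signed-rank test uses
Pratt zero handling: zeros are ranked with the rest (mid-ranks for ties)
and then dropped from the statistic. Up to 20 non-zero differences the
two-sided p is exact — all 2^m sign assignments enumerated
(meet-in-the-middle), doubling rule `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`;
beyond that a normal approximation with Pratt zero correction and tie
correction is used and labelled `WILCOXON_PRATT_APPROX` in the result.
Full enumeration is infeasible at cohort sizes (≈50–60 pairs) for any
implementation, so reporting which path ran is part of the contract.
Bonferroni adjustment returns α/m and the printed-style threshold
truncated to three decimals (0.05/6 → "<0.008"). Frequency tables report
n (%) with percentages rounded half-up to one decimal over the assessed
denominator; not-assessed entries are counted separately. The pairwise
comparison report runs one Wilcoxon–Pratt test per comparison per
location and flags significance at the per-location Bonferroni threshold.

## Pipeline

`run_full` executes simulate → train → segment → count → quantify → stats
against one run directory; every stage communicates through files, so a
full run is byte-identical to running the stages individually, and the
manifest (SHA-256 per artifact, seeds, timings) makes reruns verifiable.
Configs are validated strictly (unknown keys rejected) before any work.
Stage seeds derive from the master seed and a fixed stage index.

## Validation problem sizes

The recovery benchmark uses biopsies of 384 × 3456 px (0.19 × 1.73 mm),
giving ≥ 300 CD3⁻ surface epithelial cells per biopsy, across surface rates
{2, 5, 10, 20}/100 paired with lamina propria densities
{100, 300, 1000}/mm², with ≥ 20 seeds per setting; recovery error is the
pooled-over-seeds estimate (summed counts — the natural estimator of a
rate averaged over replicates, since per-seed ratios at rate 2 carry
~30 % noise from the handful of positives in one biopsy) compared against
the generator's realized ground truth, which isolates pipeline error from
the generator's own sampling noise. The configured-vs-estimated
comparison is reported alongside. The segmentation experiment mirrors a 12-image training /
22-image validation design at 256 × 384 px. These sizes keep the full
suite within a few CPU-minutes while leaving the per-setting Monte-Carlo
error well inside the tolerances tested.

## Known limitations

- The segmentation features include position priors tied to the
  generator's "lumen on top" layout; real whole-slide images would need
  rotation-invariant features.
- Boundary cells can flip compartments (≈ 2 µm mask uncertainty); at very
  high lamina propria densities this is the main residual bias in
  per-compartment counts.
- Equivalence with any proprietary commercial pipeline cannot be claimed;
  the contract here is the documented one.
- Geboes-scale scoring, eosinophils/plasma cells, and diagnosing real
  patients are out of scope.
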
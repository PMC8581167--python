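# Methods

## The assay being modelled

Human iPSCs seeded on 1000-μm circular micropatterned islands and exposed
to BMP4 + NODAL self-organise within 48 h into concentric germ-layer
domains: an ectoderm-like centre (SOX2), a mesoderm-like mid-ring
(BRACHYURY/BRA) and an endoderm-like outer ring (SOX17) that typically
shows angular discontinuities. High-content imaging of such plates yields,
per well, a DAPI channel plus one channel per marker. The package turns
those images into quantitative phenotypes per colony, well, experiment and
cell line, and flags lines whose phenotype deviates from a designated
control line. A companion filter selects rare, deleterious
non-synonymous SNVs from an annotated variant table, the genetic side of
the phenotype-to-genotype comparison.

## Image analysis pipeline

**Nucleus segmentation** (`segmentation`). Gaussian smoothing (σ = 2 μm) of
the DAPI channel, Otsu threshold, removal of objects below 25% of the
expected nucleus area, then a distance-transform watershed seeded at local
maxima at least 8 μm apart. Per nucleus we record the mask centroid (μm),
pixel area, and the arithmetic mean intensity over the mask in every
channel. Mean rather than summed intensity is used throughout; nuclei with
non-positive DAPI mean are dropped (the DAPI normalisation divides by it).

**Colony identification and QC** (`colonies`). The union of nucleus masks
is smoothed with a Gaussian of σ = 40 μm — of the order of the
inter-nucleus spacing — and thresholded at 30% of the mean smoothed density
over nucleus pixels; connected components are colonies and every nucleus is
assigned to the component under its centroid (or left unassigned).
Morphological closing of the mask union was evaluated first and discarded:
at realistic densities it leaves a ragged outline whose Crofton perimeter
inflates the isoperimetric quotient denominator, making a roundness gate
meaningless. The density mask yields solid, smooth discs whose area and
roundness are informative. Each colony is then gated, in fixed priority
order:

1. **edge** — mask within 10 μm of the image border (colonies printed at
   the well edge are incomplete);
2. **area** — outside [0.7, 1.3] × nominal disc area (π·500² μm²);
3. **roundness** — isoperimetric quotient 4πA/P² (capped at 1) below 0.8.
   A circle scores 1, a square π/4 ≈ 0.785, a half disc ≈ 0.747, so 0.8
   cleanly separates full discs from truncated or ragged ones.

The exact area/roundness cut-offs used on the original physical plates are
not published; the defaults above are exposed as `QCThresholds`.

**Radial profiling** (`profiling`). Each nucleus's distance D from its
colony centroid is binned into 20 half-open concentric rings of 25 μm —
[(B−1)·25, B·25) — exactly tiling the 500-μm nominal radius. Distances
beyond 500 μm (centroid jitter) are clipped into ring 20 and counted in the
run log rather than discarded, which would bias the outer ring. The
normalisation cascade is applied in a fixed order:

1. per-nucleus ratio = marker mean / DAPI mean (controls for ploidy,
   focus and staining efficiency; exactly invertible on the simulator's
   multiplicative intensity model);
2. background subtraction with floor at 0, the background estimated per
   well and marker as the mean of the lower component of a two-component
   Gaussian mixture over the nucleus ratios (the non-expressing
   population); positivity threshold = lower mean + 2 lower SD, applied to
   the *subtracted* ratio. If the mixture degenerates (a component weight
   < 2% or coincident means) the estimator falls back to percentiles
   (5th/50th) with a logged warning;
3. per-ring mean within each colony; empty rings are missing, never zero
   (zero would fabricate absence of expression in sparse rings);
4. division by the maximum ring value across the well's qualified colonies,
   so each well's brightest ring is exactly 1 (idempotent);
5. hierarchical aggregation colonies → well (technical replicate) → 
   experiment (biological replicate) → line, with SD taken over the units
   averaged at each level. Hierarchical means are *not* pooled means when
   unit sizes differ; the tests pin this on a hand-computed toy.

**Percent-positive** per colony = 100 × (nuclei whose subtracted ratio
clears the threshold) / (nuclei in the colony); it controls for cell-number
variation between colonies.

## Statistical layer (`stats`)

* **Radial patterning**: two-sample Kolmogorov–Smirnov on the radial
  distances of marker-positive nuclei (scipy `ks_2samp`). Ring-mean
  profiles have only 20 points, far too few for a distribution test, so
  the per-nucleus distance distribution is the object compared. A line is
  a *radial outlier* when its distribution differs from the designated
  control line at p < 0.01.
* **Mean expression**: two-tailed Student's (pooled-variance) t of one
  line's colony percent-positive values against all other lines' colonies
  pooled (target excluded); *outlier* at p < 0.001. Welch is available by
  flag.
* **Panel-wide differences**: Kruskal–Wallis omnibus (α = 0.05) with Dunn's
  rank-based post hoc z tests, tie-corrected, Bonferroni-adjusted by
  default (Holm optional). Dunn's test is implemented here directly since
  no installed library provides it; it is pinned against hand-computed
  ranks.
* **Marker relationships**: Spearman rank correlations of percent-positive
  values across colonies (line level optional); constant inputs yield
  missing r.
* **Line clustering**: PCA of column-standardised per-line percent-positive
  features; clonal lines sharing a donor should co-locate in score space.

## Synthetic-data generator (`simulate`)

The generator produces the ground-truthed images the pipeline is validated
on. Defaults describe the study conditions:

| parameter | default | rationale |
|---|---|---|
| pixel size | 2 μm/px | 10–20× objective scale; nuclei ~6 px across |
| colony diameter | 1000 μm | printed island size |
| colonies/well | 6 | 4–7 readable colonies per physical well |
| nuclei/colony | 800 | confluent micropatterned colony; matches the n at which percent-positive recovery is specified |
| nucleus radius | 6 μm | typical iPSC nucleus |
| min nucleus spacing | 2.5 × radius | non-overlapping, resolvable nuclei |
| DAPI intensity | Gamma, mean 400, CV 0.2 | positive, right-skewed per-nucleus brightness |
| marker baseline ratio | 0.1 | non-expressing background population |
| additive noise SD | 5 counts | ~1% of DAPI mean |
| SOX2 | centre dome, width 150 μm | central ectoderm domain |
| BRA | ring at 250 μm, width 60 μm | mid mesoderm ring |
| SOX17 | ring at 425 μm, width 40 μm, 20% angular gap | discontinuous outer endoderm ring |

Marker intensity is multiplicative in DAPI: nucleus marker signal =
(baseline + positive·amplitude·g(D)) × DAPI, with g a Gaussian radial
envelope, so the pipeline's DAPI normalisation recovers the configured
ratio exactly in the noiseless limit. Positivity is Bernoulli with
probability following the same envelope (peak values 0.85–0.9); ring
markers can carry an angular discontinuity sector forced negative.
Donor effects shift/scale a line's envelopes (centre, width, amplitude,
positive fraction) and are shared by all wells of that line; replicate
wells differ only by their RNG stream, derived deterministically from the
top-level seed. Nuclei are uniform in the disc (no radial density
gradient — none is documented for the physical colonies) with
minimum-distance rejection; truncated colonies are produced by moving the
disc centre to within 0.2–0.7 radii of the image border. Nuclei render as
filled discs blurred with a 1-px Gaussian; images are float internally,
uint16 on export.

What the generator does **not** emulate: signalling-driven pattern
formation (domains are imposed phenomenologically), cell shape and texture,
mitotic/apoptotic figures, uneven illumination, channel bleed-through and
focus drift. Passing tests therefore demonstrate that the measurement and
statistics machinery recovers known structure under realistic geometry and
noise — not that segmentation is robust to every real-microscope artefact.

## Variant filter (`variants`)

A candidate nsSNV qualifies when MAF < 0.005 in **both** the 1000 Genomes
and ExAC databases, it is carried by **fewer than five** bank lines, and
Condel predicts it deleterious — all inequalities strict, so MAF = 0.005
and a count of 5 fail. Missing MAF is treated as failing rarity
(conservative, logged); missing Condel class drops with a warning. Condel
and DUET values are consumed as annotations, never computed. "Fewer than
five" counts lines, not donors (switchable by pre-aggregating). Lines are
categorised by where their qualifying variants fall — cell-adhesion genes
(ITGB1, ITGA6, FHL2), germ-layer genes (SMAD2, FGFR1, TBXT), both, or
neither (control); the gene sets are configurable.

## Validation studies and problem sizes

`micropattern.studies` scores the pipeline against the generator's ground
truth at sizes chosen to run in minutes on one CPU:

* **ring recovery** — 4 wells × 6 colonies × 800 nuclei; fraction of
  qualified colonies whose profile peak lands within ±1 ring of the
  configured 425-μm centre; percent-positive error against realised truth
  at a uniform positive fraction of 0.4; background error against the
  configured 0.1 baseline.
* **QC** — 4 wells × 6 colonies, 30% truncated; truncated-rejection and
  complete-qualification rates.
* **calibration** — 1000 null draws for KS (n = 200 positive nuclei per
  group) and Kruskal–Wallis; 200 draws for KS power at a 100-μm ring shift
  (α = 0.01) and for pooled-t detection of a 5-SD-shifted line.
* **variant round trip** — survivors of the filters must equal the
  generator's constructed pass count exactly.

`scripts/acceptance.py` reruns all of these from scratch under a
user-supplied seed.

## Numerical and design notes

* All coordinates are converted to μm at ingest; public distances and bins
  are in μm.
* Rejection reasons are prioritised edge > area > roundness so reruns
  report deterministically.
* The GMM background fit uses `random_state=0`, `n_init=2`; the whole
  pipeline is deterministic given images and configuration.
* `assign_bin` never returns "outside": over-range distances clip into the
  last ring and are tallied.
* Whether the well-normalisation maximum is taken over ring means or
  single nuclei is not documented for the original assay; the maximum over
  colony-level ring means is used here.
* KS replicate comparisons operate on nucleus distances, not binned
  profiles (see the statistical layer above).

## Known limitations

* Segmentation is tuned for well-separated, disc-like nuclei; heavily
  confluent or apoptotic fields would need a stronger splitter.
* The background mixture assumes a dominant non-expressing mode; wells
  where nearly every nucleus expresses the marker will push the estimate
  upward.
* The statistical layer treats colonies as exchangeable within a line
  (no mixed-effects modelling of the well/experiment hierarchy), matching
  the original analysis design.
* Percent-positive for ring markers depends on the configured positive
  fraction profile; only the uniform marker gives a scalar truth to
  recover, which is why the recovery study uses one.
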
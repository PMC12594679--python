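# Methods

## Scope and inputs

`nvumorph` quantifies ultrastructure of the retinal neurovascular unit
(NVU) in *segmented* SBF-SEM stacks: multi-page TIFF (or HDF5) label
volumes indexed `(z, y, x)`, page `k` = section `z = k`, with a sidecar
mapping label ids to roles (`background`, `lumen`, `endothelium`,
`pericyte`, `basement_membrane`, `macroglia`, `tubule`).  Label 0 is
always background, which doubles as electron-lucent space: a gap that a
microscopist would read as "lucent" is simply unsegmented volume.
Voxel geometry lives in the sidecar — default (dz, dy, dx) =
(100, 6, 6) nm — and is never resampled: all measurements are taken
in-plane where resolution is ~17× finer than the section step, and the
axial direction is used only for connectivity and depth normalisation.
TIFF resolution tags are ignored (with a warning when they carry
non-trivial values) because TIFF dialects disagree about their meaning.

Raw-EM processing (alignment, contrast, segmentation, rendering) is out
of scope.

## BM thickness

Thickness is defined per 2D section, not with 3D spheres: a 100 nm
z-step would dominate any 3D inscribed sphere and make "thickness"
mostly a function of anisotropy.  Within a slice:

* The **inscribed radius** `rho(p)` is the largest integer radius whose
  closed Euclidean disc of pixel centres around `p` stays inside the
  BM mask.  It is computed from the exact squared Euclidean distance
  transform (`rho = ceil(EDT) − 1`); pixels beyond the image border
  count as background.
* The **local thickness** `LT(p)` is the diameter `2·rho(q)+1` of the
  largest disc covering `p` (Hildebrand–Rüegsegger), computed by
  painting discs in decreasing radius order.  Diameters are odd
  integers by convention: a 5×5 solid square has centre thickness 5, a
  one-pixel bar thickness 1.  For a disc that exactly fits the mask,
  `d = 2·EDT − 1`.
* **Sampling**: thickness samples are taken at the maximal-disc centres
  — the pixels with `LT(p) == 2·rho(p)+1`, i.e. the discrete medial
  axis as the locus of maximal discs.  This rule is exactly invariant
  under translation, 90° rotations and flips (thinning-based skeletons
  are not, because of tie-breaking), and it rejects boundary-bump
  pixels whose small discs are swallowed by the ridge disc.  Sampling
  the *covering* value at skeleton pixels instead would bias the mean
  upward by about one pixel on modulated shells (covering discs spill
  sideways out of thick regions), and sampling all mask pixels would
  over-weight thick regions by area.
* **Aggregation**: slices are measured independently; fragmented masks
  (e.g. flanking a planted gap) are handled per component and pooled.
  The stack mean is the sample-count-weighted mean of slice means
  (equivalently the pooled-sample mean); the maximum is the global
  per-stack maximum over samples.  Slices with an empty BM mask are
  skipped with a warning and listed in the profile; only a stack with
  no BM anywhere is an error.

A brute-force oracle (`brute_force_local_thickness`) recomputes the
map by exhaustive window tests without any distance transform; the
fast path matches it exactly on random masks (this equivalence is a
test, not an assumption).  The oracle is O(area × rho²) and capped at
20 000 mask pixels.

Expected resolution: with 6 nm pixels and odd-diameter discs, a shell
of true width `T` measures within one pixel of `T`; even pixel widths
read one pixel low (60 nm → 54 nm), which stays inside the ±6 nm
acceptance band used throughout.

## Feature detection

All three detectors work on role masks; 3D components use
26-connectivity in voxel space (features persist across sections and
face-only connectivity fragments thin pegs across the 100 nm step — a
caveat worth remembering when interpreting z-extents).  Adjacency
tests for gaps and openings are strictly in-plane (4-neighbour): two
voxels that only touch across sections are 100 nm apart and say
nothing about membrane contact.  One 3D component = one counted
formation regardless of z-extent.  Events touching the first or last
section are counted and flagged `at_boundary`.

**Endothelial envelope.**  Pegs must be found "inside the endothelium"
from labels alone.  Per slice, the capillary wall
(endothelium ∪ lumen ∪ BM) is morphologically closed with a Euclidean
disc (default radius 5 px, via two distance transforms) and
hole-filled.  The closing seals the narrow corridor where a peg shaft
pierces the BM; the fill then recovers the enclosed socket interior
(peg tip plus any lucent shell).  Closing the wall *including the BM*
is essential: closing endothelium ∪ lumen alone cannot seal a socket
whose mouth (shaft plus detached shell) is wider than twice the
structuring radius, because the corridor walls there are BM, not
endothelium.  The default peg radius in the phantoms (24 nm = 4 px)
keeps the corridor within the 5 px closing's reach.

**Peg-and-socket.**  Candidate voxels are pericyte ∧ envelope; a
component is a peg iff it is 26-adjacent to pericyte material outside
the envelope (it crosses the BM to the pericyte body; an isolated
pericyte islet inside the endothelium is not a peg).  The lucent shell
is the background inside the envelope face-adjacent to the peg; its
width is the maximum in-plane distance of shell voxels from the peg
surface, and `width ≥ lucent_gap_threshold_nm` (default 12 nm = 2 px)
classifies the formation *partially detached*.  Shell voxels are
recorded and excluded from detachment counting — no lucent voxel is
counted twice.

**Cell–BM detachment.**  Candidates are background voxels within a
bounded in-plane search distance (default 60 nm) of both the BM and the
target role.  A literal "adjacent to both surfaces" rule would find
nothing for gaps wider than two pixels (interior gap voxels touch
neither surface), and without the bound the unbounded exterior would
qualify.  A candidate component is an event iff it touches both
surfaces within one in-plane step, its width
`max(d_BM + d_target − 1)` (exact for a corridor between two walls)
reaches `min_gap_width_nm` (default 12 nm), and it spans
`min_z_slices` (default 2) sections.

**Tubules.**  Components of the tubule label, classified by in-plane
face adjacency: *luminal* (touches lumen), *abluminal* (touches BM),
*transendothelial* (both), *closed* (neither).  The transendothelial
count is reported explicitly even when zero, so the absence of
complete transendothelial channels is a single field of the summary.
Swapping the lumen and BM labels swaps luminal/abluminal and fixes
closed/transendothelial — a symmetry the tests exercise.

**Thresholds.**  `min_voxels = 20`, `min_z_slices = 2`,
`min_gap_width_nm = 12`, `lucent_gap_threshold_nm = 12`,
`max_gap_search_nm = 60`, `closing_radius_px = 5`.  These are declared
defaults of this package, all exposed in configuration; they are not
taken from any published criterion.  At the default geometry the
smallest planted features exceed the size thresholds severalfold.

**Normalisation.**  Capillary depth is `n_slices × dz` (the stack is
assumed to run along the capillary axis; oblique segments would need a
centreline length, which is out of scope).  Frequencies are
`count × 10 000 nm / (n_slices × dz_nm)` per 10 µm.

## Synthetic phantoms (study conditions)

A phantom is a capillary cross-section extruded along z: lumen disc,
endothelial annulus, BM shell, pericyte arc, macroglial sheath.
Geometry is specified in nm and rasterised by centre-sampling on the
anisotropic grid, which keeps analytic-versus-measured comparisons
predictable to ±1 pixel.  Defaults mirror the imaging conditions the
package targets: 6 nm pixels, 100 nm sections, stacks of 130–300
sections, 512² fields; lumen radius 550 nm, endothelium 280 nm, BM
base 102 nm, pericyte arc π radians at 180 nm, macroglia 180 nm —
a capillary scaled to fit the field of view with realistic layer
proportions.

The BM thickness field is
`w(θ, z) = base + A·sin(kθ·θ + 2πz/Z + φ)` (defaults `kθ = 3`, `Z` =
stack length).  `analytic_thickness_summary` integrates it by
quadrature (2048 angular nodes × all sections), independent of
rasterisation; for integer `kθ` the mean is the base exactly.
Validation requires `base − |A| ≥ 2` pixels so the shell never
vanishes, and all planted features must be pairwise disjoint in
(z-range, angular footprint).

Features: pegs are pericyte cylinders (radius 24 nm, tip 150 nm into
the endothelium) crossing the BM; partially detached pegs carve a
lucent shell of chosen width around the tip, inside the endothelium
only.  Detachments carve lucent annular arcs of chosen radial width
between the BM and the target cell (pericyte arcs fully inside, and
macroglial arcs fully outside, the pericyte coverage — a straddling
arc would touch two roles at once).  Tubules are endothelial cylinders
whose centre radius places them clear of both surfaces (closed),
tangent to one (luminal/abluminal), or spanning the wall
(transendothelial).  Ground truth records the analytic thickness
summary, exact feature counts by state/class, and the implied per-10 µm
frequencies.

An optional smooth boundary-jitter field exists (default off); the
phantoms are otherwise clean label volumes.  They deliberately do not
model segmentation errors, grayscale texture, oblique or meandering
capillaries, or features touching the stack boundary — so passing
tests demonstrate correctness of the measurement and counting logic,
not robustness to segmentation noise.

**Cohorts.**  `make_cohort` simulates per-capillary variation: feature
counts are Poisson with mean = (template prototype count) × (group
multiplier); parameters are copied from randomly chosen prototypes at
fresh non-overlapping positions; the BM base receives Gaussian
between-capillary jitter (σ = 6 nm, same law in every group).  Seeds
derive deterministically from one root seed (`SeedSequence`);
regeneration is bit-identical.  A feature that cannot be placed after
200 attempts is dropped, and ground truth counts only what was placed.

The canonical **control template** (`study_template`, 300 sections =
30 µm) carries 9 peg prototypes (one partially detached) → 3.0 per
10 µm, one detachment prototype per role, and 6 tubule prototypes
(4 closed, 1 luminal, 1 abluminal, none transendothelial) → 2.0 per
10 µm.  Group multipliers (`STUDY_EFFECTS`): control scales
detachments to a Poisson mean of 0.2 per role (rare in health); the
diabetic-like group uses pegs ×0.4, detachments ×2.0 (ten times the
control rate), tubules ×2.5, and identical thickness statistics.

**Manifest mode.**  Large statistical simulations (1000-replicate null
calibration, 200-replicate power) run on cohort *ground truths*
(`rasterise=False`, `cohort_metric_table`): the statistics consume
per-capillary frequencies and analytic thickness directly.  This is
valid because detector-equals-manifest is established separately and
exactly on rasterised phantoms; rasterising 3600 full stacks would
add hours of compute and no information.  Rasterised cohort members
still flow through the full pipeline in the end-to-end tests.

## Statistics

Per-capillary values (the capillary is the statistical unit; no
mouse-level clustering is modelled, and reports should say so when
capillaries share animals) are summarised as mean ± SEM
(`sd(n−1)/√n`; undefined at n = 1) and compared with unpaired
two-tailed tests:

* **Student's t** — classical pooled-variance form, `n_a + n_b − 2`
  df.  Zero pooled variance: p = 1 if the means agree, else p = 0.
* **Mann–Whitney U** — midrank U statistic.  For tie-free pooled
  samples with `n_a + n_b ≤ 14` the two-tailed p is exact: all
  `C(N, n_a)` rank assignments are enumerated and assignments at least
  as extreme as observed (|U − μ| with μ = n_a·n_b/2) are counted.
  Otherwise the tie-corrected normal approximation with continuity
  correction is used.  The method actually used is recorded.
* **Selection rule** (`test="auto"`): Mann–Whitney when either group
  has n < 5, is (near-)constant, or fails a Shapiro–Wilk screen at
  p < 0.05; Student's t otherwise.  The rule is configurable and the
  choice is logged per comparison.  Under null cohort simulations the
  rule's empirical type-I error at nominal 0.05 sits near 0.05
  (calibration is an acceptance test, bracketed to [0.03, 0.07]).

Significance is flagged at 0.05/0.01/0.001 with the usual asterisk
notation.  No multiple-testing correction is applied across metrics;
each panel is reported with its own p.

## Orchestration and determinism

`run_pipeline` executes cohort generation (or stack reading), thickness
measurement, feature detection and group comparison, writing a JSON
report plus per-capillary and per-event CSVs.  Configs are validated
up front with a complete violation list.  All randomness flows from
the config seed; identical config + seed gives byte-identical metric
CSVs.  Warnings (skipped slices, boundary events, single-group runs)
are duplicated into the report.

Problem sizes in the test-suite and acceptance script: thickness
recovery uses 50-section 512² stacks; feature-recovery sweeps use
80-section 512² stacks carrying up to 21 features; oracle comparisons
use ≥25 random masks up to 128²; unit tests use a proportionally
scaled-down capillary (256², 60 nm shell).  These sizes give the same
per-voxel geometry as the full stacks while keeping the whole suite in
the minutes range on one CPU.

## Known limitations

* The capillary axis is assumed parallel to z; depth is
  `n_slices × dz`.  Oblique or curved segments would underestimate
  depth and mix in-plane with oblique sections.
* 2D thickness on near-tangential sections (capillary wall almost
  parallel to the cutting plane) would read high; the phantoms do not
  model this regime.
* The odd-diameter disc convention quantises thickness to odd pixel
  multiples; sub-pixel thickness estimation is out of scope.
* Detector thresholds are package defaults, not values recovered from
  any published inclusion/exclusion protocol; conclusions about real
  stacks should report the thresholds used.
* Exact Mann–Whitney enumeration stops at `n_a + n_b = 14`; beyond
  that the normal approximation's accuracy (checked to |Δp| < 0.02 at
  7 vs 7) is inherited.
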
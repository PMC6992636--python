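# Methods

`plexuscan` re-implements, as a tested pipeline, the quantitative OCTA
analysis of the three inner-retinal capillary plexuses — superficial (SVP),
intermediate (ICP) and deep (DCP) — from the foveal centre to the far
periphery, and ships a synthetic phantom generator with voxel-level ground
truth so that every stage of the measurement chain can be validated without
patient data.

## Measurement chain

1. **Quality gates** (`volume_io.qc_gate`). A volume enters analysis only if
   its signal strength is ≥ 9/10 and manual layer-segmentation corrections
   touch at most 5% of its B-scans (`floor(0.05 × n_bscans)`; exactly 15 for
   a 300-B-scan cube). Both boundary values pass. The device's signal-
   strength index is unpublished, so for phantoms it is synthesized
   metadata; the gate logic, not the index, is what the pipeline owns.
2. **Layer segmentation** (`slabs.segment_surfaces`). The ILM is the first
   axial gradient maximum from the top of each A-line (computed on the raw
   grid — axial smoothing would dilute the thin ILM edge below threshold
   while leaving the much stronger RPE edge as the first candidate); the
   RPE is the brightest axially-smoothed band. The IPL-inner-two-thirds,
   INL–OPL and OPL–ONL interfaces are placed at fixed fractions (0.30,
   0.43, 0.62) of the local ILM→RPE span; the fractions are calibrated on
   the phantom's layer model and exposed in `SegmentationConfig`. Surface
   maps are median-filtered over 50 µm. More than 5% of A-lines without
   ILM/RPE signal is a segmentation error.
3. **Plexus slabs** (`slabs.define_slabs`). SVP: [ILM, inner two-thirds of
   the IPL); ICP: [SVP outer, INL–OPL + δ); DCP: [ICP outer, OPL–ONL + δ),
   with δ = 6 µm ("just behind" an interface, one axial resolution element;
   configurable). Half-open depth intervals make the three slabs tile the
   inner retina with no overlap, which the tests check voxelwise.
4. **Projection removal** (`slabs.remove_projection`). Per A-line, a flow
   voxel is kept iff it strictly exceeds the maximum of all shallower
   voxels; otherwise it is zeroed. The strict rule is idempotent and never
   increases a voxel; both properties are tested, along with tail
   suppression on labelled phantoms (< 1% of tail voxels survive, > 90% of
   true DCP voxels survive).
5. **En face projection** (`slabs.enface`). Per pixel, the max (default) or
   mean of the flow voxels between the slab surfaces, then min–max
   normalized per image. Max is the default because phantom capillaries are
   one voxel thick axially: a mean over a ~50-voxel slab dilutes them to a
   few percent of the vessel amplitude, beneath any workable binarization
   threshold after normalization. `mean` remains available for thicker flow
   signals.
6. **Montage** (`montage`). 3 × 3-mm volumes acquired with ~40% overlap are
   stitched into a 22-mm horizontal (nasal→temporal) and vertical
   (inferior→superior) band. Registration is translation-only normalized
   cross-correlation seeded by the nominal acquisition offsets and searched
   within ±0.5 mm; a correlation peak below 0.2 is a registration failure.
   Overlaps are blended by per-pixel mean (unbiased for density counting).
   Eccentricity is signed: temporal/superior positive. Polyak zones
   partition eccentricity with half-open intervals (foveola < 350 µm ≤
   foveal floor < 400 ≤ parafovea < 1250 ≤ perifovea < 2750 ≤ near
   periphery < 4250 ≤ mid periphery < 7250 ≤ far periphery). The optic
   nerve head is excluded on the horizontal band by a configurable disc
   (default centre 4 mm nasal, radius 1 mm; the source protocol does not
   state its exclusion geometry).
7. **C-scan density** (`density_cscan`). Large vessels are masked by
   Gaussian-smoothing the SVP en face with a 15 × 15-px window (σ =
   window/6, kernel truncated at the window) and thresholding at 0.4
   (strictly greater; ties are not vessel); the same mask applies to the
   ICP and DCP images of the field. Flow pixels are intensities strictly
   above 0.10 (the binarization rule is not pinned by the protocol; phantom
   flow is near-binary, so results are threshold-insensitive). CD is
   counted in 0.1 × 0.8-mm windows stepped every 0.1 mm along the band,
   long side across the band; windows whose masked fraction exceeds 40% are
   excluded. Masked pixels are removed from both numerator and denominator
   by default (masked large-vessel area is not capillary bed);
   `cd_denominator="total"` restores a raw-total denominator.
8. **B-scan depth profiles** (`density_bscan`). A-lines are shifted so the
   RPE is a constant plane; depths are then measured from the local ILM
   (bin 0 = [0, 6) µm). Large vessels are masked per B-scan with a 20 ×
   20-px Gaussian window. The masking threshold is not stated for the
   B-scan procedure; it defaults to 0.3 with a 3-px guard dilation, because
   the 0.4 contour of the smoothed image sits inside the vessel near its
   top corners — exactly the voxels that survive the strict
   projection-removal rule — and an escaping vessel top shows up as a
   spurious shallow flow peak. Flow voxels are counted per 6-µm depth bin
   over a 0.3 × 0.3-mm sample (rather than 40-B-scan blocks; the coverage
   is equivalent and the bookkeeping simpler), CD = 100 × flow voxels /
   unmasked voxels per bin.
9. **Peaks and interplexus distances**. Plexus peaks are plateau-aware
   local maxima of the binned profile, filtered at a minimal CD of 0.05%,
   then selected greedily highest-first under a 9-µm minimal separation
   (two closer plexuses merge into the higher peak; equal heights keep the
   shallower). The greedy selection is verified in tests against an
   exhaustive subset search (the lexicographic objective a highest-first
   peak finder optimizes) and against scipy's distance-constrained
   selection. Three peaks are labelled SVP/ICP/DCP by depth, two SVP/DCP.
   The IPD is the depth difference between labelled peaks, so
   SVP–DCP = SVP–ICP + ICP–DCP whenever three peaks exist.

## Phantom generator

The phantom emulates a healthy posterior pole as seen by a 100-kHz
swept-source OCTA device: 3 × 3-mm cubes of 300 × 300 A-scans (10 µm
transverse pitch) sampled at 2 µm axially (finer than the 6-µm analysis
bin, so depth binning is a real operation).

**Geometry.** Retinal thickness follows a radial model with a foveal pit
(120 µm deep, σ = 0.35 mm), a parafoveal maximum (320 µm) and a smooth
decline to 160 µm by the far periphery; the RPE is a (optionally tilted)
plane and inner interfaces sit at fixed thickness fractions.

**Truth functions.** Per retinal sector (temporal/nasal/superior/inferior),
capillary density anchors at 1/2/4/8/10 mm default to the published
healthy-cohort means, and plexus depth anchors put the plexuses at
67/115/157 µm below the ILM at 1 mm, converging peripherally; the SVP–DCP
spacing is 55 µm throughout 9–11 mm. Anchors are interpolated with
shape-preserving PCHIP (monotone between consecutive anchors) and clamped
beyond the end anchors. The ICP density is additionally tapered to 0 at
`icp_extinction_mm` (default 8.5 mm temporal/superior/inferior, 9.5 nasal,
taper width 1.5 mm); the un-tapered table interpolation remains available
(`apply_extinction=False`) because the published table still reports a
residual ~0.4% ICP CD at 10 mm where no distinct plexus peak is
detectable. All densities are forced to 0 within a 250-µm foveal avascular
zone (FAZ measurement itself is out of scope; the radius keeps montages
realistic). Cohorts are drawn by jittering each density anchor with its
published between-subject SD.

**Rendering.** Capillaries are rasterized on a *global* retinal pixel grid
in 0.25-mm tiles whose RNG is keyed on (seed, plexus, tile index): volumes
that overlap on the retina therefore contain the same vasculature, which is
what makes registration against generator-recorded offsets meaningful.
SVP/ICP capillaries are meandering random-walk segments of 80–220 µm
(intercapillary-segment scale); DCP capillaries are closed elliptical loops
(50–120 µm), its anastomotic lobular organisation. Strokes start on
still-unmarked pixels, and after stroke rasterization the realized count is
made exact in every 5-px (0.05-mm) subcell by largest-remainder targets
with random trims/top-ups — capillary beds are close to space-filling, and
this keeps the realized density within sampling error of truth at the
0.1 × 0.8-mm window scale (recovery RMSE ≈ 1 pp in tests). Each capillary
occupies one axial voxel at the plexus depth plus a per-segment jitter of
±4 µm (plexus thickness).

**Amplitudes and artifacts.** Flow amplitudes are drawn from disjoint bands
increasing with depth — SVP 0.40–0.52, ICP 0.58–0.70, DCP 0.76–0.88, large
vessels 1.0 — and every voxel casts a projection tail of 0.6 × its
amplitude onto all deeper voxels of its A-line. The increasing bands are a
deliberate stylization: under the strict exceeds-all-shallower projection
rule, transversally independent plexus patterns with i.i.d. amplitudes
would lose a large fraction of true deep flow (a deep voxel under one
shallower capillary survives with probability ≤ 1/2), which real
projection-resolved OCTA does not exhibit; ordered bands reproduce the
realistic outcome (tails removed, in-situ deep flow preserved) within the
strict rule. They also keep the smoothed capillary field far below the 0.4
vessel-mask threshold. Large vessels (default two per axis, 60-µm calibre,
arcade-like sinusoids offset ~0.75 mm from the foveal axes) exist only
within the SVP slab. Noise is additive uniform speckle on [0, 0.05] plus
salt impulses at rate 1e-4 with amplitudes in [0.05, 0.10] — isolated
decorrelation sparkle that a correct binarizer must reject; salt takes the
max with existing flow, never replacing it. The structural grid encodes a
layer-reflectivity staircase (dim vitreous, mid-bright inner retina, dark
ONL, bright RPE band) with its own speckle.

## What the phantom does and does not emulate

It reproduces the features the measurement chain is sensitive to: plexus
depth/density gradients with eccentricity and sector, ICP extinction,
slab-boundary geometry, large-vessel masking and projection artifacts,
speckle and impulse noise, montage overlap. It does not simulate
haemodynamics or flow speed, eye-motion artifacts, OMAGc decorrelation from
raw fringes, pathology, or the optic nerve head's vessel anatomy (the ONH
is handled as a geometric exclusion only). Passing tests therefore
demonstrate that the *analysis chain* is correct and unbiased under
realistic geometry and noise — not that it would be robust to motion or
media-opacity artifacts in clinical scans.

## Problem sizes and runtime choices

Single-volume experiments (peak recovery) use full 3 × 3-mm, 300 × 300 ×
224-voxel volumes. Cohort-scale experiments use position-anchored patch
volumes (0.5 × 0.5 mm) centred at each probed eccentricity for the B-scan
analysis — the procedure only reads a 0.3 × 0.3-mm column, and the
generator is anchored to absolute retinal position, so the measurement is
identical — and shortened bands of 1.5-mm volumes for C-scan recovery
tests. The full 22-mm, 10-subject, two-band pipeline is the `RunConfig`
default for `plexuscan run`.

## Numerical choices and degenerate inputs

* Threshold ties: a value exactly at the binarization or vessel-mask
  threshold is not flow / not vessel (strict `>`); a peak exactly at the
  0.05% floor is kept (`>=`, the stated minimum); a window masked at
  exactly 40% is kept (exclusion requires `> 0.40`).
* Peak ties within 9 µm at equal height keep the shallower peak.
* Zone boundaries belong to the outer zone (half-open intervals).
* Zero-thickness slab pixels are flagged invalid and excluded downstream;
  an all-zero structural grid or missing RPE in > 5% of A-lines raises a
  segmentation error; registration with no correlation peak above 0.2
  raises a registration error; a missing seed is an error (phantoms must be
  reproducible, and the same seed is bit-identical).
* Integer-voxel RPE alignment: depths are referenced to the post-alignment
  ILM, so alignment never biases ILM-referenced depths; recovered peak
  depths are accurate to one 6-µm bin (bin-phase straddling can move a
  peak by one bin, which is the stated tolerance of the recovery tests).

## Known limitations

* The strict projection-removal rule keeps only the first axial maximum of
  any flow structure; multi-voxel-thick vessels survive as their top
  surface. Real projection-resolved algorithms use normalized comparisons;
  the strict rule is the simplest member of that family and the phantom's
  amplitude ordering is what makes it behave like the realistic ones.
* Sector-dependent truth changes discontinuously across the ±45° diagonals;
  band analyses sample along the axes where this has no effect.
* The device's slab-boundary manual adjustment ("best identification of
  each plexus") has no published criterion and is not modelled; slabs are
  fixed relational definitions.
* `table_summary` uses the sample SD across subjects (0 for a single
  subject); the published table's SD convention is not stated.
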
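# Methods

## Scope and model

`fimid` measures, per muscle fiber, the mean cross-sectional area (CSA) of
its myofibrils and extrapolates the number of myofibrils per fiber. The
underlying model of a fiber cross-section is a planar partition: the fiber
disc is tiled by myofibril domains separated by a thin intermyofibrillar
compartment (sarcoplasmic reticulum and mitochondria). Two identities
follow and are enforced exactly in the outputs:

    occupied_area + intermyofibrillar_area = fiber_CSA
    myofibril_count = occupied_area / mean_myofibril_CSA

The count is an extrapolation from a sample of *measurable* myofibrils to
the whole fiber; it assumes the accepted objects are representative in
area of all myofibrils in the fiber (see Limitations).

## Measurement chain

1. **Deconvolution (optional, default on).** Richardson–Lucy with a
   Gaussian PSF (`psf_sigma_px`, default 1.0 px; 15 iterations), applied
   plane-wise. Implemented as a short multiplicative-update loop over
   `scipy.ndimage.gaussian_filter` with reflective boundaries, so a
   uniform image is a fixed point and total intensity is conserved to
   well under 1%. This is a generic stand-in for the proprietary
   deconvolution of the acquisition instrument; already-deconvolved
   images can be fed in with `deconvolve: false`.
2. **Focus selection.** The z-plane maximizing normalized variance
   (var/mean²) of the boundary channel; ties break to the lowest index.
   The metric name is recorded in the run manifest.
3. **Channel merge.** Per-pixel sum clipped at the bit-depth ceiling
   (ImageJ "Sum Slices" semantics). Merging autofluorescence into the
   SERCA channel completes the outline of myofibrils that are flanked by
   mitochondria; it is the default for mouse-style analysis
   (`merge_auto`), while human-style analysis runs on the single SERCA
   channel.
4. **Fiber segmentation.** Otsu threshold of the dystrophin outline,
   morphological closing, hole filling, then erosion by the estimated
   outline half-thickness (mean medial-axis distance), so the mask edge
   tracks the ring centerline and fiber CSA matches a centerline trace
   (within ~2% on synthetic discs). Manual traces can be supplied as
   label-image TIFFs instead.
5. **Fiber typing.** Score = fraction of fiber pixels whose
   autofluorescence exceeds `puncta_threshold` (default 1000 on the
   16-bit scale, above the faint boundary decoration present in all
   fibers). `Ox` if score ≥ cutoff (default 0.05, ties to Ox), else
   `Gly`; an Otsu-based automatic cutoff is available once ≥10 fibers
   are scored. Human samples are typed by which SERCA isoform was
   imaged, passed as configuration, not computed.
6. **Boundary binarization.** Adaptive local threshold: positive iff
   intensity > local mean + `sensitivity` × local SD in a `window_px`
   sliding window (31 px, sensitivity 0.5), with border-clipped windows
   and the convention that zero-contrast windows yield no signal (a
   uniform image gives an empty mask).
7. **Candidate detection.** 8-connected components of non-boundary
   pixels inside the fiber mask. Components touching the fiber border or
   image edge are discarded as truncated; "touching" is edge contact
   (4-adjacency) — a pixel merely diagonal to the outside is still fully
   delimited within the fiber.
8. **Enclosure.** For each candidate, the fraction of its
   outer-perimeter pixels (object pixels with a non-object 8-neighbor)
   having boundary signal within Chebyshev distance `reach_px` (2 px).
   This perimeter-pixel definition is a declared choice; the original
   method's internal definition is not published.
9. **Filtering.** Acceptance requires enclosure **> 0.90** (strict,
   ">90% enclosed"), aspect ratio of the best-fit ellipse **≤ 2.5**
   (inclusive at the published "approximately 2.5:1" maximum), solidity
   ≥ 0.90, and area within 0.1–20 µm². Rejection reasons are assigned by
   the first failing rule in the fixed order size → enclosure → aspect →
   shape, making filter-rate decompositions deterministic. The solidity
   floor is set at 0.90 rather than a looser 0.85 because two domains
   fused through a boundary gap have solidity ≈ 0.86 (two hexagons
   sharing an edge) and would otherwise pass, inflating the mean CSA;
   single convex domains sit at ≈ 0.95+.
10. **Quantification.** Mean myofibril CSA over accepted objects;
    intermyofibrillar area = boundary-positive pixels inside the fiber ×
    pixel area; count per the model identities. A one-step
    re-subtraction (`inter ← csa − (csa − inter)`) makes the area
    identity hold exactly in floating point. Fibers with zero accepted
    objects are flagged `unquantifiable`, never dropped.

## Synthetic data generator

The generator emulates the structures the measurement relies on, with
exact ground truth:

* **Geometry.** A disc of radius `fiber_radius_um` (default 10 µm,
  CSA ≈ 314 µm²) tessellated into `n_myofibrils` (default 200) convex
  domains by a Lloyd-relaxed Voronoi partition (3 iterations). True
  myofibril polygons are the cells shrunk by half the boundary width
  (0.2 µm), giving interior areas ≈ 1.1 µm² at defaults — inside the
  0.2–3 µm² range observed for myofibril cross-sections. The true
  intermyofibrillar area is the exact complement, so area conservation
  holds by construction. The default fiber is smaller than a real mouse
  fiber (~2000 µm²) to keep rasters desk-sized; what matters for the
  measurement — domain size in µm² relative to pixel size (0.1 µm/px) and
  ridge width — is at the biological scale.
* **Boundary gaps and puncta.** `gap_fraction` (default 0.10) of the
  total boundary length is deleted as `puncta_per_fiber` (default 40)
  contiguous segments — the sites where mitochondria displace the
  reticulum. Oxidative fibers get bright autofluorescent disks
  (radius 0.45 µm) centered on the gaps; all fibers get a faint
  autofluorescent copy of the full boundary. Rasterization is
  distance-based: a pixel is ridge iff its center lies within
  half the ridge width of the boundary network.
* **Optics and noise.** Per-plane Gaussian blur growing by
  `defocus_step_px` (1 px) per plane away from the middle (in-focus)
  plane of `n_planes` (5); Poisson shot noise scaled by `noise_gain`
  (2.0) plus Gaussian read noise (SD 50) on a 16-bit scale. Intensity
  amplitudes (boundary 3000, faint autofluorescence 300, puncta 3000,
  outline 3000 over background 100) are free parameters recorded in the
  spec JSON written by `fimid simulate`.
* **Cohorts.** `simulate_cohort` jitters fiber radius and domain count
  across fibers (oxidative fibers drawn smaller, as observed for
  mitochondria-rich fibers) so per-fiber mean CSA spans ~0.5–2.5 µm²,
  which is what makes estimated-vs-true correlation informative.

What a green synthetic test does *not* establish: robustness to
sectioning artifacts, uneven staining, oblique sectioning, out-of-plane
structure, or fiber-packing geometries unlike relaxed Voronoi tiles. The
generator has no physically rigorous optical model.

## Numerical choices

* Coordinates are (row, col), 0-based, pixel centers at integers; areas
  in µm² via `pixel_size_um²`.
* Bilinear resampling uses half-pixel-aligned centers with edge
  clamping; the optional 6144×6144 resize of the original protocol is
  unnecessary here because everything is calibrated in µm.
* Focus ties, classification ties (score = cutoff → Ox), and rejection
  ordering are all fixed so outputs are deterministic; identical config
  and inputs give byte-identical CSVs.
* Degenerate inputs: blank outline images yield no fibers; uniform
  boundary images yield empty masks; candidates with zero minor axis get
  infinite aspect ratio and are filtered by size or aspect.

## Validation behavior and known limitations

On a 20-fiber default-noise cohort the pipeline recovers cohort mean
myofibril CSA and total count to within ~1–5% and correlates with
per-fiber truth at r ≈ 0.99 (see `scripts/acceptance.py` output).
Individual fibers can deviate by up to ~±15%: the >90%-enclosure rule
preferentially rejects domains adjacent to boundary gaps, and since gaps
land on long edges more often, the accepted sample skews slightly small
in non-oxidative fibers where the faint autofluorescence cannot complete
the outline. This size-selection bias is a property of the enclosure
criterion itself (shared with the original method, whose manual raters
applied the same rule), not of the implementation. Intermyofibrillar
area is correspondingly under-measured by roughly the gap fraction in
Gly fibers. Mouse-style merged analysis removes both effects for Ox
fibers, which is precisely why the merge step exists.
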
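# Methods

## Scope and model of the data

`t3tomo` reconstructs a whole tumor from serial, optically cleared
macrosections (thick vibratome slabs, nominally 400 µm) imaged as
multi-channel confocal z-stacks, and quantifies the spatial organisation of
five immunofluorescence markers: a tumor marker (Her2), an immune-checkpoint
ligand (PD-L1), endothelium (CD31), leukocytes (CD45) and proliferation
(Ki-67).  The names are labels only — every stage treats channels
generically.

The voxel grid is anisotropic: the default spacing is 6.25 µm axially and
1.78 µm laterally, matching a 10x confocal survey scan.  All geometric
parameters (radii, distances, bin widths, PSF widths) are given in
micrometres and converted per axis internally; distances in outputs are
always physical, never voxel counts.

## Pipeline stages

**Tile stitching.**  Pairwise offsets between grid-adjacent 3D tiles are
estimated by phase correlation on a reference image (default: sum of all
channels).  The cyclic ambiguity of the correlation peak is resolved by
scoring every wrap candidate with normalized cross-correlation (NCC) in the
implied overlap, followed by a ±1-voxel hill climb on that score (with
overlaps of ~10% of the tile, the raw phase peak can be biased by a voxel).
Pairs scoring below 0.3 NCC fall back to the nominal grid offset — phase
correlation is meaningless on nearly empty tiles, and the stage prior is the
honest substitute.  Global positions solve a least-squares problem on the
pairwise offset graph anchored at the first tile; positions are rounded to
integers by default so the default path never resamples.  Fusion blends
overlaps with a separable linear distance-to-edge ramp, which passes equal
values through unchanged.

**Depth normalization.**  Per channel, the mean intensity of each optical
slice's foreground is rescaled to the foreground mean of the whole slab,
with the gain clamped to [1/3, 3] (the upper cap follows the established 3x
limit for this correction; the symmetric lower clamp is our addition,
flagged in the audit trail).  Foreground is defined by one Otsu threshold
per channel computed over the whole stack: a slice-wise Otsu would redefine
"foreground" from slice to slice on sparse channels (background on empty
slices, objects on occupied ones), which makes the gain series meaningless.
Slices with fewer than 50 foreground voxels keep unit gain and are flagged.
When several slabs are reconstructed together the pipeline passes a shared
target (the mean of the per-slab foreground means) so all sections land on
one intensity scale; without this, any global threshold on the fused volume
splits between sections instead of between background and signal.  The
cut-face slices of interior junctions are excluded from their own gain
computation and inherit the gain of the nearest interior slice: their
foreground mean is depressed by sectioning loss, and re-amplifying it here
would double the signal once the fusion stage sums the two touching faces
— the summation, not the gain, is what restores the cut plane.

**Serial-section registration and fusion.**  Only the touching faces of
adjoining slabs share structure, so registration uses the single boundary
slice of each (configurable to a deeper MIP): translation by phase
correlation, rotation by a coarse (1°) then fine (0.1°) search over ±10°
maximizing NCC.  Both images are gradient-magnitude filtered first; the raw
boundary images are dominated by the broad smooth tumor body, whose NCC is
nearly flat in rotation (measured Δ≈5·10⁻⁴ over ±1°), while edges of the
rim, vessels and cells carry the rotation signal.  Scores below 0.2 return
the identity with a warning.  Fusion chains transforms cumulatively into the
first section's frame, concatenates the slabs and closes each cut by
replacing the two touching boundary slices with one voxelwise-summed slice,
clipped at the intensity type's maximum; the fused depth is therefore
`sum(depths) − (n − 1)`.  Background outside the stained tissue is then
cleared: a 3-class Otsu on the log of the smoothed reference separates dark
mountant / autofluorescent tissue / bright stain (a plain 2-class Otsu
deletes the stroma), followed by per-slice closing (edge-padded — zero
padding would erode tissue touching the image border), hole filling and
largest-component selection.

**Segmentation.**  Tumor and ligand masks come from one global threshold
each (Otsu over nonzero voxels, or a manual cutoff applied as ≥; a manual
value outside the data type's representable range is an error).  Vessels are
extracted with a multiscale Hessian vesselness filter whose Gaussian
derivative widths are specified in micrometres and rescaled per axis, so
tubularity is judged by physical radius on the anisotropic grid; closed-form
symmetric-3×3 eigenvalues keep this fast.  Hysteresis thresholding (7% / 25%
of the vesselness maximum), minimum-volume filtering and connected-component
labelling follow; per-label radii are estimated from the anisotropic
distance transform.  Membrane-labelled cells are detected either by a
trainable random-forest pixel classifier on a multiscale feature stack
(fixed seed, recorded in the mask metadata) or, by default, by a
parameter-free fallback: light smoothing, a per-slice robust background
threshold (median + 8·1.4826·MAD of the nonzero voxels — per-slice because
depth gains rescale whole slices; robust statistics because membrane signal
occupies well under 1% of voxels and any histogram-partition threshold
collapses into the background mode), then a hollowness filter that keeps
only components with an enclosed dark interior.  Hollowness is scored
slice-wise on the component re-thresholded at half its own peak (at the
detection threshold the blurred halo of a shell seals its interior), and
touching cells are split by watershed seeded with connected
distance-transform cores (point maxima oversplit: the anisotropic grid
quantizes a cell's distance plateau into several peaks).  The tumor outline
is the closed, per-slice hole-filled, minimum-volume-filtered tumor mask
minus its 6-connected erosion.

**Quantification.**  Double positivity is reported voxel-wise
(|A∧B|/|A|; the default, parameter-free) and object-wise (components of A
counted positive when ≥50% of their voxels lie in B).  Vessel ligand
positivity uses a dilated-surface test (in-plane dilation by 2 voxels,
≥10% shell overlap) because perivascular ligand sits just outside the
endothelium; fractions are reported overall and per region.  Intensity
correlation follows the product-of-differences-from-the-mean construction:
PDM_i = (A_i − Ā)(B_i − B̄) over an analysis mask, with Pearson r (flagged
undefined for zero-variance channels) and the intensity correlation
quotient ICQ = (fraction of positive-PDM voxels) − ½ ∈ [−0.5, 0.5].
Distance profiling applies an anisotropic Euclidean distance transform to
the outline; each cell centroid takes the distance of its containing voxel,
cells outside the tumor are binned separately as stromal, and the histogram
uses 25 µm bins (≈4 axial steps).  The core/periphery partition labels tumor
voxels within 80 µm of the outline as periphery, the rest as core.

## The phantom

The generator renders the structures the pipeline exists to measure, with
complete ground truth: an ellipsoidal tumor with a ligand-positive surface
rim whose thickness is solved so a target fraction (default 0.43) of tumor
voxels is ligand-positive including perivascular contributions; a branching
random-walk vessel tree with larger, fully ligand-sheathed vessels confined
to the core and smaller bare vessels confined to the band between rim and
core (a peripheral vessel inside the rim would be genuinely ligand-positive
and falsify its own truth flag); 150 membrane-labelled cells rendered as
6–9 µm hollow shells, 70% clustered just outside the tumor margin and the
rest placed inside with an exponential (50 µm) depth profile, plus 30 filled
distractor blobs for the hollowness filter to reject; and proliferation
puncta.  Signal is blurred with a Gaussian PSF of (2.0, 1.5, 1.5) µm in
(z, y, x) — the pipeline ingests deconvolved stacks, so the phantom models
post-deconvolution resolution; with a broader axial PSF the polar caps of a
9 µm shell would bleed ~22% of their amplitude into the interior one
6.25 µm slice away and no method could see rings at this sampling.  Each
slab attenuates per optical slice as exp(−z·Δz/τ) with τ = 400 µm, keeping
the required gain inside the 3x cap.  Slabs share one boundary slice whose
signal is halved in each copy, so boundary summation during fusion
approximately restores it; sections 2+ receive rigid perturbations of up to
±6 voxels and ±3°, and each slab is cut into a 2×2 grid of tiles with 10%
overlap and ±2 voxel jitter.  Noise is Poisson (0.8 photons per intensity
unit) plus Gaussian read noise (σ=2), applied independently per tile.

The reference condition is 3 slabs × 48 slices × 256×256 voxels (five
channels, ≈46 M voxel values), chosen so the full generate-and-analyze cycle
runs in about two minutes; the same generator scales to larger fields by
changing `shape` and the tile grid.  What the phantom does **not** emulate:
refractive-index artefacts and clearing gradients, depth-dependent PSF
broadening, nuclear texture, autofluorescence structure, elastic tissue
deformation between sections, and stitching illumination fields.  Passing
recovery tests therefore demonstrates the correctness of the computational
chain under the stated noise and misalignment model, not robustness to
every optical artefact of real cleared-tissue data.

## Numerical choices and degenerate inputs

Intensities are processed as float32 and cast back to the input integer
type only on write (boundary summation and gain multiplication overflow
8-bit ranges).  Otsu thresholds that feed a ``>=`` comparison are computed
with edge semantics (the upper edge of the winning background bin): a
bin-centre threshold puts any value sharing that bin — such as an exact
background level — on the wrong side of the cut, which can flip entire
slices into "foreground".  Rotation resampling uses linear interpolation for
intensities and nearest-neighbour for labels.  Subpixel tile offsets are
rounded by default; the flag `subpixel=True` enables fractional positions.
Otsu on an empty or constant image is treated as "no foreground" rather
than an error wherever a slice-level statistic feeds a gain or mask; empty
tissue masks, empty tumor masks and zero-variance PDM channels raise or
flag explicitly.  All stochastic components (phantom, random forest) are
seeded; two runs with the same configuration produce byte-identical CSVs.

## Known limitations

Rigid in-plane registration only — no elastic deformation correction.
Vessel components may merge where vessels touch (counts are per connected
component, so region positivity fractions are robust to merging but the
absolute vessel count underestimates the generated number).  The fallback
membrane detector assumes shells are resolvable in-plane; heavily clumped
cells beyond what the watershed separates are counted as one.  Region
assignment of a vessel is by majority voxel, so a vessel straddling the
core boundary contributes wholly to one side.
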
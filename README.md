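# t3tomo

Whole-tumor 3D multiplexed immunofluorescence reconstruction and spatial
quantification.

Thick (400 µm) optically cleared tumor macrosections can be imaged through
their full depth on a confocal microscope, and a whole tumor can then be
reassembled computationally from a handful of such slabs.  `t3tomo`
implements that computational chain: it stitches overlapping 3D tile
mosaics, compensates depth-dependent intensity loss, rigidly registers and
fuses the serial slabs (closing the cut gaps by boundary-slice summation),
clears background outside the stained tissue, segments five
tumor-microenvironment markers, and quantifies their spatial organisation —
double-positive fractions, intensity-correlation (PDM) maps, per-vessel
ligand positivity by region, and distance-to-margin profiles of immune
cells.  A seeded phantom generator produces synthetic macrosections with
complete ground truth, so the whole pipeline is testable without microscope
data.

## The measurements

For binary marker masks $A$ (e.g. Her2⁺ tumor) and $B$ (e.g. PD-L1⁺), the
double-positive fraction is $|A \cap B| / |A|$.  Intensity correlation of
two channels over a mask of $N$ voxels uses the product of the differences
from the mean,

$$\mathrm{PDM}_i = (A_i - \bar A)(B_i - \bar B),$$

with Pearson $r = \sum_i \mathrm{PDM}_i / \sqrt{\sum_i (A_i-\bar A)^2
\sum_i (B_i-\bar B)^2}$ and the intensity correlation quotient
$\mathrm{ICQ} = \#\{\mathrm{PDM}_i > 0\}/N - \tfrac12 \in [-0.5, 0.5]$.
Immune-cell positions are profiled by the anisotropic Euclidean distance
transform of the tumor outline (voxel spacing 6.25 µm axially, 1.78 µm
laterally by default), with cells outside the tumor reported separately as
stromal.  Per-slice depth gains are capped at 3x.  All distances are in
micrometres.

## Worked example

```python
from t3tomo.phantom import PhantomSpec, generate_phantom
from t3tomo.pipeline import analyze_sections

sections, truth = generate_phantom(PhantomSpec(seed=1))
result = analyze_sections(sections)

pos = result.record("her2+pdl1+")
print(f"double-positive fraction: {pos.fraction:.3f} (truth {truth.dp_voxel_fraction:.3f})")
print(f"membrane cells: {result.profile.total_count} (truth {truth.immune_count})")
print(f"median margin distance: {result.profile.median_um:.1f} um "
      f"(truth {truth.median_inside_distance_um:.1f})")
print(f"PD-L1+ vessel fraction, core: "
      f"{result.record('cd31+ligand+_vessels', region='core').fraction:.2f}")
```

prints (seed 1):

```
double-positive fraction: 0.429 (truth 0.430)
membrane cells: 160 (truth 150)
median margin distance: 32.7 um (truth 33.1)
PD-L1+ vessel fraction, core: 1.00
```

Here 0.429 means 42.9% of tumor-marker-positive voxels are also
ligand-positive (the phantom is built with a 43% ligand-positive rim); the
cell count and median distance-to-margin show the membrane detector and the
anisotropic distance profiling recovering the generator's ground truth; the
core vessel fraction reflects that every core vessel carries a perivascular
ligand sheath in the phantom.

The `t3` command exposes the stages individually (`t3 phantom`, `t3 stitch`,
`t3 normalize`, `t3 register`, `t3 fuse`, `t3 clearbg`, `t3 segment`) and
`t3 run config.yaml` drives a full configured run with a provenance
manifest.

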
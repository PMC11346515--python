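# mitovol

Quantitative 3D morphometry of mitotic chromosomes from volume electron
microscopy, for people who segment serial block-face SEM stacks of
dividing cells and want numbers out the other end: per-chromosome
volume, surface area, axis length, width, centromere position and
identity; DNA packing densities; and the nucleosome concentration that
follows from them.

Serial block-face SEM images an entire mitotic cell as an aligned stack
with anisotropic voxels (here 25 × 25 × 60 nm after binning).  Because
the contrast of stained chromatin is strong, chromosomes can be
segmented by a global grayscale threshold, separated by
marker-controlled watershed on the distance transform, and measured as
voxel sets.  Pairing the measured geometry with known per-chromosome DNA
content *M* (Mb) then gives

- the linear packing ratio  k = Σ(MᵢLᵢ)/Σ(Lᵢ²)  (Mb/µm, fit through the
  origin; per chromatid k/2 for cohesed chromosomes),
- the volumetric density  ρ = M_total / V_total  (Mb/µm³),
- and, assuming a 195-bp nucleosome repeat (146 bp core + 49 bp linker),
  the nucleosome number density  n = ρ·10⁶/195  per µm³, the volume
  available per nucleosome  10⁹/n  nm³, and the molar concentration
  c = n·10¹⁵/N_A·10⁶  µM — near-millimolar for metaphase chromatin
  (89.2 Mb/µm³ → 4.57·10⁵ µm⁻³ → 2,186 nm³ → 760 µM).

Raw EM stacks are too large to ship, so the package includes a phantom
generator: tubular chromatids with spline centrelines, a Gaussian
centromeric constriction and hemispherical caps, rasterized with
realistic contrast and noise and accompanied by closed-form ground
truth.  Every measurement stage is validated against these phantoms
(volume to 2%, length to 5%, width to one voxel diagonal).

## Worked example

Two cohesed chromosomes — one chromosome-1-sized (248.4 Mb per
chromatid), one chromosome-19-sized (61.7 Mb) — are generated as a
phantom, segmented and measured end to end:

```python
import numpy as np
from mitovol import phantom, segment3d, morphometry
from mitovol import identity_density as idd

spec = phantom.complement_spec(
    [248.4, 61.7],              # Mb per chromatid
    names=["big", "small"],
    mb_per_um=66.0,             # cohesed linear packing ratio
    radius_nm=[498.0, 320.0],   # effective cohesed-chromosome radii
    constriction_factor=0.75,
    noise_sd=12.0,
    seed=0,
)
vol, _, truth = phantom.generate_phantom(spec)
labels, info = segment3d.segment(vol, segment3d.SegmentationConfig(bin_factors=(1, 1, 1)))
objects = morphometry.measure_all(labels)
for obj in objects:
    print(f"label {obj.label}: V={obj.volume:.2f} um3  L={obj.length:.2f} um  "
          f"width={obj.mean_width:.2f} um  class={obj.morphology_class}")

total_mb = 2 * (248.4 + 61.7)   # replicated sister-chromatid content
density = idd.volumetric_density(total_mb, sum(o.volume for o in objects))
report = idd.nucleosome_metrics(density)
print(f"DNA density      {density:.1f} Mb/um3")
print(f"nucleosomes      {report.nucleosomes_per_um3:.3g} per um3")
print(f"volume each      {report.volume_per_nucleosome_nm3:.0f} nm3 "
      f"({report.cube_side_nm:.1f} nm cube)")
print(f"concentration    {report.concentration_um:.0f} uM")
```

prints

```
label 1: V=6.06 um3  L=7.56 um  width=0.95 um  class=metacentric
label 2: V=0.71 um3  L=1.88 um  width=0.60 um  class=metacentric
DNA density      91.7 Mb/um3
nucleosomes      4.7e+05 per um3
volume each      2127 nm3 (12.9 nm cube)
concentration    781 uM
```

The measured lengths recover the configured 7.53 and 1.87 µm axes, the
7.5-µm chromosome is correctly called metacentric from its central
constriction, and the density chain lands in the near-millimolar range
expected for condensed chromatin (a two-chromosome complement sits a few
percent above the full-complement value because cap volume does not
average out over so few objects).

## Command line

The same stages are available as subcommands of `mitovol`:

```sh
mitovol phantom  --config phantom.yaml --out out/
mitovol segment  --in out/stack.tif --spacing 25,25,60 --bin 1,1,1 --out out/labels.tif
mitovol measure  --labels out/labels.tif --spacing 25,25,60 --out out/measurements.csv
mitovol identify --measurements out/measurements.csv --karyotype k.csv --out out/identified.csv
mitovol density  --measurements out/measurements.csv --karyotype k.csv --out out/report.json
mitovol nfr      --bed peaks.bed --genome-bp 1520000000
mitovol distances --landmarks landmarks.csv --out out/distances.csv
mitovol stage    --cells cells.csv --out out/stages.csv
mitovol run      --config run.yaml --out out/ --seed 0
```

`run` executes the whole pipeline and writes a manifest echoing every
parameter; identical configs and seeds give byte-identical outputs.

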
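# dardose

Small-scale ²²³Ra dosimetry of bone-metastasis biopsy sections from
quantitative digital autoradiography (DAR) and histology.

## The problem

α-particle radiopharmaceuticals such as [²²³Ra]RaCl₂ deposit megaelectron-
volt energies over path lengths of a few cell diameters. At that scale the
absorbed dose in a bone metastasis is anything but uniform: the
bone-seeking ion concentrates at the bone–tissue interface, leaving
adjacent marrow and tumor tissue orders of magnitude apart in dose. A
whole-sample activity measurement erases exactly the structure that
determines the biology. This package implements the measurement chain that
exposes it, for biopsy sections imaged by storage-phosphor autoradiography
alongside H&E histology:

1. **Segmentation** — CIE-L\*a\*b\* moment features on image subtiles,
   k-means for the background/soft-tissue split, and a pluggable trained
   per-pixel classifier for bone.
2. **Registration** — downsampling to DAR pitch, coarse similarity
   estimate from foreground moments, refinement by mutual-information
   maximization.
3. **Compartments** — bone core, soft-tissue core, and the bone–tissue
   interface extending 50 μm into each compartment, built at histology
   resolution and carried to the DAR grid.
4. **Quantification** — DLU → Bq calibration from co-imaged activity
   standards, decay correction to biopsy time.
5. **Dosimetry** — MIRD voxel formalism,

   D = Ã · Δ · φ / m,

   with cumulated activity Ã = A/λ (extrapolation to infinity, physical
   ²²³Ra decay only, daughters ²¹⁹Rn/²¹⁵Po/²¹¹Bi fixed in place),
   Δ = 4.23 × 10⁻¹² J/(Bq·s) from ICRP-107 chain α energies, φ = 1
   (local deposition), voxels of 43.2 × 43.2 × 8 μm at 1.92 g/cm³ (bone)
   or 1.03 g/cm³ (soft tissue and interface).
6. **Reporting** — per-compartment activity histograms, mean/max/SD doses,
   volumes above mean + 1/2 SD, bulk concentrations, correlations.

Patient sections cannot ship with a package, so a first-class **synthetic
phantom** generates biopsy sections with full ground truth — trabecular
geometry, H&E-like rendering, surface-seeking activity, storage-phosphor
image formation (PSF, Poisson counting, linear gain), a known
inter-modality misalignment, and a standards strip — making every stage of
the chain quantitatively testable.

## Worked example

`examples/04_voxel_dosimetry.py` runs the full chain on one synthetic
section (seed 11) and prints:

```
Delta (chain mean alpha energy): 4.225e-12 J/(Bq*s)
calibration: floored 6985 sub-background voxels; detection limit 12.5 uBq/voxel

  compartment  n_voxels  mean_dose_gy  max_dose_gy  sd_dose_gy
    bone_core      1155          16.9        102.8        14.6
  tissue_core      3671          13.7        260.5        21.2
    interface      1109         104.4        513.0        52.2
whole_section      5935          31.3        513.0        45.4

interface mean dose, pipeline vs truth: 104.4 vs 115.3 Gy (-9.4%)
```

Reading this: the 50-μm interface band receives a mean absorbed dose ~6×
that of either core compartment — the localized-dose picture that
motivates voxel-level dosimetry — and the whole measurement chain
(segmentation, registration, calibration, dosimetry) recovers the mean
interface dose computed directly from the known true activity to within
10%. The other examples exercise one capability each: phantom generation
(`01`), segmentation (`02`, bone Dice 0.999 on a held-out section), and
registration (`03`, residual 0.06 DAR px ≈ 2.4 μm).

A thin CLI mirrors the pipeline stages:

```sh
dardose run-all --seed 3 --outdir out/          # everything on one phantom
dardose simulate --seed 3 --outdir out/         # or stage by stage:
dardose segment ... ; dardose register ... ; dardose quantify ...
```

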
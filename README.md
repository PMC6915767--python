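# arraytomo

Quantification of synapses and synaptic pathology from array-tomography
image stacks.

Array tomography embeds brain tissue in resin, cuts it into ribbons of
ultrathin (70 nm) serial sections, immunostains each ribbon for synaptic
and pathological proteins, and images the same field on every section.
Re-stacking the sections computationally yields a 3D volume in which
individual presynaptic terminals (synaptophysin) and postsynaptic
densities (PSD95) can be resolved and counted — the measurement behind
questions such as *how much synapse loss occurs near amyloid plaques,
and what fraction of synapses contain tau or oligomeric Aβ?*

`arraytomo` implements the full analysis chain for this kind of study:

1. **Registration** — per-section rigid (translation) alignment by phase
   correlation, chained section-to-section and refined against the
   reference section; integer misalignments are recovered losslessly.
2. **Segmentation** — each channel is binarised per section with a
   *union* of automatic thresholding algorithms (Otsu + Triangle by
   default) so that both bright and dim puncta are captured without
   manual tuning.
3. **3D reconstruction** — 2D footprints are linked across consecutive
   sections (≥ 1 px overlap in xy) into 3D puncta; objects present in
   only a single section are removed as noise. Densities are reported
   per µm³ with the anisotropic voxel calibration (e.g. 0.1 × 0.1 ×
   0.07 µm) handled as metadata, never by resampling.
4. **Plaque proximity** — fibrillar plaques are detected on the
   Thioflavin-S channel; a physical edge-distance field classifies each
   synapse or ROI as *near* (< 20 µm from a plaque edge) or *far*. The
   oligomeric halo is the pan-Aβ mask minus the fibrillar core, and
   burden metrics (percent area, plaque count, mean size) follow the
   standard histology definitions. Region volumes are estimated from
   sparsely sampled section areas (Σ area × spacing × hemisphere factor).
5. **Colocalization** — a synaptic punctum is positive for tau or Aβ
   when ≥ 50 % of its voxel volume overlaps that marker's binary mask;
   markers are scored independently and "double positive" is their
   conjunction.
6. **Statistics** — every metric is first collapsed to one value per
   animal (the experimental unit), then groups are compared with
   Mann-Whitney U tests (exact by full enumeration when the combined
   sample is ≤ 12 without ties) and genotype ratios with a chi-square
   goodness-of-fit test.
7. **Open field** — trajectory-based locomotion metrics: total distance
   and the inner-20×20 cm / outer-zone split of distance and occupancy
   used as a hyperactivity/anxiety readout.

Because raw microscope data is not redistributable at this scale, the
package ships a first-class synthetic generator
(`arraytomo.synthetic`) that renders calibrated multi-channel serial
section stacks with known ground truth — puncta, single-section specks,
plaques with halos, textured nuclei, per-section misalignments — so
every stage is tested against exact truth.

## Worked example

```python
import numpy as np
from arraytomo import *
from arraytomo.synthetic import SynthParams

params = SynthParams(seed=1, field_size_px=(300, 300),
                     plaque_spec=[((6.0, 6.0), 3.0, 5.0)])
stack, truth = generate_stack(params)

transforms = estimate_shifts(stack)
aligned = apply_transforms(stack, transforms)
plaques = detect_plaques(aligned, pan_channel="abeta")

puncta = filter_single_section(link_3d(binarize_stack(aligned, "PSD95")))
density = punctum_density(puncta, stack.volume_um3)
tau_mask = binarize_stack(aligned, "tau")
near_far = [classify_near_far(plaques.distance_at(*p.centroid_um)) for p in puncta]
res = coloc_rates(puncta, {"tau": tau_mask}, [{"near_far": nf} for nf in near_far])
```

prints (via the obvious formatting):

```
sections aligned:    20 (max |shift| = 4 px)
plaques detected:    1, mean core area 28.3 um^2
PSD95 puncta:        1291 in 1260 um^3 -> density 1.025 per um^3 (truth 1.027)
tau-positive (far): 13/221 = 5.9%
tau-positive (near): 62/1070 = 5.8%
```

The 20 injected section shifts were recovered (the aligned stack is the
generator's pre-misalignment volume), the postsynaptic density estimate
(1.025/µm³) matches the generator's realised truth (1.027/µm³) within a
fraction of a percent, and the recovered tau-positive synapse fractions
in both plaque-distance strata sit near the generator's 5 % labelling
probability.

There is also a CLI for file-based runs — `arraytomo simulate`,
`register`, `segment`, `quantify`, `behavior`, `stats`, and `run-all`,
each driven by a YAML config and re-entrant from the previous stage's
files. `arraytomo run-all --config cfg.yaml --out out/ --seed 7`
simulates a cohort (groups × animals), analyses every stack, and writes
`puncta.csv`, `density.csv`, `coloc.csv`, `stats.csv` plus a manifest
with the config hash; reruns with the same config and seed are
byte-identical.

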
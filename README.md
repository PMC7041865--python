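# histoquant

Quantification of fluorescence tissue images for tumor viability and drug
uptake studies — the analysis layer between a slide scanner and a figure.

Built for experiments that compare matched *in vivo* tumors and *ex vivo*
tumor explants: sections are stained with DAPI plus a viability panel
(Ki67 for proliferation, cleaved caspase-3 for apoptosis, Beclin 1 for
autophagy), or imaged for uptake of a fluorophore / fluorophore-labeled
drug. The package answers, reproducibly: *how many cells are positive for
each marker, per condition* — and *how much signal did each tissue take up,
in viable vs necrotic regions*.

## What it does

- **Nucleus segmentation** by mathematical morphology: CLAHE contrast
  normalization → white top-hat background subtraction (structuring element
  sized by the theoretical nucleus radius) → distance-transform maxima for
  seeds, including touching nuclei → seeded watershed → artifact/cluster
  removal → Voronoi cell partition with a distance map.
- **Per-cell marker scoring**: stained channels normalized against a
  secondary-only control; a cell is positive when supra-threshold signal
  overlaps its nucleus (nuclear markers) or its perinuclear rim (cytosolic
  markers). Reports pool sections into percent-positive ± SEM with QC
  (≥ 5000 nuclei, ≥ 10 ROIs) and one-way ANOVA group comparison.
- **Whole-tissue uptake**: mean per-pixel fluorescence over a tissue ROI
  that excludes a ~10 µm edge border and fold artifacts; control tissue as
  a parallel baseline; viable/necrotic region comparison from provided
  masks; dose-titration tables with a monotonicity flag.
- **Reagent QC**: exact monoisotopic mass and [M+zH]^z+ m/z for a molecular
  formula; fluorophore:antibody degree of labeling from absorbance readings
  with the 1.1–3.3 acceptance band.
- **Synthetic scenes**: a ground-truthed generator for all of the above,
  so the whole pipeline is testable without microscope data.

## Worked example

```python
import histoquant as hq
from histoquant.pipeline import quantify_section
from histoquant.scene import default_viability_params

# a 512-px section with ~250 nuclei, 15% Ki67-positive, and its control
params  = default_viability_params(positive_fractions={"Ki67": 0.15}, rng_seed=1)
img, truth = hq.generate_tissue_scene(params)
control, _ = hq.generate_tissue_scene(
    default_viability_params(
        positive_fractions={"Ki67": 0.0, "CC-3": 0.0, "Beclin1": 0.0}, rng_seed=99
    )
)

nuclei, cells = hq.segment(img)
print("true nuclei:", truth.nucleus_label_map.n_nuclei, "| detected:", nuclei.n_nuclei)

calls  = quantify_section(img, control)
report = hq.summarize_viability({"control": [calls]})
row = report.row("control", "Ki67")
print(f"Ki67: {row['percent_positive']:.1f}% positive ({row['n_positive']}/{row['n_cells']})")
```

prints

```
true nuclei: 250 | detected: 228
Ki67: 16.2% positive (37/228)
```

228 of 250 ground-truth nuclei survive segmentation and cluster removal —
the generator renders 30% of nuclei touching a neighbour with area overlap
up to 40%, and the deepest-overlapping pairs are excluded rather than
miscounted. The recovered Ki67 fraction 16.2% sits near the generating
15%; at a single ~250-cell section the binomial SE alone is about 2.3
points, which is why real reports pool ≥ 5000 nuclei across sections.

The same operations are exposed as a CLI for shell pipelines:

```bash
histoquant simulate --config scene.yaml --seed 5 --out scene/
histoquant segment --image scene/ --out seg/
histoquant conjugate-qc mass --formula C47H60F2N10O12S --charge 2
histoquant quantify-intensity --image scene/ --viable-mask v.tif --necrotic-mask n.tif --out report.json
```

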
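# mtlseg

Hybrid surface/volume multi-template segmentation of the mesiotemporal
lobe: hippocampus (HP), amygdala (AM) and entorhinal cortex (EC).

Atrophy of these structures marks temporal-lobe epilepsy, Alzheimer's
disease and other conditions, and its quantification needs accurate
segmentation. Multi-template (multi-atlas) methods segment a subject by
selecting similar labelled templates from a library, aligning them, and
fusing their labels. Purely volumetric variants are robust but blur
boundaries; purely surface-based variants describe boundaries precisely but
degrade when template and subject are misaligned. `mtlseg` implements a
hybrid of the two, in three ideas:

1. **Hybrid template selection.** Templates are ranked by
   `O_total = O_volume + w_surface · O_surface`, where `O_volume` is a
   masked intensity cross-correlation (or normalized mutual information)
   and `O_surface ≤ 0` penalizes the deviation between the template's
   surface-sampled texture features and the features estimated on the test
   image along that surface. Features are 9 per vertex — normalized
   intensity, relative intensity (boundary contrast) and gradient
   magnitude, each over 3/5/7 mm spherical neighbourhoods split into inner
   and outer regions by the structure boundary.
2. **Boundary-weighted non-linear registration.** Each selected template is
   deformed to the test image by a control-lattice free-form model
   maximizing `O_vol,reg + w_surf,reg · O_surf,reg − λ·O_smooth`: masked
   intensity correlation plus the correlation of relative-intensity
   features along the deforming surface, optimized node-wise with
   derivative-free Nelder–Mead.
3. **Global-to-local weighted shape averaging.** The warped template
   surfaces (with shape-inherent vertex correspondence on a shared
   icosphere sampling) are fused by a weighted vertex average; weights are
   optimized globally on the simplex and then refined per region on nested
   icosphere levels (42 vertices at the coarsest level upward), maximizing
   the similarity between the weighted feature model and the features
   estimated along the averaged surface.

Because no imaging data ships with the package, a first-class synthetic
module generates phantom cohorts — template libraries and test subjects
with known ground truth, population shape variability, tissue contrast,
noise, and a patient subgroup with volumetric atrophy — on which the whole
pipeline is exercised and tested.

## Worked example

`examples/04_segment_subject.py` builds a 12-template phantom library,
segments one unseen subject, and prints the stage-wise Dice overlap with
the ground truth:

```
stage                    HP     AM     EC   mean
initial_subset        0.801  0.723  0.736  0.753
registration          0.942  0.957  0.818  0.906
restricted_subset     0.937  0.957  0.821  0.905
global_weighting      0.939  0.955  0.826  0.907
local_weighting       0.938  0.957  0.828  0.908

final label Dice vs ground truth: {'HP': 0.938, 'AM': 0.957, 'EC': 0.828, 'mean': 0.908}
global fusion weights: [0.195 0.202 0.185 0.182 0.236]
```

Reading the numbers: the unweighted average of the selected template
surfaces already overlaps the truth at Dice ≈ 0.75; the boundary-weighted
registration contributes the largest single gain; restriction and weighted
averaging refine the result further. EC ends lowest — it has the weakest
boundary contrast by design, mirroring its status as the hardest of the
three structures. The fusion weights show how the n_b warped templates were
mixed.

The other examples cover phantom generation (`01`), feature extraction
(`02`), template ranking including the exact self-match identity
`O_total = 1.0` (`03`), and atrophy detection with Cohen's d and z-score
flags (`05`).

## Command-line interface

A thin CLI wraps the library for shell use:

```bash
mtlseg simulate --out cohort/ --seed 7           # phantom cohort with truth
mtlseg build-library --images a.nii.gz --labels a_lab.nii.gz ... --out lib/
mtlseg segment --test x.nii.gz --library lib/ --out out/ \
       --n-a 6 --n-b 5 --similarity cc
mtlseg evaluate --pred out/segmentation.nii.gz --truth x_lab.nii.gz
mtlseg library-size-experiment --cohort cohort/ --fractions 1,0.5,0.25 \
       --repeats 3 --out report.json
```

Labels follow the codebook 0=background, 1=HP, 2=AM, 3=EC; images are
NIfTI-1, surfaces are Wavefront OBJ bundles with a JSON sidecar.

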
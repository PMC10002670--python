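# histoquant

Section-to-atlas registration, quality-control scoring and regional
stain-load quantification for serial histology, with the downstream
load × gene-expression statistics — implemented as a tested library plus CLI,
exercisable end-to-end on seeded synthetic data.

## What it does

- **`histoquant.atlas`** — labeled 3D atlas volumes (NIfTI or raw int32 +
  JSON sidecar), region ontologies (CSV/JSON trees), collapsing of the
  ontology onto a customized "intermediate hierarchy" (nearest selected
  ancestor-or-self; unmappable labels reported), hemisphere masks.
- **`histoquant.registration`** — oblique plane slicing through the atlas
  from nine-number anchorings `(o, u, v)` with pixel-center sampling and
  nearest-voxel lookup; nonlinear in-plane refinement from anchor-point
  pairs via a Delaunay-triangulated piecewise-linear displacement field
  (exact at anchors, zero at the untouched image frame), applied by backward
  nearest-neighbor warping; JSON registration-descriptor I/O.
- **`histoquant.qc`** — systematic sampling grids, marker bookkeeping,
  damage fraction per section (strict >30% exclusion rule), per-region
  accuracy (`accurate / (accurate + inaccurate)`, undefined when nothing is
  verifiable) and uncertainty (`uncertain / total`) scores, multi-rater
  mean ± SEM aggregation with undefined accuracies excluded.
- **`histoquant.quantify`** — per-region stained-pixel load (% of region
  area) with 8-connectivity object splitting (an object overlapping k
  regions contributes its exact pixel share to each and counts once per
  region), mask exclusion, pixel-sum pooling per brain after removal of
  damaged sections, and linear-vs-nonlinear load differences.
- **`histoquant.loadstats`** — expected-read-count gene filter (>10 counts
  in more than 50% of samples, both strict), Benjamini–Hochberg FDR, Pearson
  correlation of expression with load with and without age adjustment
  (within-age-group centering, df = n − g − 1), gene classification into
  age-dependent / age-independent / both / ns, two-factor (age + strain)
  Type-II ANOVA per region, and paired Wilcoxon signed-rank comparison of
  registration methods.
- **`histoquant.synth`** — deterministic seeded generators for every input
  shape with ground truth attached: nested-box atlases, sectioned brains
  whose objects have known size and location (true loads are exact by
  construction), simulated raters with known error rates, and expression
  matrices with known gene classes.

## CLI

```sh
histoquant simulate brain --seed 1 --out sim/          # synthetic dataset
histoquant slice --atlas sim/atlas.raw --registration sim/registration.json --out maps/
histoquant warp  --atlas sim/atlas.raw --registration sim/registration.json --out maps_nl/
histoquant quantify --seg-dir sim --atlas sim/atlas.raw \
    --registration sim/registration.json --hierarchy sim/hierarchy.txt --out load.tsv
histoquant qc accuracy --markers markers.tsv --out qc.tsv
histoquant qc damage --markers markers.tsv
histoquant integrate --loads meta.tsv --counts normalized.tsv --meta meta.tsv --out corr.tsv
```

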
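# smartscan

Event-driven **intelligent microscopy** without the microscope: a
self-contained framework for feedback acquisition, in which a fast,
low-resolution **primary scan** surveys a large sample area, image analysis
detects targets or live events, and a high-resolution **secondary scan** is
triggered only at the detected positions.

High-resolution fluorescence microscopy of wide sample regions produces
overwhelming data volumes, and for live samples the light dose and frame
budget are hard-limited — yet often only a tiny fraction of the field holds
the objects of interest: sparse mitotic cells, rare abnormal FISH genotypes,
singly occupied micropatterns, or transient nuclear-envelope-breakdown (NEB)
events. smartscan is aimed at microscopists and image-analysis developers who
want to prototype, test and debug such feedback-acquisition protocols
end-to-end on a fully deterministic **virtual microscope**, with the same
engine code that a hardware bridge would drive.

## What is in the box

| module | role |
| --- | --- |
| `smartscan.core` | stage/pixel geometry, target lists, dedup, focus-map interpolation, CSV persistence |
| `smartscan.imgops` | the primitive operators the workflows are built from: disk median filter, bright/dark outlier removal, clamped subtraction, global/non-zero thresholds, Laplacian-of-Gaussian (LoG) band-pass, prominence-based local minima, connected-particle analysis, max projection, tile assembly, review montage |
| `smartscan.detectors` | four registered target-detection workflows: `metaphase`, `fish`, `micropattern`, `mitosis_live` (plus a plug-in registry for custom ones) |
| `smartscan.simulator` | virtual microscope: renders multi-channel z-stack tiles of synthetic samples with exportable ground truth; can serve images through the text protocol and exchange folder |
| `smartscan.protocol` | CAM-dialect text messages, tile-filename convention, exchange-folder collection, offline replay |
| `smartscan.engine` | the four acquisition state machines (tiled/block × fixed/live), target review and capping, scan-plan arithmetic |
| `smartscan.cli` | `smartscan run / simulate / replay / detect / plan / fixtures` |

## The detection workflows

* **metaphase** — mitotic cells show increased DNA-stain fluorescence from
  chromatin condensation. Pipeline: median filter → bright-outlier removal →
  clamped subtraction (isolating small bright cores) → non-zero threshold →
  8-connected particles of area ≥ 12 px. Targets are particle centroids in
  stage coordinates.
* **fish** — nuclei are segmented from the DNA stain (Otsu, hole filling,
  watershed splitting), excluded on invalid size/shape, and classified by
  per-channel FISH spot counts (LoG blob extrema above a prominence) against
  user-defined signatures, e.g. `ch1 == 1, ch2 == 0, ch3 == 1`; the first
  matching signature labels the target, so several phenotypes can be
  collected in one experiment.
* **micropattern** — printed adhesive patterns are localized in their label
  channel; significant LoG intensity minima (nuclei) are counted inside each
  dilated pattern bounding box, and only boxes holding **exactly one**
  nucleus become targets.
* **mitosis_live** — from the 3-frame queue of tubulin-channel maps:
  clamped difference of the two newest frames → median filter → threshold →
  nucleus-like particles (area, circularity, contrast gates), each confirmed
  only if a nucleus (a significant LoG minimum of the previous frame, where
  the nucleus is still tubulin-dark) lies inside it. This captures NEB, when
  tubulin invades the formerly dark nuclear region at mitosis onset.

In live modes the engine is **blind** while acquiring the fixed-length
secondary time-lapse: no detection calls happen between the switch to
secondary and the switch back, and the frame queue is flushed afterwards.

## Worked example

Survey 200 asynchronously growing nuclei (2.5% of them condensed/mitotic at
3× intensity) as a 10×10 tiled map, detect the condensed ones and acquire
the 3 best at high resolution:

```yaml
# metaphase.yaml
mode: tiled_fixed
seed: 1
simulator: {kind: metaphase, seed: 1}
review: false
target_cap: 3
```

```text
$ smartscan run metaphase.yaml --out run_out
run finished: completed; 3 target(s) acquired; outputs in run_out

$ head -4 run_out/targets.csv
x_um,y_um,z_um,label,score,frame_index,block_index
389.285714,101.500000,0.000000,metaphase,67.07142857142857,0,
86.400000,108.600000,0.000000,metaphase,65.46666666666667,0,
232.500000,329.285714,0.000000,metaphase,65.14285714285714,0,
```

The detector found all 5 condensed nuclei (`"n_targets": 5` in
`run_out/log.jsonl`); the cap kept the 3 highest-scoring, and each was
acquired once with the secondary scan centered on it. The scan-plan
calculator shows what the survey saved: covering the same region at
secondary resolution would need 900 tiles × 3 channels × 65 z-slices,

```text
$ smartscan plan --tiles 900 --channels 3 --z 65
n_images: 175500
n_fov: 900
```

i.e. 175,500 images instead of the handful actually acquired. The same
arithmetic for a 144-block × 144-pattern micropattern chip (one 75-image
stack per pattern) gives 20,736 fields of view and 1,555,200 images —
whereas in practice only ~15% of patterns hold a single cell and get
acquired.

A recorded primary-scan folder can be re-analyzed offline with identical
behaviour:

```bash
smartscan simulate metaphase out_folder --seed 1   # record + ground truth
smartscan replay out_folder metaphase.yaml --out replay_out
```

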
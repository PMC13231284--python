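# qseg

Segmentation of diffusion-weighted MRI (dMRI) with **arbitrary q-space
samplings**. A per-voxel set encoder — invariant to the order of the
measurements and to the antipodal sign of the b-vectors — turns a
variable-length collection of (b-vector, b-value, normalized signal)
triplets into a fixed-length *diffusion embedding*. A 2.5D convolutional
segmenter (three 2D view networks, aggregated by mean probability) consumes
the embedding channels concatenated with the mean b0 slice and its two
neighbors (`C = L + 3`). One trained model segments inputs with 10, 30, or
90 diffusion directions without retraining.

A synthetic phantom module (diffusion-tensor forward simulation with Rician
noise on seeded digital anatomies) makes every stage trainable and testable
on a single CPU — no dataset downloads, no GPU. All neural components are
implemented in NumPy with explicit backward passes (gradient-checked in the
test suite).

## Layout

| module              | role |
|---------------------|------|
| `qseg.qspace`       | gradient tables: generation (antipodal electrostatic repulsion), maximum-coverage sub-sampling, Haar-uniform rotations, FSL bvec/bval I/O |
| `qseg.phantom`      | digital anatomies, per-voxel tensors, signal simulation `S = S0·exp(-b·gᵀDg)`, Rician noise |
| `qseg.encoder`      | set encoder/decoder, signal normalization, reconstruction pre-training, checkpoints |
| `qseg.segmenter`    | embedding volumes, slice assembly, composite loss (median-frequency weighted CE + edge boost + soft Dice), per-view training (three schemes), multi-view inference |
| `qseg.evaluation`   | label merging, DSC, HD99 (pooled boundary distances, 99th percentile), region grouping, one-sided exact Wilcoxon signed-rank tests |
| `qseg.pipeline`/`qseg.cli`/`qseg.io` | seeded stage orchestration, NIfTI I/O, run manifests with checksums |

## CLI

The pipeline runs stage by stage from a YAML config (see
`qseg.pipeline.RunConfig` for all keys and defaults):

```bash
qseg simulate  --config run.yaml          # phantoms + DWIs + gradient tables
qseg pretrain  --config run.yaml          # reconstruction pre-training
qseg train     --config run.yaml          # per-view segmentation training
qseg segment   --config run.yaml          # segment held-out subjects
qseg evaluate  --config run.yaml          # DSC / HD99 tables
qseg report    --config run.yaml          # summary + significance tests
```

`segment` also works standalone on explicit files:

```bash
qseg segment --dwi dwi.nii --bvec s.bvec --bval s.bval --mask mask.nii \
             --b0 meanb0.nii --checkpoint-dir ckpt/ --directions 10 --out seg.nii.gz
```

Each run writes a `manifest.json` with per-file SHA-256 checksums; identical
config + seed reproduces identical checksums for deterministic stages.

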
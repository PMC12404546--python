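# ihcprior

Prior-guided classification of immunohistochemistry (IHC) patches.

Pathologists grade IHC slides — for example CD34-stained glioma tissue,
where the DAB chromogen marks vascular endothelium brown against blue
hematoxylin-counterstained nuclei — by the *intensity* and the *area* of
positive staining.  Plain CNN classifiers look at raw RGB pixels and have
to rediscover this chemistry from data.  `ihcprior` instead injects it as a
prior: a color-deconvolution module unmixes each patch into per-stain
concentrations via the Lambert–Beer law and feeds the DAB channel (the
"anomaly map") to a second network branch, while a feature-importance
attention (a class activation map built from grayscale-masked feature
channels) focuses the image branch on stained regions.  Both branches are
pooled, fused (`LayerNorm` + linear head) and trained end-to-end with
cross-entropy into a 4-class grader: negative / weak positive / positive /
strong positive.

The core model, in brief: optical density `OD_c = -log10(I_c / I_0)` is
linear in stain concentration, so per-pixel concentrations are
`C = OD · M̂⁻¹` for the published unit-norm stain matrix M̂ (the printed
H-E-DAB deconvolution matrix, entry (1,1) ≈ 1.88, is `inv(M̂ᵀ)`); the
attention is `F̂ = (1 + ReLU(Σ_c S_c F_c)) ⊗ F` with channel scores `S`
learned from grayscale-masked features.  A Lambert–Beer forward simulator
generates labeled synthetic patches (semi-quantitative score: intensity
0–3 + proportion 0–4 → class), so every stage is trainable and testable
with no external dataset.  See `docs/methods.md` for details and
assumptions.

Everything runs on numpy (the CNN engine, with analytic backprop verified
against finite differences, lives in `ihcprior.nn`); no GPU framework is
required.

## Worked example

```python
from ihcprior import IHCClassifier, synth

# 1. simulate a labeled cohort (32 px patches keep this CPU-friendly)
records = synth.generate_dataset(
    {c: 50 for c in synth.CLASS_NAMES}, patch_size=32, seed=0)
synth.split_dataset(records, ratio=(7, 3), seed=0)   # stratified, floor rule
train = [r for r in records if r.split == "train"]
val = [r for r in records if r.split == "val"]

# 2. fit the prior-guided classifier (desk preset: 30 epochs, lr 1e-3)
model = IHCClassifier(train, val, backbone="small_cnn", feature_channels=32)
results = model.fit(seed=0)
print(results.summary())
```

This prints (numbers from this exact script):

```
Prior-guided IHC patch classifier
================================================
backbone: small_cnn   prior branch: True   attention: True
parameters: 29,125 (0.03M)
train/val patches: 140/60   classes: 4
epochs: 30  lr: 0.001  seed: 0   best epoch: 11
------------------------------------------------
evaluated patches: 60    accuracy: 0.9333
                 precision  recall     f1  support
negative            0.8333  1.0000 0.9091       15
weak_positive       0.9231  0.8000 0.8571       15
positive            1.0000  0.9333 0.9655       15
strong_positive     1.0000  1.0000 1.0000       15
macro    P/R/F1: 0.9391 / 0.9333 / 0.9329
weighted P/R/F1: 0.9391 / 0.9333 / 0.9329
```

Read it as: the fused two-branch model reaches 93.3% validation accuracy on
this small synthetic grading task; the residual confusion sits between the
adjacent negative/weak grades, exactly where the semi-quantitative score
bins adjoin (the default desk-scale study in the test suite, with 400
training patches instead of 140, reaches ~0.97 macro-F1).  `results.export_cams(val[:8], "cams/")`
writes the attention maps, which concentrate on the DAB-positive
structures; `results.plot_curves("curves.png")` and
`results.plot_confusion("confusion.png")` render the training curves and
confusion matrix.

The ablation study — the same task with and without the deconvolution
branch, three seeds each — is one call:

```python
from ihcprior import ExperimentConfig, compare_prior
with_prior, no_prior, table = compare_prior(ExperimentConfig())
print(table)   # mean metrics per arm + delta (prior minus baseline)
```

A `click` CLI wraps the same pipeline for shell use
(`ihcprior synth-generate / patchify / split / train / eval / cam-export /
run-experiment`; see `ihcprior --help`).

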
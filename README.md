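# hyperrigid

Simulation and analysis pipeline for a visual-psychophysics task: judging
whether a moving 3D cube or 4D hypercube (tesseract) is **rigid** or
**non-rigid** from its projection.

## The problem

Our retinae receive 2D images, yet we perceive 3D structure — and a rigid
3D object's 2D projection is *not* rigid, so judging rigidity requires
reconstructing the object in its native dimension. The same logic lifts one
dimension up: a rigid 4D hypercube rotating in 4D projects to a 3D wireframe
whose edge lengths stretch and shrink, so judging *its* rigidity probes the
ability to extract structure beyond three dimensions. This package rebuilds
that experiment as testable code for researchers in spatial cognition and
structure-from-motion:

- **geometry** — d-cube wireframes (2^d vertices, d·2^(d−1) edges, 100 cm
  sides) with a controlled irregularity perturbation (each vertex shifted
  by 12/18/24 cm in a random 3D direction);
- **motion** — rigid motion as oscillating plane rotations (in 4D a rotation
  fixes a *plane*; the hypercube rotates with the y-z, x-z and x-y planes
  invariant) and non-rigid motion adding per-vertex deformation plus an
  axial shear along x, y or z;
- **projection** — perspective 4D→3D projection (scale by
  w_e/(w_e − w)) and off-axis stereo pinhole projection to per-eye pixel
  coordinates, with disparity f·e·(1/Z − 1/D);
- **rigidity oracle** — ground truth: max relative pairwise-distance
  deviation across frames plus a proper-rotation Procrustes (Kabsch) RMSD
  per frame;
- **experiment** — counterbalanced two-alternative forced-choice sessions
  (Experiment 1: 54 trials, fixed headset; Experiment 2: 84 trials, active
  headset, x axis removed), 3 s response window, 1–5 confidence ratings;
- **synthetic observer** — configurable per-cell accuracy, log-normal RT,
  latent-normal confidence negatively coupled to RT (default −0.52), and
  18 Hz head-pose traces (54 samples per 3 s trial);
- **analysis** — trial/subject filtering, Tables-style cell summaries,
  LMM-ANOVA (random intercept per subject, Wald F with containment
  denominator df), Pearson confidence–RT correlation, and per-trial
  median / interquartile head-angle statistics.

## Worked example

```python
from hyperrigid import PipelineConfig, run_pipeline

config = PipelineConfig(experiment=1, seed=1, n_subjects=5, n_sessions=2)
artifacts = run_pipeline(config, "bundle")
print(artifacts["summary"][["accuracy_mean", "rt_mean", "confidence_mean"]].round(2))
```

prints

```
                             accuracy_mean  rt_mean  confidence_mean
dimension displacement_axis
3         x                          98.86   659.40             4.94
          y                          61.18   883.33             3.85
          z                          64.37   858.58             3.55
4         x                         100.00   499.81             4.56
          y                          75.00   786.47             3.87
          z                          47.67   979.41             3.23
```

— the fixed-headset pattern: near-ceiling accuracy with fast, confident
responses when the non-rigid shear displaces vertices along the x axis, and
much weaker performance for y- and z-axis displacement, similarly in 3D and
4D. The accompanying LMM-ANOVA shows a dominant displacement-axis effect
(F(2, 507) = 57.8) and a negligible dimensionality effect (F(1, 507) = 0.04),
and the pooled confidence–RT correlation comes out at r = −0.53: quick
answers are confident answers.

The `examples/` directory holds one short script per capability
(stimulus construction, motion + rigidity oracle, projection, session
design, the synthetic experiment, head movement). A thin CLI mirrors the
pipeline: `hyperrigid generate-stimulus | build-session | run-synthetic |
analyze | validate | run-pipeline`.

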
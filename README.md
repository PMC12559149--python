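# torsionlab

Motion artifacts are among the most common causes of non-diagnostic MRI.
For automated musculoskeletal pipelines — bone segmentation followed by
geometric quantification of lower-limb torsion — artifact-degraded input
silently corrupts both the segmentation and every downstream angle.
`torsionlab` is a desk-scale laboratory for studying exactly that failure
chain. It is aimed at researchers developing or stress-testing automated
torsion-measurement pipelines who need controllable, fully synthetic inputs
with known ground truth.

The package chains six components:

1. **Phantoms** — synthetic axial hip/knee/ankle stacks (bilateral, T2-like
   contrast, anisotropic spacing) built from geometric primitives whose
   torsion angles are known in closed form.
2. **Artifact simulation** — k-space operators for ghosting (periodic
   phase-encode line attenuation), spiking (Hermitian point insertions →
   herringbone stripes) and motion (line-wise k-space assembly from
   rigidly displaced anatomy), plus blur, bias field and noise, with
   graded none/mild/moderate/severe presets and a probabilistic sampler
   (each artifact with probability 0.5, spikes 0.02).
3. **Preprocessing & augmentation** — crop / z-score / resample, the
   general-purpose training augmentation sampler, and the MRI-specific
   sampler, as composable paired image/label transforms.
4. **Segmentation** — a deterministic stand-in segmenter (automatic
   threshold, morphology, component rules) with Dice metrics; the natural
   substitution point for a learned model.
5. **Torsion geometry** — femoral torsion after Lee (least-squares circle
   centers of femoral head and neck vs the posterior condylar tangent) and
   tibial torsion after the Ulm method (posterior tibial plateau tangent vs
   the distal tibio-fibular centroid line). All angles are undirected
   (mod 180°), reported in (−90°, 90°], anteversion positive.
6. **Statistics** — MAD, Pearson r with Fisher-z CIs, ICC(2,1) from explicit
   mean squares, repeated-measures ANOVA, Tukey HSD, random-intercept
   linear mixed models (REML), and a-priori RM-ANOVA power analysis
   (noncentrality λ = f²·n·m/(1−ρ)).

The torsion conventions in brief: femoral torsion
`FT = θ_neck − θ_condyles`, tibial torsion `TT = θ_plateau − θ_ankle`, each
wrapped into (−90°, 90°], where θ are in-plane line angles measured
counterclockwise from the patient-left x-axis and left limbs are mirrored
in x so positive torsion means anteversion bilaterally.

## Worked example

Generate a phantom limb with 15° femoral and 35° tibial torsion, corrupt
the hip stack with severe artifacts, segment, and measure:

```sh
$ torsionlab phantom --out-dir demo --femoral-torsion 15 --tibial-torsion 35 --seed 1
wrote 6 stacks + truth to demo

$ torsionlab corrupt demo/P001_right_hip_none_img.nii.gz demo/hip_severe.nii.gz \
      --severity severe --seed 2
applied ['motion'] -> demo/hip_severe.nii.gz

$ torsionlab segment demo/hip_severe.nii.gz demo/hip_severe_seg.nii.gz
$ torsionlab dice demo/hip_severe_seg.nii.gz demo/P001_right_hip_none_seg.nii.gz --label 1
label,dice
1,0.938423

$ torsionlab measure --hip demo/P001_right_hip_none_seg.nii.gz \
      --knee demo/P001_right_knee_none_seg.nii.gz \
      --ankle demo/P001_right_ankle_none_seg.nii.gz --side right
{
  "success": true,
  "femoral_torsion_deg": 15.056582768898172,
  "tibial_torsion_deg": 35.01478957324758,
  ...
}
```

On the clean label maps the geometric chain recovers both planted angles to
well under 0.1°; the severe motion corruption drops the femur Dice of the
stand-in segmenter from ≈0.99 to 0.94 in this single draw, and much further
once ghosting, noise and bias combine (see the experiment tables).

`torsionlab run-all --seed 7 --out-dir results/` runs the whole experiment
(synthetic cohort → graded corruption → segmentation → torsion →
statistics) and writes per-record CSVs plus Dice, success-rate, angle and
mixed-model summary tables.

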
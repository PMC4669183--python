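# mr2plan

MR-only radiotherapy treatment planning for the rat brain on a
kilovoltage small-animal irradiation platform.

Cone-beam CT, the onboard guidance of small-animal irradiators, has poor
soft-tissue contrast: a rodent brain target is essentially invisible. MR
shows the target but carries no electron-density information for dose
calculation. `mr2plan` implements the workflow that bridges the gap:

1. **Phantom simulation** — synthetic rat heads (label map, five MR
   sequences T1/T2/UTE1/UTE2/ZTE with Rician noise and a multiplicative
   bias field, reference CT), so every stage is testable without animal
   data.
2. **Bias-field correction** — a 3-D coherent local intensity clustering
   (CLIC) estimator minimising
   `E = Σ_x Σ_i u_i(x)^q [K * (I(x) − b(·)c_i)²](x)` by closed-form cyclic
   updates; only the bias estimate `b` is kept.
3. **Segmentation** — multi-channel fuzzy c-means minimising
   `Q = Σ_i Σ_j u_ij^m ‖x_i − c_j‖²` (Σ_j u_ij = 1, m = 2) over any of the
   31 non-empty subsets of the five sequences; clusters are named
   air/soft/bone from centroid signatures; hard labels by maximum
   membership inside a T1-derived head mask.
4. **Similarity** — per-class 3-D Dice `D = 2|R∩A|/(|R|+|A|)` for bone and
   soft tissue, averaged, to rank sequence combinations against a
   reference segmentation.
5. **Pseudo-CT and dose** — bulk density/attenuation assignment per class,
   then a documented primary-photon kV engine
   `D ∝ (SAD/r)² e^{−∫μ dl} (μ_en/ρ)` with exact Siddon ray tracing, for a
   single 3×3 mm static beam, a 120° coplanar arc, or three non-coplanar
   arcs, scaled to deliver 15 Gy to a 2.5 mm spherical target.
6. **DVH analysis** — cumulative DVHs, D5/D50/D90, MR/CT metric ratios and
   Mann-Whitney U tests across animals.

It is aimed at preclinical radiotherapy physicists and methods developers
who want a transparent, fully scriptable reference implementation of
MR-only planning with bulk-assigned pseudo-CTs.

## Worked example

Segment a synthetic animal from its ZTE+UTE2 pair after bias correction
(64³ head, seed 1):

```python
from mr2plan.phantom import PhantomSpec, default_sequence_models, generate_phantom
from mr2plan.bias_field import ClicParams, estimate_bias, apply_correction
from mr2plan.fcm_segmentation import FcmParams, make_air_mask, segment_subset
from mr2plan.similarity import dice_report

spec = PhantomSpec(grid_shape=(64, 64, 64), spacing=(0.55, 1.0, 0.55),
                   skull_thickness=1.2, seed=1)
truth = generate_phantom(spec, default_sequence_models())

head = make_air_mask(truth.noisy_images["T1"])
corrected = {}
for name, img in truth.noisy_images.items():
    state = estimate_bias(img, head, ClicParams())
    corrected[name] = apply_correction(img, state, head)

asmr = segment_subset(corrected, ("ZTE", "UTE2"), head, FcmParams(seed=0))
rep = dice_report(truth.labels, asmr)
print(f"combination {rep.combination}: Dice bone {rep.dice_bone:.3f}, "
      f"soft {rep.dice_soft:.3f}, mean {rep.dice_mean:.3f}")
```

prints

```
combination UTE2-ZTE: Dice bone 1.000, soft 1.000, mean 1.000
```

(the phantom has pure-class voxels, so a short-TE combination separates
the classes essentially perfectly — real-animal Dice is far lower).

Dose impact of a segmentation error: overgrow the anterior skull (the
rostrum, the structure hardest to segment from MR), fix the machine
output on the CT-based plan, and recompute on the MR-based pseudo-CT:

```python
from mr2plan.phantom import generate_labels, missegment_rostrum
from mr2plan.pseudo_ct import assign_properties
from mr2plan.dose_engine import (ArcSpec, BeamSpec, PlanSpec, TargetSpec,
                                 plan_dose_raw, prescription_scale, sphere_voi)
from mr2plan.dvh_analysis import dose_metrics

labels = generate_labels(spec)
mr_labels = missegment_rostrum(labels, spec)
iso = tuple(c + o for c, o in zip(spec.center, (0.0, 6.0, 3.0)))
target = TargetSpec(center=iso, diameter=2.5)
common = dict(isocenter=iso, field_size=(3.0, 3.0), source_axis_distance=350.0)
plans = {
    "1 beam": PlanSpec(segments=(BeamSpec(gantry_angle=90, couch_angle=90, **common),),
                       target=target),
    "3 arcs": PlanSpec(segments=tuple(ArcSpec(couch_angle=c, angular_step=10.0, **common)
                                      for c in (0, 45, 90)), target=target),
}
for name, plan in plans.items():
    raw_ct = plan_dose_raw(assign_properties(labels), plan)
    scale = prescription_scale(raw_ct, plan)          # 15 Gy to the target on CT
    voi = sphere_voi(iso, 2.5, raw_ct)
    d50_ct = dose_metrics(raw_ct.like(raw_ct.data * scale), voi).d50
    raw_mr = plan_dose_raw(assign_properties(mr_labels), plan)
    d50_mr = dose_metrics(raw_mr.like(raw_mr.data * scale), voi).d50
    print(f"{name}: D50 CT {d50_ct:.2f} Gy, D50 MR {d50_mr:.2f} Gy, "
          f"ratio {d50_mr/d50_ct:.3f}")
```

prints

```
1 beam: D50 CT 15.26 Gy, D50 MR 8.74 Gy, ratio 0.573
3 arcs: D50 CT 15.04 Gy, D50 MR 14.38 Gy, ratio 0.956
```

The single beam entering through the mis-segmented rostrum underestimates
the target dose (ratio < 1); spreading the entry directions over three
non-coplanar arcs makes the calculation far less sensitive to the same
error.

## Command line

```bash
mr2plan simulate --config phantom.yaml --out data/ --seed 1
mr2plan correct  --in data/t1.nii.gz --mask head.nii.gz --out t1_corr.nii.gz
mr2plan segment  --inputs t1=... --inputs zte=... --subset zte,ute2 --out asmr.nii.gz
mr2plan sweep    --inputs ... --ref labels.nii.gz --report dice.csv
mr2plan plan     --labels asmr.nii.gz --plan plan.yaml --out dose.nii.gz
mr2plan run      --config experiment.yaml --out results/
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.
Label encoding in NIfTI: air = 0, soft = 1, bone = 2.

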
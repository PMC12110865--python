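# freshfusion

Multimodal fish-freshness classification from pH-indicator-film photographs
and chemical spoilage indicators, plus a synthetic spoilage-data simulator
that makes the whole pipeline reproducible without laboratory data.

## The problem

Fish spoilage releases volatile amines that raise tissue pH, drive up total
volatile basic nitrogen (TVB-N, mg/100 g) and total viable count (TVC,
log10 CFU/g), and shift the colour of a betalain pH-indicator film from
dark red toward yellow. Classifying a specimen as **fresh / qualified /
inedible** from a phone photo of the film alone is fragile under lighting
and angle variation; from the chemistry alone it ignores the cheap visual
signal. This package implements a gated multimodal classifier for
researchers in food-quality sensing who want to study that fusion:

- **Image branch** — a truncated MobileNetV2-style backbone (320 channels
  at stride 32) followed by multi-scale dilated fusion attention (MDFA):
  parallel 3×3 convolutions with dilations 6 and 12 (receptive fields
  13×13 and 25×25), a global-context branch, 1×1 fusion to 256 channels
  and a sigmoid spatial-attention gate; pooled to F_img ∈ R²⁵⁶.
- **Chemical branch** — pseudo-temporal resampling of the (pH, TVB-N, TVC)
  series, causal dilated temporal convolutions (k = 3, d = 2, 4, 8), a 1-D
  MDFA (d = 3, 6) and a 64 → 256 projection to F_chem.
- **CAG-Fusion** — with s = cos(F_img, F_chem), a 513 → 64 → 1 sigmoid MLP
  over [s; F_img; F_chem] yields the gate g, and the classifier consumes
  F_fused = g·F_img + (1 − g)·F_chem. A hinge penalty
  λ·E[max(0, 0.7 − g)·1(pH < 6.8) + max(0, g − 0.3)·1(pH > 7.2)] keeps the
  gate physically interpretable: image-dominant early, chemistry-dominant
  late.

Everything runs on a compact numpy autodiff engine (`freshfusion.nn`) —
no GPU or deep-learning framework required — and is exactly reproducible
from a single seed.

## Worked example

Simulate one specimen's spoilage kinetics and check the film-colour → pH
calibration:

```python
import numpy as np
from freshfusion import (KineticsParams, simulate_trajectory, ph_to_film_color,
                         color_scalar, fit_ph_calibration, rgb_to_ph,
                         receptive_field)

traj = simulate_trajectory(KineticsParams())
print("t (h)   pH     TVB-N   TVC")
for t, ph, tvbn, tvc in zip(traj.times, traj.ph, traj.tvbn, traj.tvc):
    print(f"{t:5.0f}  {ph:5.2f}  {tvbn:6.2f}  {tvc:5.2f}")

ph_grid = np.linspace(5.8, 8.6, 20)
scalars = np.array([color_scalar(ph_to_film_color(p)) for p in ph_grid])
cal = fit_ph_calibration(scalars, ph_grid)
err = max(abs(rgb_to_ph(cal, ph_to_film_color(p)) - p)
          for p in np.linspace(5.8, 8.6, 57))
print(f"calibration R^2 = {cal.r_squared:.4f}, max round-trip error = {err:.4f} pH")
print("receptive fields:", receptive_field(3, 6), receptive_field(3, 12))
```

prints

```
t (h)   pH     TVB-N   TVC
    0   6.22    5.68   4.56
    5   6.29    8.72   4.84
   10   6.58   21.18   5.97
   15   7.12   43.82   8.03
   20   7.41   56.28   9.16
   25   7.48   59.32   9.44
calibration R^2 = 1.0000, max round-trip error = 0.0000 pH
receptive fields: 13 25
```

The trajectory starts at the fresh reference state (pH ≈ 6.20,
TVB-N < 6.08 mg/100 g, TVC < 5.40 log CFU/g) and ends severely spoiled
(TVB-N > 50). The cubic calibration recovers pH from the film colour
exactly on noiseless data because the simulated hue is affine in pH.

A full training run from the shell (scaled-down configuration):

```bash
cat > config.yaml <<'EOF'
simulate: {n_specimens: 14, image_size: 64, shots_per_condition: 1}
model: {variant: full, slim: true}
train: {lr0: 0.001, max_epochs: 12}
EOF
freshfusion simulate --config config.yaml --out data/ --seed 42
freshfusion train --data data/ --config config.yaml --variant full --out run/ --seed 42
freshfusion evaluate --model run/model --data data/ --report report/ --seed 42
freshfusion predict --model run/model --image data/images/img_000000.png
```

`evaluate` writes the metrics table, per-sample gate records
(sample_id, s, g, pH, stage, predicted, true) and a confusion-matrix plot;
`predict` emits a JSON object with class probabilities, the gate value g
and the image/chemistry similarity s.

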
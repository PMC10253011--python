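# plaquevae

Semi-supervised tissue classification of peripheral-artery chronic total
occlusions from multi-contrast MRI, using a two-dimensional-latent
convolutional variational autoencoder (VAE).

## Who this is for

Percutaneous revascularization of peripheral arterial disease (PAD) fails
acutely in a substantial fraction of patients because the guidewire cannot
cross a hard occlusion.  High-resolution "MRI histology" — co-registered
ultrashort-echo-time (UTE), T1-weighted and T2-weighted volumes of the
lesion — can distinguish soft occlusion tissue (fat, thrombus,
microchannels, loose fibrous tissue; crossable) from hard tissue (dense
collagen, calcium; often not).  This package implements an automated
pipeline that turns such volumes into a per-lesion **tissue score**
summarizing how much hard/soft occlusion the lesion contains, for
researchers working on MRI-based lesion-crossability assessment.

## The method

1. **Pseudo-color fusion.**  The three co-registered contrasts are
   normalized cohort-wide (pooled 1st/99th percentile → 0/255) and stacked
   as an RGB image: red = T1w, green = T2w, blue = UTE.  Arterial wall
   renders red/pink, flowing lumen green, soft occlusion bright blue,
   collagen dark blue, calcium black.
2. **Axial reslicing and standardization.**  The outlined lesion volume is
   resliced into axial cross-sections (multiplanar reconstruction), each
   slice auto-cropped, resized to 64×64, and wall pixels (packed RGB in
   `0x800000`–`0xff0000`) removed so only occlusion tissue remains.
3. **Convolutional VAE.**  Each slice `x` is encoded by five stride-2
   convolutions into a diagonal Gaussian posterior `q(z|x) = N(mu(x),
   diag(sigma^2(x)))` over a 2-D latent space; a mirrored transposed-
   convolution decoder reconstructs `x` from a sample `z = mu + sigma * eps`.
   Training minimizes `MSE(x, x_hat) + beta * KL(q(z|x) || N(0, I))` with
   Adam (learning rate 5e-4, batch 128, 500 epochs at full scale).
4. **Latent partition and scoring.**  The latent plane is split into four
   rectangles by one x- and one y-threshold, one per tissue class:
   1 = lumen patent (score 0), 2 = partially patent (1), 3 = mostly
   occluded soft (3), 4 = mostly occluded hard (5).  Thresholds are
   calibrated on a small labelled subset (`calibrate_boundaries`).  The
   lesion's average tissue score is the mean per-slice score, i.e. the dot
   product of class fractions with (0, 1, 3, 5).

Because real 7 T specimen data are not publicly deposited, the package
ships a synthetic vessel-phantom generator that reproduces the pseudo-color
semantics with exact ground-truth labels, so the entire chain is testable
end to end.

## Worked example

```python
import numpy as np
import plaquevae as pv

# 1. a 4-class phantom lesion with known labels
rng = np.random.default_rng(0)
seq = tuple(rng.permutation([1]*50 + [2]*50 + [3]*50 + [4]*50).tolist())
stack = pv.generate_phantom(pv.PhantomSpec(class_sequence=seq, noise_sd=0.0, seed=0))

# 2. preprocessing tail: crop, resize, strip the wall signal
images = np.stack([pv.standardize_slice(s) for s in stack.slices])

# 3. train the desk-scale VAE and embed every slice
results = pv.TissueVAE(images, pv.VaeConfig.desk_scale(seed=0, epochs=100)).fit()
points = results.encode(images)

# 4. calibrate rectangular boundaries on a labelled half, score the lesion
labels = np.asarray(stack.labels)
half = rng.permutation(len(labels))[: len(labels) // 2]
bounds, agreement = pv.calibrate_boundaries(points[half], labels[half])
report = pv.score_lesion(pv.classify_points(points, bounds), "phantom-1")

print(f"calibration agreement: {agreement:.2f}")
print(f"average tissue score:  {report.average_tissue_score:.2f}")
print("class percentages:     ", report.class_percentages)
```

Typical output (one desk-scale training run, ~2 minutes on a laptop CPU):

```
calibration agreement: 0.89
average tissue score:  2.38
class percentages:      {1: 26.5, 2: 15.5, 3: 33.5, 4: 24.5}
```

A perfectly recovered cohort would print 25 % per class and an average
score of (0+1+3+5)/4 = 2.25; the report above misclassifies some
borderline partially/mostly-occluded slices (class 2 vs 3), which is the
expected failure mode of rectangular boundaries on a continuous occlusion
spectrum.

The same flow is available from the shell:

```bash
plaquevae run --config run.yaml      # end-to-end with a YAML run config
plaquevae phantom --classes 1,2,3,4 --out slices/
```

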
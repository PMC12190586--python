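# gazecam

Gaze-supervised attention training for lesion image classification.

When an endoscopist reads an image, their fixations dwell on the diagnostic
region. `gazecam` turns that signal into supervision for a CNN classifier:

1. **Gaze-attention maps** (`gazecam.gaze`). Eye-tracker fixations, logged in
   screen-pixel coordinates while the image is displayed centered on the
   display, are spread with a Gaussian field-of-view model
   G(x, y) = (1/(√(2π)σ))·exp(−((x−x_c)² + (y−y_c)²)/(2σ²)), accumulated,
   smoothed with a separable discrete Gaussian kernel, and max-normalized to
   [0, 1] — the human attention map **A_human**. The width σ defaults to
   30 px; a viewing-geometry helper estimates it from angular error θ and
   eye-screen distance R as σ = (θ/360)·π·R·√((H_p·W_p)/(H·W)).
2. **Attention-consistency training** (`gazecam.attention`,
   `gazecam.training`). The classifier is a feature extractor + global
   average pooling + fully connected head. Its class activation map for the
   predicted class — the rectified head weights used as channel weights over
   the last feature map, summed, bilinearly upsampled and sigmoid-activated —
   is the network attention map **A_model**. Training minimizes
   `LOSS = CE + λ·MSE(A_model, A_human)` with Adam and a cosine-annealing
   warm-restarts schedule (λ = 0 recovers the plain classifier for the
   ablation). The network stack is implemented in NumPy with analytic
   gradients; the bundled reference backbone is a 3-block strided CNN
   (64×64×3 → 8×8×32) and any extractor honoring the same contract plugs in.
3. **One-vs-rest evaluation** (`gazecam.evaluation`). Confusion matrices,
   per-class and macro accuracy/precision/recall/F1/MCC, Cohen's kappa,
   midrank one-vs-rest AUC, and an attention-alignment score: the IoU
   between the Otsu-binarized attention map and the ground-truth lesion mask.
4. **Synthetic study** (`gazecam.synthetic`). A phantom generator — one
   elliptical lesion per image, three visually distinct classes recoverable
   from pixel statistics, simulated scanpaths concentrated on the lesion,
   patient-level 60/20/20 splits — makes every stage testable with no eye
   tracker and no clinical data.

## Worked example

Train the reference backbone on the synthetic study (30 patients, ~250
images of 64×64, gaze rendered at σ = 6.4 px) with gaze supervision:

```python
import numpy as np
from gazecam import (PhantomSpec, ScanpathSpec, generate_dataset,
                     render_gaze_map, create_tiny_bundle, TrainConfig, train,
                     Sample, forward, compute_network_attention,
                     attention_alignment, ConfusionMatrix, classification_report)

records, manifest = generate_dataset(PhantomSpec(n_patients=30, seed=0),
                                     ScanpathSpec(), seed=0)
split = dict(zip(manifest.image_id, manifest.split))
sets = {"train": [], "val": [], "test": []}
for r in records:
    gm = render_gaze_map(r.fixations, 64, 64, sigma=6.4, kernel_taps=39).values
    sets[split[r.image_id]].append(Sample(r.image_id, r.image, r.label, gm, r.mask))

cfg = TrainConfig(max_epochs=30, lambda_gaze=1.0, seed=1)
best, state = train(create_tiny_bundle(num_classes=3, seed=1),
                    sets["train"], sets["val"], cfg)

images = np.stack([s.image for s in sets["test"]])
labels = np.array([s.label for s in sets["test"]])
probs = best.predict_proba(images)
preds = probs.argmax(axis=1)
cm = ConfusionMatrix.from_predictions(labels, preds, 3)
report = classification_report(cm, scores=probs, labels=labels)
ious = []
for s, p in zip(sets["test"], preds):
    _, fmap = forward(best, s.image)
    att = compute_network_attention(fmap, best, int(p), 64, 64)
    ious.append(attention_alignment(att, s.mask))
print(f"test accuracy: {report.accuracy:.3f}   macro F1: {report.f1:.3f}")
print(f"kappa        : {report.kappa:.3f}   macro AUC: {report.auc:.3f}")
print(f"attention IoU: {np.mean(ious):.3f}")
```

Output:

```
test accuracy: 0.963   macro F1: 0.964
kappa        : 0.944   macro AUC: 0.992
attention IoU: 0.351
```

96.3% of held-out-patient test images are classified correctly; the macro
AUC says the three one-vs-rest score orderings are nearly perfect; kappa
0.944 is agreement far above chance; and the attention IoU says the
Otsu-binarized network attention overlaps the true lesion with IoU 0.35 —
versus ~0.3 for the same model trained without gaze (see the ablation in
`tests/test_acceptance.py`).

The same pipeline is available from the shell:

```bash
gazecam make-synthetic --out data --n-patients 30 --seed 0
gazecam render-gaze --gaze-csv data/gaze.csv --images data/images --out maps \
        --sigma 6.4 --kernel 39
gazecam train --manifest data/manifest.csv --gaze-csv data/gaze.csv \
        --config cfg.yaml --out-dir run
gazecam evaluate --ckpt run/best.ckpt --manifest data/manifest.csv \
        --split test --out report.json
gazecam explain --ckpt run/best.ckpt --image data/images/pat000_img00.png \
        --out overlay.png
```

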
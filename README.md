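# rccnet

Non-invasive renal-tumor subtype classification from multiphasic CT
attenuation, as a tested, reproducible Python package.

## The problem

Renal cell carcinoma (RCC) subtypes — clear cell (CCC), papillary (PPC)
and chromophobe (CPC) — differ in prognosis and treatment, and the benign
oncocytoma (OCC) mimics them on imaging. Their contrast-enhancement
kinetics differ too: on quadriphasic multidetector CT, a lesion's peak
attenuation (Hounsfield Units) in the unenhanced, corticomedullary,
nephrographic and excretory phases forms a four-vector
`x = (x_u, x_cm, x_n, x_e)` that carries subtype information, with clear
cell showing by far the strongest corticomedullary enhancement.

`rccnet` implements the full pipeline for classifying that four-vector:

1. **Gaussian class-conditional simulator** — no public corpus pairs
   phase vectors with confirmed subtypes, so labeled cohorts are drawn
   with each phase an independent `Normal(mean[s,p], sd[s,p])` per
   subtype `s`. The shipped defaults use the four published patient
   vectors as class means with a common 15 HU SD; any other
   parameterization is a YAML file away.
2. **Feed-forward softmax classifier** — the fixed published
   architecture, `y1 = ReLU(W1 x + b1)`, `y2 = ReLU(W2 y1 + b2)`,
   `z = softmax(W3 y2 + b3)` with two 50-node hidden layers (3,004
   parameters), trained by mini-batch Adam on categorical cross-entropy.
   Forward pass, backpropagation and the optimizer are implemented
   directly in NumPy.
3. **Bayes-optimal oracle** — the closed-form diagonal-Gaussian
   discriminant `P(s|x) ∝ prior[s] Π_p N(x_p; mean[s,p], sd[s,p])`,
   computed in log-space: the accuracy ceiling any classifier on this
   simulator can reach, used to verify the trained network.
4. **Evaluation arithmetic** — row-normalized confusion matrices,
   per-class diagnostic accuracy and overall concordance with
   histopathology, including the packaged 50-patient reference cohort.

## Worked example

```python
import numpy as np
from rccnet import SubtypeClassifier, default_params

params = default_params()
model = SubtypeClassifier.from_generative(params, n_per_class=8000, seed=7)
res = model.fit(seed=7)
print(res.summary())
```

```
Renal-tumor subtype classifier — fit summary
====================================================
architecture          4 -> 50 (ReLU) -> 50 (ReLU) -> 4 (softmax)
trainable parameters  3004
training records      32000
epochs run            22 (max 50)
final train loss      0.3804
final train accuracy  83.3%
final val accuracy    84.7%
feature scaling       per-phase standardization
simulator fingerprint 3b2b662fe6dd03e0
```

Classify a measured patient vector (phases in acquisition order —
unenhanced, corticomedullary, nephrographic, excretory):

```python
label, confidence, z = res.predict_one(np.array([54, 163, 120, 77]))
print(label.name, f"{confidence:.1f}%")        # CCC 100.0%
print(res.agreement_with_bayes(2000, seed=99)) # 98.225
```

The strongly corticomedullary-enhancing lesion is called clear cell with
essentially certain confidence, and across 8,000 fresh simulated lesions
the network gives the same label as the Bayes-optimal rule 98.2% of the time — it has
essentially learned the optimal decision boundary of the simulator.

The same pipeline is available from the shell:

```bash
rccnet simulate --n-per-class 8000 --seed 7 --out cohort.csv
rccnet train --cohort cohort.csv --seed 7 --model-out model.json
rccnet predict --model model.json --input 54,163,120,77
rccnet cohort-metrics         # packaged 50-patient reference cohort
rccnet reproduce-tables       # every packaged reference check at once
```

`rccnet cohort-metrics` recomputes the reference cohort's diagnostic
accuracy from its outcome counts: 76.0% (CCC), 58.3% (PPC), 60.0% (CPC),
62.5% (OCC), and an overall concordance with histopathology of 68.0%
(34/50 cases).

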
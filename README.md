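# roarbout

Classification of lion roaring-bout call types and individual identity
from fundamental-frequency (F0) contours.

African lions (*Panthera leo*) advertise territory and keep contact with
pride members through roaring bouts — stereotyped sequences that open
with **moans**, build to **full-throated roars** (FTRs), taper through
shorter **intermediary roars** (IRs) and close with **grunts**. FTRs
carry an individually identifiable vocal signature, which makes them the
unit of interest for passive acoustic monitoring and acoustic
capture–recapture of lion populations — but selecting FTRs by ear is
expert-dependent and biased. `roarbout` implements a data-driven
alternative for bioacousticians:

* **F0 extraction** — a call is bandpassed to the lion fundamental band
  (30–375 Hz; zero-phase Butterworth or Hann-windowed FFT mask) and its
  F0 contour extracted by windowed normalized autocorrelation (128-sample
  windows, half-window hop, amplitude gating at the top 1% of |x|).
* **Call-type classification** — each call type's contour dynamics are
  modelled by a two-state Gaussian hidden Markov model
  (π, A, N(μ_k, σ²_k) over Hz), fitted by Baum–Welch EM from random
  restarts; a held-out call is assigned to the class whose HMM maximises
  the forward-algorithm log-likelihood, under leave-one-call-out
  cross-validation.
* **K-means call typing** — two bounding-box features per call, duration
  (s) and maximum frequency (Hz), standardized and clustered at k=4
  (all types) or k=3 (moans removed); the FTR cluster gives a
  reproducible, data-driven FTR selection rule.
* **Individual identification** — per-lion HMMs over the FTR contours,
  scored per bout (sum of per-call log-likelihoods) under
  leave-one-bout-out cross-validation.
* **Synthetic bouts** — a generator of labeled corpora (grammar-correct
  bouts, parametric contour templates, per-lion signatures, optional
  rendered audio) so the whole pipeline is testable without field
  recordings.

Performance is reported as a confusion matrix with the four one-vs-rest
metrics — accuracy (TP+TN)/(TP+TN+FP+FN), recall TP/(TP+FN), precision
TP/(TP+FP) and F1 = 2PR/(P+R) — under micro and macro averaging. Note
the TN-inclusive accuracy exceeds plain fraction-correct for more than
two classes; both are printed.

## Worked example

```python
from roarbout import (gen_dataset, fit_hmm, FitConfig,
                      run_calltype_kmeans, RunConfig)

# a labeled synthetic corpus: 5 lions, 10 bouts each
ds = gen_dataset(n_individuals=5, bouts_per_individual=10, seed=1)

# fit one 2-state HMM to all full-throated-roar contours
ftrs = [c for c, lab in ds.labeled_calls() if lab == "full_throated_roar"]
print(fit_hmm(ftrs, FitConfig(n_restarts=5, seed=1)).summary())
```

```
Gaussian HMM fit
============================================
states: 2   sequences: 181   frames: 45355
log-likelihood: -208380.3711   EM iterations: 15   restarts: 5

state    mean (Hz)    sd (Hz)   start p
    0      211.820     20.739    1.0000
    1      282.625     26.295    0.0000

transition matrix:
  0.9922  0.0078
  0.0083  0.9917
```

The two states split the roar's arch into its low flanks (~212 Hz) and
its peak (~283 Hz); every contour starts in the low state (start
probability 1) and the sticky transitions (~0.99) reflect the slow
rise–fall. Clustering the same corpus with moans removed:

```python
rep = run_calltype_kmeans(ds.annotations, RunConfig(seed=1, k=3, drop_moans=True))
print(rep.summary())
```

separates FTRs, IRs and grunts perfectly (micro accuracy 1.0000 on 658
calls) — whereas the k=4 run with the high-variance moans included is
the harder problem, which is exactly why the pipeline treats moan
removal as its one manual step.

The same experiments run from the shell:

```bash
roarbout synth --lions 5 --bouts 10 --seed 1 --out corpus/
roarbout cluster --data corpus/ --k 3 --drop-moans --out runs/kmeans3
roarbout classify-calls --data corpus/ --repeats 3 --restarts 3 --out runs/hmm
roarbout identify --data corpus/ --source kmeans --out runs/id
```

Every run writes `manifest.yaml` (all parameters + seed), the confusion
matrix and the metric report.

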
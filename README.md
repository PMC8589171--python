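# protopolicy

Prototype-based treatment selection for tabular patient cohorts.

## The problem

In many clinical settings — antidepressant prescription for major
depressive disorder is the motivating example — several treatments are
about equally effective *at the population level*, yet individual patients
respond very differently, and the current standard of care is educated
trial and error.  If patients fall into latent subgroups with different
per-treatment response profiles, a model that recovers those subgroups can
recommend the arm with the highest individual remission probability.

The catch is that each patient's record contains the outcome of only the
one treatment they received; the counterfactuals are never observed.
`protopolicy` is for methodologists and applied biostatisticians who want
to (a) train selection policies on such data and (b) benchmark them on
simulated cohorts where the full counterfactual surface is known.

## The method

The core estimator is a **differential-prototype network**: a symmetric
autoencoder `e`/`d`, a layer of ℓ trainable latent prototypes, and a
classifier `h` that maps a patient's vector of squared distances to the
prototypes, concatenated with a treatment one-hot, to a remission
probability Pr̂(r | x, t).  The policy is π(x) = argmax_t Pr̂(r | x, t).
Training jointly minimizes

```
L = L1 + λ1·L2 + λ2·L3
```

where `L1` is the binary cross-entropy on observed outcomes, `L2` the
reconstruction distance ‖x − d(e(x))‖, and `L3` the *negated* weighted sum
of the intra- and inter-prototype variances of the ℓ×k prototype-outcome
matrix Y_P (every prototype scored under every treatment).  Minimizing
`L3` pushes the prototypes toward "actionable" subgroups — those whose
predicted outcome actually depends on the treatment — rather than
subgroups that merely share an overall prognosis.

Included alongside: a synthetic cohort generator with latent subgroups and
full counterfactual ground truth, K-means+classifier (KMNN) and case-based
reasoning (CBR) baselines, ranking-oriented policy metrics (MRR, RPL,
retrospective remission rate), and a repeated-CV benchmark harness with
Friedman/Wilcoxon/Bonferroni method comparison.  Everything is seeded and
reproducible; the network is plain numpy with hand-derived,
finite-difference-verified gradients.

## Worked example

```python
import numpy as np
from protopolicy import SyntheticConfig, generate_cohort, DPNNPolicy
from protopolicy import mean_reciprocal_rank, remission_policy_loss

cohort = generate_cohort(SyntheticConfig(seed=0))          # N=10,000, d=20, k=4
idx = np.random.default_rng(0).permutation(cohort.n_patients)
train, test = cohort.subset(idx[:8000]), cohort.subset(idx[8000:])

model = DPNNPolicy(n_prototypes=5, epochs=75, random_state=0)
model.fit(train.X, train.y, treatment=train.t)

pred = model.predict_all(test.X)                           # 2000 x 4 probabilities
print("recommended arm counts:", np.bincount(model.recommend(test.X), minlength=4))
print("MRR :", round(mean_reciprocal_rank(pred, test.P_true, "shifted"), 3))
print("RPL :", round(remission_policy_loss(pred, test.P_true), 3))
```

```
recommended arm counts: [  18    0    0 1982]
MRR : 0.421
RPL : 0.041
```

On this cohort draw one arm happens to be best for almost every patient,
and the policy finds that out.  The shifted MRR of 0.421 is close to its
ceiling here (an oracle that reads the true probabilities scores 0.442 —
ties among near-equally-good arms keep even a perfect policy below 1/2 on
this scale), and the RPL of 0.041 means the recommended arm's true
remission probability is on average only 4.1 points below the best
achievable arm's.  A uniform-random policy on the same cohort has an RPL
around 0.44.

The same workflow is available from the shell:

```bash
protopolicy simulate --seed 1 --out cohort/
protopolicy train --cohort cohort/ --seed 0 --out model.npz
protopolicy predict --model model.npz --cohort cohort/ --out pred.csv
protopolicy experiment1 --reps 5 --seed 0 --out results/
protopolicy sweep --l-min 2 --l-max 9 --reps 5 --seed 0 --out sweep.csv
```

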
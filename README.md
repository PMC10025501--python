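# mpptree

Monte Carlo parameter-recovery study of the **midpoint-primary-process (MPP)
IRTree model** for 5-point Likert data.

Item response tree (IRTree) models explain an ordinal survey response as the
outcome of a sequence of binary decisions, each governed by its own latent
trait and 2PL item parameters. For a 5-point scale the MPP variant posits
three decision nodes:

1. **midpoint (M)** — respond with the scale midpoint (category 3) or give a
   directed response;
2. **agreement (A)** — given a directed response, agree (4/5) or disagree (1/2);
3. **extreme (E)** — given a directed response, pick the endpoint (1/5) or not (2/4).

Node *k*'s "yes" probability for person *v* and item *i* is a 2PL in
intercept form,

```
P(yes) = σ(α_ki θ_vk + d_ki),   d_ki = α_ki · b_ki,
```

with discrimination α > 0, difficulty *b* on the trait scale, and logistic
function σ. The category probabilities are products along the tree branches
(e.g. P(5) = (1 − p_M) p_A p_E), and a Likert matrix decomposes losslessly
into three binary *pseudo-items* per item — the agreement and extreme codes
being **structurally missing** whenever the midpoint was chosen.

This package is aimed at psychometricians who want to know how well the MPP
model's item parameters can be recovered from data that truly follow the
model, as a function of sample size and test length. It provides:

- `mpptree.core` — the model mathematics: node/category probabilities,
  pseudo-item decomposition and recomposition, and the decomposed-data
  log-likelihood;
- `mpptree.simulate` — the study's generative conditions: per-node
  log-normal discriminations and normal difficulties, a trivariate-normal
  trait distribution with r(M,A) = −0.10, r(A,E) = 0.10, r(M,E) = −0.50, and
  the 4 (N) × 3 (J) design grid;
- `mpptree.estimation` — a bespoke adaptive Metropolis-within-Gibbs sampler
  for the three-node model with structural missingness, plus split-R-hat,
  effective-sample-size, and posterior-summary utilities;
- `mpptree.evaluation` — per-item RMSE/bias across replicates and cell-level
  means, SEs, and 95% CIs;
- `mpptree.anova` — between-subjects factorial ANOVA on item-level RMSE with
  partial η² and pairwise node contrasts;
- `mpptree.study` / `mpptree.cli` — the orchestrated study with seeding,
  checkpointing, resumability, and a scaled-down replication mode.

## Worked example

Simulate one design cell (N = 1,000 persons, J = 10 items), decompose, fit,
and score the fit against the generating parameters:

```python
import numpy as np
from mpptree import (ChainConfig, decompose, draw_item_params, draw_thetas,
                     fit_irtree_mcmc, simulate_responses)

params = draw_item_params(10, seed=1)          # 10-item scale
traits = draw_thetas(1000, seed=2)             # N = 1,000 persons
likert = simulate_responses(params, traits, seed=3)
codes = decompose(likert)

print("category counts:", np.bincount(likert.responses.ravel())[1:])
print("observed pseudo-item cells (M, A, E):", codes.observed.sum(axis=(0, 1)))

fit = fit_irtree_mcmc(
    codes, chains=ChainConfig(chains=2, iterations=2000, burn_in=1000, seed=4)
)
for k, node in enumerate(("midpoint", "agreement", "extreme")):
    a = fit.point("alpha", node)
    print(node, "alpha RMSE vs truth:",
          round(float(np.sqrt(np.mean((a - params.alpha[k]) ** 2))), 3))
```

Output:

```
category counts: [2373  814 3400  888 2525]
observed pseudo-item cells (M, A, E): [10000  6600  6600]
midpoint alpha RMSE vs truth: 0.084
agreement alpha RMSE vs truth: 0.168
extreme alpha RMSE vs truth: 0.21
```

The category counts show the response-style structure of the generator
(heavy midpoint and endpoint use), and the observed-cell counts show the
structural missingness: every midpoint response (34% here) removes the
agreement and extreme pseudo-item observations for that person × item. The
RMSE gradient — midpoint smallest, extreme largest — is the study's central
finding: estimation error inflates as the decision hierarchy deepens, because
later nodes see fewer observations and operate in flatter regions of the
likelihood.

The same pipeline is scriptable from the shell:

```sh
mpptree simulate -n 1000 -j 10 --seed 1 --out sim/
mpptree decompose sim/responses.csv --out codes.csv
mpptree fit codes.csv --chains 2 --iterations 2000 --seed 4 --out posterior.csv
mpptree replicate-study --scale 0.01 --seed 7 --out replication/
```

`replicate-study` runs the full 12-condition grid at a fraction of the
original 2,000 replicates per cell and prints observed node-level mean RMSEs
next to the published values, with a verdict on the midpoint < agreement <
extreme ordering.

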
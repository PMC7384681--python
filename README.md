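# perturbnet

Perturbation-biology network inference and in-silico drug-combination
screening for drug-response time series.

## The problem

Systematic drug screens on cancer cell lines perturb the same cells with a
panel of targeted drugs — singly at low and high dose, and pairwise at low
dose — and follow both the molecular response (dozens to hundreds of
protein and phospho-protein levels by reverse-phase protein array, RPPA)
and the phenotypic response (cell number and apoptosis by live-cell
imaging) over time. `perturbnet` turns such a dataset into an ensemble of
quantitative network models and uses them to nominate new drug-target
combinations, for computational biologists working at the interface of
signaling and pharmacology.

## The model

Every measured node i (molecular or phenotypic, as log2 ratio to the DMSO
control) follows a tanh-coupled ODE

    dx_i/dt = ε_i tanh( Σ_{j≠i} w_ij x_j + Σ_l d_il u_l(t) ) − α_i x_i

with drug nodes given analytically by u_l(t) = tanh(δ_l c_l)(1 − e^{−10t})
for relative dose c_l ∈ {0, 1, 2}. Phenotype nodes receive only molecular
input and emit no edges. All parameters (ε, α, W, D, δ) are inferred by
Adam on RSS + λ Σ|w_ij|, with per-step cropping (|w| < 0.01, |d| < 0.05 set
to zero) producing sparse networks; gradients are exact discrete adjoints
through the fixed-step RK2 integrator. λ is selected by BIC
(n ln(RSS/n) + k ln n) on training fits and cross-checked by validation
RSS on held-out drug-pair conditions. The fitted ensemble then drives an
in-silico screen: each molecular node is inhibited by a step concentration,
dose–response curves are summarized by a Hill fit
x(c) = E1(1 − 1/(1 + (c/EC50)^n)), and every node pair is simulated at its
own EC50 doses to rank combinations by predicted growth reduction or
apoptosis increase. See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic 4-drug study (10 molecular + 2 phenotypic nodes, 14
conditions, noise sd 0.05 on the log2 scale), fit a small ensemble, and
screen combinations:

```python
import numpy as np
import perturbnet as pn
from perturbnet import synthetic as syn
from perturbnet.inference import FitConfig
from perturbnet.perturbation import (
    combinatorial_screen, estimate_ec50_map,
)

truth = pn.generate_ground_truth(
    pn.GroundTruthSpec(n_molec=10, n_phen=2, n_drug=4,
                       edge_density=0.10, drug_target_count=3, seed=3))
design = syn.demo_design(4, include_control=False)
dataset = pn.simulate_dataset(truth, design, noise_sd=0.05, seed=7)
print(f"{len(dataset.conditions)} conditions, {len(dataset.times)} time points, "
      f"{dataset.n_measured} measured values")

cfg = FitConfig(max_iterations=2000, step_h=0.2)
ensemble = pn.fit_ensemble(dataset, 0.05, 3, base_seed=1, config=cfg)
for r in ensemble:
    print(f"seed {r.seed}: rss/point {r.rss_train/dataset.n_measured:.4f}, "
          f"{r.n_nonzero_w} interactions")

params = [r.params for r in ensemble]
ec50, fits = estimate_ec50_map(params, "cell_growth")
screen = combinatorial_screen(params, ec50, "cell_growth", fallback_dose=1.0)
for r in pn.rank_targets(screen, top_unique=4):
    print(f"{r.node_a} + {r.node_b}: predicted growth change {r.effect:+.3f}")
```

Output:

```
14 conditions, 8 time points, 1260 measured values
seed 1: rss/point 0.0023, 22 interactions
seed 2: rss/point 0.0024, 36 interactions
seed 3: rss/point 0.0025, 34 interactions
node003 + node007: predicted growth change -0.772
node003 + node008: predicted growth change -0.607
node007 + node008: predicted growth change -0.478
node002 + node003: predicted growth change -0.466
```

Each fit reaches the measurement-noise floor (0.05² = 0.0025 per point)
while keeping the network sparse; the ranked list reads "inhibiting
node003 and node007 together at their in-silico EC50 doses is predicted to
reduce the cell count by 0.77 log2-units (≈ 42%) at 72 h, averaged over
the ensemble".

The same chain is available from the shell:

```bash
perturbnet simulate-synthetic --n-drug 4 --out-dir demo
perturbnet fit demo/dataset.tsv --design demo/design.tsv --lambda 0.05 \
    --n-models 10 --out-dir demo/models
perturbnet screen --models demo/models --phenotype cell_growth --out-dir demo/screen
perturbnet run config.yaml        # or the whole pipeline from a YAML config
```

Raw RPPA dilution-series spot tables are normalized with
`perturbnet normalize` (Cook's-distance spotting-error removal, closed-form
dilution fit, double-median loading correction, DMSO subtraction).

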
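# Methods

## The model

`perturbnet` infers data-driven network models of drug response in a
cultured cell line. The state of the system is a vector of *measured nodes*:
`N_molec` molecular nodes (protein and phospho-protein levels measured by
reverse-phase protein arrays) plus `N_phen` phenotypic nodes (cell number
and apoptosis from live-cell imaging), all expressed as log2 ratios to the
unperturbed (DMSO) control, so the resting state is `x = 0`.

Each molecular node obeys

    dx_i/dt = eps_i * tanh( sum_{j != i} w_ij x_j + sum_l d_il u_l(t) ) - alpha_i x_i

with `eps_i > 0` the dynamic range (log2-units/h), `alpha_i > 0` the rate of
return to baseline (1/h), `w_ij` the signed interaction from node j to node
i, and `d_il` the effect of drug l on node i. The tanh transfer function
caps reaction rates and models saturation: the interaction-driven change of
node i is bounded to `[-eps_i, eps_i]`, and every trajectory is bounded by
`|x_i(t)| <= (eps_i/alpha_i)(1 - exp(-alpha_i t))`, which the test suite
verifies against random instances.

Drug nodes are fast first-order units with fixed rate 10/h driven by the
saturated dose, giving the closed form

    u_l(t) = tanh(delta_l c_l) * (1 - exp(-10 t)),

where `c_l` is the relative dose (0 absent / 1 low / 2 high) and `delta_l`
the inferred effective impact. Because the rate constant is 10/h the drug
node reaches 99% of its plateau within half an hour — effectively a step
input on the timescale of the molecular response. The closed form is used
directly instead of numeric integration; this removes the only stiff
component from the system. For `delta_l * c_l << 1` the drug drive is nearly
linear in dose; for `delta_l * c_l >> 1` it saturates, so dose doubling is
informative only in the unsaturated regime.

Phenotypic nodes follow the same law but receive only molecular inputs:
they emit no edges and take no direct drug input. Both constraints are
enforced structurally (the corresponding entries of `W` and `D` are never
free parameters), not by penalty.

## Numerical integration

Trajectories are computed with Heun's two-stage second-order Runge-Kutta at
a fixed step. Each interval between requested output times is subdivided
into an integer number of equal steps so measurement times are hit exactly.
The default simulation step is 0.01 h, at which 10-node networks drawn from
the synthetic generator agree with an adaptive high-accuracy reference
integrator (`scipy.integrate.solve_ivp`, rtol 1e-10) to a few times 1e-4
max-abs over the full 67 h horizon; the observed convergence order is 2.
Fitting uses a coarser step (0.2 h by default): the loss is defined on — and
differentiated through — that discretization, so the only cost is a
trajectory bias far below measurement noise for decay rates up to ~2/h
(explicit RK2 remains stable for `alpha * h < 2`).

## Loss, gradients and optimization

The training loss is the residual sum of squares over all *measured*
(node, condition, time) entries — the phenotype time grid is sparser than
the molecular one, and normalization can drop samples, so a measured-mask
is threaded through everywhere — plus an L1 penalty `lambda * sum |w_ij|`
on the interactions only.

Minimization is Adam (fixed learning rate 0.01) on all free parameters
`(eps, alpha, W, D, delta)`. Positivity of `eps`, `alpha`, `delta` is
enforced by optimizing their logarithms. Gradients are exact for the
discretized trajectories: a hand-written reverse-mode (discrete-adjoint)
sweep through the RK2 steps, validated against central finite differences
to ~1e-6 relative. The sweep is vectorized over ensemble members — fitting
M models to the same data costs one batched pass, which is purely a speed
device and bit-reproduces sequential fits (tested).

Sparsity comes from per-step cropping rather than soft thresholding: after
every Adam update (past a burn-in of 100 iterations, configurable) entries
with `|w_ij| < 0.01` or `|d_il| < 0.05` are set to exactly zero. The burn-in
exists because the small random initialization (`w, d ~ N(0, 0.1^2)`,
`eps = alpha = 1`, `delta = 0.5`) would otherwise lose a fraction of its
entries to the crop before any signal has propagated. A cropped entry can
re-enter only if a single Adam step pushes it past the threshold (step
magnitudes are ~learning rate, i.e. marginal), so the support essentially
freezes as the fit settles; runs that end with an entirely zero `W` are
flagged failed and discarded, and ensembles replace them with fresh seeds.

## Model selection

The conditions are split into a training set (control plus every
single-drug condition at both doses) and a bisection of the pairwise
combinations into validation and test halves in which every drug occurs
equally often on both sides. The balanced bisection is found by seeded
randomized restarts with greedy pair-swap repair; when exact balance is
impossible (e.g. two drugs and a single pair) the best partition found is
used and flagged.

The regularization strength is scanned on a grid; per value, `n_restarts`
models are fitted on the training conditions and summarized by the
simplified Bayesian information criterion

    BIC = n ln(RSS/n) + k ln(n),

where `k` counts the non-zero parameters (non-zero entries of `W` and `D`
plus all `eps`, `alpha`, `delta`, which are never cropped) and `n` the
training data points. The selected lambda minimizes the BIC (validation RSS
and Pearson r are reported as cross-checks), ties breaking toward the
sparser (larger) value. Held-out evaluation reports per-point RSS and
Pearson correlation overall, for phenotype nodes only, and for configurable
time windows (late time points are where this model class is most
accurate).

## In-silico perturbation screening

A node inhibition is a constant `-c_i` added inside the tanh argument of
the targeted molecular node for all `t >= 0` — an idealized, perfectly
specific step inhibitor; phenotypes cannot be targeted. For each node the
phenotype change at the 72 h horizon is evaluated on a log-spaced dose grid
(default 12 points over [0.01, 100], arbitrary units), averaged over the
model ensemble, and summarized by a Hill curve with zero baseline,

    x(c) = E1 * (1 - 1 / (1 + (c/EC50)^n)),

fit by bounded nonlinear least squares (Hill slope n in [0.2, 8], three
EC50 starting points, two slope starting points). Curves with asymptotic
effect `|E1| < 0.02` log2-units are flagged "no effect" and get no EC50.
On exactly Hill-shaped input the fit recovers (E1, EC50, n) to 1e-6
relative (tested).

The combination screen doses every node at its own fitted EC50, simulates
every unordered pair (plus singles for the diagonal) across the ensemble in
one batched sweep, and reports the ensemble-mean phenotype change as a
symmetric matrix: entry (i, j) equals (j, i) because the dosing rule is
order-free, and both orientations are counted when reporting screen size
(124 nodes x 101 models = 15,252 pair conditions and 1,540,452 responses
per phenotype). Ranking walks the sorted combinations (most negative first
for cell growth, most positive first for apoptosis; lexicographic
tie-break) until 20 distinct nodes (configurable) have been collected.

## RPPA normalization

Raw input is a 4-spot dilution series per (antibody, sample) at fractions
(1/4, 1/2, 3/4, 1) of the loading concentration. The chain:

1. *Spotting-error detection.* Cook's distance of each spot under the
   straight-line fit, cutoff 0.8, single pass; samples with fewer than two
   surviving spots become missing values.
2. *Dilution fit.* Ordinary least squares of intensity on concentration.
   With all four spots the closed-form pseudoinverse is used — intercept
   weights (1, 0.5, 0, -0.5) and slope weights (-6/5, -2/5, 2/5, 6/5)/c —
   which equals a generic least-squares solve to 1e-10 (tested); after spot
   removal a generic solve on the survivors.
3. *RFI.* The fitted line evaluated at 0.625 x the reference concentration
   (0.2 mg/ml), i.e. at the mean of the four dilution points.
4. *Loading correction.* Either double-median normalization of the log2
   matrix (subtract per-antibody medians, then per-sample medians of the
   centered values — afterwards every sample's median over antibodies is
   exactly zero), or division by per-sample median-centered protein factors
   where those were measured.
5. *Replicate medians, control subtraction.* Replicates collapse by the
   median; the control condition's time course is subtracted per node,
   making the control column identically zero.

Two antibody panels measured on the same design merge by union; antibodies
present in both (inter-platform controls) resolve by the mean of the two
panels' values by default. Phenotype counts become
`log2(count / count_DMSO)` on the imaging grid (1, 3, 9, 24, 48, 67 h).

Known limitation: with only four points per series, Cook's distances depend
only on the residual *pattern*, not the outlier's magnitude. An endpoint
outlier flags both endpoints — the refit then passes through the clean
interior spots and repairs the sample exactly — but an *interior* outlier
shifts suspicion to the opposite, high-leverage endpoint, so the refit can
retain the corrupted spot. This is inherent to the published procedure
(cutoff 0.8, one pass) and is reproduced faithfully; the tests pin the
implementation to the textbook leave-one-out computation rather than to an
idealized "the outlier is always caught" expectation.

The double-median operation is likewise *not* idempotent for general
matrices (only its per-sample-median-zero property is guaranteed; already
row- and column-centered matrices pass through unchanged), and the tests
assert exactly that.

## The synthetic study

The generator emulates the structure of the real screen: ~9 drugs applied
singly at low/high dose and pairwise at low dose (54 drug conditions plus
optional DMSO control), 124 + 2 nodes, molecular sampling at 10, 27, 72 min
and 3, 9, 24, 48, 67 h, phenotype sampling at 1, 3, 9, 24, 48, 67 h, and
additive Gaussian noise on the log2 scale (multiplicative on the raw
scale). Ground-truth networks draw `eps, alpha` log-uniform on [0.2, 2]
(relaxation times of half an hour to five hours — numerically tame and
biologically plausible for signaling), interaction magnitudes uniform on
[0.5, 1.5] x `weight_scale` with random signs (comfortably above the crop
thresholds), a configurable molecular edge density, a fixed number of
incoming molecular edges per phenotype, and a fixed number of molecular
targets per drug with mixed signs. The raw-spot-table generator produces
exactly collinear dilution series whose recorded loading is the nominal
concentration while the actual loading varies log-normally — so uneven
loading appears as a per-sample intensity factor, which is precisely what
double-median normalization removes; the full chain round-trips to the
generating values up to exactly computable median offsets (tested).

What the synthetic data do *not* model: antibody cross-reactivity and
off-target drug effects, batch/plate effects beyond loading variation,
saturating detection chemistry, cell-cycle or confluence effects on the
phenotype counts, and model mismatch (the data are generated by the same
ODE family that is fitted). Passing tests therefore demonstrate the
correctness and internal consistency of the machinery, and identifiability
under the study design — not that the tanh-ODE family is an adequate model
of any particular cell line.

## Desk-scale study sizes and the recovery experiment

The shipped tests and the acceptance script run a desk-scale study: 10
molecular + 2 phenotypic nodes, 4 drugs (14 conditions), noise sd 0.05.
For the edge-recovery experiment the generator uses edge density 0.10 and 3
targets per drug, so nearly every node is directly excited — a precondition
for identifiability that the real screen met by choosing its drug panel.
Recovery fits use lambda = 0.05: at this problem size the training RSS at
the true parameters is ~3, so a lambda of 1 or more would dominate the
objective and prune genuine edges. The optimization budget is 10,000
iterations (the production setting); at a fifth of that budget the fits are
demonstrably short of the objective floor. The best of 5 restarts — by the
penalized objective actually minimized — recovers >= 80% of strong-edge
(|w| >= 0.5) signs and reaches the noise-floor training error. Even a fit
initialized at the truth loses a small fraction of edges: with 4 drugs the
excitation is effectively rank-4, and a few true edges are simply not
supported by the achievable data, which is the expected identifiability
limit of this design, not an optimizer defect.

## Defaults at a glance

| Quantity | Default | Unit / note |
| --- | --- | --- |
| Simulation RK2 step | 0.01 | h |
| Fitting RK2 step | 0.2 | h; loss is defined on this grid |
| Learning rate | 0.01 | Adam, fixed |
| Max iterations | 10,000 | per fit |
| Crop thresholds | 0.01 / 0.05 | on w_ij / d_il, each step after burn-in |
| Crop burn-in | 100 | iterations |
| Init scale | 0.1 | sd of w, d initialization |
| Lambda grid | 0..10 step 1 | linear |
| Restarts per lambda | 10 | |
| Production ensemble | 101 | models |
| Screen horizon | 72 | h |
| Dose grid | 12 pts, 0.01-100 | log-spaced, arbitrary units |
| "No effect" threshold | 0.02 | log2-units on E1 |
| Hill slope bounds | 0.2-8 | |
| Cook's cutoff | 0.8 | |
| Reference concentration | 0.2 | mg/ml, RFI at 0.625 x |
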
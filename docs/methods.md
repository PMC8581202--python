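# Methods

## Model

The classifier is a hybrid of a fully connected feed-forward network and
a linear large-margin-distribution SVM (LM_SVM). The network contributes
only hidden layers: it is an *explicit kernel map* φ, and the LM_SVM is
the output layer. This sidesteps kernel selection (the map is learned)
while giving the network a head with better generalization behavior than
a trained softmax/MSE output on small, highly overlapping EEG data.

Forward propagation is a^h = σ(W^h a^{h−1} + b^h) with a^0 = x. The
hidden activation defaults to the logistic sigmoid; relu and identity
are available (identity makes the pretraining loss convex, which the
tests exploit). Backpropagation of the half-squared-error loss follows
the standard recurrences δ^H = (a^H − y) ⊙ σ′(z^H),
δ^h = (W^{h+1})ᵀ δ^{h+1} ⊙ σ′(z^h), with ∂J/∂W^h = δ^h (a^{h−1})ᵀ and
∂J/∂b^h = δ^h. The derivative factor σ′ is applied at every layer
including the output — the only reading consistent with the chain rule.

The LM_SVM augments the L2-slack SVM objective with the (negated) mean
of the functional margins γ̄ = (1/N) Σ yᵢ(φ(xᵢ)ᵀw + b), weighted by
λ ≥ 0:

    min ½‖w‖² + C Σ ξᵢ² − λ γ̄   s.t.  yᵢ(φ(xᵢ)ᵀw + b) ≥ 1 − ξᵢ, ξᵢ ≥ 0.

Only the margin *mean* enters the objective; a margin-variance term is a
possible extension but is deliberately not part of the optimized
criterion. Because the slack penalty is quadratic, the optimal slack is
ξᵢ = max(0, 1 − yᵢ f(xᵢ)) and ξᵢ ≥ 0 never binds, so the constrained
program is equivalent to a smooth unconstrained convex primal. The bias
is not regularized (standard SVM convention).

### Training procedure

Training is staged, since nothing forces the map and head to be learned
jointly:

- **Stage A** — the hidden stack plus a temporary output head is trained
  by full-batch gradient descent on the MSE loss against one-hot class
  targets (column 0 ↔ +1/left, column 1 ↔ −1/right).
- **Stage B** — the temporary head is discarded; all training inputs are
  mapped through the hidden stack and the LM_SVM is fitted on Φ.
- **Stage C** (optional, `joint_finetune`) — additional gradient steps
  on the combined primal, with ∂obj/∂φᵢ = (−2Cξᵢ − λ/N) yᵢ w
  backpropagated through the stack, followed by a re-solve of the head
  at the final map so the stored diagnostics are exact.

Sequential training is the default; joint fine-tuning is off by default
because it adds a step-size knob without changing any tested guarantee
(the unit test asserts it lowers the primal objective). Optional greedy
autoencoder pretraining of the hidden stack is available behind a flag
and off by default; no specific unsupervised scheme is privileged.

### Solver

The unconstrained primal is piecewise quadratic with continuous
gradient. It is minimized by a finite Newton active-set iteration: with
A = {i : yᵢ f(xᵢ) < 1}, the exact minimizer of the current piece solves
(P + 2C M_Aᵀ M_A) θ = 2C M_Aᵀ y_A + (λ/N) Mᵀ y, where θ = (w, b),
M = [Φ, 1] and P zeroes the bias penalty; each step is safeguarded by an
Armijo backtracking line search and the iteration stops at gradient
∞-norm below 1e-10 (typically 2–10 steps). Plain gradient descent with
backtracking was evaluated first and reached the same objective values,
but stalled at gradient norms around 1e-7 while using thousands of
iterations per fit — far too slow for grid searches — so the Newton
iteration is the production path. Two independent cross-checks guard
it: a brute-force constrained QP over (w, b, ξ) solved with scipy's
trust-region interior method (analytic gradient, constant Hessian), and,
for λ = 0 without intercept, liblinear's squared-hinge LinearSVC.

### Degenerate inputs and tie-breaks

- decision score exactly 0 predicts +1 (documented tie-break);
- constant feature columns get scale 1 in the z-score normalizer
  (centered, not divided by zero);
- an odd class count in the half split sends the extra trial to the test
  half, keeping the training half class-balanced;
- grid-search ties are broken by fewer layers, then fewer total units,
  then lower learning rate, then lower λ;
- non-finite training loss aborts with the iteration number;
- single-class training sets are rejected everywhere.

## Parameters

| parameter | default | meaning |
|---|---|---|
| hidden_units | (11, 6) | widths of the map's hidden layers |
| lr | 0.07 | Stage-A gradient-descent step size |
| iters | 2500 | Stage-A full-batch iterations |
| C | 1.0 | slack penalty (no principled prior value exists; exposed in config) |
| λ | 0.1 | margin-mean weight |
| bands | 8–12, 18–26 Hz | mu and beta log band-power features |
| window | 4–9 s | imagery period within the 9-s trial |
| filter | Butterworth order 5, 0.5–30 Hz, forward–backward | zero-phase broadband filter |
| fs | 128 Hz | sampling rate of the trial layout |

The architecture, learning rate, iteration budget and λ defaults are the
operating point selected by the search protocol this package implements
(greedy layer-by-layer width sweep, then lr over 0.05–0.14 in steps of
0.01, then λ over 0.01–100, each cell scored on the held-out half).
Feature extraction itself is a design choice of this package: log
band-power is the standard discriminative statistic for ERD, and a
`flatten` mode (windowed raw samples, decimated) is provided for
experiments that let the network learn features directly.

## Synthetic data

`generate_mi_trials` emulates exactly the structure the classifier must
exploit: each trial is broadband white Gaussian noise (default SD 5 µV)
plus a 10-Hz random-phase sinusoid (default amplitude 10 µV) on every
channel of a C3/Cz/C4 montage; during the 4–9 s imagery window the
amplitude on the hemisphere contralateral to the imagined hand is
multiplied by (1 − erd_depth). Left-hand trials (+1) attenuate C4 and
right-hand trials (−1) attenuate C3, the physiological lateralization.
Defaults — 140 trials per class, 9-s trials at 128 Hz — mirror a
standard cue-paradigm session. ERD depth 0.8 with these amplitudes puts
the class gap in the lateral mu log-power features above 15 pooled SDs,
i.e. a strong, cleanly recoverable signal; erd_depth 0 makes the class
distributions identical by construction.

What the generator does **not** model: volume conduction and channel
correlation, 1/f background spectra (a pink-noise option exists, off by
default to keep the band-power checks analytic), artifacts, ERD latency
jitter and nonstationarity. Passing tests on this data therefore show
that the pipeline recovers a contralateral band-power contrast when one
exists and stays at chance when none does — not that it attains any
particular accuracy on real recordings. The competition trial-layout
loader exists so real data can be substituted, but no result here
depends on it.

## Numerical choices

- Gradient checks use central differences at ε = 1e-5 (balancing
  truncation against roundoff in 64-bit) and norm-wise relative error
  per layer; relu networks are evaluated at inputs whose pre-activations
  are bounded away from the kink, where the comparison is well defined.
- Network initialization is uniform in ±1/√fan-in, seeded; every source
  of randomness in the package flows through explicit integer seeds, and
  all reported metrics are byte-reproducible.
- The accuracy metric is evaluated in exact rational arithmetic
  (`fractions.Fraction`) before float conversion.
- The QP oracle runs trust-constr with gtol 1e-12 on instances up to a
  few hundred samples; it is a test oracle, not a production path.
- Checks that involve the full pipeline use 100 trials per class and the
  default 2500 iterations (seconds per run); solver cross-checks use 20
  random instances with N ≤ 50, d ≤ 5.

## Known limitations

- The staged procedure fixes the map after Stage A; if Stage-A targets
  are uninformative the head can only exploit whatever the random-ish
  map preserves. (This is visible at `iters=0`.)
- The competition `.mat` loader maps by array shape, not by variable
  name, and assumes the published 3-channel / 128-Hz layout; unusual
  containers will be rejected rather than guessed.
- Model selection uses a single stratified half split (a k-fold option
  is provided for users); selection noise on small data is accordingly
  high.
- The margin-variance extension and multi-class operation are out of
  scope; the head is strictly binary with ±1 labels.
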
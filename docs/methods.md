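# Methods

## Problem and overall design

The toolkit implements a hybrid classification method for two-class
medical-image problems (motivated by tumor / no-tumor discrimination on
brain MRI slices): an AlexNet-shaped convolutional stack turns each
227×227×3 image into a 9216-dimensional feature vector, an extreme
learning machine (ELM) classifies those features, and the ELM's hidden
layer is tuned by an amended grasshopper optimization algorithm (AGOA)
rather than by gradient descent.  Because the motivating clinical data is
access-restricted, every experiment here runs on synthetic surrogates
generated by the package itself; what that does and does not demonstrate
is discussed at the end.

## Grasshopper optimization and the amendments

GOA maintains `N` agents in a box `[lb, ub]^D`.  Each iteration, agent
`i`'s new position in dimension `d` is

    x_i^d  <-  c * Σ_{j≠i} [ c (ub_d−lb_d)/2 · s(|x_j^d − x_i^d|) · (x_j^d − x_i^d)/d_ij ]  +  T_d

where `s(r) = f e^{−r/l} − e^{−r}` is the social-force kernel
(attraction at long range, repulsion at short; `f = 0.5`, `l = 1.5`, the
standard values), `d_ij` the Euclidean inter-agent distance, `T` the best
position found so far, and `c` the comfort coefficient, decreasing
linearly from `c_max = 1.0` to `c_min = 0.01` over the `L` iterations.
The comfort coefficient appears twice (outer and inner), exactly as in
the update rule above.  Coincident agents contribute zero to the sum (the
limit convention) rather than raising a division error.  Gravity and wind
force terms exist as optional constants but default to zero, since the
working update rule omits them.  The target is replaced only on strict
improvement, so the best-so-far history is non-increasing by
construction.

AGOA adds two amendments:

* **Singer chaotic streams.**  Three scalars `r1, r2, r3` are iterated
  through the quartic singer map
  `r ← 1.07 (7.9 r − 23.3 r² + 28.7 r³ − 13.3 r⁴)`, advancing once per
  iteration.  `r1` scales the social-interaction sum, `r2` the target
  term, and `r3` supplies the uniform fraction of the quasi-opposition
  draw.  A grid scan of the raw quartic shows it exceeds 1 on roughly 10%
  of the unit interval (max ≈ 1.0093); the safeguard folds excursions
  back via `|v| mod 1`, with an exact 0 remapped to 1e-6 so streams stay
  strictly inside (0,1).  Streams are seeded from the run's RNG, so a run
  is fully determined by its integer seed.
* **Quasi-opposition-based learning (QOBL).**  After the position update,
  each agent `x` is compared against a point drawn uniformly between the
  box centre `m` and the reflected point `lb + ub − x`; the lower-fitness
  member survives (ties keep the original).  Each quasi-opposite
  candidate costs one objective evaluation and `evaluations_used` counts
  it, so budget comparisons between variants are honest.

Whether the streams should advance per-agent or per-iteration is an open
choice; per-iteration was selected as the simplest rule consistent with
"one chaotic sequence per parameter".  The baseline GOA uses the update
rule verbatim with no `r` scalars and no QOBL.

## Benchmark harness

Five standard minimization problems validate the optimizer: sphere (F1),
a shifted quadratic `Σ(x_i+0.5)²` (F2), Schwefel 2.22 (F3), a quartic
with additive uniform[0,1) noise (F4), and Rosenbrock (F5); all have
minimum 0 inside their boxes.  F2 is implemented literally as the
quadratic (minimizer `−0.5·1`), with the classic De Jong floor-step
variant `Σ⌊x_i+0.5⌋²` available by flag since that is the likely intent
behind the printed form; both have minimum 0.  F2's summation runs over
all `n` coordinates (an upper limit of `n−1` would leave the last
coordinate unconstrained), while F5 keeps the pairwise limit `n−1` that
Rosenbrock requires.  The harness runs an optimizer `n_runs` times with
consecutive seeds (default protocol: 35 runs, population 50, 100
iterations) and reports the mean (AVE) and sample standard deviation
(STD, `ddof=1`) of the final best fitnesses.  F4's noise RNG is derived
from the same per-run seed, so even the stochastic benchmark is
bit-reproducible.

The comparison dimension for published summary tables of this protocol
is not stated anywhere, so absolute AVE/STD values are not reproducible
targets; the meaningful, reproducible property is the *ordering* —
amended ≤ baseline — which this package checks at D=10 with 20 paired
seeds on F1, F3 and F5.

## Extreme learning machine and the fitness coupling

The ELM is a single-hidden-layer network: `H = σ(X Wᵀ + b)` with sigmoid
hidden units (L_h = 50 by default at the library level; the image
pipeline uses 20, see below), and output weights solved in closed form as
the minimum-norm least squares solution `β = H† T` via the Moore–Penrose
pseudoinverse, with one-hot targets over the two classes (two output
units, linear output map).  Tied argmax scores resolve to the lowest
class index.

AGOA searches over the flat vector `(vec(W), b)` of length
`L_h·d + L_h`, bounded in `[−1, 1]` per component, minimizing the
training sum of squared errors `Σ_k (D_k − H_k β)²` with `β` recomputed
in closed form inside every evaluation.  The training-SSE fitness is the
literal objective; an optional validation-split mode exists but is off by
default.  The hidden-node count is treated as a fixed hyperparameter, not
searched (tuning it is a possible extension).  A plain ELM baseline — a
single random `(W, b)` draw from the same box plus the closed-form `β` —
is provided for paired comparisons.

## Feature extraction

Preprocessing resizes any PNG/JPEG to 227×227 (bilinear), replicates
grayscale to three channels, and scales to [0,1].  The convolutional
stack follows the AlexNet geometry exactly:

    conv 96@11×11 s4 → pool 3×3 s2 → conv 256@5×5 p2 → pool
    → conv 384@3×3 p1 → conv 384@3×3 p1 → conv 256@3×3 p1 → pool
    → flatten: 6·6·256 = 9216

Each convolution is followed by batch normalization and ReLU.  The
first layer uses padding 0: a padding of 2 with stride 4 cannot produce
the documented 55×55×96 output ((227−11+4)/4+1 is not an integer), so the
shape table wins.  Pool hyperparameters (3×3, stride 2) are the standard
AlexNet values forced by the printed shape chain.

No filters are trained.  Defaults are seeded random tensors with
unit-norm rows, making the stack a structured random projection that
preserves the architecture's receptive-field geometry; externally
computed filter tensors can be plugged in.  Batch normalization is the
mini-batch transform `y = a + b·(z − mean)/sqrt(var + ε)` with the biased
(1/N) variance; at inference each channel map is normalized with its own
per-image statistics, since there is no training phase to accumulate
running averages (defaults `a = 0`, `b = 1`, `ε = 1e−5`).  Gradient-based
training knobs (learning rate, epochs, softmax head) have no referent in
this closed-form design and are deliberately absent.

## Metrics

Eight indicators derive from the binary confusion counts: accuracy,
sensitivity, specificity, precision (≡ PPV), F1, MCC, PPV and NPV, all on
the 0–1 scale with an optional percent flag.  MCC uses the standard
Matthews form `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` — the
only form bounded in [−1, 1].  A zero denominator makes that metric
undefined: it is reported as NaN in memory and `null` in JSON, never
silently 0, and never aborts the rest of the report.

## Synthetic data

Two generators stand in for the restricted clinical images:

* **Feature clusters**: two isotropic unit-variance Gaussians in `d`
  dimensions with means `class_separation` standard deviations apart
  along a random unit direction.  At separation `s`, the Bayes error of
  the optimal projection is `Φ(−s/2)` — separation 6 gives ≈0.13% error,
  which is what the separability tests exploit.
* **Head phantoms**: a mid-gray ellipse ("head", intensity 0.45) on a
  dark background (0.05) with additive Gaussian pixel noise; positive
  images add one bright ellipsoidal blob (radius 10–22 px, intensity lift
  +0.35 by default) placed uniformly within the inner 60% of the head so
  resizing never clips it.  The "easy" configuration used by the
  end-to-end study raises the lift to 0.45 and lowers the noise to 0.02.

Splitting is stratified by label (80/20 by default, mirroring the
motivating study's ≈80% training share); stratification keeps metrics
stable on small synthetic sets.  All generators are bit-reproducible
under a fixed seed.

These surrogates contain a single, localized intensity signal and no MRI
physics, multi-modality structure, partial-volume effects, or anatomical
variability.  Passing the end-to-end tests therefore demonstrates that
the pipeline is wired correctly and that the optimizer genuinely improves
the classifier on a learnable signal — not that the method reaches any
particular accuracy on clinical MRI.

## Pipeline problem sizes and numerical choices

The end-to-end study uses 200 phantom images (100 per class), an 80/20
stratified split, and an AGOA-ELM head with 20 hidden units, swarm size
10, and 20 iterations — sizes chosen so the full study runs in about a
minute on a single core while leaving the optimizer enough budget to
dominate the one-draw baseline.  Features are standardized with training
statistics and scaled by `1/√d` so hidden pre-activations `w·x + b` stay
O(1) for box-bounded weights and the sigmoid units remain responsive;
without the rescaling, a 9216-dimensional dot product saturates every
hidden unit.  The benchmark-validation defaults (35 runs, population 50,
100 iterations) match the stated protocol; the acceptance study's paired
comparison uses 20 seeds at D=10.

Other numerical conventions: non-finite objective values are recorded as
+∞ and the run continues; the positions are clamped to the box after
every update; constant feature columns get unit scale during
standardization; model serialization is JSON metadata plus an `.npz`
array sidecar.

## Known limitations

* The convolutional filters are random projections, not learned
  representations; absolute accuracies on real images would differ.
* AGOA's advantage over baseline GOA on the raw (non-normalized-distance)
  update rule is dominated by the QOBL step: at benchmark-scale boxes the
  social kernel is nearly zero at typical inter-agent distances, so the
  baseline stalls near its best initial sample. This mirrors the
  documented premature-convergence weakness the amendments target.
* The quasi-opposition fraction in AGOA is one scalar per iteration
  (shared across agents and dimensions); an independent-per-component
  chaotic draw is a reasonable alternative not explored here.
* Published absolute accuracy figures on the restricted clinical dataset
  are out of scope by design; only orderings and synthetic-data
  quantities are reproduced.
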
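# Methods

## Model

The package models the *C. elegans* premotor circuit as a driven dynamical
system: a recurrent core of n premotor interneurons whose GCaMP z-scores
x_1..x_n obey

    τ dx_i/dt = f(x_i) + d_i + β Σ_j W_ij (x_j − x_i) + Σ_j A_ij σ(x_j),

driven by m signal neurons whose traces enter the sums as data, not as
state. The intrinsic cubic f(x) = −2 (x + 0.8)(x − 0.1)(x − 1) gives every
neuron Schmitt-trigger bistability (stable rest at −0.8, stable plateau at
1, unstable threshold at 0.1) with saturation at large |x|; the per-neuron
bias d_i tilts or removes one stable state. In voltage units the analogous
cubic for the RMD neuron, dV/dt = −(1/8000)(V + 70)(V + 60)(V + 50), has
stable fixed points near −70 and −50 mV and an unstable point at −60 mV.
Gap junctions act diffusively with symmetric nonnegative weights W (taken
from a connectome edge table, unnormalized); chemical synapses act through
the rectifier σ = ReLU with signed weights A restricted to the connectome's
synapse support — a hyperpolarized neuron exerts no synaptic influence.
There are no recovery variables: these neurons do not spike, and a stable
high state is a feature, not an artifact.

Modeling choices that the data do not pin down, resolved here:

* The ReLU is applied uniformly to core and signal presynaptic activity
  (the synaptic sum runs over both), and signal neurons contribute
  gap-junction input through the same W rows as synaptic input.
* Gap-junction weights are consumed as the connectome's raw relative
  values; no normalization is applied.
* Roots of the cubic closer than 1e−8 are merged and classified
  semi-stable; stability elsewhere is the sign of f′ at the root.

## Parameter inference

With τ fixed to 1 during fitting, the ODE rearranges per core neuron i into
a linear regression: the response at each time sample is
dx_i/dt + 2(x_i + 0.8)(x_i − 0.1)(x_i − 1) − β Σ_j W_ij (x_j − x_i), the
predictors are σ(x_j) for every presynaptic j on the support plus an
intercept for d_i, solved by ordinary least squares. Every time sample at
which all required traces are observed contributes one row; no subsampling.
Derivatives are second-order central differences by default (one-sided at
the ends); a Savitzky–Golay variant is available but off by default so that
supplying exact derivatives makes the noiseless recovery an algebraic
identity. A presynaptic trace that never depolarizes within a dataset gives
an identically-zero column; its coefficient is marked inestimable (NaN)
there and excluded from cross-dataset averaging for that entry. Rank
deficiency falls back to the minimum-norm solution and is flagged per
neuron.

β is chosen by a grid sweep minimizing the mean hybrid error
`error_hybrid = error_regress + 0.05 · error_deriv` over datasets (ties
toward smaller β). `error_regress` pools the L2 norms of the regression
residuals over core neurons; `error_deriv` pools the L2 norm of the data
derivative minus the full reconstructed rate on the observed traces. When
both are evaluated on the same sample rows these two are algebraically
identical; they diverge only when rows are dropped from a regression
(missing traces), which is why both are tracked. The 0.05 weight is fixed
but exposed in configuration.

Dataset selection requires at least one paired forward-cluster neuron
(AVBL/AVBR/RIBL/RIBR), one member of every reversal class, and one AVD
neuron. Missing left/right homologs are proxied by their partner when the
pair's mean correlation across datasets reaches 0.7; substitutions are
logged. Dataset averaging is the entrywise mean over fits in which each
entry was estimable.

τ is calibrated after the regression by simulating each dataset's core
response on a τ grid and matching the behavioral switching rate
(state transitions per minute of the classified strip) to the data's; the
paper-level notion of "switching at the same speed" is operationalized as
this rate because it is well-defined on any strip and monotone in τ.
The synaptic magnification factor (default 1.4) is applied only at
simulation time, to compensate for signal neurons missing from a given
dataset; it is never applied during fitting, and the synthetic generator
defaults it to 1 because synthetic corpora are complete.

## Simulation

Integration uses an adaptive embedded Runge–Kutta 4(5) scheme with relative
tolerance 1e−8 and absolute tolerance 1e−10 by default. Signal traces are
interpolated piecewise linearly and queries outside their coverage are
errors; because the drive is only piecewise smooth, the solver's step size
is capped at the signal sampling interval so local error estimates remain
valid across kinks. The default initial condition places every core neuron
at the resting mode −0.8.

Stimulation (for propagation maps) is an additive current entering like the
bias term, default amplitude 2.0 — chosen so a disconnected bistable neuron
is pushed across its threshold — over a 5-minute window, starting from the
baseline fixed point of the undriven system (integrated until the
vector-field norm is below 1e−8; non-settling states raise an error rather
than returning a bogus "steady state"). The propagation map records each
target's activity at the end of the stimulation window minus its baseline.
Ablation of a core class zeroes every synaptic and gap-junction entry
linking its members to the rest of the network, in both directions,
retaining intrinsic dynamics.

## Behavior

F(t) and R(t) are the unweighted forward- (N=5) and reversal- (N=8) cluster
means; z = F − R classifies each sample as F (z > 0.5), R (z < −0.5) or P.
Two smoothing rules apply in order: forward/reversal bouts shorter than 2 s
flanked by pause become pause; pauses shorter than 5 s flanked by the same
locomotion state take that state. A short pause between different
locomotion states is left unchanged (there is no single enclosing state),
and boundary intervals are never relabeled. Classification is reported
unsmoothed unless smoothing is requested. Dwell histograms use 0.1-minute
bins and drop intervals shorter than 0.05 minutes.

## Influence ranking

A signal neuron's score for a (target cluster, direction) pair accumulates
A_ij · σ(x_j) · dt over the cluster members i and the 10 s preceding each
switch into the relevant state (to-forward for forward promoters and
reversal suppressors; to-reversal otherwise). Scores are totals over
switches (a per-switch average is available); multiplying by the sampling
interval makes the score a discrete time integral, invariant to resampling
density. Gap junctions are excluded — the ranking concerns synaptic
influence. The window length is a free choice, reported in all outputs.
Knockouts re-simulate with the named traces zeroed and report occupancy
changes.

## Locomotion paths

Forward intervals advance at 0.15 mm/s along the heading; reversals retrace
at 0.075 mm/s along the reversed heading (straight-line retrace — the
curvature of real reversals is not modeled); pauses are stationary. A turn
is drawn only when forward motion resumes immediately after a reversal:
regular with probability 0.65 (uniform −90°..90°) or omega with probability
0.35 (magnitude uniform 90°..270°, signed by a fair coin since the printed
range is unsigned). Initial heading is east from the origin. Total path
length is exactly forward_speed·T_F + reversal_speed·T_R by construction.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
any particular recording:

* **Connectome**: symmetric nonnegative gap weights (gamma-distributed,
  density 0.3 within the core, half that for signal–core pairs) and a
  Bernoulli synapse mask without self-synapses.
* **Ground truth**: synaptic magnitudes gamma-distributed around 0.4 with
  signs drawn per block (within-cluster excitatory, cross-cluster
  inhibitory, alternating signal groups promoting forward or reversal);
  biases N(0, 0.1).
* **Signals**: per-neuron Ornstein–Uhlenbeck latents (stationary sd 1.5,
  correlation time 0.5 min) mixed with a shared group driver (weight 0.8)
  and mapped through 0.1 + 0.9·tanh(·), which yields smooth traces with
  bimodal marginals peaked near −0.8 and 1 and within-group correlations
  above 0.7. The real data constrain only this marginal shape; the
  generative law itself is a package choice.
* **Datasets**: the core response is integrated from the generated signals
  under the ground truth (tight tolerances, 1e−10/1e−12) and additive white
  Gaussian observation noise (default sd 0.05) is applied to the core rows.
  The exact model rates along the noiseless solution are emitted alongside,
  which is what makes the exact-recovery identity testable.

Defaults mirror the real study's scale (15 core, 112 signal neurons,
12-minute recordings at 0.01-minute sampling); the test suite uses smaller
networks (3–4 core, 8–12 signal neurons, 1200–5000 samples) so the whole
suite runs in minutes on one CPU. Identifiability checks generate at τ = 1,
matching the regression's convention, so that recovery is exact rather than
rescaled; the τ-calibration check generates at τ = 0.2 with a strongly
driven network whose switching rate discriminates the grid. What passing
these tests shows is that the inference and analyses are correct under the
model's own assumptions — not that real imaging data satisfy those
assumptions (real noise is not white, real missingness is not random, and
real neurons are not exactly cubic).

## Known limitations

* Recurrent feedback from core to signal neurons, motor-neuron feedback,
  and polysynaptic pathways through unmodeled neurons are absent; functional
  relationships in the model can therefore be sharper than in experimental
  propagation maps.
* error_deriv adds information over error_regress only in the presence of
  missing data (see above).
* The regression is unregularized; strongly collinear presynaptic traces
  (e.g. perfectly synchronized homologs) make individual weights poorly
  determined even when their sum is well determined.
* The behavior classifier knows only F/R/P; turns and quiescence are out of
  scope, and the path simulator imposes a stylized run–reverse–turn cycle.
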
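# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not
demonstrate.

## Recording model

A recording is a 1 Hz multichannel series with integer-second
timestamps, a per-measurement beverage label (0–4, or −1 for
wash/transfer rows that are discarded before sampling), and
session/cycle metadata. Timestamps may have gaps where invalid
measurements were removed; downstream stages treat the stored row
sequence as contiguous, accepting the implicit discontinuities. Cycle
ids group consecutive segments until all five beverages have been seen;
a cycle is *complete* when it contains all five.

## Synthetic generator

The generator produces the study conditions for all experiments. Its
signal model per channel k and segment of beverage b is

    x(t) = μ_s(b, k) + settling + drift + noise

* **Offsets** μ(b, k) dominate the signal (the hallmark of
  electrochemical beverage data): hand-set per beverage/channel so the
  two wines are similar on most channels, carbonation raises
  conductivity for sparkling water and cava, and cava shares features of
  both groups. Temperature and the nitrate ISFET are near-constant
  across beverages relative to their noise, making them the two
  least-informative channels by construction.
* **Settling**: first-order exponential approach to the new segment's
  offset with time constant `transition_tau` = 20 s (typical of
  ion-selective membranes after a transfer), continuous across segments
  and washes.
* **Drift**: a per-channel linear trend (random sign, magnitudes of
  order 2 mV/h on ISFETs) plus a Gaussian random walk; charge-buildup
  drift has no agreed functional form, so a trend+walk is the simplest
  model with both deterministic and stochastic components. Magnitudes
  are set so drift is visible against noise over a two-hour session but
  does not overwhelm the class structure.
* **Noise**: i.i.d. Gaussian per channel, in channel units (e.g. 1 mV on
  ISFETs, 0.02 mS/cm on conductivity); wash periods get 3× the SD and
  label −1 with a distinct low-ion offset vector (deionized water).
* **Sessions**: each session redraws a common per-channel offset shift;
  sessions 2 and 3 additionally *replace* sensors (Na⁺/Cl⁻/Ca²⁺, then
  pH/Cl⁻), redrawing offset and gain of those channels. This is what
  forces per-session normalization.
* **Transitions**: the beverage order is an Eulerian circuit on the
  complete digraph K₅ (seed-permuted), so every ordered pair of
  beverages occurs as a transition — 20 transitions, 21 segments of
  300 s separated by 30 s washes per session; three sessions ≈ 21 k
  measurements, comparable to a multiday lab campaign.

**What the generator does not emulate**: electrochemical first
principles (Nernstian slopes, membrane kinetics, cross-sensitivity
matrices), temperature coupling into other channels, correlated noise,
or realistic failure modes beyond offset/gain replacement. Passing
results on synthetic data therefore demonstrate the *pipeline's*
correctness and the conversion's fidelity, not field performance on real
beverages.

For sensor-importance recovery experiments, a variant config flattens
one channel's offsets entirely (pure noise + drift). Because the default
array deliberately contains *two* nearly uninformative channels, the
recovery experiment strengthens the nitrate channel's offsets so the
planted channel is the unique ground truth for "least informative".

## Preprocessing

Order per session: cycle balancing → high-pass → outlier gate →
quantile map. Sessions are processed independently and concatenated.

* **Balancing**: cycles missing any beverage are dropped whole; segments
  longer than 300 s are truncated to their first 300 s; −1 rows dropped.
* **Filter**: H(s) = s/(s + 2π f_p), f_p = 0.5 mHz (time constant
  ≈ 318 s), discretized by the bilinear transform (exact unity gain at
  Nyquist, stable pole mapping; frequency warping is negligible at
  f ≪ f_s). State is initialized at steady state for the first sample of
  each session, so constant input maps to exactly zero with no startup
  transient. Filtering runs over the stored row sequence after row
  removal; discontinuities at removed gaps are accepted.
* **Outlier gate**: per-channel mean and *population* SD (ddof = 0) on
  training rows; a row is dropped iff any channel is strictly further
  than 4 SD from its mean ("further than" read strictly, so the boundary
  value is retained).
* **Quantile normalization**: the map "Gaussianize, then squash through
  the normal CDF" composes to the empirical CDF, which is what is stored:
  1000 reference quantiles with linear interpolation between them and
  clipping outside the training range (the only bounded choice for [0,1]
  output). Training data maps to a uniform distribution; monotonicity
  and hence rank order are preserved.

Leakage discipline: the hold-out is the last complete cycle of the final
session; because the filter is causal and the hold-out is chronologically
last, an audit test verifies that perturbing held-out rows changes no
fitted statistic.

## Windowing and split

A sample is T consecutive stored rows (default T = 16, i.e. 16 s)
ending at t_i, with stride 1; windows containing more than one label are
discarded, and the window's label is its latest row's. Windows never
span session boundaries. Windows whose end row falls in the final
session's last complete cycle form the test set; consecutive segments
always change beverage, so no window can straddle the cycle boundary.

## CNN

Three causal 1-D conv layers (kernel 4, 32 kernels, ReLU, left zero
padding preserving length T) and a dense softmax head on the flattened
T×32 output; no biases and no normalization layers anywhere, because
both distort rate-based spiking conversion. For N = 7 input channels and
T = 16 this is 11,648 weights. The flatten head is the minimal reading
of a "fully-connected softmax stage"; multi-layer heads are deliberately
out of scope.

No maintained deep-learning framework is part of this package's
dependency set; the forward/backward pass is written directly on im2col
matrices (all heavy operations are BLAS matmuls) and verified against
finite differences. Training uses a bounded-adaptive optimizer:
Adam-style moment estimates whose per-parameter step size is clipped
into [final_lr·(1 − 1/(γt+1)), final_lr·(1 + 1/(γt))], so it behaves
adaptively early and anneals toward SGD at `final_lr`. Defaults: initial
rate 10⁻³, final rate 0.1, γ = 10⁻³, global gradient-norm clip 1.0,
L2 10⁻⁴, batch 128. The canonical epoch budget is 1,500 (no
normalization layers means slow convergence on hard data); the synthetic
experiments converge far earlier, so the packaged experiments and the
acceptance script train for 200 epochs — a problem-size choice, recorded
here as such. Training is deterministic given the seed; ensembles train
five seeds and report mean ± SD.

## Spiking conversion and simulation

* **Scales**: λ_l = 99th percentile of the pooled training activation
  distribution of conv layer l; the input scale is fixed at 1 because
  quantile normalization already bounds inputs to [0, 1] (avoids double
  scaling). The percentile (not the max) makes the scale robust to a few
  extreme activations.
* **Weights**: W′_l = W_l·λ_{l−1}/λ_l; thresholds 1 everywhere;
  connectivity identical to the CNN. The output head is a non-spiking
  accumulator with weights multiplied by λ_last.
* **Dynamics**: synchronous clock-driven steps. Input neurons integrate
  their constant normalized value as a bias current; hidden neurons
  integrate weighted spikes from the previous layer *within the same
  step*; V ≥ 1 emits one spike (at most one per neuron per step) and
  resets by subtraction, preserving residual charge. After `n_steps`
  (default 50) the prediction is the argmax of the output accumulator —
  identical to argmax of spike rates or softmax, since all are monotone
  in the potentials; numpy's argmax breaks ties toward the lowest label.
* **Exactness**: for constant drive c and threshold θ the spike count
  from V₀ = 0 after n steps is exactly ⌊nc/θ⌋ (saturating at n); the
  test suite checks this on binary-fraction grids where float
  accumulation is exact. For one layer, |rate·λ − clipped activation| is
  O(λ/n_steps).
* **Energy proxy**: hardware power is out of scope; instead the
  simulator counts synaptic operations (each spike costs its neuron's
  fan-out; input bias integrations counted separately) against the MAC
  count of one dense CNN forward pass (zero-padded positions included,
  as a dense implementation would compute them). On synthetic data the
  50-step SNN performs *more* raw operations than one ANN pass — the
  neuromorphic advantage lies in the relative cost of an additive
  synaptic event vs a MAC on the respective hardware, which this proxy
  deliberately does not model.
* An optional 8-bit fixed-point weight quantization switch probes the
  accumulation of discretization errors; it is off by default.

## Baselines

* **k-NN**: Euclidean distance on flattened preprocessed windows (the
  same inputs the CNN sees — the minimal consistent feature choice).
  Implemented directly (cdist + stable argsort) so the declared tie
  rules are guaranteed: distance ties → lower training index, vote ties
  → lowest label; verified against an exhaustive oracle. The sweep grid
  is odd k on a logarithmic grid up to n_train; a literal "up to
  2·n_train" sweep is impossible since k ≤ n_train.
* **Random forest**: scikit-learn, 1,000 trees, Gini impurity, fitted on
  single preprocessed measurements (one feature per sensor) so exactly
  one normalized importance per channel results. Preprocessed rather
  than raw rows are used because raw per-session offsets would let the
  forest key on session identity rather than beverage chemistry.
  Rankings are stable across seeds on well-separated data; the top-7
  selection drops the two least informative channels.

## Evaluation

Macro accuracy = mean of per-class accuracies (diagonal fractions of the
confusion matrix), robust to the mild class imbalance left by cycle
balancing. Delay curves make a prediction at every step from beverage
onset; the first possible prediction uses the window ending at delay
T − 1 (the onset convention is a package choice), and per-step
accuracies are binned into 10-step means. The window-length sweep
retrains from scratch per length and reports mean ± SD over seeds,
plus surviving sample counts (longer windows discard more).

## Problem sizes

The packaged experiments use the default generator (3 sessions,
~21 k measurements, ~13 k after balancing, ~12 k windows), 200 training
epochs, 50 simulation steps, and 1,000-tree forests; the
sensor-recovery experiment uses single-session datasets over five
seeds. These sizes are the package's reference configuration for
reproducible desk-scale runs.

## Known limitations

* The synthetic generator's realism caveats above; no claim is made
  about accuracy on real beverage recordings.
* The external-deposit adapter handles flat wide-table dumps via column
  aliases only; other layouts must be converted upstream.
* The simulator is synchronous and unpartitioned; asynchronous
  multi-core neuromorphic execution, compartment mapping and hardware
  quantization pipelines are out of scope.
* No recurrent or multi-head classifier variants; no data augmentation;
  no random train/test sampling mode (chronological splits only, to
  avoid overlap leakage).
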
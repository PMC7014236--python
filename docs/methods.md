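# Methods

## Neuron model and integration

Neurons are two-variable quadratic (Izhikevich-type) point neurons,

    dv/dt = 0.04 v² + 5 v + 140 − u + I,
    du/dt = a (b v − u),     spike when v ≥ 30 mV, then v ← c, u ← u + d,

with the canonical regular-spiking set (a = 0.02, b = 0.2, c = −65, d = 8)
for excitatory neurons and fast-spiking (a = 0.1, b = 0.2, c = −65, d = 2)
for inhibitory neurons; all parameters are per-neuron configurable. Forward
Euler with dt = 0.5 ms is the default grid; the membrane update is split
into two half-steps per step for stability (the recovery variable advances
once). Spike detection and reset happen on step entry: a neuron whose v
crossed threshold during the previous step is reset and skips integration
for that step, so the spike time is quantized upward by at most dt. Halving
dt changes the spike count of a 1 s tonic-firing run by at most one spike,
and the default grid stays within ±1 spike/s of a dt = 0.01 ms reference
(asserted in the test suite). |v| > 10³ mV or any non-finite state aborts
the run with a diagnostic.

The driving current is I = ξ + I_syn + I_stml. The noise term ξ is an
independent Normal(0, D) draw **per integration step** — the variance is
deliberately not rescaled by dt, so a stated variance (e.g. the rest
detector's D = 70) has exactly one meaning on the default grid; changing dt
changes the effective noise power, which is documented rather than hidden.

## Synapses, traces, and event ordering

Synapses are current-based: I_syn(i) = Σⱼ gⱼ wⱼᵢ yⱼ with gⱼ = +2/−2 fixed by
the presynaptic neuron's type and yⱼ the synaptic-output trace. Every trace
follows dy/dt = −y/τ plus a unit jump at each spike of its source neuron,
integrated with exact exponential decay factors per step. Four traces are
kept per neuron: synaptic output (τ = 100 ms), fast plasticity trace y¹
(τ₁ = 10 ms), slow plasticity trace y² (τ₂ = 100 ms), and the averaged
activity trace y_avg (τₒ = 100 ms).

Per step the order is: spike detection/reset → trace decay → LTD then LTP
(both reading post-decay, pre-increment traces) → forgetting → trace
increments of the spiking neurons → current assembly → membrane update. The
pre-increment read matters: a spike must pair with traces left by *earlier*
spikes, otherwise every postsynaptic spike would potentiate itself through
its own slow trace. Simultaneous pre- and postsynaptic spikes in one step
apply LTD first, then LTP — a deterministic tie-break. With these
conventions the stepped updates reproduce the closed-form trace products
exactly for grid-aligned spike times (off-grid times converge at O(dt)); an
event-driven replay (`plasticity.replay_events`) provides the exact
reference for arbitrary times.

## Learning rules

With multiplicative soft bounds F⁺(w) = λ(1−w), F⁻(w) = λαw (λ = 0.001,
α = 1):

* pair LTP at a post spike: Δw = F⁺(w)·y¹_pre;
* pair LTD at a pre spike: Δw = −F⁻(w)·y¹_post;
* triplet LTP at a post spike: Δw = F⁺(w)·y¹_pre·y²_post (minimal triplet
  rule — LTD stays pair-based);
* forgetting: dw/dt = −w·y_avg/τ_f, integrated every step as
  w ← w·exp(−y_avg·dt/τ_f).

The bounds plus the forgetting sign keep plastic weights in [0, 1] under any
spike sequence (property-tested). Non-plastic weights are constants and are
not restricted to [0, 1] (lateral-inhibition strengths above 1 are used).

### Calibration of the forgetting time τ_f

τ_f sets the synaptic-competition strength and must be matched to the
learning rate and to the protocol's timescale. A mean-field balance makes
the constraint explicit: a synapse driven at presynaptic rate r onto a
neuron firing at rate R equilibrates near

    w* ≈ LTP / (LTP + F),   LTP ≈ λ·ȳ¹(r)·ȳ²(R)·R,   F ≈ ȳ_avg(R)·1000/τ_f  [1/s]

so the crossover of the weight–rate sigmoid sits where λ·ȳ¹(r)·R·τ_f/1000 ≈ 1.
A τ_f on the order of the trace time constants (tens of ms) would make F
exceed LTP by several orders of magnitude and drive every weight to zero
regardless of rate (verified by simulation); competition only functions when
forgetting operates on the λ-scale of potentiation. Two presets follow:

* **Single-neuron rate coding** (1000 s protocol, rates 0.1–50 Hz):
  τ_f = 10⁶ ms puts the sigmoid crossover mid-range; low-rate weights decay
  toward ~0.1 while high-rate weights are sustained.
* **EMG classifier** (one-minute online training, sensory rates ~50–80 Hz):
  τ_f = 2×10⁴ ms, so a classifier's unused inputs decay substantially within
  a few gesture presentations — the differentiation must complete ~50×
  faster than in the 1000 s protocol.

## Stimulation

External drive is delivered through stimulators bound to neurons:
rectangular pulses (2 ms, amplitude 40 by default — suprathreshold for the
regular-spiking neuron even with an elevated recovery variable, giving 1:1
entrainment on periodic trains up to 50 Hz without double-firing from rest)
or continuous sampled currents (zero-order hold). Temporal patterns fire
stimulator j at offset (j−1)·Δt within each 1 Hz repetition cycle; rate
patterns are Poisson trains with a 5 ms refractory floor (the exponential
part is rescaled so the mean rate is exact); the supervised "teacher" is a
periodic 40 Hz train confined to labelled gesture intervals. EMG drive is
full-wave rectified and scaled, I = k·|EMG| with k = 2×10⁶ — raw surface
EMG is zero-mean, so signed injection would cancel on average.

## Single-neuron coding protocols

Ten presynaptic neurons project through plastic synapses onto one
postsynaptic neuron; each presynaptic neuron is driven 1:1 by a stimulator.
Training lasts 1000 s (default); evaluation presents the familiar and
unknown test patterns for 30 s each with learning frozen, and the response
is the postsynaptic spike count divided by the window.

Initial weights are a protocol-level choice the data do not fix, and the two
protocols probe different things:

* **Temporal coding** starts fully potentiated (w = 1). The repeating pulse
  sequence must initially fire the neuron *within* the sequence so that
  after-spike refractoriness can depress the couplings ranked behind the
  spike; from a mid-range start the first response occurs after the whole
  (≤ 50 ms) pattern and no rank structure can form at Δt ≤ 2 ms. With the
  potentiated start, trained weights decrease with spike rank at short
  intervals (Spearman ρ ≈ −0.6 … −0.8 for both pair and triplet rules) and
  alternate at Δt = 10 ms.
* **Rate coding** starts at w = 0.5, near the pair-rule equilibrium, so the
  steady-state weight–rate relation is measured without the large downward
  transient a saturated start superimposes. Pair or triplet STDP alone
  produces no selectivity (familiar/reversed response ratio ≈ 1.1–1.4) and
  an almost flat weight profile; triplet STDP with forgetting produces a
  monotone sigmoid (ρ ≈ 1.0) and a familiar response tens of times the
  reversed-pattern response.

Two quantitative limitations of these protocols, both stable across the
broad parameter ranges we scanned (initial weights 0.2–1.0, postsynaptic
adaptation d 8–20, noise 0–1, pulse shapes), are worth stating plainly.
First, in temporal coding the *rate* contrast between familiar and unknown
half-patterns saturates near 1: with τ = 100 ms synaptic traces, five
depressed synapses still deliver a transient above the quadratic neuron's
firing cliff, so the unknown half keeps evoking one (late) spike per
presentation — the discrimination lives in the ~20 ms response-latency
difference and in the weight structure rather than in the spike count.
Second, under plain pair/triplet STDP the trained weights retain a small but
consistent monotone trend with presynaptic rate (range < 0.1 across a 500×
rate span, driven by the causal pre→post correlation term), so a rank
correlation reads high even though the weight *magnitudes* are flat and no
behavioural selectivity exists.

## EMG classifier network

Input layer: one excitatory sensory neuron per channel, each with a
fast-spiking inhibitory partner; each partner inhibits all *other* sensory
neurons (fixed w = 0.5; its own driver excites it at w = 1) — classic
lateral inhibition that contrasts the channel pattern. A rest-detector
neuron (D = 70) receives strong fixed inhibition (w = 4) from every partner
and a constant bias current (default 160) so that, uninhibited, it fires
~270 Hz: its single plastic synapse must carry drive comparable to the
three-channel gesture groups, and mean-zero noise alone cannot fire an
Izhikevich neuron hot enough for its association to survive the synaptic
competition. During any gesture the partner inhibition silences it
(< ~1 Hz residual at gesture transitions). Sensory and classifier neurons
carry moderate noise (D = 5): a classifier whose rest-detector weight eroded
during the early contested phase can still fire occasionally at rest and
relearn the association — without this escape route the rest class can end
in a silent state where neither potentiation nor forgetting acts.

Output layer: n_classes excitatory classifiers, each exciting a fast-spiking
partner (w = 1) that inhibits the *other* classifiers (w = 4, winner-take-
all; only the momentary winner keeps firing, hence only it learns). All
sensory-layer excitatory neurons and the rest detector project to every
classifier through plastic triplet+forgetting synapses initialized uniformly
on [0.5, 1.0] — a high start ensures every input pathway (including the
rest detector's) can fire some classifier before any association exists,
and the spread breaks ties; losers' unused weights then forget downward.

Training is online: the raw synthetic recording (~63 s of alternating
rest/flexion/extension, 3 s each) drives the sensory layer with learning
active throughout. Unsupervised learning uses no label information; the
supervised variant adds the 40 Hz teacher to the mapped classifier during
each labelled segment (learning stays on between stimuli). Labels enter the
unsupervised pipeline only afterwards: a frozen run on a held-out labelled
recording yields the response matrix, the gesture→classifier assignment is
the permutation maximizing the summed own-class rates (exhaustive over n!;
an all-zero matrix is flagged degenerate and assigned deterministically),
and accuracy per gesture is the assigned classifier's rate divided by all
classifiers' summed rate, duration-weighted overall. Samples within a
configurable window after a label change can be excluded (errors concentrate
at movement changes); the default excludes nothing.

On the default synthetic conditions (checked over twenty seeds),
unsupervised training yields three distinct winners in 20/20 seeds with
median accuracy ≈ 0.96 (minimum 0.92); supervised training binds every
target in 20/20 seeds with median accuracy ≈ 0.97, strictly above the
unsupervised median. The winning classifier's rate is linear in the
recording's mean absolute value across effort levels (Pearson r ≈ 0.95–0.99,
monotone; the lowest effort level sits near the response threshold), and
the learned per-channel weights correlate with the per-channel mean
rectified amplitude at r ≥ 0.95 for both movement gestures.

## Synthetic EMG generator

Each channel is unit-RMS Gaussian noise band-passed to 20–95 Hz (4th-order
Butterworth, zero-phase) at fs = 200 Hz, multiplied by the envelope
`baseline + effort · channel_weight · max_amplitude`. Default profiles:
flexion dominant on channels 1–3, extension on channels 5–7, each with a
weak secondary channel; the profiles' cosine similarity is < 0.3. The
default max_amplitude = 4×10⁻⁵ V was chosen so that, through the k = 2×10⁶
scaling, full-effort gestures drive sensory neurons at ~50–80 Hz — the
regime in which one-minute competitive learning at λ = 0.001 can form and
hold associations. Segment boundaries are blended with a 150 ms raised
cosine (instantaneous envelope steps are non-physiological and would
overstate transition errors). MAV of a segment is therefore affine in
effort, which is what makes the gradual-response linearity testable
end-to-end.

What the generator does **not** emulate: motor-unit structure and
recruitment, electrode shift, fatigue, inter-subject variability,
crosstalk-induced correlation between channels, and amplitude
non-stationarity within a gesture. Passing tests on this data show the
network's competitive-learning mechanics work as designed; they do not
certify performance on real recordings, whose channel profiles are noisier
and less orthogonal.

## Reproducibility and problem sizes

Every stochastic component (noise streams, Poisson trains, weight
initialization, EMG carriers) derives from an explicit integer seed;
identical (topology, stimuli, seed, dt) give bit-identical spike rasters.
The simulation kernel is JIT-compiled (numba) with a pure-Python fallback
(`_step_range.py_func`) that implements the identical update sequence.
Default problem sizes: 1000 s single-neuron protocols with 30 s frozen
tests, 63 s classifier training with ~27 s held-out evaluation, five seeds
with medians for all classifier statistics, dt = 0.5 ms throughout.

## Known limitations

* Axonal delays, conductance-based synapses, and homeostatic alternatives to
  the forgetting rule are out of scope.
* The per-step noise convention ties D's meaning to the integration grid.
* The rest detector relies on a bias current; with pure mean-zero noise the
  unsupervised rest association does not bootstrap (the supervised teacher
  does not need the bias, but the default network keeps one preset).
* The temporal-coding rate ratio and the plain-STDP rank-correlation caveats
  described under "Single-neuron coding protocols".
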
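# Methods

This note documents the generative model, the inference scheme, the
coupled-dyad construction and the numerical choices behind `syrinx`. It
is the authoritative account of what the package computes; every
empirical statement here is reproduced by the test suite or the
acceptance script.

## 1. The generative model of song

Each bird's model has two levels of hidden states, each a Lorenz system

    x_dot = (1/tau) [ sigma (x2 - x1);  x1 (rho - x3) - x2;  x1 x2 - beta x3 ]

with sigma = 10, beta = 8/3 at both levels.

* **Level 2 (extrasensory, "narrative")**: tau2 = 2.5 s, fixed Rayleigh
  number rho2 = 28 — an autonomous chaotic attractor an order of
  magnitude slower than level 1. Its output map sends a control signal
  down: `v = 0.5 * x2[0] + 32`, i.e. the slow attractor's first state
  sweeps v over roughly [22, 42].
* **Level 1 (sensory)**: tau1 = 0.25 s; its effective Rayleigh number is
  the descending control scaled by the coupling parameter,

      rho_eff = theta * sat(v),     sat(v) = 64 tanh(v / 64).

  At theta = 1 the sweep of v carries the fast attractor through
  fixed-point, periodic and chaotic regimes; at theta = 0 the level is
  disconnected (rho_eff = 0) and collapses to its origin. The soft
  saturation represents the bounded gain of the descending pathway; it is
  mild (< 12%) over the operating band and, crucially, bounds the
  positive-feedback loop in which inferred control and fast-state errors
  could otherwise inflate each other without limit. theta is the single
  learned parameter: it is the bird's "vocabulary", the mapping from
  narrative to articulation.
* **Syrinx**: two fast states drive the vocal organ. Frequency is affine
  in x1[2] (60 Hz per state unit above 2 kHz, clipped to the 2–5 kHz
  band). Amplitude is the vibration magnitude `max(0, |x1[1]| - 4)`: the
  sign of the controlling state is vibratory phase, not loudness, so both
  lobes of the attractor are audible — with one-sided rectification a
  bird's audibility would be a coin flip on which lobe the attractor
  happens to orbit. Chirps are the attractor's large excursions: with
  these time constants they recur every few hundred milliseconds,
  modulated over seconds by the slow sweep (the song's prosody).
* **Sensory channels**: four — auditory (frequency-state, amplitude-state)
  and proprioceptive (the same two, sensed through the bird's own vocal
  apparatus). Both are predicted by the same linear map of the same
  hidden states: expectations are amodal, and whether they are "about"
  self-made or heard song is decided only by precision.

The sonogram (time x 64 frequency bins, Gaussian ridge of 150 Hz width)
is a rendering of the two control channels; all analysis runs on the
channels or the sonogram envelope, the ridge width is cosmetic.

## 2. Inference in generalized coordinates

Expectations are carried with n = 6 temporal derivatives for hidden
states and 2 for the descending cause (the conventional orders for
generalized filtering of chaotic flows). Prediction errors:

* sensory:  `eps_s = s_tilde - g1(mu_x1_tilde)` per channel and order,
* cause:    `eps_v = mu_v_tilde - g2(mu_x2_tilde)`,
* dynamical: `eps_x = D mu_tilde - f_tilde(mu_tilde)` per level,

where D is the shift operator and the generalized flow uses the standard
linearization (row k >= 1 is the Jacobian applied to the k-th derivative;
causes truncated at their own order). Each error block is weighted by
`exp(omega) * S(gamma)^-1`, the channel log-precision times the inverse
covariance among derivative orders of fluctuations with Gaussian
autocorrelation of roughness gamma = 4 (per sample squared).

**Internal time unit.** The engine measures time in samples (dt = 1/64 s):
flows and Jacobians are scaled by dt, so one filter step advances one
sample. This keeps the k-th derivative of the chaotic flow O(1) instead
of O((1/dt)^k) — in SI seconds the order-6 jets of the fast attractor
reach 1e12 and every precision-weighted quantity is numerically
meaningless. The roughness default gamma = 4 is therefore per sample^2
(the generalized-filtering convention; the equivalent SI value would be
4/dt^2).

**Update scheme.** One step integrates the gradient flow
`mu_dot = D mu - dF/dmu` by local linearization: the matrix exponential
of the Gauss–Newton Jacobian `D - E' Pi E` (E the exact error Jacobian,
including the flow's second derivatives, so dF/dmu is exact to machine
precision — verified against central finite differences at < 1e-4
relative error). The sensory jet advances inside the same exponential
under its own shift operator, which makes the error-free update an exact
temporal translation. A trust region (norm 100 per step) never binds in
healthy runs and prevents runaway steps near the chaotic flow's violent
excursions. On linear models this filter reproduces a discrete
Kalman–Bucy oracle to < 1% relative RMS (embedding orders 2–6).

**Action.** The action variables are the two syrinx controls; they enter
sensation directly on the proprioceptive channels, so the reflex arc
`da/dt = -kappa (ds/da)' Pi eps` is linear in a and integrated exactly.
kappa = 0.25 per sample per unit precision gives the reflex a ~30 ms lag
when proprioception is precise. The lag matters: an instantaneous reflex
makes the self-audition loop (the bird hears exactly its own prediction)
an undamped echo, and self-singing after silence then diverges.

## 3. The dyad

Two agents alternate 2 s (or 1 s) epochs; exactly one sings at a time.
The schedule sets (proprioceptive, auditory) log-precisions to (0, −2)
when singing and (−8, +2) when listening; the level-2 cause precision is
fixed at 4 throughout. Log-precisions ramp linearly over 8 samples
(125 ms) at each role switch: attention does not move instantaneously,
and an instantaneous switch slams song-scale expectations against new
evidence within ~2 samples, injecting a burst of spurious
parameter-evidence of systematic sign.

**The acoustic channel** is idealized: the listener receives the singer's
emitted control signals as a local jet — order 0 is the singer's realized
action, higher orders the derivatives of its descending predictions
(which the reflex is slaved to). Estimating six derivatives of the
channel online by one-sided differencing would amplify noise
catastrophically; the centered Taylor embedding (`embed_sequence`) is
reserved for canned, fully-known stimuli (the omission experiment),
where it is legitimate. Out of earshot, the listener receives ambient
quiet: white noise with sd e^-3, well below its assumed sensory noise
floor (e^-1 at log-precision +2). This gap is deliberate — if ambient
noise sits at the assumed level, the filter over-explains the jitter
through the descending coupling and theta drifts up during silent
listening rather than decaying.

**Initial expectations** are N(0,1) on the order-0 coordinates, with the
slow level additionally placed at a random phase on its attractor.
Starting both birds' slow levels near the origin leaves them climbing the
same origin-escape transient for many seconds, which masks the divergence
that random narratives are supposed to show.

## 4. Learning theta

Because theta does not change in time, its free-energy derivatives are
summed over every step of an epoch and applied once at the boundary:

    posterior precision = prior precision (64) + curvature
    posterior mean      = prior mean - gradient / posterior precision

with the prior re-centred on the posterior mean at each boundary
(precision reset to 64, never sharpened). The belief is clipped at
theta >= 0. Two refinements are essential:

1. **Mean-field gradients.** The gradient at the posterior mean alone
   cannot express the key piece of evidence in this model: exactly-zero
   expectations are flow-consistent at *any* theta (the origin is always
   a fixed point), so a bird listening to silence would learn nothing.
   What makes silence informative is that quiet *fluctuations* are
   unlikely under an unstable attractor. We therefore add the Laplace
   mean-field terms — traces of the Gauss–Newton state covariance
   `(E' Pi E)^-1` against the mixed second derivatives of F — to both
   gradient and curvature. With them, sustained silence pushes theta
   toward zero at roughly 0.1 per listening epoch, which is exactly the
   no-hearing collapse.
2. **Evidence weighting by scheduled auditory precision.** Each step's
   contribution is scaled by `exp(omega_aud - 2)`: 1 while listening,
   e^-4 while singing. Self-generated evidence is circular — the singer's
   sensory stream is produced by its own predictions and carries almost
   no information about theta — and without the weighting the small
   systematic residuals of self-song bias theta upward. Learning is thus
   driven almost entirely by heard song, which is also where precise
   auditory prediction errors live.

With these, the audible experiment (theta 0.5 vs 1.0, 32 one-second
exchanges) converges with step-like updates concentrated after listening
epochs (final gap ~0.17, both means inside [0.5, 1.0]); the inaudible
variant decays both parameters toward zero and the emitted songs go
extinct at the 11th–15th exchange (median 13 over seeds).

## 5. The omission experiment

A canned song (4 s, theta = 1) is played to a purely listening bird; the
truncated variant zeroes the channels after the offset of the 2nd
detected chirp group. The stimulus is embedded with the centered
polynomial window, so evidence of the truncation reaches the filter about
half a window (~50 ms) before the nominal cut — omission-response windows
account for this.

The listening bird resolves auditory frequency finely (log-precision +2)
and loudness coarsely (−1). The split is psychoacoustically natural
(frequency discrimination is far more precise than intensity
discrimination) and is also what makes the phenomenon expressible at
all: with uniform +2 the silence evidence pins the expectations within
~2 samples and no anomalous percept can occur, while with uniformly
loose audition the full-song percept degrades. With the split, the full
song is perceived veridically (percept–stimulus sonogram correlation
≥ 0.8), premature termination evokes a precision-weighted sensory error
burst several times larger than anything during heard chirps, and the
percept shows a transient amplitude bump in the silent period — the
model's expectation of the chirp that never came.

## 6. What the generator emulates, and what a green test shows

The synthetic world *is* the stated model: songs are generated by the
same hierarchy the birds invert, acoustic transmission is noiseless and
delay-free, and the two birds differ only in theta and initial
conditions. Green tests therefore establish that the inference scheme
expresses the claimed phenomena *under matched models* — entrainment,
generalized synchronization, omission responses, silence-driven
unlearning. They do not establish robustness to model mismatch,
transmission delay (known to destroy prosody), asymmetric hierarchies,
or learning of more than one scalar parameter; none of these are
modelled.

## 7. Numerical choices and degenerate inputs

* dt = 1/64 s everywhere; local-linearization (matrix-exponential) steps
  for both generation and filtering; bit-reproducibility from a single
  seed via spawned substreams (per agent, per world).
* Smoothness covariances are inverted by Cholesky; they are well
  conditioned up to order 6 for gamma in [0.1, 10].
* The trust region (norm 100/step) and the tanh control saturation are
  the only global safeguards; simulations that still blow up raise a
  `SimulationError` naming the agent and time. The bifurcation sweep
  records such failures as missing rather than fatal (none occur on the
  default grid).
* Degenerate analysis inputs: constant traces make the sync fit report
  `r_squared = nan`; an all-zero sonogram yields an empty chirp set;
  chirp detection merges segments closer than 50 ms and thresholds at
  10% of the sonogram's peak by default (an epoch that emits exact
  silence — the syrinx threshold makes true zeros common — therefore has
  zero chirps, which is what "song extinction" means operationally).
* Extremum extraction for the bifurcation diagram discards the first 20%
  of each window and counts sign changes of the first difference;
  extrema closer than 0.5 state units merge when counting distinct ones.
* The sync fit is joint-with-intercept OLS from one bird's slow-level
  expectations and their first derivative rows (taken directly from the
  generalized coordinates, not re-differenced) onto the other's; both
  the per-epoch convenience wrapper and the raw fit are exposed.
* Turn order: agent A opens every exchange (configurable via
  `first_singer`; swapping labels, seeds and the opener swaps the traces
  exactly).

## 8. Known limitations

* The no-hearing collapse rate (hence the extinction exchange) depends on
  the ambient-noise floor and the precision-ramp length; these are fixed
  by the considerations in §3–4, not fitted, and the extinction point
  lands at exchange 11–15 rather than exactly 16.
* The theta posterior is a scalar Laplace approximation; conditional
  state uncertainty enters learning only through the Gauss–Newton
  covariance (no full covariance propagation between steps).
* Precisions are scheduled, never inferred: attention is an input, not a
  posterior.
* The linear observation model transmits state-carrying channels even
  when the syrinx is below its sound threshold; only ambient silence and
  truncation are acoustically "empty". A rectified (truly audibility-
  gated) observation model would need a nonlinear sensory map.
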
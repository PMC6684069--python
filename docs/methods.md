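# Methods

`cpgnet` analyses coupling between central pattern generating (CPG)
networks from multichannel rhythmic burst recordings, the way such
recordings arise in deafferented insect preparations: one extracellular
channel per hemisegmental motoneuron pool (labels `pro/meso/meta` x
`L/R`), pilocarpine-induced bursting at roughly 0.1–0.5 Hz, and weak
central coupling between the segmental oscillators.  Two independent
routes are implemented — a descriptive, undirected phase-connectivity
(PC) analysis, and a generative, directed spectral-model analysis with
Bayesian model selection — plus a synthetic-data generator that makes
both testable against known ground truth.

## Synthetic data generator

Ground truth is a network of Kuramoto-type phase oscillators integrated
by Euler–Maruyama:

    dφ_i = [2π f_i + Σ_j K_ij sin(φ_j − φ_i)] dt + σ_φ dW_i

with `K[i, j]` the directed influence of node j on node i (positive
couplings attract toward in-phase lock, negative toward anti-phase).
The analysis stages never assume this functional form; it is chosen
because weak-coupling lock states are analytically checkable.
Rendering: each channel is a rectangular burst envelope — active while
the cycle fraction `(φ mod 2π)/2π` is below the duty — gating a 30 Hz
carrier, with a small per-cycle amplitude jitter, optional small-unit
contamination (Poisson events, 50 ms half-sine × carrier kernels, at an
amplitude ratio of the burst amplitude), and additive Gaussian noise.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| intrinsic frequency | 0.2 Hz (± 0.005 Hz/node) | ~5 s cycles, mild detuning between hemisegments |
| duration | 600 s | order of the usable stretches of real recordings (hundreds to ~2000 s) |
| raw rate | 1000 Hz | exercises the decimation to 200 Hz nontrivially |
| burst duty | 0.4 | depressor-like burst/interburst proportion |
| phase noise σ_φ | 0.1 rad/√s | visible cycle-length variability without destroying the rhythm |
| observation noise | 0.02 (burst amplitude 1) | mild recording noise floor |
| initial phases | uniform on [0, 2π) | unsynchronised onset; set the spread to 0 for deterministic fixtures |

What the generator does *not* emulate: spike shapes and motor-unit
statistics, amplitude drift, electrode artifacts, or any slow
modulation of cycle frequency.  Tests passing on generator data
therefore demonstrate correctness of the algorithms under the stated
dynamics, not performance on every pathology of real recordings.

The cut-connective design simulates trial 1 from the intact network and
trial 2 from a copy with every intersegmental coupling set to zero
(optionally rescaling intrasegmental couplings per segment to emulate
post-cut compensation), using child seeds spawned from the trial seed.

## Preprocessing

Per channel, in order: subtract the mean, rectify (absolute value),
centered moving average (default 0.05 s — short against ~5 s cycles,
long against the 30 Hz carrier), anti-aliased decimation to 200 Hz
(zero-phase FIR low-pass at 0.8× the target Nyquist), and a final mean
re-subtraction.  The final re-subtraction is load-bearing: only a
zero-mean rhythm has an analytic-signal trajectory that encircles the
origin, which is what makes Poincaré-section crossings well defined.
The order (smooth before decimate, de-mean last) is fixed here; the
original acquisition-software chain does not document its internal
order.

## Phase extraction

The analytic signal X = X_r + i·X_i (X_i the FFT-based Hilbert
transform) turns each channel into a trajectory in the complex plane.
Burst onsets are the counter-clockwise crossings of a Poincaré section,
a ray at a configurable angle from the origin; crossing times are
refined by linear interpolation of the wrapped angle.  The default
section is the positive real axis.  Any fixed ray yields a consistent
reference phase; a section at −π/2 additionally lands at the rising
edge of the burst (the Hilbert transform of a rising step dives toward
−i), which the timing tests exploit.  A configurable stretch at each
end is excluded from detection (Hilbert edge artifacts).

Small-unit filtering reproduces the k = 2 k-means amplitude split:
onset amplitudes (peak |X| until the next crossing) are clustered with
deterministic min/max centroid initialisation, and only the
large-centroid cluster is retained.  If the centroid ratio small/large
exceeds 0.6 the split is declared degenerate and all onsets are kept
with a warning — this auto-detects recordings without small-unit
contamination, where forcing a split would discard real bursts.

Phase between retained onsets k and k+1 is linear,
φ(t) = 2π·[k + (t − t_k)/(t_{k+1} − t_k)], exactly 2πk at onset k, NaN
outside the onset span.  Unwrapped radians throughout; cycles are
radians/2π.

## Phase connectivity

For a channel pair, the mean resultant length ("R-vector") of the
phase differences,

    R = (1/T) |Σ_j exp(i(φ₁(j) − φ₂(j)))| ∈ [0, 1],

is computed in a 15 s gliding window (step 1 s; finer steps change
nothing at this window length).  An interval is coupled when (1) the
window R exceeds 0.8 for at least 50 s (~10 cycles), and (2) the
R-vector over the whole candidate interval exceeds 0.3 — the anti-drift
criterion: a difference that ramps slowly through full turns keeps every
window R high while the whole-interval R collapses.  Both thresholds
are configuration, not constants; they were hand-adjusted in the
original workflow.  Interval bounds are the outer edges of the first
and last qualifying window (deterministic and conservative).  The
coupling likelihood is the summed coupled time divided by the recording
length; no coupled interval means 0.  The statistic is undirected.
"Clear histogram peak" is operationalised purely as the whole-interval
R > 0.3 rule; no histogram-shape heuristic is applied.

Connection classes (e.g. meso-meso vs meso-meta) are compared with
Welch two-sample t-tests on per-animal values; p-values are reported
raw, with no multiple-comparison correction, and flagged as such in
reports.

## Spectral model ("DCM-lite")

The directed analysis fits the linear coupled model z' = (A + uB)z
(u = 0/1 indicating the experimental condition).  Where the original
workflow embeds this in neural mass models, each node here is a damped
stochastic oscillator — two latent states with drift block
[[−γ, −ω], [ω, −γ]], white-noise innovation q on both states — so the
full latent drift is M = blockdiag(nodes) + embed(A) and the model
stays linear with a closed-form one-sided stationary cross-spectral
density

    S(f) = 2·G (i2πf·I − M)⁻¹ Q (−i2πf·I − Mᵀ)⁻¹ Gᵀ + σ_obs²·I.

This is a deliberate departure from neural-mass DCM: it preserves
exactly the quantities of interest (masked A strengths, condition
changes B, evidence-based architecture comparison) while remaining
desk-scale, closed-form and testable against an exact simulation oracle
(matrix-exponential discretization of the same SDE).

Empirical spectra are Welch averages over half-overlapping
Hann-tapered 20 s segments, restricted to 0.05–2 Hz (≈40 frequencies;
covers the ~0.2 Hz fundamental and harmonics).  The likelihood is
Gaussian on the real and imaginary parts of the CSD entries with
Whittle-style variances S_ii S_jj / (2K) (diagonal S_ii²/K), K the
segment count; the weighting diagonals are smoothed over 5 frequency
bins so the weights do not correlate with bin-level noise.

Parameters are log-transformed (γ, ω, q, σ_obs², and per-edge
strengths as sign·exp(θ), one global sign per architecture —
excitatory and inhibitory variants are separate models, mixtures
excluded).  Priors:

| parameter | prior mean | prior SD |
|---|---|---|
| log γ | log 1.0 s⁻¹ | 0.5 |
| log ω | log(2π·empirical peak f) | 0.3 |
| log q | log(2γ₀·band power) | 1.0 |
| log σ_obs² | log(high-band spectral floor) | 1.5 |
| log edge strength | log(0.1·γ₀) | 0.75 |

The edge prior deserves comment.  A connection the architecture allows
never vanishes exactly (the exp parameterisation), and the prior holds
it at a moderate fraction of the node damping.  This is the shrinkage
behaviour the method relies on — and it is also what gives Bayesian
model selection its discriminating power here: the Bayes factor between
nested architectures is, in essence, the prior mass a larger model
wastes on couplings the data show to be absent.  A prior concentrated
on plausibly strong couplings makes a spurious connection costly
(misfit or prior penalty), which recovered the true architecture
reliably in the self-consistency experiments, whereas a vaguer prior
(SD ≥ 1.5) left nested comparisons within the noise of the evidence
approximation.

Optimisation is multi-start L-BFGS-B (default 8 starts; the first from
the prior means, the rest seeded perturbations; bounds at ±6 prior SD),
keeping the best converged start.  The log evidence is the Laplace
approximation

    log p(y|m) ≈ −NLJ(θ̂) + (d/2)·log 2π + ½·log det Σ_post,

with Σ_post from a central-difference Hessian of the negative log
joint; eigenvalues below the smallest prior precision are treated as
finite-difference artifacts and clipped there.  BMS reports log
evidences relative to the least probable model and posterior
probabilities as the softmax under equal model priors (exactly
1/(1+e^(−log B)) for two models).

Two-condition fits share the node parameters, give trial 2 an
independent strength per allowed edge (so B = A₂ − A₁; every connection
may change — no prior information on which), and report
100·((A+B)/A − 1) per connection, flagging magnitudes above 70% as
reliable.  The reporting unit mirrors the left-right symmetry
convention: both directions between a node pair are averaged before the
percent change is taken (one value per side), and strength summaries
likewise average mirror-image directed connections into per-class
values, normalised either max-to-1 or to a named reference class
(e.g. meso-meso).

## Model spaces

Two-segment space (4 nodes; edge classes: intrasegmental contralateral,
ipsilateral intersegmental, diagonal cross): (1) fully connected,
(2) intra + ipsilateral ("eight-shaped"), (3) intra + diagonal,
(4) ipsilateral + diagonal, (5) diagonal only, (6) intra only,
(7) empty.  Three-segment space (6 nodes): (1) union of the two
eight-shaped subnetworks, (2) +diagonal pro↔meta, (3) +bidirectional
ipsilateral pro↔meta, (4) +unidirectional ipsilateral meta→pro.  Edge
sets of the less canonical members are not fully documented upstream;
they are user-overridable via `ModelArchitecture`.

## Numerical choices and degenerate inputs

* Uniform-sampling check on file read: relative tolerance 1e-6 on time
  steps; non-monotone or ragged tables are format errors.
* All-zero channels raise ("no oscillation"); fewer than two section
  crossings raise ("rhythm too short"); spectra without band power
  raise before fitting.
* Unstable drift matrices (any eigenvalue with non-negative real part)
  are rejected in the closed form and smoothly penalised inside the
  optimiser.
* k-means ties: min/max initialisation makes the 1-D split
  deterministic; equal amplitudes short-circuit to the degenerate path.
* Seeds: every stochastic step takes a single integer seed;
  sub-streams are spawned (`SeedSequence`) so trial pairs and waveform
  rendering are independent yet reproducible; identical configuration
  implies byte-identical reports.

## Problem sizes used in the test suite

Self-consistency studies run at sizes a single CPU handles comfortably:
parameter recovery on 600 s linear-model recordings (10 seeds), model
recovery (BMS winner) on 1000 s recordings (10 coupled + 10 uncoupled
seeds, 7 architectures each, 3 optimiser starts), the cut-connective
analogue on one designated 600 s pair plus a same-data control, and the
closed-form-vs-Welch oracle on a 4000 s two-node simulation.  These
sizes sit inside the range of the real recordings the workflow targets.

## Known limitations

* Under strong global phase lock every channel pair is coherent at the
  common frequency, and steady-state second-order statistics carry
  little information about which architecture generated the lock; in
  that regime BMS resolves "coupled vs not" decisively but the members
  of the connected-model cluster sit within a few nats of one another
  (the end-to-end pipeline test asserts exactly this structure).
  Biased (phase-coupled) epoch selection sharpens strength estimates
  but cannot restore architecture identifiability once the data are
  fully synchronised.
* Directed-strength recovery from cross-spectra is information-limited:
  at 600 s and the default noise levels the posterior SD of a log
  strength is ~0.2, so ~25% point-estimate accuracy is near the
  attainable floor, and individual directions of a reciprocal pair are
  the weakest-identified combinations.
* The Laplace evidence is a local approximation; between nested
  architectures whose difference is a few nats it is noisy, which is
  the dominant failure mode of winner recovery at desk scale.
* The Whittle-Gaussian likelihood ignores correlations between CSD
  entries at one frequency and between neighbouring frequencies
  (half-overlapping segments); both approximations are standard for
  averaged periodograms.
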
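# Methods

## Overview

`corticonn` asks how well directed functional connectivity, estimated from
field-potential signals, recovers the underlying structural connectome.  The
ground truth is explicit: a multi-area spiking network whose inter-areal
synaptic weights are set by a weighted directed connectome, so the functional
estimates can be compared edge-by-edge with the wiring that generated the
dynamics.  The chain is

1. structural connectome (FLN matrix, distances) →
2. conductance-based spiking simulation →
3. per-area LFP proxy from synaptic currents →
4. MVAR fit + generalized partial directed coherence (GPDC) →
5. structure–function statistics (correlations, variability vs. centrality,
   activity flow, partial-observation experiments).

## Structural connectome

Connection weights are FLNs (fractions of labeled neurons), the standard
edge measure of retrograde tract-tracing connectomes: `FLN[i, j]` is the
fraction of neurons projecting to target area `i` that sit in source area
`j`.  Rows therefore index targets, columns sources, row sums are nodal
in-strength `s_i = Σ_{j≠i} FLN_ij` and lie in (0, 1] (the denominator of the
fraction includes areas outside the modeled set, so rows need not sum to 1).
Validation enforces nonnegativity, a zero diagonal and the row-sum bound.

Because public tract-tracing matrices are not bundled, the `synthetic`
module generates connectomes with the statistical signature of such data:
Bernoulli edge existence at 97% density, log-normal weights (log10 mean
−2.5, SD 1.0, spanning roughly 10⁻⁵–10⁻¹), and per-target row sums drawn
uniformly from [0.3, 0.9] so in-strength varies across areas.  Distances
come from uniform random area positions in an 8 mm box (mouse-cortex scale).
Every generated matrix passes the loader's validation unchanged.

Eigenvector centrality is computed by power iteration on the in-edge
orientation (high centrality = strongly targeted area), unit L2 norm,
checked in tests against a dense eigendecomposition; the out-edge variant is
available via a flag.

## Spiking network model

Each area is a population of 2,000 single-compartment Hodgkin–Huxley
neurons, 1,600 excitatory (C_m = 0.50 nF) and 400 inhibitory (0.25 nF), with
g_Na = 12.5 µS, g_K = 4.74 µS, g_L = 0.025 µS, E_Na = 40 mV, E_K = −80 mV,
E_L = −65 mV.  Gate kinetics use the shifted-rate HH form; the two removable
singularities (α_m at V = −16 mV, α_n at V = −20 mV) are evaluated by their
analytic limits.  The gate equations follow the standard form dx/dt =
α_x(V)(1−x) − β_x(V)x for x ∈ {m, h, n}.

Synapses are conductance-based with instantaneous rise and exponential decay
(τ_E = 2 ms, E = 0 mV; τ_I = 8 ms, E = −70 mV).  Intra-areal wiring is
Bernoulli with p = 0.10 over ordered pairs, weights Gaussian per class
(E→E and E→I 2.5 ± 1.0 nS; I→E and I→I 240 ± 10 nS; background 3.2 ± 1.0 nS)
truncated at zero by resampling so a conductance never flips sign, and a
fixed 1 ms axonal delay.  Every neuron receives an independent 7.3 kHz
Poisson background train through an excitatory conductance with its own
fixed weight draw.  Long-range projections originate from excitatory neurons
only, wire across areas with p = 0.05, carry weight µ_E·FLN_ij = 50·FLN_ij nS
onto excitatory targets and µ_I·FLN_ij = 25·FLN_ij nS onto inhibitory
targets, and are delayed by distance / 3.5 m/s rounded to the nearest
integration step (ties up, minimum one step).

Integration is exponential Euler at dt = 0.1 ms: gates are advanced exactly
for frozen V (which keeps them in [0, 1] unconditionally), then V is
advanced exactly on the conductance-linearized membrane equation.  A
purpose-built numba kernel advances the whole network in-place; spikes are
scattered into delay ring buffers as conductance increments.  Runs are
bitwise reproducible given (spec, seed): wiring, initial conditions and
background noise all derive from one seed sequence.

Choices the model statement leaves open, fixed here and configurable:
spike detection at the upward crossing of 0 mV with a 2 ms detection
refractory (HH spikes here overshoot well past 0 mV; detection counts are
insensitive to the threshold within ±20 mV); initial V uniform in
[−70, −60] mV with gates at steady state; the first 1 s discarded as
transient; I_ext = 0 (all drive is synaptic).

With these parameters an isolated area settles at a balanced, mostly
asynchronous working point of a few Hz (inhibitory faster than excitatory),
and the long-range drive raises both rates toward the reference working
point of ≈3.6 Hz (E) and ≈4.7 Hz (I); in the reduced configurations shipped
here the excitatory rate lands on its reference while the inhibitory rate
sits about 5% below it.  Population rates use a 100 ms sliding window.

## LFP proxy

The per-area LFP is the electrode resistance (R = 1 MΩ) times the mean over
excitatory neurons of the rectified synaptic currents:
LFP(t) = R Σ_i (|I_E,i| + |I_I,i| + |I_bkg,i|) / N_E.  Rectification is
applied per neuron and per current component (the alternative — rectifying
the per-neuron sum — is a config flag away, since the proxy definition is
ambiguous on this point).  The raw 10 kHz signal is mean-subtracted,
low-pass filtered with an 8th-order zero-phase Butterworth filter and
decimated to 1 kHz.  The anti-alias cutoff defaults to 450 Hz (0.9× the
output Nyquist): a literal 1 kHz cutoff before decimation *to* 1 kHz would
not prevent aliasing, so the default honors the filter's purpose; the 1 kHz
cutoff remains available as an option.  The PSD is an averaged modified
periodogram (1 s segments, 50% overlap); simulated LFPs peak in the gamma
band.

## MVAR and GPDC

The M-channel LFP is modeled as x(t) = Σ_{k=1..p} A_k x(t−k) + ε(t) with
white innovations of covariance Σ.  Coefficients are estimated by ordinary
least squares through a QR decomposition (at p = 50 and M = 19 the design
has 950 regressors, where normal equations would be fragile); the innovation
covariance uses the small-sample denominator T_eff − M·p with T_eff = T − p.
Order selection minimizes AIC = ln det Σ̂ + 2pM²/T_eff over p = 1..p_max
(default 50), ties toward smaller p.  The scan evaluates all nested orders
from one triangularization of the lag-ordered design on the common
estimation sample (algebraically the per-order OLS fits), then refits
exactly at the argmin.

GPDC from source j to target i at normalized frequency λ ∈ [0, 0.5] is

    GPDC_ij(λ) = (1/σ_i)|Ā_ij(λ)| / sqrt(Σ_k |Ā_kj(λ)|²/σ_k²),
    Ā(λ) = I − Σ_k A_k e^(−i2πλk),

with σ_k² the innovation variances.  It is column-normalized
(Σ_i GPDC_ij(λ)² = 1 identically), bounded in [0, 1], and invariant to
per-channel rescaling.  The spectrum is evaluated on 512 uniform
frequencies; per-edge scalars are the peak over frequencies (used
throughout), the mean, and the trapezoidal area under the curve.  Self-edges
are set to 0 in all summaries.  Conditioning modes: `full` fits one model on
all channels; `subset` fits only the observed channels; `pairwise` fits each
ordered pair bivariately.  Each fit selects its own order.

The estimation stack is validated against analytic ground truth: GPDC of a
known stable VAR is recovered from T = 30,000 samples to < 0.05 everywhere;
independent white noise yields 95th-percentile spurious peaks ≈ 0.01;
AIC recovers a VAR(3) order (±1) in 100% of 50 replicates; and on an
x→y→z chain the bivariate x→z estimate exceeds the trivariate-conditioned
one in ~100% of seeds — the mechanism behind the degradation of pairwise
estimates under partial observation.

## Structure–function analyses

The edge table holds one row per directed edge per simulation (FLN plus
GPDC peak/mean/AUC).  Correlations are plain Pearson r; per-simulation and
pooled scopes are both provided, means of correlations are arithmetic (no
Fisher z, available as an option), and edges with FLN = 0 are excluded when
the connectome is not complete (at 97% density this is marginal).  The
80-edge bootstrap resamples edges with replacement (1,000 resamples,
percentile CI).  Variability analysis computes the per-edge coefficient of
variation of the GPDC peak across simulations (edges with zero mean are
flagged and excluded), sums CV per source (column sums) and per target (row
sums), and correlates the sums with in-strength and eigenvector centrality;
raw-SD sums are reported alongside.  Activity flow estimates the input to
area i as P_i = Σ_{j≠i} W_ij r_j with W either the FLN or the GPDC-peak
matrix and r_j the mean excitatory rate of the source area over the
post-transient window; each estimate is correlated with the target areas'
own rates.

The partial-observation experiment draws, per cluster size, uniform random
area subsets (without replacement within a subset; repeats across draws are
allowed), computes the FLN–GPDC correlation per simulation under full /
subset / pairwise conditioning, and compares restricted modes to full
conditioning with Welch t-tests, Holm-corrected across sizes.  Sizes below
3 are rejected (fewer than 6 edges makes the correlation meaningless).

## Problem sizes

The reference configurations (in `corticonn.benchmarks`) are sized for a
single CPU:

* **Three-area rate benchmark** — 3 areas × 2,000 neurons, synthetic
  connectome with rows normalized to 0.6, conduction delays spanning
  1–3 ms, 10 s at dt = 0.1 ms, 1 s transient.  This is the configuration
  the acceptance script runs.
* **Full pipeline** — 19 areas × 2,000 neurons (~60 M synapses), 2
  simulations × 8 s, GPDC with p_max = 20 (at T ≈ 7,000 output samples,
  950-regressor fits at p = 50 would be badly overparameterized; AIC
  selects p ≈ 12–17 here, so the cap does not bind).  The single-size
  partial-observation check uses the full 150 random clusters (cluster
  evaluation is cheap once the simulations exist); the multi-size,
  multi-mode sweep in `analysis/05` uses 12 clusters per size to keep the
  pairwise fits affordable.

Longer runs and more repetitions reproduce the same qualitative picture
with tighter statistics; all sizes are function arguments.  The
structure–function correlations grow with recording length (the MVAR fits
see more data): at 8 s per run the per-simulation full-conditioned
correlation sits a few hundredths below its long-recording value, and the
small-cluster (subset-conditioned) mean sits slightly below 0.6.

## What the synthetic data does and does not show

The generator reproduces the marginal statistics of tract-tracing
connectomes (density, log-normal weight spread, heterogeneous in-strength)
but not their topology: no spatial weight–distance decay, no community
structure, and area identities are opaque labels.  Passing tests therefore
demonstrate that the estimation chain recovers structure from dynamics
generated by *a* realistic connectome, not that any particular biological
cortex behaves this way.  The LFP proxy ignores volume conduction and
electrode noise; the network omits plasticity, neuromodulation and state
switching, so functional-connectivity variability here reflects only wiring,
noise realization and finite data.

## Numerical notes

* Gate updates are unconditionally stable and bounded; the membrane update
  is exact for frozen gates/conductances, so the integrator tolerates
  conductance spikes (240 nS inhibitory weights) at dt = 0.1 ms.
* Non-finite membrane potentials abort the run with (area, neuron, time).
* The spike detector's refractory is purely a detection constraint (2 ms);
  the model itself has no imposed refractory.
* Degenerate inputs raise rather than warn: constant channels in the MVAR
  fit, zero innovation variances in GPDC, zero-variance correlation inputs,
  zero inter-areal distances (undefined delay).
* Bootstrap, cluster draws, wiring, initial conditions and noise all take
  explicit seeds; identical seeds give identical results to the bit.
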
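# Methods

## Model

The simulator iterates a fully coupled discrete-time stochastic network
of `N` continuous-state units,

    u_i(t)   = W * Σ_j w_ij s_j(t) + r * η_i(t),    η_i(t) ~ N(0, 1)
    s_i(t+1) = tanh(u_i(t)),

with `w_ij` a base weight matrix drawn once per network from a
*condition* (below), `W` a dimensionless global weight strength and `r`
a dimensionless noise strength. Noise is redrawn independently per
neuron and per step; the noise applied at step *t* produces the state
at *t+1*. Initial states are uniform on (−1, 1) per neuron.
Two-dimensional (grid) networks run the same update on a row-major
flattened index; the spatial arrangement enters only through the
condition's class mask. There is no learning, no asynchronous update,
and no energy-based sampling: the interest is purely in the forward
stochastic dynamics.

States are binarized by a threshold (default 0; a state exactly equal
to the threshold maps to 0). The threshold and all other cut-offs are
explicit parameters.

## Weight conditions

Each ordered neuron pair belongs to exactly one weight class, sampled
uniformly from its interval: strong = [0.7, 1.0], medium = [0.2, 0.3],
weak = [0.0, 0.05]; the `normal` condition instead draws every entry
from N(0, 1). Named conditions:

* **diagonal** — strong self-weights, weak elsewhere.
* **blocky** — two contiguous neuron blocks (3+2 for five neurons,
  3+4 for seven; the top-left 3×3 and bottom-right 2×2 sub-grids for
  the 5×5 grid), all pairs *within* a block strong, weak elsewhere.
* **quantum** — strong self-weights on block members, medium weights on
  every *cross-block* pair, weak elsewhere. Thresholded at θ = 0.2
  this produces diagonal sub-relations surrounded by related cells,
  whose rough-set lattice is quantum logic; thresholding the diagonal
  condition at θ = 0.7 gives the identity relation and Boolean logic.
  The grid version applies the same rule to the two spatial blocks
  (strong self-weights for block members, medium across blocks): this
  is the direct analog of the five-neuron pattern and the only reading
  whose thresholded relation reproduces the horizontal-sum lattice.
  Alternative medium ranges (e.g. [0.25, 0.65]) are available as named
  variants.

The exact spatial masks are configuration data built in
`rrscope.network.condition` and are deliberately easy to edit.

## Entropy, mutual information, and recurrence resonance

The binarized states over a neuron subset form bit-words; *global*
scope uses all neurons and is refused above 20 neurons (the 2^N word
space cannot be populated), *local* scope names a subset (default in
the workflows: the first grid row). Metric entropy is the base-2
Shannon entropy of the plug-in (relative-frequency) word distribution
over all T time points. Mutual information is computed between the
word at *t* and the word at *t+1* from the T−1 overlapping consecutive
pairs, as H(X) + H(Y) − H(X,Y) on the joint's own marginals.

Estimators are deliberately plug-in. The plug-in MI is positively
biased when the 2^2k joint space is undersampled; for 5-bit words
estimated from T = 1000 steps of effectively independent uniform words
the bias plateau is close to 1 bit and shrinks substantially at
T = 10,000 — this bias *is* the high-noise MI plateau the sweep
workflows exhibit, so no correction is applied by default. A
Miller–Madow-corrected variant (`corrected=True`) exists for users who
want it.

`noise_sweep` evaluates H and I over a (W, r) grid. One weight matrix
is drawn per (W, replicate) and held fixed along the noise axis, so
each replicate traces the noise response of a specific network;
replicates average over the condition's ensemble. Every grid cell has
an independent 31-bit dynamics seed derived from the base seed and
logged in the output table, and results are bit-identical whether
cells run batched or one at a time (noise is consumed from per-replica
generators in fixed 256-step blocks to guarantee this).

`detect_rr` calls a mean MI curve resonant when its maximum is
interior to the grid and exceeds both end values by a margin (default
0.05 bits, chosen to sit above sampling jitter at T = 10,000). It also
reports the contiguous *resonance region* where MI stays above halfway
between the peak and the larger end value, and the region's midpoint.
The midpoint, not the argmax, is the default operating noise for
spectral runs: the argmax of a sampled, jittery curve is fragile,
while the half-maximum midpoint is a stable representative point
inside the resonance. For non-resonant conditions the spectral
fallback is the midpoint of the noise grid.

## Spectral analysis

The power spectrum is the raw normalized DFT modulus squared,
S(f) = |(1/T) Σ_t s_t e^{−i2πtf/T}|², reported at positive
frequencies; no window or detrend is applied (the sample mean affects
only the excluded DC bin; a linear-detrend flag exists for recorded
signals). The all-bin spectrum satisfies Parseval's identity
Σ_f S(f) = (1/T) Σ_t s_t² to 1e−10, and the transform of the circular
autocorrelation reproduces it bin-for-bin (discrete Wiener–Khinchin),
which `wiener_khinchin_residual` verifies to < 1e−8.

Power-law exponents are the signed OLS slope of log10 S on log10 f, so
pink noise reports ≈ −1.0. Two fitting modes exist: plain OLS over all
in-band bins (the contract of `fit_slope`, exact on synthetic power-law
input), and octave-binned OLS (`n_log_bins`), which first averages the
spectrum into equal log-frequency bins. The trace and recording
pipelines always use 12 log bins: linearly spaced bins put roughly 90%
of the weight into the top octave of a band and were measured here to
underestimate multi-decade exponents by ≈ 0.4; equal-per-octave
weighting is the appropriate estimator for a scaling law defined in
log-log coordinates.

Single-neuron spectra of a *condition* are averaged over 50 trials
with fresh random initial values **and a fresh weight draw per trial**.
The ensemble average is essential to the 1/f result: one realization
of a clustered (diagonal/quantum) network gives a telegraph process
with a single switching rate — a Lorentzian spectrum, flat then f^−2 —
because the switching rate depends exponentially on that network's
self-weight draw. Averaging over the condition's ensemble superposes
Lorentzians whose rates are spread over decades, and that superposition
is 1/f-like across the band covered by the rate spread (the classical
mechanism by which distributed activation barriers produce flicker
noise). Holding the weights fixed across trials averages only over
noise and initial conditions and does not produce 1/f.

Band conventions: the "low-frequency half" is f ≤ Nyquist/2 and the
"high-frequency half" is f > Nyquist/2; both are always explicit
parameters of the fit, never silent. The dual-regime split for
recorded signals defaults to 10^−2 Hz with the split bin assigned to
the low regime.

The default weight strength for spectral runs is W = 2: the smallest
of the studied strengths {1, 2, 5, 10} at which the strong-class
self-gain W·w_ii exceeds 1 for every draw, i.e. the units are bistable
and attractor switching — the dynamics recurrence resonance feeds on —
exists at all. The default noise is the RR-region midpoint found by
the local-MI sweep, as above. With these defaults the 5×5 quantum grid
yields a low-band slope of ≈ −0.9 to −1.0 and the normal grid |slope|
< 0.2; the five-neuron (linear) clustered conditions redden the
*high*-frequency half instead, consistent with the faster switching
rates their weaker interaction produces.

RMS fluctuation F(Δt) partitions the mean-removed series into
non-overlapping windows of length Δt, takes each window's RMS deviation
about its own mean, and averages; α_fit is the OLS slope of log F
against log Δt. For a power-law signal the theoretical exponent is
α_theo = (1 + |β|)/2. The window-local definition (rather than
cumulative-sum/DFA profiles with polynomial detrending) was chosen as
the most direct reading of the scaling law; it is known to saturate
near α ≈ 1 and to under-read long-range correlation relative to
α_theo, so the two exponents are reported side by side and not
interchangeably. Windows are capped at T/4 so at least four windows
enter every average.

## Synthetic colored noise

`gen_powerlaw_noise` synthesizes series in the spectral domain:
amplitudes ∝ f^{β/2}, i.i.d. uniform phases, inverse transform,
rescaled to the requested RMS. T must be a power of two ≥ 256 for a
clean synthesis grid; defaults (dt = 1 s, T = 2^14) emulate recordings
of roughly ten thousand seconds. The dual-regime generator matches
amplitudes continuously at the crossover so near-split bins are
unbiased. Round trips through the estimator recover β to within 0.02
in the mean (T = 2^16). The generator emulates only the second-order
(spectral) structure of recordings: it is Gaussian, stationary, and
free of drift, line noise, pulses and stimulation artifacts, so tests
passing on it validate the estimator chain, not the biology of any
real signal.

## Rough-set lattices

Subsets are bitmask-encoded; exhaustive fixed-point enumeration is
guarded at |U1| ≤ 20. The classifier first verifies that every lattice
element is the join of the atoms below it (joins are computed as the
smallest fixed point containing a union, which exists because
Galois-connection fixed-point families are intersection-closed). Atoms
are grouped by co-occurrence below a common non-extremal element; lone
atoms — which arise from 2×2 diagonal sub-relations whose pairwise
join is already the top — are paired up into 2² blocks (any pairing
yields the same abstract lattice). Each candidate block must contain
exactly 2^k − 2 non-extremal elements and (verified exhaustively up to
2^12 subsets) realize every proper atom subset as a distinct element.
One block ⇒ Boolean; two or more ⇒ quantum (horizontal sum); any
failure ⇒ `other`, never a guess.

## Numerical choices

* tanh rounds to exactly ±1.0 in float64 once |u| ≳ 19; states are
  clamped to the largest double below 1 (perturbation < 1.2e−16) so
  the open-interval invariant survives saturation.
* 0·log 0 := 0 throughout; plug-in MI is floored at 0 (it can go
  −1e−16 through rounding).
* Binarization ties map to 0.
* Per-replica noise streams are drawn in 256-step blocks; this block
  size is part of the reproducibility contract (same seed ⇒ bit-equal
  trajectory, batched or serial).
* Sweep/ensemble seeds are 31-bit integers derived from the base seed
  via `SeedSequence` and logged in every output.

## Scales used by the bundled analyses

Sweeps run T = 10,000 steps per grid cell (T = 1000 where the
undersampling plateau itself is the quantity of interest), with grids
of ~50–100 noise values and 3–10 replicates; ensemble spectra use 50
trials of T = 8192 samples; generator round trips use T = 2^16 with
50-trial averages. These sizes give sampling error comfortably below
the tolerances asserted in the tests while keeping any single analysis
in the seconds-to-minutes range.

## Known limitations

* The printed-weight reference network's global entropy at
  (W = 1, r = 1.3) evaluates to ≈ 4.8 bits under this model — the
  sweep landmarks are sensitive to the absolute noise scale (see the
  entropy curves' steep rise between r ≈ 0.1 and 1), so entropy values
  quoted at specific noise strengths should be read against this
  implementation's own curves.
* Plug-in estimates at 5-bit global scope need T ≫ 2^10 to leave the
  bias-dominated regime; the package reports bias-level MI honestly
  rather than correcting silently.
* The fluctuation exponent α_fit from window-local RMS systematically
  undershoots α_theo for strongly correlated signals; comparing the
  two quantifies that gap rather than estimating one number two ways.
* `classify` is structural on the fixed-point family; it does not
  implement a general orthomodularity test and reports `other` outside
  the Boolean/horizontal-sum shapes.
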
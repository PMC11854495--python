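"""Detect recurrence resonance in a 5-neuron network.

Sweeps the noise strength for the diagonal condition (strong
self-coupling, weak cross-coupling) at two weight strengths, and locates
the mutual-information peak that signals recurrence resonance: noise of
intermediate strength excites the network's attractors, so the
binarized state words become temporally structured before strong noise
washes the structure out.
"""

import numpy as np

import rrscope as rr

spec = rr.condition("diagonal", "linear", 5)
grid = list(np.round(np.arange(0.1, 5.01, 0.1), 10))
sweep = rr.noise_sweep(spec, [1.0, 10.0], grid, T=10_000, seed=0, n_reps=3)

for W in (1.0, 10.0):
    det = rr.detect_rr(sweep, W)
    c = sweep.curve(W)
    h_at_peak = float(c["H_bits"].iloc[int(c["I_bits"].idxmax())])
    print(f"W={W:4}: resonant={det.is_resonant}  peak MI={det.peak_mi:.2f} bits "
          f"at r={det.peak_noise:.2f}  (entropy there: {h_at_peak:.2f} bits, "
          f"RR region r in [{det.region[0]:.2f}, {det.region[1]:.2f}])")

# The MI peak grows roughly threefold from W=1 to W=10 under this
# condition: stronger self-coupling deepens the attractors the noise
# can excite, so the resonance is more pronounced.
r1 = sweep.curve(1.0)["I_bits"].max()
r10 = sweep.curve(10.0)["I_bits"].max()
print(f"peak-MI ratio W=10 vs W=1: {r10 / r1:.2f}")
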
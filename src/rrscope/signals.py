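"""Colored-noise synthesis and built-in reference fixtures.

`gen_powerlaw_noise` produces a real time series whose power spectrum
follows S(f) ~ f^beta by spectral synthesis: Fourier amplitudes are set
to f^(beta/2), phases are i.i.d. uniform, and the inverse transform is
rescaled to the requested RMS.  This gives exact control of the target
exponent, which the generator/estimator round-trip tests rely on.
`gen_dual_regime_signal` uses one exponent below and one above a
crossover frequency, with the amplitude matched continuously at the
split so no spectral step biases near-split bins.  Defaults (dt = 1 s,
T = 2^14 samples) emulate membrane-potential recordings of roughly ten
thousand seconds.

`fixture` returns named reference objects used across the examples and
tests: the fixed 5x5 normal-condition weight matrix, the 3+2
block relation whose rough-set lattice is the canonical quantum-logic
example, sampled condition matrices, and the quantum-grid variants with
alternative medium (cross-block) coupling ranges.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .lattice import BinaryRelation
from .network import ConditionSpec, WeightMatrix, condition, sample_weights

__all__ = [
    "NoiseSpec",
    "gen_powerlaw_noise",
    "gen_dual_regime_signal",
    "fixture",
    "available_fixtures",
    "NORMAL5_WEIGHTS",
    "MEDIUM_RANGE_VARIANTS",
]

#: Fixed 5-neuron normal-condition weight matrix (one standard-normal
#: draw, kept verbatim so every analysis on it is exactly reproducible).
NORMAL5_WEIGHTS = np.array([
    [-0.6, -2.0, -2.2,  0.7, -1.1],
    [-0.1,  0.3,  0.3, -1.2, -0.7],
    [ 0.5,  1.4, -0.6, -0.4,  1.5],
    [ 1.9,  0.1, -0.6, -0.8, -1.2],
    [-0.5,  1.5, -1.0, -0.5, -1.6],
])
NORMAL5_SHA256 = "fe39ebdf6d629904137112fdc179cad4c749a9549e9a0206014cbab4589d323f"

#: Alternative medium-class (cross-block) ranges for the 5x5 quantum
#: grid, keyed a-g.
MEDIUM_RANGE_VARIANTS = {
    "a": (0.25, 0.65),
    "b": (0.20, 0.70),
    "c": (0.35, 0.65),
    "d": (0.45, 0.65),
    "e": (0.10, 0.20),
    "f": (0.08, 0.18),
    "g": (0.09, 0.19),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Recipe for a synthetic power-law series.

    beta is the signed spectral slope (-1 = pink noise); the optional
    dual regime (beta_low, beta_high, f_split in Hz) switches exponent
    at the crossover frequency.
    """

    beta: float = -1.0
    T: int = 2 ** 14
    dt: float = 1.0
    amplitude_mV: float = 1.0
    seed: int | None = None
    dual: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.T < 256 or self.T & (self.T - 1):
            raise ValueError("T must be a power of two >= 256")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dual is not None:
            _, _, f_split = self.dual
            if not (1.0 / (self.T * self.dt) < f_split < 1.0 / (2 * self.dt)):
                raise ValueError("f_split must lie strictly inside the "
                                 "resolvable frequency range")


def _synthesize(T: int, amps: np.ndarray, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform spectral amplitudes with random phases."""
    phases = rng.uniform(0.0, 2.0 * np.pi, len(amps))
    half = np.zeros(T // 2 + 1, dtype=complex)
    half[1:] = amps * np.exp(1j * phases)
    half[-1] = np.abs(half[-1])  # Nyquist bin must be real
    x = np.fft.irfft(half, n=T)
    cur = np.sqrt(np.mean(x ** 2))
    return x * (rms / cur) if cur > 0 else x


def gen_powerlaw_noise(spec: NoiseSpec) -> np.ndarray:
    """Series with target spectral slope ``spec.beta``; seeded and exact."""
    rng = np.random.default_rng(spec.seed)
    f = np.arange(1, spec.T // 2 + 1, dtype=float) / (spec.T * spec.dt)
    amps = f ** (spec.beta / 2.0)
    return _synthesize(spec.T, amps, spec.amplitude_mV, rng)


def gen_dual_regime_signal(spec: NoiseSpec) -> np.ndarray:
    """Series with slope beta_low below f_split and beta_high above it.

    Amplitudes are matched continuously at the split:
    A(f) = f^(beta_low/2) for f <= f_split and
    A(f) = f_split^((beta_low-beta_high)/2) * f^(beta_high/2) above.
    """
    if spec.dual is None:
        raise ValueError("spec.dual must provide (beta_low, beta_high, f_split)")
    beta_low, beta_high, f_split = spec.dual
    rng = np.random.default_rng(spec.seed)
    f = np.arange(1, spec.T // 2 + 1, dtype=float) / (spec.T * spec.dt)
    if np.sum(f <= f_split) < 3 or np.sum(f > f_split) < 3:
        raise ValueError("each regime needs at least 3 frequency bins")
    amps = np.where(
        f <= f_split,
        f ** (beta_low / 2.0),
        f_split ** ((beta_low - beta_high) / 2.0) * f ** (beta_high / 2.0),
    )
    return _synthesize(spec.T, amps, spec.amplitude_mV, rng)


def _block_relation_3_2() -> BinaryRelation:
    """The 3+2 block relation: identity within blocks {A,B,C} and {D,E},
    every cross-block cell related.  Its closure fixed points form a
    horizontal sum of a 2^3 and a 2^2 Boolean algebra (quantum logic)."""
    m = np.zeros((5, 5), dtype=bool)
    for i in range(3):
        m[i, i] = True
    for i in range(3, 5):
        m[i, i] = True
    m[:3, 3:] = True
    m[3:, :3] = True
    return BinaryRelation(matrix=m)


def _fixture_builders() -> dict:
    b = {
        "normal5": lambda seed: WeightMatrix(
            entries=NORMAL5_WEIGHTS.copy(),
            condition=condition("custom", "linear", 5, fixed=NORMAL5_WEIGHTS),
            seed=None),
        "block_relation_3_2": lambda seed: _block_relation_3_2(),
        "diagonal5": lambda seed: sample_weights(condition("diagonal", "linear", 5), seed),
        "blocky5": lambda seed: sample_weights(condition("blocky", "linear", 5), seed),
        "quantum5": lambda seed: sample_weights(condition("quantum", "linear", 5), seed),
        "diagonal7": lambda seed: sample_weights(condition("diagonal", "linear", 7), seed),
        "quantum7": lambda seed: sample_weights(condition("quantum", "linear", 7), seed),
        "diagonal_grid5": lambda seed: sample_weights(condition("diagonal", "grid", 5), seed),
        "blocky_grid5": lambda seed: sample_weights(condition("blocky", "grid", 5), seed),
        "quantum_grid5": lambda seed: sample_weights(condition("quantum", "grid", 5), seed),
        "normal_grid5": lambda seed: sample_weights(condition("normal", "grid", 5), seed),
    }
    for key, rng_ in MEDIUM_RANGE_VARIANTS.items():
        b[f"quantum_grid5_{key}"] = (
            lambda seed, _r=rng_: sample_weights(
                condition("quantum", "grid", 5, medium_range=_r), seed))
    return b


def available_fixtures() -> tuple[str, ...]:
    return tuple(sorted(_fixture_builders()))


def fixture(name: str, seed: int = 0):
    """Return a named reference object (WeightMatrix or BinaryRelation).

    Stochastic fixtures (sampled condition matrices) are drawn with the
    given seed; fixed fixtures ignore it.  The fixed 5x5 matrix is
    checksummed — `verify_checksums` fails if it is edited.
    """
    builders = _fixture_builders()
    if name not in builders:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(builders))}")
    return builders[name](seed)


def verify_checksums() -> bool:
    """Assert the immutable fixtures still hash to their recorded digests."""
    digest = hashlib.sha256(
        np.ascontiguousarray(NORMAL5_WEIGHTS, dtype="<f8").tobytes()).hexdigest()
    if digest != NORMAL5_SHA256:
        raise AssertionError("normal5 fixture has been modified "
                             f"(sha256 {digest})")
    return True
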
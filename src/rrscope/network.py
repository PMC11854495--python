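"""Noisy recurrent tanh networks with structured connection-weight conditions.

The dynamical system is a discrete-time, fully coupled stochastic network
("Boltzmann machine" in the loose, continuous-state sense):

    u_i(t)   = W * sum_j w_ij s_j(t) + r * eta_i(t),    eta_i(t) ~ N(0, 1)
    s_i(t+1) = tanh(u_i(t))

where ``w_ij`` is a base weight matrix drawn once from a *condition* (a
stochastic recipe assigning each ordered neuron pair to a weight class),
``W`` is a global weight-strength multiplier and ``r`` the noise strength.
Two-dimensional (grid) networks use the same update on a row-major
flattened index; spatial structure enters only through the condition's
class mask.

Conditions
----------
normal
    every entry drawn from the standard normal distribution.
diagonal
    self-weights strong (uniform on [0.7, 1.0] by default), everything
    else weak (uniform on [0.0, 0.05]).
blocky
    all pairs within each of two contiguous neuron blocks strong, the
    rest weak.
quantum
    self-weights strong, pairs *across* the two blocks medium (uniform on
    [0.2, 0.3] by default), everything else weak.  Thresholding such a
    matrix yields a relation whose rough-set lattice is a horizontal sum
    of Boolean blocks, i.e. quantum logic (see :mod:`rrscope.lattice`).
custom
    a fixed, user-supplied matrix returned unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_CLASS_RANGES",
    "ConditionSpec",
    "WeightMatrix",
    "Trajectory",
    "BinaryTrajectory",
    "condition",
    "sample_weights",
    "step",
    "simulate",
    "simulate_batch",
    "binarize",
]

#: Default uniform sampling intervals per weight class (dimensionless).
DEFAULT_CLASS_RANGES: dict[str, tuple[float, float]] = {
    "strong": (0.7, 1.0),
    "medium": (0.2, 0.3),
    "weak": (0.0, 0.05),
}

_CLASSES = ("strong", "medium", "weak", "normal_gauss")

#: Noise is drawn from each replica's generator in blocks of this many
#: steps, so that batched and one-at-a-time simulation consume identical
#: random streams (see `_run_batch`).
NOISE_CHUNK = 256

#: tanh rounds to exactly +/-1.0 in float64 once |u| exceeds ~19, which
#: would leave the mathematically open interval (-1, 1); states are
#: clamped to the largest representable value below 1 (a perturbation
#: below 1.2e-16).
_SAT = float(np.nextafter(1.0, 0.0))


def _default_blocks(n: int) -> tuple[int, int]:
    """Split ``n`` neurons into the two blocks used by blocky/quantum masks."""
    if n == 5:
        return (3, 2)
    if n == 7:
        return (3, 4)
    return (int(math.ceil(n / 2)), int(math.floor(n / 2)))


@dataclass(frozen=True)
class ConditionSpec:
    """A stochastic recipe for a weight matrix.

    Parameters
    ----------
    name
        One of ``normal, diagonal, blocky, quantum, custom``.
    topology
        ``"linear"`` (a row of ``n`` neurons) or ``"grid"`` (an n-by-n
        square, flattened row-major).
    n
        Number of neurons for a linear topology, side length for a grid.
    class_mask
        ``n_total x n_total`` array of class labels, one per ordered pair.
    class_ranges
        Map from class label to the uniform sampling interval
        ``(low, high)``; ``normal_gauss`` entries ignore the ranges and
        sample from N(0, 1).
    fixed
        For ``name="custom"``: the matrix returned verbatim.
    """

    name: str
    topology: str
    n: int
    class_mask: np.ndarray = field(repr=False)
    class_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_RANGES))
    fixed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.class_mask)
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError("class_mask must be a square matrix of class labels")
        if mask.shape[0] != self.n_total:
            raise ValueError(
                f"class_mask is {mask.shape[0]}x{mask.shape[0]} but the "
                f"topology has {self.n_total} neurons"
            )
        unknown = {str(c) for c in np.unique(mask)} - set(_CLASSES)
        if unknown:
            raise ValueError(f"unknown weight class(es) in mask: {sorted(unknown)}")
        for cls, (lo, hi) in self.class_ranges.items():
            if lo > hi:
                raise ValueError(f"class {cls!r} has an empty range [{lo}, {hi}]")
        if self.name == "custom":
            if self.fixed is None:
                raise ValueError("custom condition requires a fixed matrix")
            fx = np.asarray(self.fixed, dtype=float)
            if fx.shape != (self.n_total, self.n_total):
                raise ValueError("fixed matrix shape does not match topology")
            if not np.all(np.isfinite(fx)):
                raise ValueError("fixed matrix contains non-finite entries")

    @property
    def n_total(self) -> int:
        return self.n * self.n if self.topology == "grid" else self.n


def condition(
    name: str,
    topology: str = "linear",
    n: int = 5,
    blocks: tuple[int, int] | None = None,
    medium_range: tuple[float, float] | None = None,
    fixed: np.ndarray | None = None,
) -> ConditionSpec:
    """Build the class mask for one of the named weight conditions.

    For linear topologies the two blocks partition the neuron indices
    contiguously (default split 3+2 for five neurons, 3+4 for seven).
    For grid topologies the blocks are the top-left 3x3 and bottom-right
    2x2 sub-grids of a 5x5 arrangement (scaled proportionally for other
    side lengths); neurons outside both blocks have weak weights only.

    ``medium_range`` overrides the quantum condition's medium interval,
    e.g. ``(0.25, 0.65)`` for the stronger cross-block coupling variants.
    """
    if topology not in ("linear", "grid"):
        raise ValueError(f"unknown topology {topology!r}")
    n_total = n * n if topology == "grid" else n
    if n_total < 1:
        raise ValueError("need at least one neuron")

    ranges = dict(DEFAULT_CLASS_RANGES)
    if medium_range is not None:
        ranges["medium"] = (float(medium_range[0]), float(medium_range[1]))

    mask = np.full((n_total, n_total), "weak", dtype=object)
    if name == "normal":
        mask[:] = "normal_gauss"
    elif name == "custom":
        pass  # classes irrelevant; the fixed matrix is returned verbatim
    elif name in ("diagonal", "blocky", "quantum"):
        if topology == "linear":
            b1, b2 = blocks if blocks is not None else _default_blocks(n)
            if b1 + b2 != n:
                raise ValueError(f"blocks {b1}+{b2} do not cover {n} neurons")
            groups = [np.arange(0, b1), np.arange(b1, n)]
        else:
            side1 = max(1, round(n * 3 / 5))
            idx = np.arange(n_total).reshape(n, n)
            groups = [idx[:side1, :side1].ravel(), idx[side1:, side1:].ravel()]
        if name == "diagonal":
            mask[np.diag_indices(n_total)] = "strong"
        elif name == "blocky":
            for g in groups:
                mask[np.ix_(g, g)] = "strong"
        else:  # quantum: strong self-weights, medium across the two blocks
            mask[np.ix_(groups[0], groups[1])] = "medium"
            mask[np.ix_(groups[1], groups[0])] = "medium"
            d = np.diag_indices(n_total)
            member = np.zeros(n_total, dtype=bool)
            member[np.concatenate(groups)] = True
            mask[d] = np.where(member, "strong", mask[d])
    else:
        raise ValueError(f"unknown condition {name!r}")

    return ConditionSpec(
        name=name, topology=topology, n=n, class_mask=mask,
        class_ranges=ranges, fixed=None if fixed is None else np.asarray(fixed, float),
    )


@dataclass(frozen=True)
class WeightMatrix:
    """A realized base weight matrix with its generating provenance."""

    entries: np.ndarray
    condition: ConditionSpec | None
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return self.entries.shape[0]


def sample_weights(spec: ConditionSpec, seed: int) -> WeightMatrix:
    """Draw one weight matrix from a condition.

    Every entry is sampled independently from its class's distribution
    (uniform on the class interval, or N(0, 1) for ``normal_gauss``);
    ``custom`` specs return their fixed matrix unchanged.  Reproducible
    given the seed.
    """
    if spec.name == "custom":
        return WeightMatrix(entries=np.array(spec.fixed, dtype=float),
                            condition=spec, seed=seed)
    rng = np.random.default_rng(seed)
    n = spec.n_total
    w = np.empty((n, n), dtype=float)
    mask = spec.class_mask
    # Draw class by class; iteration order is fixed so the draw is
    # reproducible independent of which classes the mask uses.
    for cls in _CLASSES:
        sel = mask == cls
        k = int(sel.sum())
        if k == 0:
            continue
        if cls == "normal_gauss":
            w[sel] = rng.standard_normal(k)
        else:
            lo, hi = spec.class_ranges[cls]
            w[sel] = rng.uniform(lo, hi, k)
    return WeightMatrix(entries=w, condition=spec, seed=seed)


def step(
    state: np.ndarray,
    weights: WeightMatrix | np.ndarray,
    W: float,
    r: float,
    noise_draw: np.ndarray,
) -> np.ndarray:
    """One synchronous update: ``tanh(W * w @ s + r * noise)``.

    The grid case is the same computation on the flattened index.
    """
    w = weights.entries if isinstance(weights, WeightMatrix) else np.asarray(weights)
    state = np.asarray(state, dtype=float)
    noise_draw = np.asarray(noise_draw, dtype=float)
    if state.shape != (w.shape[0],) or noise_draw.shape != state.shape:
        raise ValueError(
            f"dimension mismatch: weights {w.shape}, state {state.shape}, "
            f"noise {noise_draw.shape}"
        )
    return np.clip(np.tanh(W * (w @ state) + r * noise_draw), -_SAT, _SAT)


@dataclass(frozen=True)
class Trajectory:
    """Simulated neuron states over time (rows are time steps)."""

    states: np.ndarray
    weight_strength: float
    noise_strength: float
    seed: int | None
    initial_state: np.ndarray

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def n_total(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class BinaryTrajectory:
    """Thresholded trajectory: bit = 1 iff state > threshold."""

    bits: np.ndarray
    threshold: float

    @property
    def T(self) -> int:
        return self.bits.shape[0]

    @property
    def n_total(self) -> int:
        return self.bits.shape[1]


def _run_batch(
    weight_stack: np.ndarray,
    W: np.ndarray,
    r: np.ndarray,
    T: int,
    rngs: list[np.random.Generator],
    initial_states: np.ndarray | None = None,
    record: np.ndarray | None = None,
) -> np.ndarray:
    """Advance R independent replicas T steps; returns all states (R, T, N).

    Each replica has its own generator; per replica the stream layout is:
    one ``uniform(-1, 1, N)`` draw for the initial state (skipped when an
    initial state is supplied), then ``standard_normal((chunk, N))``
    draws in blocks of `NOISE_CHUNK` steps.  Because the layout is
    per-replica, simulating replicas together or one at a time yields
    bit-identical trajectories.

    ``record`` optionally restricts storage to the listed neuron columns.
    """
    R, N = len(rngs), weight_stack.shape[-1]
    if initial_states is None:
        s = np.stack([g.uniform(-1.0, 1.0, N) for g in rngs])
    else:
        s = np.array(initial_states, dtype=float, copy=True)
        if s.ndim == 1:
            s = np.broadcast_to(s, (R, N)).copy()
    cols = slice(None) if record is None else np.asarray(record)
    width = N if record is None else len(record)
    out = np.empty((R, T, width), dtype=float)
    Wc = np.asarray(W, dtype=float).reshape(R, 1)
    rc = np.asarray(r, dtype=float).reshape(R, 1)
    t0 = 0
    while t0 < T:
        L = min(NOISE_CHUNK, T - t0)
        noise = np.stack([g.standard_normal((L, N)) for g in rngs])
        for t in range(L):
            # one formulation for shared (N,N) and stacked (R,N,N)
            # weights so results are bit-identical either way
            drive = (weight_stack @ s[..., None])[..., 0]
            s = np.clip(np.tanh(Wc * drive + rc * noise[:, t]), -_SAT, _SAT)
            out[:, t0 + t] = s[:, cols]
        t0 += L
    return out


def simulate(
    weights: WeightMatrix | np.ndarray,
    W: float,
    r: float,
    T: int,
    seed: int | None = None,
    initial_state: np.ndarray | None = None,
) -> Trajectory:
    """Iterate the network ``T`` steps with fresh N(0,1) noise per neuron
    and step.

    If no initial state is given it is drawn uniformly from (-1, 1) with
    the same seed, so the whole run is reproducible from ``(seed,)``
    alone.  Noise at step t produces the state at t+1; all recorded
    states (from step 1 on) lie strictly inside (-1, 1).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    w = weights.entries if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    if initial_state is None:
        init = rng.uniform(-1.0, 1.0, w.shape[0])
    else:
        init = np.asarray(initial_state, dtype=float)
        if init.shape != (w.shape[0],):
            raise ValueError("initial_state length must match the neuron count")
    states = _run_batch(w, np.array([W]), np.array([r]), T, [rng],
                        initial_states=init[None, :])[0]
    return Trajectory(states=states, weight_strength=float(W),
                      noise_strength=float(r), seed=seed, initial_state=init)


def simulate_batch(
    weight_stack: np.ndarray,
    W,
    r,
    T: int,
    seeds,
    record=None,
) -> np.ndarray:
    """Vectorized ensemble front end to the batched engine.

    ``weight_stack`` is either one shared ``(N, N)`` matrix or a stack
    ``(R, N, N)``; ``W``, ``r`` and ``seeds`` are scalars or length-R
    sequences.  Returns states of shape ``(R, T, n_recorded)``.  Each
    replica is bit-identical to ``simulate(w_k, W_k, r_k, T, seed_k)``.
    """
    seeds = np.atleast_1d(np.asarray(seeds, dtype=object))
    R = len(seeds)
    W = np.broadcast_to(np.asarray(W, dtype=float), (R,))
    r = np.broadcast_to(np.asarray(r, dtype=float), (R,))
    rngs = [np.random.default_rng(int(s)) for s in seeds]
    return _run_batch(np.asarray(weight_stack, float), W, r, T, rngs, record=record)


def binarize(traj: Trajectory | np.ndarray, threshold: float = 0.0) -> BinaryTrajectory:
    """Threshold states into bits: 1 iff state > threshold (ties map to 0)."""
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    return BinaryTrajectory(bits=(states > threshold).astype(np.uint8),
                            threshold=float(threshold))
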
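"""Pulse-coupled neural network with a hierarchical (multi-class) pulse output.

One neuron per pixel of a 2D slice.  The classical dynamics are

    F(n) = exp(-aF dt) F(n-1) + S + vF (M * Y(n-1))      feeding channel
    L(n) = exp(-aL dt) L(n-1) +     vL (W * Y(n-1))      linking channel
    U(n) = F(n) (1 + beta L(n))                          internal activity
    theta(n) = exp(-at dt) theta(n-1) + vt Y(n-1)        dynamic threshold

with 3x3 synaptic kernels M and W (zero center, zero-padded at borders).
The classical binary pulse Y = step(U - theta) is replaced by a graded,
hierarchical output

    xi = U - theta
    G_ij = sum_{r,t in {-1,0,1}} |xi_ij - xi_{i+r,j+t}|      (3x3 window)
    Y = xi / max(xi) * k

where k is the number of gray-level tiers to resolve, so equal-intensity
neighborhoods map to equal graded pulses and round(clamp(Y, 0, k)) yields a
k+1-class labeling.  G (the local variation of xi) is computed and returned
as telemetry; it does not enter Y.

The per-iteration order follows the algorithm: L, F, U, Y, then theta, each
update reading the previous iteration's pulse, which reproduces the printed
recurrences exactly when Y and theta start at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

__all__ = [
    "LINKING_KERNEL",
    "PCNNParams",
    "PCNNState",
    "init_state",
    "feeding",
    "linking",
    "internal_activity",
    "threshold_update",
    "improved_output",
    "run",
    "labels_from_output",
]

#: 3x3 synaptic weight matrix: 0.1 for 4-neighbors, 0.07 for diagonals,
#: zero self-coupling.  Used for both the linking and feeding kernels.
LINKING_KERNEL = np.array([
    [0.07, 0.1, 0.07],
    [0.1, 0.0, 0.1],
    [0.07, 0.1, 0.07],
])


def _default_kernel() -> np.ndarray:
    return LINKING_KERNEL.copy()


@dataclass
class PCNNParams:
    """Network constants.

    beta : linking strength (coupling of L into U).
    vF, vL, vTheta : normalizing constants of the feeding, linking and
        threshold channels; vTheta is large so a fired neuron's threshold
        jumps to a very high value (refractory behavior).
    aF, aL, aTheta : exponential decay coefficients.
    dt : time constant of the decays.
    W, M : 3x3 linking / feeding kernels (zero center); by default both are
        the standard 0.07/0.1 weight matrix.
    k : number of intensity tiers the hierarchical output resolves.
    n_iter : number of iterations N.  At n = 1 the graded output is exactly
        the normalized stimulus S / max(S) * k; at n = 2 the freshly fired
        thresholds transiently dominate xi = U - theta; from n = 3 on the
        output settles back into a calibrated [0, k] tier map (provided the
        grid contains unfired, near-zero stimulus so max(xi) stays anchored).
    """

    beta: float = 0.2
    vF: float = 0.1
    vL: float = 0.2
    vTheta: float = 20.0
    aF: float = 0.1
    aL: float = 0.3
    aTheta: float = 0.2
    dt: float = 1.0
    W: np.ndarray = field(default_factory=_default_kernel)
    M: np.ndarray = field(default_factory=_default_kernel)
    k: int = 3
    n_iter: int = 10

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.M = np.asarray(self.M, dtype=np.float64)
        for name, kern in (("W", self.W), ("M", self.M)):
            if kern.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
            if kern[1, 1] != 0:
                raise ValueError(f"{name} must have a zero center (no self-coupling)")
        if min(self.aF, self.aL, self.aTheta) < 0:
            raise ValueError("decay coefficients must be >= 0")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError("k must be a positive integer")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class PCNNState:
    """Per-neuron arrays at iteration n (all grids share one 2D shape)."""

    F: np.ndarray
    L: np.ndarray
    U: np.ndarray
    theta: np.ndarray
    Y: np.ndarray
    firate: np.ndarray
    n: int = 0


def init_state(S: np.ndarray) -> PCNNState:
    """Zero-initialized network for stimulus grid ``S``.

    F, L, U, theta, Y and the firing counter all start at 0, so the first
    feeding step gives U(1) = S (1 + beta*0) = S: the first internal
    activity equals the external stimulus.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("stimulus must be a nonempty 2D grid")
    if not np.all(np.isfinite(S)):
        raise ValueError("stimulus contains non-finite values")
    zeros = lambda: np.zeros(S.shape, dtype=np.float64)  # noqa: E731
    return PCNNState(F=zeros(), L=zeros(), U=zeros(), theta=zeros(), Y=zeros(),
                     firate=np.zeros(S.shape, dtype=np.int64), n=0)


def _stamp(Y: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 correlation with zero padding (missing border neighbors give 0)."""
    return correlate(np.asarray(Y, dtype=np.float64), kernel, mode="constant", cval=0.0)


def feeding(state: PCNNState, S: np.ndarray, params: PCNNParams) -> np.ndarray:
    """F(n) = exp(-aF dt) F(n-1) + S + vF (M * Y(n-1))."""
    return (np.exp(-params.aF * params.dt) * state.F
            + np.asarray(S, dtype=np.float64)
            + params.vF * _stamp(state.Y, params.M))


def linking(state: PCNNState, params: PCNNParams) -> np.ndarray:
    """L(n) = exp(-aL dt) L(n-1) + vL (W * Y(n-1))."""
    return (np.exp(-params.aL * params.dt) * state.L
            + params.vL * _stamp(state.Y, params.W))


def internal_activity(F: np.ndarray, L: np.ndarray, beta: float) -> np.ndarray:
    """U = F (1 + beta L): multiplicative linking modulation."""
    return np.asarray(F) * (1.0 + beta * np.asarray(L))


def threshold_update(state: PCNNState, params: PCNNParams) -> np.ndarray:
    """theta(n) = exp(-aTheta dt) theta(n-1) + vTheta Y(n-1)."""
    return (np.exp(-params.aTheta * params.dt) * state.theta
            + params.vTheta * state.Y)


def improved_output(U: np.ndarray, theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hierarchical pulse output (xi, G, Y).

    xi = U - theta; G_ij sums |xi_ij - xi_neighbor| over the 3x3 window
    (out-of-border neighbors skipped); Y = xi / max(xi) * k, or Y = 0
    everywhere when max(xi) = 0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    xi = np.asarray(U, dtype=np.float64) - np.asarray(theta, dtype=np.float64)
    G = np.zeros_like(xi)
    for r in (-1, 0, 1):
        for t in (-1, 0, 1):
            if r == 0 and t == 0:
                continue
            shifted = np.full_like(xi, np.nan)
            src = xi[max(r, 0) or None: min(r, 0) or None,
                     max(t, 0) or None: min(t, 0) or None]
            shifted[max(-r, 0) or None: min(-r, 0) or None,
                    max(-t, 0) or None: min(-t, 0) or None] = src
            diff = np.abs(xi - shifted)
            G += np.where(np.isnan(shifted), 0.0, diff)
    xmax = xi.max()
    if xmax == 0:
        Y = np.zeros_like(xi)
    else:
        Y = xi / xmax * k
    return xi, G, Y


def run(S: np.ndarray, params: PCNNParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Run the improved PCNN for ``params.n_iter`` iterations.

    Per iteration: linking, feeding, internal activity, graded pulse output,
    threshold update.  ``firate`` counts, per pixel, the iterations at which
    Y reached half the hierarchy range (Y >= k/2).  Deterministic; returns
    ``(Y_final, firate)``.
    """
    params = params or PCNNParams()
    S = np.asarray(S, dtype=np.float64)
    state = init_state(S)
    for n in range(1, params.n_iter + 1):
        L = linking(state, params)
        F = feeding(state, S, params)
        U = internal_activity(F, L, params.beta)
        _, _, Y = improved_output(U, state.theta, params.k)
        # theta reads the freshly emitted pulse: from iteration n+1's
        # viewpoint this is theta(n) = decay*theta(n-1) + vTheta*Y(n-1).
        state.Y = Y
        theta = threshold_update(state, params)
        state.F, state.L, state.U, state.theta = F, L, U, theta
        state.firate += (Y >= 0.5 * params.k)
        state.n = n
    return state.Y, state.firate


def labels_from_output(Y: np.ndarray, k: int) -> np.ndarray:
    """Bin the graded output into integer classes {0..k}.

    class = round(clamp(Y, 0, k)); equal Y values get equal classes.
    """
    return np.rint(np.clip(np.asarray(Y, dtype=np.float64), 0, k)).astype(np.int64)
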
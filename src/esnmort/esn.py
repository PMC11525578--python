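"""Echo state network: initialization, state evolution, ridge readout.

A leaky-integrator echo state network maps a sequence of input vectors
``u_n`` (flattened normalized temperature fields) to scalar monthly
mortality rates.  Input and reservoir weights are random and fixed; only
the linear readout is trained, by closed-form ridge regression.

State update (leakage ``alpha``, recurrent matrix ``W``, input matrix
``W_in``)::

    x_n = (1 - alpha) x_{n-1} + alpha tanh(W_in [1; u_n] + W x_{n-1})

Output::

    y_n = W_out [1; u_n; x_n]

``W_in`` entries are uniform on [-0.5, 0.5]; ``W`` entries likewise, with
each entry independently zeroed with probability ``1 - connectivity`` and
the matrix then rescaled so its spectral radius equals ``spectral_radius``.
The readout sees the bias, the raw input, and the reservoir state, so the
prediction responds both through the reservoir's memory and directly to
the current input.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

logger = logging.getLogger(__name__)

#: Reservoir sizes up to this use dense eigenvalues for the spectral radius;
#: larger ones use ARPACK on the largest-magnitude eigenvalue.
_DENSE_EIG_LIMIT = 2500


@dataclass(frozen=True)
class ESNConfig:
    """Hyperparameters of the echo state network.

    Defaults are the study configuration: a 9000-node reservoir, leakage
    0.5, spectral radius 1.25, connectivity 0.5 and ridge penalty 1e-8.

    Parameters
    ----------
    reservoir_size
        Number of reservoir nodes N.
    leakage
        Leakage parameter alpha in (0, 1]: fraction of each update
        contributed by the new nonlinear drive.
    spectral_radius
        Largest absolute eigenvalue of the recurrent matrix after scaling.
    connectivity
        Fraction c in [0, 1] of reservoir weights kept nonzero.
    ridge_lambda
        Tikhonov penalty of the readout regression, >= 0.
    washout
        Number of initial months discarded before fitting the readout
        (transient suppression; the state still evolves through them).
    seed
        Seed for weight initialization.
    """

    reservoir_size: int = 9000
    leakage: float = 0.5
    spectral_radius: float = 1.25
    connectivity: float = 0.5
    ridge_lambda: float = 1e-8
    washout: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reservoir_size < 1:
            raise ValueError("reservoir_size must be >= 1")
        if not 0.0 < self.leakage <= 1.0:
            raise ValueError("leakage must be in (0, 1]")
        if not 0.0 <= self.connectivity <= 1.0:
            raise ValueError("connectivity must be in [0, 1]")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be positive")
        if self.washout < 0:
            raise ValueError("washout must be >= 0")

    def replace(self, **kwargs) -> "ESNConfig":
        return replace(self, **kwargs)


@dataclass
class ESNWeights:
    """Fixed random matrices of one network, plus the trained readout.

    ``w_in`` has shape (N, 1+K), ``w`` (N, N) and ``w_out`` — present only
    after training — (n_outputs, 1+K+N).
    """

    w_in: np.ndarray
    w: np.ndarray
    config: ESNConfig
    w_out: np.ndarray | None = None

    @property
    def n_reservoir(self) -> int:
        return self.w.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1] - 1

    @property
    def is_trained(self) -> bool:
        return self.w_out is not None


@dataclass
class ReservoirState:
    """Activation vector ``x`` of length N at step ``n``."""

    x: np.ndarray
    n: int = 0

    @classmethod
    def zeros(cls, n_reservoir: int) -> "ReservoirState":
        return cls(x=np.zeros(n_reservoir), n=0)


@dataclass(frozen=True)
class ErrorMetric:
    """Root-mean-square misfit, absolute and relative to the target mean."""

    rms: float
    rms_relative: float  # percent of the mean target


def spectral_radius(w: np.ndarray) -> float:
    """Largest absolute eigenvalue of a square matrix."""
    n = w.shape[0]
    if n <= _DENSE_EIG_LIMIT:
        return float(np.max(np.abs(np.linalg.eigvals(w))))
    val = scipy.sparse.linalg.eigs(w, k=1, which="LM", tol=1e-10,
                                   return_eigenvectors=False)
    return float(np.abs(val[0]))


def init_esn(config: ESNConfig, n_inputs: int) -> ESNWeights:
    """Draw and scale the fixed input and reservoir matrices.

    ``w_in`` is uniform on [-0.5, 0.5] with shape (N, 1+K).  ``w`` starts
    from the same distribution; each entry is independently zeroed with
    probability 1 - connectivity, then the matrix is rescaled so its
    spectral radius equals ``config.spectral_radius``.  Deterministic given
    ``config.seed``.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    n = config.reservoir_size
    rng = np.random.default_rng(config.seed)
    w_in = rng.uniform(-0.5, 0.5, size=(n, 1 + n_inputs))
    w = rng.uniform(-0.5, 0.5, size=(n, n))
    keep = rng.random(size=(n, n)) < config.connectivity
    w *= keep
    if not keep.any():
        logger.warning(
            "connectivity %g left the reservoir matrix all-zero; "
            "spectral-radius rescaling skipped", config.connectivity)
        return ESNWeights(w_in=w_in, w=w, config=config)
    rho = spectral_radius(w)
    if rho == 0:
        raise ValueError(
            "reservoir matrix has spectral radius 0 and cannot be rescaled")
    w *= config.spectral_radius / rho
    return ESNWeights(w_in=w_in, w=w, config=config)


def update_state(weights: ESNWeights, state: ReservoirState,
                 u: np.ndarray, alpha: float | None = None) -> ReservoirState:
    """One leaky-integrator step:
    ``x <- (1-alpha) x + alpha tanh(W_in [1; u] + W x)``."""
    if alpha is None:
        alpha = weights.config.leakage
    u = np.asarray(u, dtype=float).ravel()
    if u.size != weights.n_inputs:
        raise ValueError(
            f"input length {u.size} does not match W_in "
            f"(expects {weights.n_inputs})")
    if state.x.size != weights.n_reservoir:
        raise ValueError(
            f"state length {state.x.size} does not match W "
            f"(expects {weights.n_reservoir})")
    drive = weights.w_in[:, 0] + weights.w_in[:, 1:] @ u + weights.w @ state.x
    x_new = (1.0 - alpha) * state.x + alpha * np.tanh(drive)
    return ReservoirState(x=x_new, n=state.n + 1)


def run_reservoir(weights: ESNWeights, inputs: np.ndarray,
                  x0: ReservoirState | None = None) -> np.ndarray:
    """Drive the reservoir over an input sequence.

    ``inputs`` has shape (T, K).  Returns the activation matrix of shape
    (N, T); column t is the state after consuming input t.  The state is
    never reset between consecutive steps.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[0] == 0:
        raise ValueError("empty input sequence")
    state = x0 if x0 is not None else ReservoirState.zeros(weights.n_reservoir)
    out = np.empty((weights.n_reservoir, inputs.shape[0]))
    for t in range(inputs.shape[0]):
        state = update_state(weights, state, inputs[t])
        out[:, t] = state.x
    return out


def _design_matrix(inputs: np.ndarray, activations: np.ndarray) -> np.ndarray:
    """Rows ``[1; u_t; x_t]``, shape (T, 1+K+N)."""
    t = inputs.shape[0]
    return np.hstack([np.ones((t, 1)), inputs, activations.T])


def _ridge_solve(design: np.ndarray, targets: np.ndarray,
                 lam: float) -> np.ndarray:
    """Closed-form ridge regression via whichever normal-equation
    formulation has the smaller linear system.

    Primal (features <= samples): ``w = (D'D + lam I)^-1 D'y``.
    Dual (features > samples):    ``w = D'(DD' + lam I)^-1 y``.
    The two agree exactly for lam > 0; the dual keeps the system at the
    sample count when the feature space (1 + K + N) dwarfs the number of
    training months.
    """
    n_samples, n_features = design.shape
    if np.allclose(design, design[0], rtol=0, atol=0):
        warnings.warn("degenerate (all-identical) design matrix; "
                      "falling back to a pseudo-inverse solution")
        return np.linalg.pinv(design) @ targets
    if n_features <= n_samples:
        gram = design.T @ design + lam * np.eye(n_features)
        return scipy.linalg.solve(gram, design.T @ targets, assume_a="pos")
    gram = design @ design.T + lam * np.eye(n_samples)
    if lam == 0:
        coef = scipy.linalg.lstsq(gram, targets)[0]
    else:
        coef = scipy.linalg.solve(gram, targets, assume_a="pos")
    return design.T @ coef


def train_readout(weights: ESNWeights, inputs: np.ndarray,
                  activations: np.ndarray, targets: np.ndarray,
                  ridge_lambda: float | None = None,
                  washout: int | None = None) -> ESNWeights:
    """Fit the readout ``W_out`` by ridge regression on ``[1; u_t; x_t]``.

    Only steps ``t >= washout`` enter the fit (zero-based, i.e. the first
    ``washout`` months are discarded).  Returns a new :class:`ESNWeights`
    carrying ``w_out`` of shape (n_outputs, 1+K+N).
    """
    cfg = weights.config
    lam = cfg.ridge_lambda if ridge_lambda is None else ridge_lambda
    cut = cfg.washout if washout is None else washout
    if lam < 0:
        raise ValueError("ridge_lambda must be >= 0")
    if cut < 0:
        raise ValueError("washout must be >= 0")
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    targets = np.asarray(targets, dtype=float)
    y = targets.reshape(targets.shape[0], -1)
    if inputs.shape[0] != y.shape[0] or activations.shape[1] != y.shape[0]:
        raise ValueError(
            f"misaligned training data: {inputs.shape[0]} inputs, "
            f"{activations.shape[1]} activation columns, {y.shape[0]} targets")
    if inputs.shape[0] - cut < 1:
        raise ValueError(
            f"washout {cut} leaves no training samples out of {inputs.shape[0]}")
    design = _design_matrix(inputs[cut:], activations[:, cut:])
    coef = _ridge_solve(design, y[cut:], lam)
    w_out = np.atleast_2d(coef.T)
    return ESNWeights(w_in=weights.w_in, w=weights.w, config=cfg, w_out=w_out)


def predict(weights: ESNWeights, inputs: np.ndarray,
            x0: ReservoirState | None = None,
            activations: np.ndarray | None = None) -> np.ndarray:
    """Response mode: drive the reservoir over ``inputs`` and apply
    ``y_n = W_out [1; u_n; x_n]`` at each step.

    Pass ``activations`` to reuse states from an earlier
    :func:`run_reservoir` pass (e.g. a contiguous train+test stream);
    otherwise the reservoir is run from ``x0`` (zeros by default).
    Returns an array of shape (T,) for a single output, else (T, n_out).
    """
    if weights.w_out is None:
        raise ValueError("network is untrained: no readout weights")
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if activations is None:
        activations = run_reservoir(weights, inputs, x0=x0)
    design = _design_matrix(inputs, activations)
    y = design @ weights.w_out.T
    return y[:, 0] if y.shape[1] == 1 else y


def rms_error(pred: Sequence[float], target: Sequence[float]) -> ErrorMetric:
    """RMS misfit and its percentage of the mean target."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size == 0 or target.size == 0:
        raise ValueError("empty prediction or target series")
    if pred.size != target.size:
        raise ValueError(
            f"length mismatch: {pred.size} predictions, {target.size} targets")
    rms = float(np.sqrt(np.mean((pred - target) ** 2)))
    mean_target = float(np.mean(target))
    rel = float("nan") if mean_target == 0 else rms / mean_target * 100.0
    return ErrorMetric(rms=rms, rms_relative=rel)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ARCHIVE_SCHEMA = 1


def save_esn(weights: ESNWeights, path) -> None:
    """Serialize a network (weights + config + seed) to one ``.npz`` archive."""
    meta = {"schema": _ARCHIVE_SCHEMA, "config": asdict(weights.config)}
    arrays = {"w_in": weights.w_in, "w": weights.w,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if weights.w_out is not None:
        arrays["w_out"] = weights.w_out
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_esn(path) -> ESNWeights:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        if meta.get("schema") != _ARCHIVE_SCHEMA:
            raise ValueError(f"unsupported archive schema {meta.get('schema')}")
        config = ESNConfig(**meta["config"])
        w_out = npz["w_out"] if "w_out" in npz.files else None
        return ESNWeights(w_in=npz["w_in"], w=npz["w"], config=config,
                          w_out=w_out)
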
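"""Sparse-coding encoders and matched pointwise baselines.

The central object is the locally competitive algorithm (LCA): a recurrent
network whose membrane potentials ``u`` integrate a feedforward drive
``b = Phi^T s`` minus lateral inhibition ``G a`` (G the dictionary Gram
matrix, self-connection excluded) minus a leak, with activations
``a = T_lam(u)`` given by a nonnegative soft threshold.  At its fixed point
the network minimizes the sparse-coding energy

    E(a) = 1/2 ||s - Phi a||^2 + lam * sum_i |a_i|,   a >= 0.

Linear, rectified and sigmoidal encoders sharing the same dictionary serve
as pointwise-nonlinearity controls: their response to a stimulus depends on
a single projection ``Phi_k^T s`` only, which is what makes their
iso-response geometry flat.

Gradients with respect to the input are computed by exact reverse-mode
differentiation of the unrolled Euler dynamics (threshold subgradient
``1{u > lam}``), so the gradient corresponds to precisely the computation
the encoder performs in ``n_steps`` steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic_data import StimulusBatch


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class EncodingFailure(RuntimeError):
    """Raised when the dynamics produce non-finite state."""


class TrainingFailure(RuntimeError):
    """Raised when dictionary learning diverges; carries the training log."""

    def __init__(self, message: str, log: list[dict] | None = None):
        super().__init__(message)
        self.log = log or []


@dataclass
class Dictionary:
    """Feedforward weight matrix with unit-norm columns.

    ``phi`` is P x N; the same matrix defines both the feedforward drive and
    (through its Gram matrix) the lateral inhibition.
    """

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be a 2-D (P x N) matrix")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi contains non-finite entries")
        norms = np.linalg.norm(self.phi, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary columns must be unit norm (within 1e-8)")

    @classmethod
    def from_columns(cls, phi: np.ndarray) -> "Dictionary":
        """Build a dictionary, normalizing columns to unit L2 norm."""
        phi = np.asarray(phi, dtype=float)
        norms = np.linalg.norm(phi, axis=0)
        if np.any(norms < 1e-12):
            raise ValueError("cannot normalize a zero column")
        return cls(phi / norms)

    @property
    def n_pixels(self) -> int:
        return self.phi.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.phi.shape[1]

    @property
    def overcompleteness(self) -> float:
        return self.n_atoms / self.n_pixels

    def gram(self) -> np.ndarray:
        return self.phi.T @ self.phi

    def lateral(self) -> np.ndarray:
        """Gram matrix with the self-connection (diagonal) excluded."""
        G = self.gram()
        np.fill_diagonal(G, 0.0)
        return G

    def save(self, path: str | Path) -> None:
        np.savez(Path(path).with_suffix(".npz"), phi=self.phi)

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        with np.load(Path(path).with_suffix(".npz")) as archive:
            return cls(archive["phi"])


@dataclass
class LCAParams:
    """Integration parameters of the LCA dynamics.

    ``lam`` is the sparsity threshold (activation units); ``step`` the
    dimensionless Euler step dt/tau; ``n_steps`` the number of update steps.
    The nonnegative threshold variant is fixed on.
    """

    lam: float = 0.2
    n_steps: int = 150
    step: float = 0.05
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 < self.step <= 1:
            raise ValueError("step must be in (0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.nonneg:
            raise ValueError("only the nonnegative threshold variant is supported")


@dataclass
class EncodeResult:
    """Final state of one encode: activations, membrane state, optional traces."""

    a: np.ndarray
    u: np.ndarray
    u_trace: np.ndarray | None = None
    energy_trace: np.ndarray | None = None


@dataclass
class LearnConfig:
    """Dictionary-learning hyperparameters."""

    eta: float = 0.1
    batch_size: int = 100
    n_epochs: int = 10
    seed: int = 0
    divergence_tol: float = 0.10    # relative epoch-over-epoch energy increase

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


# ---------------------------------------------------------------------------
# Threshold, energy, dynamics
# ---------------------------------------------------------------------------

def soft_threshold(u: np.ndarray, lam: float) -> np.ndarray:
    """Nonnegative soft threshold: 0 for u <= lam, u - lam above."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    u = np.asarray(u, dtype=float)
    return np.where(u > lam, u - lam, 0.0)


def energy(s: np.ndarray, a: np.ndarray, dictionary: Dictionary, lam: float) -> float:
    """Sparse-coding energy 1/2 ||s - Phi a||^2 + lam * sum |a_i|."""
    s = np.asarray(s, dtype=float)
    a = np.asarray(a, dtype=float)
    residual = s - dictionary.phi @ a
    return 0.5 * float(residual @ residual) + lam * float(np.abs(a).sum())


def _check_stimulus(S: np.ndarray, dictionary: Dictionary) -> np.ndarray:
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[1] != dictionary.n_pixels:
        raise ValueError(
            f"stimulus has {S.shape[1]} pixels, dictionary expects "
            f"{dictionary.n_pixels}")
    return S


def lca_iterate(
    S: np.ndarray,
    dictionary: Dictionary,
    params: LCAParams,
    record_trace: bool = False,
    record_masks: bool = False,
):
    """Run the batched Euler dynamics from u = 0.

    Returns ``(U, A, u_trace, energy_trace, masks)``; trace entries are None
    unless requested.  ``masks[t]`` is the active set 1{u_t > lam} *before*
    step t (needed for reverse-mode differentiation).
    """
    S = _check_stimulus(S, dictionary)
    n = S.shape[0]
    B = S @ dictionary.phi                       # feedforward drive, n x N
    G = dictionary.lateral()
    U = np.zeros((n, dictionary.n_atoms))
    u_trace = [] if record_trace else None
    energy_trace = [] if record_trace else None
    masks = [] if record_masks else None
    for t in range(params.n_steps):
        A = soft_threshold(U, params.lam)
        if record_masks:
            masks.append(U > params.lam)
        U = U + params.step * (B - A @ G - U)
        if not np.all(np.isfinite(U)):
            raise EncodingFailure(
                f"non-finite membrane state at step {t + 1} "
                f"(|u|_max before divergence check = {np.nanmax(np.abs(U)):.3g})")
        if record_trace:
            u_trace.append(U.copy())
            At = soft_threshold(U, params.lam)
            energy_trace.append([energy(S[i], At[i], dictionary, params.lam)
                                 for i in range(n)])
    A = soft_threshold(U, params.lam)
    if record_masks:
        masks.append(U > params.lam)             # mask at the final state
    return (
        U,
        A,
        np.array(u_trace) if record_trace else None,
        np.array(energy_trace) if record_trace else None,
        masks,
    )


def lca_encode(
    s: np.ndarray,
    dictionary: Dictionary,
    params: LCAParams | None = None,
    record_trace: bool = False,
) -> EncodeResult:
    """Encode a single stimulus with the LCA network.

    ``u`` starts at zero and evolves for ``n_steps`` Euler steps of
    ``u <- u + step * (b - G a - u)`` with self-inhibition excluded from G;
    the returned activations are the thresholded final state.
    """
    params = params or LCAParams()
    U, A, u_trace, energy_trace, _ = lca_iterate(
        np.atleast_2d(s), dictionary, params, record_trace=record_trace)
    return EncodeResult(
        a=A[0], u=U[0],
        u_trace=u_trace[:, 0, :] if u_trace is not None else None,
        energy_trace=energy_trace[:, 0] if energy_trace is not None else None,
    )


def lca_fixed_point_residual(result: EncodeResult, s: np.ndarray,
                             dictionary: Dictionary) -> float:
    """L-infinity norm of u - (b - G a) at the returned state."""
    b = dictionary.phi.T @ np.asarray(s, dtype=float)
    target = b - dictionary.lateral() @ result.a
    return float(np.max(np.abs(result.u - target)))


# ---------------------------------------------------------------------------
# Dictionary learning
# ---------------------------------------------------------------------------

def learn_dictionary(
    batches: StimulusBatch | np.ndarray,
    init_dictionary: Dictionary,
    learn_config: LearnConfig | None = None,
    lca_params: LCAParams | None = None,
    return_log: bool = False,
):
    """Learn the dictionary by gradient descent on the sparse-coding energy.

    Each update averages the Hebbian-like residual rule
    ``delta Phi_k = eta * (s - s_hat) * a_k`` over a minibatch, then
    renormalizes every column to unit norm (the Gram matrix is only
    interpretable as receptive-field overlap for unit-norm atoms).
    Deterministic given ``learn_config.seed``.  Raises
    :class:`TrainingFailure` if the mean energy rises epoch-over-epoch
    beyond ``divergence_tol``.
    """
    cfg = learn_config or LearnConfig()
    params = lca_params or LCAParams()
    S = batches.data if isinstance(batches, StimulusBatch) else np.asarray(batches)
    S = np.atleast_2d(S)
    rng = np.random.default_rng(cfg.seed)
    phi = init_dictionary.phi.copy()
    n = S.shape[0]
    log: list[dict] = []
    prev_energy = None
    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_energy, epoch_l0, n_seen = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = S[idx]
            d = Dictionary(phi)
            _, A, _, _, _ = lca_iterate(batch, d, params)
            recon = A @ phi.T
            residual = batch - recon
            if cfg.eta > 0:
                phi = phi + cfg.eta * (residual.T @ A) / len(idx)
                norms = np.linalg.norm(phi, axis=0)
                norms[norms < 1e-12] = 1.0
                phi = phi / norms
            epoch_energy += 0.5 * float((residual**2).sum()) \
                + params.lam * float(np.abs(A).sum())
            epoch_l0 += float((A > 0).sum())
            n_seen += len(idx)
        mean_energy = epoch_energy / n_seen
        mean_l0 = epoch_l0 / n_seen
        log.append(dict(epoch=epoch, mean_energy=mean_energy, mean_l0=mean_l0))
        if prev_energy is not None and \
                mean_energy > prev_energy * (1.0 + cfg.divergence_tol):
            raise TrainingFailure(
                f"energy rose from {prev_energy:.4g} to {mean_energy:.4g} "
                f"at epoch {epoch}", log=log)
        prev_energy = mean_energy
    learned = Dictionary(phi)
    return (learned, log) if return_log else learned


def save_training_log(log: list[dict], path: str | Path) -> None:
    """Line-delimited JSON: one record per epoch."""
    Path(path).write_text("\n".join(json.dumps(rec) for rec in log) + "\n")


# ---------------------------------------------------------------------------
# Pointwise baseline responses
# ---------------------------------------------------------------------------

def linear_encode(s: np.ndarray, dictionary: Dictionary) -> np.ndarray:
    """Linear responses Phi^T s (vector in, vector out; batch in, batch out)."""
    s = np.asarray(s, dtype=float)
    if s.ndim == 1:
        return _check_stimulus(s, dictionary)[0] @ dictionary.phi
    return _check_stimulus(s, dictionary) @ dictionary.phi


def relu_encode(s: np.ndarray, dictionary: Dictionary, bias: float = 0.0) -> np.ndarray:
    """Rectified responses max(0, Phi^T s + bias)."""
    return np.maximum(0.0, linear_encode(s, dictionary) + bias)


def sigmoid_encode(s: np.ndarray, dictionary: Dictionary,
                   bias: float = 0.0, gain: float = 1.0) -> np.ndarray:
    """Sigmoidal responses 1 / (1 + exp(-gain * (Phi^T s + bias)))."""
    z = gain * (linear_encode(s, dictionary) + bias)
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Encoder objects (shared interface for geometry / selectivity / robustness)
# ---------------------------------------------------------------------------

class Encoder:
    """Maps a batch of stimuli (n x P) to activations (n x N).

    Subclasses implement :meth:`encode` and
    :meth:`backprop` (vector-Jacobian product with respect to the input),
    which is all the downstream geometry and attack machinery needs.
    """

    tag = "base"

    def __init__(self, dictionary: Dictionary):
        self.dictionary = dictionary

    def encode(self, S: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backprop(self, S: np.ndarray, G_out: np.ndarray) -> np.ndarray:
        """Given dL/da (n x N) at S, return dL/ds (n x P)."""
        raise NotImplementedError

    def __call__(self, S: np.ndarray) -> np.ndarray:
        return self.encode(S)

    def response(self, S: np.ndarray, neuron_k: int) -> np.ndarray:
        """Activation of one neuron for each stimulus row."""
        return self.encode(np.atleast_2d(S))[:, neuron_k]

    def weight(self, neuron_k: int) -> np.ndarray:
        return self.dictionary.phi[:, neuron_k]

    def input_gradient(self, s: np.ndarray, neuron_k: int) -> np.ndarray:
        """Gradient of neuron k's activation with respect to the input."""
        S = np.atleast_2d(np.asarray(s, dtype=float))
        G_out = np.zeros((S.shape[0], self.dictionary.n_atoms))
        G_out[:, neuron_k] = 1.0
        grad = self.backprop(S, G_out)
        return grad[0] if np.asarray(s).ndim == 1 else grad


class LinearEncoder(Encoder):
    tag = "linear"

    def encode(self, S: np.ndarray) -> np.ndarray:
        return _check_stimulus(S, self.dictionary) @ self.dictionary.phi

    def backprop(self, S: np.ndarray, G_out: np.ndarray) -> np.ndarray:
        return G_out @ self.dictionary.phi.T


class ReluEncoder(Encoder):
    tag = "relu"

    def __init__(self, dictionary: Dictionary, bias: float = 0.0):
        super().__init__(dictionary)
        self.bias = bias

    def encode(self, S: np.ndarray) -> np.ndarray:
        return relu_encode(_check_stimulus(S, self.dictionary),
                           self.dictionary, self.bias)

    def backprop(self, S: np.ndarray, G_out: np.ndarray) -> np.ndarray:
        z = _check_stimulus(S, self.dictionary) @ self.dictionary.phi + self.bias
        return (G_out * (z > 0)) @ self.dictionary.phi.T


class SigmoidEncoder(Encoder):
    tag = "sigmoid"

    def __init__(self, dictionary: Dictionary, bias: float = 0.0, gain: float = 1.0):
        super().__init__(dictionary)
        self.bias = bias
        self.gain = gain

    def encode(self, S: np.ndarray) -> np.ndarray:
        return sigmoid_encode(_check_stimulus(S, self.dictionary),
                              self.dictionary, self.bias, self.gain)

    def backprop(self, S: np.ndarray, G_out: np.ndarray) -> np.ndarray:
        a = self.encode(S)
        return (G_out * self.gain * a * (1.0 - a)) @ self.dictionary.phi.T


class LCAEncoder(Encoder):
    """The population-nonlinear encoder: thresholded lateral-inhibition dynamics."""

    tag = "lca"

    def __init__(self, dictionary: Dictionary, params: LCAParams | None = None):
        super().__init__(dictionary)
        self.params = params or LCAParams()

    def encode(self, S: np.ndarray) -> np.ndarray:
        _, A, _, _, _ = lca_iterate(S, self.dictionary, self.params)
        return A

    def backprop(self, S: np.ndarray, G_out: np.ndarray) -> np.ndarray:
        """Exact reverse sweep through the unrolled Euler steps.

        Forward: u_{t+1} = u_t + step*(b - G a_t - u_t), a_t = T(u_t),
        b = S Phi.  The Jacobian of one step w.r.t. u_t is
        (1-step) I - step G D_t with D_t = diag(1{u_t > lam}); the drive b
        receives step * g at every step and maps back to S through Phi^T.
        """
        S = _check_stimulus(S, self.dictionary)
        params = self.params
        _, _, _, _, masks = lca_iterate(S, self.dictionary, params,
                                        record_masks=True)
        Glat = self.dictionary.lateral()
        g_u = G_out * masks[-1]                   # through a_T = T(u_T)
        g_b = np.zeros_like(g_u)
        for t in range(params.n_steps - 1, -1, -1):
            g_b += params.step * g_u
            g_u = (1.0 - params.step) * g_u - params.step * ((g_u @ Glat) * masks[t])
        return g_b @ self.dictionary.phi.T


POINTWISE_ENCODERS = {"linear": LinearEncoder, "relu": ReluEncoder,
                      "sigmoid": SigmoidEncoder}
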
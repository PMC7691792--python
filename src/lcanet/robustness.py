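"""Adversarial attacks and the lateral-inhibition robustness comparison.

Two attack families:

* **Single-neuron attacks** perform projected gradient ascent/descent on
  one neuron's activation under an L-infinity bound: with perturbation
  iterates ``e_i``, ``q = eta * grad f(s + e_i) + e_i`` followed by the
  projection ``e_{i+1} = sign(q) * min(|q|, eps)``.  Inside the constraint
  set the attack simply follows the activation gradient, which is always
  orthogonal to the neuron's iso-response contours — that is what lets the
  response geometry predict attack trajectories.

* **Targeted confidence attacks** on a classifier iterate the sign-gradient
  rule ``s* <- clip(s* + alpha * sign(grad log p_target))``, unbounded
  except for pixel clipping, and halt once the softmax confidence in a
  random incorrect target label reaches a criterion (default 90%).  The
  headline comparison measures the per-pixel mean squared perturbation
  needed to reach that criterion for a classifier reading a
  lateral-inhibition (LCA) code versus a parameter-matched pointwise
  (leaky-rectifier) network on raw pixels.

Gradients through the LCA encoder are exact reverse-mode derivatives of the
unrolled dynamics (see :mod:`lcanet.encoders`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .encoders import Encoder, LCAEncoder


# ---------------------------------------------------------------------------
# Configuration and traces
# ---------------------------------------------------------------------------

@dataclass
class AttackConfig:
    """Attack hyperparameters (pixel units; images live in [clip_lo, clip_hi])."""

    step: float = 1e-3                  # alpha: per-iteration step size
    eps_inf: float = np.inf             # L-infinity bound for projected attacks
    conf_target: float = 0.90           # halting confidence
    conf_snapshot: float = 0.95         # secondary snapshot confidence
    max_iters: int = 10_000
    clip_lo: float = 0.0
    clip_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 < self.conf_target < 1:
            raise ValueError("conf_target must be in (0, 1)")
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be below clip_hi")


@dataclass
class AttackTrace:
    """Iterate history of one attack.

    ``confidences`` holds the target-class probability (classifier attacks)
    or the neuron activation (single-neuron attacks) at each stored iterate.
    ``halted_at`` is the first iteration meeting the halting criterion, or
    None; ``perturbation`` and ``mse`` refer to the halting iterate (final
    iterate if the attack never halted).
    """

    iterates: np.ndarray
    confidences: np.ndarray
    halted_at: int | None
    perturbation: np.ndarray
    mse: float
    snapshot: np.ndarray | None = None
    snapshot_at: int | None = None


# ---------------------------------------------------------------------------
# Single-neuron attacks
# ---------------------------------------------------------------------------

def encoder_input_gradient(encoder: Encoder, neuron_k: int,
                           s: np.ndarray) -> np.ndarray:
    """Gradient of neuron k's activation with respect to the input.

    For the LCA encoder this differentiates through the unrolled Euler
    steps with threshold subgradient ``1{u > lam}`` (zero exactly at
    ``u = lam``).
    """
    return encoder.input_gradient(s, neuron_k)


def single_neuron_attack(encoder: Encoder, neuron_k: int, s: np.ndarray,
                         config: AttackConfig, sign: int = +1) -> AttackTrace:
    """Projected-gradient attack on a single neuron's activation.

    ``sign=+1`` maximizes the activation (ascends the gradient); ``sign=-1``
    minimizes it.  Every iterate satisfies ``||e||_inf <= eps_inf`` exactly.
    """
    if not np.isfinite(config.eps_inf):
        raise ValueError("single-neuron attack requires a finite eps_inf")
    s = np.asarray(s, dtype=float)
    e = np.zeros_like(s)
    iterates = [s.copy()]
    confidences = [float(encoder.response(s, neuron_k)[0])]
    for _ in range(config.max_iters):
        grad = encoder.input_gradient(s + e, neuron_k)
        q = sign * config.step * grad + e
        e = np.sign(q) * np.minimum(np.abs(q), config.eps_inf)
        iterates.append(s + e)
        confidences.append(float(encoder.response(s + e, neuron_k)[0]))
    return AttackTrace(
        iterates=np.array(iterates), confidences=np.array(confidences),
        halted_at=None, perturbation=e, mse=float(np.mean(e**2)),
    )


# ---------------------------------------------------------------------------
# Softmax classifier on codes
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


@dataclass
class SoftmaxClassifier:
    """Multinomial logistic read-out on encoder activations."""

    weights: np.ndarray               # N x K
    bias: np.ndarray                  # K
    temperature: float = 1.0
    converged: bool = True
    final_loss: float = np.nan

    def logits(self, codes: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(codes) @ self.weights + self.bias) / self.temperature

    def predict_proba(self, codes: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(codes))

    def predict(self, codes: np.ndarray) -> np.ndarray:
        return self.logits(codes).argmax(axis=1)


def train_softmax(codes: np.ndarray, labels: np.ndarray, seed: int = 0,
                  tol: float = 1e-8, max_iter: int = 2000,
                  l2: float = 1e-3) -> SoftmaxClassifier:
    """Fit the softmax read-out by full-batch cross-entropy minimization.

    Deterministic (zero initialization, quasi-Newton full-batch descent to
    gradient tolerance ``tol``); non-convergence is reported on the returned
    classifier, not raised.  The small ridge penalty ``l2`` keeps the optimum
    well defined even on separable data, where unpenalized cross-entropy has
    no minimizer and the logit scale (hence any confidence-based comparison)
    would be an artifact of early stopping.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, n_feat = codes.shape
    n_class = int(labels.max()) + 1
    onehot = np.eye(n_class)[labels]

    def objective(theta: np.ndarray):
        W = theta[: n_feat * n_class].reshape(n_feat, n_class)
        b = theta[n_feat * n_class:]
        p = _softmax(codes @ W + b)
        loss = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean() \
            + 0.5 * l2 * float(np.sum(W * W))
        g_logits = (p - onehot) / n
        grad = np.concatenate([(codes.T @ g_logits + l2 * W).ravel(),
                               g_logits.sum(axis=0)])
        return loss, grad

    theta0 = np.zeros(n_feat * n_class + n_class)
    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            options=dict(maxiter=max_iter, gtol=tol, ftol=0.0))
    W = res.x[: n_feat * n_class].reshape(n_feat, n_class)
    b = res.x[n_feat * n_class:]
    return SoftmaxClassifier(weights=W, bias=b, converged=bool(res.success),
                             final_loss=float(res.fun))


# ---------------------------------------------------------------------------
# Classifier models exposing input gradients
# ---------------------------------------------------------------------------

class ClassifierModel:
    """Common surface: class probabilities and gradient of log p(target)."""

    tag = "model"

    def predict_proba(self, S: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, S: np.ndarray) -> np.ndarray:
        return self.predict_proba(np.atleast_2d(S)).argmax(axis=1)

    def accuracy(self, S: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(S) == np.asarray(labels)))

    def target_logprob_grad(self, S: np.ndarray, y: np.ndarray) -> np.ndarray:
        """d log p(y | s) / d s for each row (n x P)."""
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        raise NotImplementedError


class LCAClassifierModel(ClassifierModel):
    """Softmax read-out of a (fixed, unsupervised) LCA code — "w/ LCA"."""

    tag = "with_lca"

    def __init__(self, encoder: LCAEncoder, classifier: SoftmaxClassifier):
        self.encoder = encoder
        self.classifier = classifier

    def predict_proba(self, S: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(self.encoder.encode(np.atleast_2d(S)))

    def target_logprob_grad(self, S: np.ndarray, y: np.ndarray) -> np.ndarray:
        S = np.atleast_2d(S)
        codes = self.encoder.encode(S)
        p = self.classifier.predict_proba(codes)
        onehot = np.zeros_like(p)
        onehot[np.arange(len(p)), np.asarray(y, dtype=int)] = 1.0
        g_codes = (onehot - p) @ self.classifier.weights.T \
            / self.classifier.temperature
        return self.encoder.backprop(S, g_codes)

    @property
    def n_params(self) -> int:
        d = self.encoder.dictionary
        return d.n_pixels * d.n_atoms + self.classifier.weights.size \
            + self.classifier.bias.size


class PixelMLPModel(ClassifierModel):
    """One-hidden-layer leaky-rectifier network on raw pixels — "w/o LCA"."""

    tag = "without_lca"

    def __init__(self, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray,
                 b2: np.ndarray, leak: float = 0.1, temperature: float = 1.0):
        self.W1, self.b1, self.W2, self.b2 = W1, b1, W2, b2
        self.leak = leak
        self.temperature = temperature

    def _forward(self, S: np.ndarray):
        z = np.atleast_2d(S) @ self.W1 + self.b1
        h = np.where(z > 0, z, self.leak * z)
        logits = (h @ self.W2 + self.b2) / self.temperature
        return z, h, logits

    def predict_proba(self, S: np.ndarray) -> np.ndarray:
        return _softmax(self._forward(S)[2])

    def target_logprob_grad(self, S: np.ndarray, y: np.ndarray) -> np.ndarray:
        z, _, logits = self._forward(S)
        p = _softmax(logits)
        onehot = np.zeros_like(p)
        onehot[np.arange(len(p)), np.asarray(y, dtype=int)] = 1.0
        g_h = ((onehot - p) / self.temperature) @ self.W2.T
        g_z = g_h * np.where(z > 0, 1.0, self.leak)
        return g_z @ self.W1.T

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + self.b2.size


def matched_hidden_size(n_pixels: int, n_atoms: int, n_classes: int) -> int:
    """Hidden width giving the pixel MLP the same trainable-weight count as
    dictionary + softmax read-out."""
    total = n_pixels * n_atoms + n_atoms * n_classes + n_classes
    return max(2, round((total - n_classes) / (n_pixels + n_classes + 1)))


def train_pixel_mlp(S: np.ndarray, labels: np.ndarray, hidden: int,
                    seed: int = 0, leak: float = 0.1, tol: float = 1e-7,
                    max_iter: int = 3000, l2: float = 1e-3) -> PixelMLPModel:
    """Train the leaky-rectifier control by full-batch cross-entropy descent.

    Deterministic given ``seed`` (Gaussian init scaled by 1/sqrt(fan-in)).
    The ridge penalty ``l2`` matches the one applied to the paired softmax
    read-out, so both models' logit scales are set by the data rather than
    by optimizer stopping.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, P = S.shape
    K = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    shapes = [(P, hidden), (hidden,), (hidden, K), (K,)]
    init = np.concatenate([
        (rng.standard_normal(np.prod(sh)) / np.sqrt(sh[0] if len(sh) == 2 else 1))
        for sh in shapes])
    sizes = [int(np.prod(sh)) for sh in shapes]
    splits = np.cumsum(sizes)[:-1]
    onehot = np.eye(K)[labels]

    def unpack(theta):
        parts = np.split(theta, splits)
        return [part.reshape(sh) for part, sh in zip(parts, shapes)]

    def objective(theta):
        W1, b1, W2, b2 = unpack(theta)
        z = S @ W1 + b1
        h = np.where(z > 0, z, leak * z)
        p = _softmax(h @ W2 + b2)
        loss = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean() \
            + 0.5 * l2 * (float(np.sum(W1 * W1)) + float(np.sum(W2 * W2)))
        g_logits = (p - onehot) / n
        g_h = g_logits @ W2.T
        g_z = g_h * np.where(z > 0, 1.0, leak)
        grad = np.concatenate([
            (S.T @ g_z + l2 * W1).ravel(), g_z.sum(axis=0),
            (h.T @ g_logits + l2 * W2).ravel(), g_logits.sum(axis=0)])
        return loss, grad

    res = optimize.minimize(objective, init, jac=True, method="L-BFGS-B",
                            options=dict(maxiter=max_iter, gtol=tol, ftol=0.0))
    W1, b1, W2, b2 = unpack(res.x)
    return PixelMLPModel(W1, b1, W2, b2, leak=leak)


# ---------------------------------------------------------------------------
# Targeted confidence attacks
# ---------------------------------------------------------------------------

def targeted_attack_batch(model: ClassifierModel, S: np.ndarray,
                          y_targets: np.ndarray,
                          config: AttackConfig,
                          return_perturbations: bool = False):
    """Run the clip-projected sign-gradient attack on a batch of images.

    Each image iterates ``s* <- clip(s* + alpha * sign(grad log p_target))``
    until the target confidence reaches ``conf_snapshot`` (or max_iters);
    ``halted_at`` marks the first iterate at ``conf_target`` and ``mse`` is
    measured there.  Images already past the criterion halt at iteration 0
    with zero perturbation.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float)).copy()
    y_targets = np.asarray(y_targets, dtype=int)
    n = S.shape[0]
    S_star = S.copy()
    halted_at = np.full(n, -1)
    halt_images = np.zeros_like(S)
    snapshot_at = np.full(n, -1)
    conf = model.predict_proba(S_star)[np.arange(n), y_targets]
    reached = conf >= config.conf_target
    halted_at[reached] = 0
    halt_images[reached] = S_star[reached]
    done = conf >= max(config.conf_target, config.conf_snapshot)
    snapshot_at[done] = 0
    active = ~done
    for it in range(1, config.max_iters + 1):
        if not active.any():
            break
        grad = model.target_logprob_grad(S_star[active], y_targets[active])
        step = config.step * np.sign(grad)
        S_star[active] = np.clip(S_star[active] + step,
                                 config.clip_lo, config.clip_hi)
        conf_active = model.predict_proba(S_star[active])[
            np.arange(active.sum()), y_targets[active]]
        idx = np.flatnonzero(active)
        newly_halted = idx[(conf_active >= config.conf_target)]
        newly_halted = newly_halted[halted_at[newly_halted] < 0]
        halted_at[newly_halted] = it
        halt_images[newly_halted] = S_star[newly_halted]
        finished = idx[conf_active >= config.conf_snapshot]
        snapshot_at[finished] = it
        active[finished] = False
    perturb = np.where(halted_at[:, None] >= 0, halt_images - S, S_star - S)
    mse = np.mean(perturb**2, axis=1)
    table = pd.DataFrame(dict(
        y_target=y_targets, halted_at=[h if h >= 0 else None for h in halted_at],
        snapshot_at=[s if s >= 0 else None for s in snapshot_at],
        mse=mse, halted=halted_at >= 0,
    ))
    return (table, perturb) if return_perturbations else table


def targeted_confidence_attack(model: ClassifierModel, s: np.ndarray,
                               y_target: int,
                               config: AttackConfig,
                               record_iterates: bool = False) -> AttackTrace:
    """Single-image targeted attack with full iterate/confidence history."""
    s = np.asarray(s, dtype=float)
    s_star = s.copy()
    iterates = [s_star.copy()]
    conf = float(model.predict_proba(s_star[None])[0, y_target])
    confidences = [conf]
    halted_at = 0 if conf >= config.conf_target else None
    snapshot, snapshot_at = None, None
    if conf >= config.conf_snapshot:
        snapshot, snapshot_at = s_star.copy(), 0
    halt_image = s_star.copy() if halted_at == 0 else None
    if halted_at is None or snapshot_at is None:
        for it in range(1, config.max_iters + 1):
            grad = model.target_logprob_grad(s_star[None], [y_target])[0]
            s_star = np.clip(s_star + config.step * np.sign(grad),
                             config.clip_lo, config.clip_hi)
            conf = float(model.predict_proba(s_star[None])[0, y_target])
            if record_iterates:
                iterates.append(s_star.copy())
            confidences.append(conf)
            if halted_at is None and conf >= config.conf_target:
                halted_at, halt_image = it, s_star.copy()
            if conf >= config.conf_snapshot:
                snapshot, snapshot_at = s_star.copy(), it
                break
    e = (halt_image - s) if halt_image is not None else (s_star - s)
    return AttackTrace(
        iterates=np.array(iterates), confidences=np.array(confidences),
        halted_at=halted_at, perturbation=e, mse=float(np.mean(e**2)),
        snapshot=snapshot, snapshot_at=snapshot_at,
    )


# ---------------------------------------------------------------------------
# Paired robustness experiment
# ---------------------------------------------------------------------------

class AccuracyMismatch(RuntimeError):
    """Paired models failed the validation-accuracy matching requirement."""


def random_incorrect_targets(labels: np.ndarray, n_classes: int,
                             rng: np.random.Generator) -> np.ndarray:
    """A uniformly random wrong label for each image."""
    labels = np.asarray(labels, dtype=int)
    offsets = rng.integers(1, n_classes, size=len(labels))
    return (labels + offsets) % n_classes


def robustness_experiment(
    models: dict[str, ClassifierModel],
    test_images: np.ndarray,
    test_labels: np.ndarray,
    n_classes: int,
    config: AttackConfig,
    seed: int = 0,
    accuracy_margin: float = 0.02,
) -> pd.DataFrame:
    """Attack every test image under each model with shared random targets.

    Models must match in test accuracy within ``accuracy_margin`` (the
    comparison is only meaningful between classifiers of comparable
    competence); otherwise the experiment aborts with the measured
    accuracies.  Non-halting attacks are flagged and excluded from MSE
    summaries by the caller.
    """
    accs = {tag: m.accuracy(test_images, test_labels)
            for tag, m in models.items()}
    if max(accs.values()) - min(accs.values()) > accuracy_margin + 1e-9:
        raise AccuracyMismatch(f"test accuracies differ beyond margin: {accs}")
    rng = np.random.default_rng(seed)
    targets = random_incorrect_targets(test_labels, n_classes, rng)
    frames = []
    for tag, model in models.items():
        table = targeted_attack_batch(model, test_images, targets, config)
        table.insert(0, "model", tag)
        table["accuracy"] = accs[tag]
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def mse_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-model MSE box statistics over halted attacks."""
    rows = []
    for tag, sub in table.groupby("model"):
        halted = sub[sub["halted"]]
        vals = halted["mse"].to_numpy()
        q = np.percentile(vals, [5, 25, 50, 75, 95]) if len(vals) else [np.nan] * 5
        rows.append(dict(model=tag, n_halted=len(halted), n_total=len(sub),
                         mean=float(vals.mean()) if len(vals) else np.nan,
                         p05=q[0], q1=q[1], median=q[2], q3=q[3], p95=q[4]))
    return pd.DataFrame(rows)


def save_trace(trace: AttackTrace, path) -> None:
    """Persist one attack trace (iterates, confidences, perturbation)."""
    np.savez(path, iterates=trace.iterates, confidences=trace.confidences,
             halted_at=np.array(-1 if trace.halted_at is None
                                else trace.halted_at),
             perturbation=trace.perturbation, mse=np.array(trace.mse))


def perturbation_alignment(perturbations: np.ndarray, targets: np.ndarray,
                           class_means: np.ndarray) -> np.ndarray:
    """Cosine similarity between each perturbation and its target-class mean.

    A proxy for how "semantically relevant" the perturbations are: attacks
    that must move toward the target class's actual appearance score higher.
    """
    perturbations = np.atleast_2d(perturbations)
    means = class_means[np.asarray(targets, dtype=int)]
    num = np.sum(perturbations * means, axis=1)
    den = np.linalg.norm(perturbations, axis=1) * np.linalg.norm(means, axis=1)
    return np.divide(num, den, out=np.zeros(len(num)), where=den > 1e-300)
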
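"""Synthetic stimulus generation.

Everything the analysis pipeline consumes is generated here: sparse patches
drawn from a known linear generative model with a ground-truth Gabor
dictionary, full-field sinusoidal grating batteries, and a small labelled
bar-composite image set for classification/attack experiments.  All
generators are pure functions of their arguments (including the seed), so
every experiment is bit-reproducible.

Conventions
-----------
Images are H x W pixel grids flattened row-major into length-P vectors
(P = H*W).  Pixel coordinates (x, y) are centered at the patch midpoint and
measured in pixels; orientation is measured counter-clockwise from the
horizontal axis.  Spatial frequency is in cycles/pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StimulusBatch:
    """A batch of flat images plus optional per-stimulus parameters.

    ``data`` has shape (n_stimuli, P) with P = height * width; ``meta`` is a
    DataFrame aligned row-for-row with ``data`` (orientation/phase/frequency/
    contrast for gratings, ``label`` for classed sets) or ``None``.
    """

    data: np.ndarray
    height: int
    width: int
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != self.height * self.width:
            raise ValueError(
                f"data has {self.data.shape[1]} pixels, expected "
                f"{self.height}x{self.width}={self.height * self.width}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stimulus batch contains non-finite pixels")
        if self.meta is not None and len(self.meta) != len(self.data):
            raise ValueError("meta table length does not match batch size")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def images(self) -> np.ndarray:
        """Return the batch reshaped to (n, height, width)."""
        return self.data.reshape(self.n, self.height, self.width)


@dataclass
class GroundTruth:
    """Generating dictionary and coefficients of the sparse linear model.

    Data are assumed to arise as ``s = phi_star @ a + noise`` with ``a``
    sparse and nonnegative; ``coeffs`` stores the coefficients of the most
    recent :func:`sample_sparse_patches` draw.
    """

    phi_star: np.ndarray                    # (P, N*) unit-norm columns
    noise_sd: float = 0.0
    coeffs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.phi_star = np.asarray(self.phi_star, dtype=float)
        norms = np.linalg.norm(self.phi_star, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("ground-truth atoms must have unit L2 norm")

    @property
    def n_pixels(self) -> int:
        return self.phi_star.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.phi_star.shape[1]


# ---------------------------------------------------------------------------
# Gabor ground-truth dictionary
# ---------------------------------------------------------------------------

def _pixel_lattice(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered pixel coordinates; x runs along columns, y along rows."""
    y, x = np.mgrid[0:height, 0:width].astype(float)
    x -= (width - 1) / 2.0
    y -= (height - 1) / 2.0
    return x, y


def gabor_atom(
    height: int,
    width: int,
    theta: float,
    phase: float,
    frequency: float,
    sigma: float,
    aspect: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """A single unit-norm Gabor patch, flattened row-major.

    ``theta`` is the orientation of the carrier wave vector (rad, CCW from
    horizontal), ``frequency`` in cycles/pixel, ``sigma`` the envelope width
    in pixels and ``aspect`` the envelope elongation across/along the wave.
    """
    x, y = _pixel_lattice(height, width)
    xc, yc = x - center[0], y - center[1]
    xr = xc * np.cos(theta) + yc * np.sin(theta)
    yr = -xc * np.sin(theta) + yc * np.cos(theta)
    envelope = np.exp(-(xr**2 + (aspect * yr) ** 2) / (2.0 * sigma**2))
    carrier = np.cos(2.0 * np.pi * frequency * xr + phase)
    patch = (envelope * carrier).ravel()
    norm = np.linalg.norm(patch)
    if norm < 1e-12:      # degenerate draw (phase kills the envelope)
        raise FloatingPointError("degenerate Gabor atom")
    return patch / norm


def make_gabor_dictionary(
    height: int,
    width: int,
    n_atoms: int,
    seed: int,
    freq_range: tuple[float, float] = (0.08, 0.35),
    sigma_frac_range: tuple[float, float] = (0.12, 0.3),
    center_frac: float = 0.3,
) -> np.ndarray:
    """Random bank of unit-norm Gabor atoms, deterministic given ``seed``.

    Orientations are uniform on [0, pi), phases uniform on [0, 2pi),
    frequencies and envelope widths uniform on the given ranges (widths as a
    fraction of min(height, width)), centers jittered uniformly within
    ``center_frac`` of the patch around the midpoint.
    """
    if height <= 0 or width <= 0 or height * width < 4:
        raise ValueError("patch must have at least 4 pixels")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    side = min(height, width)
    atoms = np.empty((height * width, n_atoms))
    i = 0
    while i < n_atoms:
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        freq = rng.uniform(*freq_range)
        sigma = side * rng.uniform(*sigma_frac_range)
        aspect = rng.uniform(0.5, 1.0)
        cx = rng.uniform(-center_frac, center_frac) * width
        cy = rng.uniform(-center_frac, center_frac) * height
        try:
            atoms[:, i] = gabor_atom(
                height, width, theta, phase, freq, sigma, aspect, (cx, cy)
            )
        except FloatingPointError:
            continue
        i += 1
    return atoms


def make_gabor_ground_truth(
    height: int, width: int, n_atoms: int, seed: int, noise_sd: float = 0.02
) -> GroundTruth:
    """Convenience wrapper bundling a Gabor bank into a :class:`GroundTruth`."""
    return GroundTruth(
        phi_star=make_gabor_dictionary(height, width, n_atoms, seed),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# Sparse patches from the generative model
# ---------------------------------------------------------------------------

def sample_sparse_patches(
    ground_truth: GroundTruth,
    n: int,
    sparsity: float,
    seed: int,
) -> StimulusBatch:
    """Draw patches ``s = phi_star @ a + eps`` from the generative model.

    Each coefficient is independently nonzero with probability ``sparsity``;
    nonzero values are Exponential(1) (nonnegative, heavy-tailed).  Pixel
    noise is i.i.d. Gaussian with sd ``ground_truth.noise_sd``.  The drawn
    coefficients are stored on ``ground_truth.coeffs``.
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_atoms = ground_truth.n_atoms
    mask = rng.random((n, n_atoms)) < sparsity
    coeffs = np.where(mask, rng.exponential(1.0, size=(n, n_atoms)), 0.0)
    data = coeffs @ ground_truth.phi_star.T
    if ground_truth.noise_sd > 0:
        data = data + rng.normal(0.0, ground_truth.noise_sd, size=data.shape)
    ground_truth.coeffs = coeffs
    side = int(round(np.sqrt(ground_truth.n_pixels)))
    height, width = (side, side) if side * side == ground_truth.n_pixels else (
        1, ground_truth.n_pixels)
    return StimulusBatch(data=data, height=height, width=width)


def standardize(batch: StimulusBatch) -> StimulusBatch:
    """Zero-mean, unit-L2-norm each patch (all-zero rows are left at zero).

    Encoders in this package expect standardized inputs; raw generative draws
    keep their natural scale so the generative identities remain exact.
    """
    data = batch.data - batch.data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data, axis=1, keepdims=True)
    data = np.divide(data, norms, out=np.zeros_like(data), where=norms > 1e-12)
    return StimulusBatch(data=data, height=batch.height, width=batch.width,
                         meta=batch.meta)


def expected_pixel_energy(ground_truth: GroundTruth, sparsity: float) -> float:
    """Exact E[s_p^2] averaged over pixels under the generative model.

    With activation probability p and Exponential(1) magnitudes,
    E[a_j a_k] = 2p (j = k) and p^2 (j != k); the atom Gram matrix supplies
    the cross terms and the pixel noise adds noise_sd^2.
    """
    phi = ground_truth.phi_star
    p = sparsity
    gram = phi.T @ phi
    diag = np.trace(gram)                      # = n_atoms for unit-norm atoms
    off = gram.sum() - diag
    per_pixel = (2.0 * p * diag + p * p * off) / phi.shape[0]
    return per_pixel + ground_truth.noise_sd**2


# ---------------------------------------------------------------------------
# Grating batteries
# ---------------------------------------------------------------------------

def grating(
    height: int,
    width: int,
    theta: float,
    phase: float,
    frequency: float,
    contrast: float = 1.0,
) -> np.ndarray:
    """Full-field sinusoidal grating, flattened row-major.

    ``contrast * sin(2*pi*f*(x cos(theta) + y sin(theta)) + phase)`` on the
    centered pixel lattice.
    """
    x, y = _pixel_lattice(height, width)
    arg = 2.0 * np.pi * frequency * (x * np.cos(theta) + y * np.sin(theta))
    return (contrast * np.sin(arg + phase)).ravel()


def make_grating_battery(
    height: int,
    width: int,
    n_orientations: int = 32,
    n_phases: int = 8,
    frequencies: Sequence[float] = (0.1, 0.2, 0.3),
    contrast: float = 1.0,
) -> StimulusBatch:
    """Battery of gratings over all (orientation, phase, frequency) triples.

    Orientations are evenly spaced on [0, pi); phases on [0, 2pi).  Battery
    size is n_orientations * n_phases * len(frequencies) and ``meta`` records
    the triple for every row.
    """
    if n_orientations < 2:
        raise ValueError("need at least 2 orientations")
    frequencies = list(frequencies)
    if not frequencies:
        raise ValueError("frequency list must be non-empty")
    thetas = np.linspace(0.0, np.pi, n_orientations, endpoint=False)
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=False)
    rows, recs = [], []
    for theta in thetas:
        for phase in phases:
            for freq in frequencies:
                rows.append(grating(height, width, theta, phase, freq, contrast))
                recs.append(dict(orientation=theta, phase=phase,
                                 frequency=freq, contrast=contrast))
    return StimulusBatch(
        data=np.array(rows), height=height, width=width,
        meta=pd.DataFrame.from_records(recs),
    )


# ---------------------------------------------------------------------------
# Labelled toy image classes
# ---------------------------------------------------------------------------

def _bar_image(height: int, width: int, theta: float, offset: float,
               thickness: float, amplitude: float) -> np.ndarray:
    """Soft oriented bar: Gaussian profile across an oriented line."""
    x, y = _pixel_lattice(height, width)
    d = -x * np.sin(theta) + y * np.cos(theta) - offset
    return (amplitude * np.exp(-(d**2) / (2.0 * thickness**2))).ravel()


def class_prototype(height: int, width: int, class_id: int, seed: int) -> np.ndarray:
    """Fixed prototype for one class: a superposition of 2-4 oriented bars.

    Poses are drawn from a class-specific deterministic stream so that every
    call with the same (class_id, seed) returns the same image.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, class_id]))
    n_bars = int(rng.integers(2, 5))
    img = np.zeros(height * width)
    for _ in range(n_bars):
        theta = rng.uniform(0.0, np.pi)
        offset = rng.uniform(-0.25, 0.25) * min(height, width)
        thickness = rng.uniform(0.5, 1.2)
        amplitude = rng.uniform(0.6, 1.0)
        img += _bar_image(height, width, theta, offset, thickness, amplitude)
    return np.clip(img, 0.0, 1.0)


def make_toy_classes(
    height: int,
    width: int,
    n_classes: int = 10,
    n_per_class: int = 100,
    jitter_sd: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> StimulusBatch:
    """Labelled image set: jittered, noisy renderings of fixed bar prototypes.

    Samples are the class prototype translated by a Gaussian positional
    jitter (``jitter_sd`` pixels, bilinear interpolation with wrap-around)
    plus i.i.d. Gaussian pixel noise, clipped to [0, 1].  ``meta['label']``
    holds the integer class.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    protos = [class_prototype(height, width, c, seed).reshape(height, width)
              for c in range(n_classes)]
    rows, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = protos[c]
            if jitter_sd > 0:
                shift = rng.normal(0.0, jitter_sd, size=2)
                img = ndimage.shift(img, shift, order=1, mode="grid-wrap")
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            rows.append(np.clip(img, 0.0, 1.0).ravel())
            labels.append(c)
    return StimulusBatch(
        data=np.array(rows), height=height, width=width,
        meta=pd.DataFrame({"label": labels}),
    )


def toy_prototypes(height: int, width: int, n_classes: int, seed: int) -> np.ndarray:
    """Stack of the fixed class prototypes, shape (n_classes, P)."""
    return np.array([class_prototype(height, width, c, seed)
                     for c in range(n_classes)])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_batch(batch: StimulusBatch, path: str | Path) -> None:
    """Write a batch to ``<path>.npz`` with a JSON meta sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=batch.data,
             shape=np.array([batch.height, batch.width]))
    if batch.meta is not None:
        path.with_suffix(".meta.json").write_text(
            batch.meta.to_json(orient="records"))


def load_batch(path: str | Path) -> StimulusBatch:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as archive:
        data = archive["data"]
        height, width = (int(v) for v in archive["shape"])
    meta_path = path.with_suffix(".meta.json")
    meta = None
    if meta_path.exists():
        meta = pd.DataFrame(json.loads(meta_path.read_text()))
    return StimulusBatch(data=data, height=height, width=width, meta=meta)


def export_meta_csv(batch: StimulusBatch, path: str | Path) -> None:
    if batch.meta is None:
        raise ValueError("batch has no meta table")
    batch.meta.to_csv(path, index=False)
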
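"""Iso-response geometry of single neurons.

A neuron's iso-response surface is the set of stimuli mapped to the same
activation.  To characterize it we restrict the stimulus space to 2-D
planes spanned by the target neuron's (unit-norm) weight vector and an
orthonormal second axis, sample the neuron's response on a regular grid in
that plane, extract level-crossing contours of the normalized response, and
fit second-order polynomials whose quadratic coefficients quantify the
contour curvature:

* ``c_iso``  — curvature of an iso-response contour, from the fit
  x(y) = c2 y^2 + c1 y + c0; positive c2 bends the contour away from the
  origin (exo-origin, the signature of hyperselectivity).
* ``c_att``  — curvature of the response-attenuation profile along the
  direction orthogonal to the weight vector, sign-flipped so positive means
  the response falls off away from the axis.

Second axes come from two protocols: "comparison" planes orthogonalize
another neuron's weight against the target (one Gram-Schmidt step), which
maximizes the chance of lateral competition; "random" planes draw the
second axis isotropically from the orthogonal complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .encoders import Dictionary, Encoder


N_BINS = 10


class DegeneratePlaneError(ValueError):
    """Target and comparison weight vectors are (anti)parallel."""


# ---------------------------------------------------------------------------
# Planes
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """Ordered orthonormal pair spanning a 2-D stimulus subspace.

    ``phi_hat`` is the normalized target weight vector; ``nu`` the second,
    orthogonal axis.  ``method`` records the protocol that produced ``nu``.
    """

    phi_hat: np.ndarray
    nu: np.ndarray
    method: str                      # "comparison" | "random"
    target_id: int
    comparison_id: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.phi_hat = np.asarray(self.phi_hat, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if abs(np.linalg.norm(self.phi_hat) - 1) > 1e-10 or \
                abs(np.linalg.norm(self.nu) - 1) > 1e-10:
            raise ValueError("plane axes must be unit norm")
        if abs(self.phi_hat @ self.nu) > 1e-10:
            raise ValueError("plane axes must be orthogonal")

    def embed(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Map plane coordinates (x_i, y_i) to stimuli x*phi_hat + y*nu."""
        return np.outer(xs, self.phi_hat) + np.outer(ys, self.nu)


def make_comparison_plane(dictionary: Dictionary, target_k: int,
                          comparison_j: int) -> Plane:
    """Plane through the target and a comparison neuron's weight vectors.

    One Gram-Schmidt step orthogonalizes the comparison weight against the
    target weight; the result is coplanar with both.
    """
    if target_k == comparison_j:
        raise DegeneratePlaneError("target and comparison must differ")
    phi_k = dictionary.phi[:, target_k]
    phi_j = dictionary.phi[:, comparison_j]
    phi_hat = phi_k / np.linalg.norm(phi_k)
    cos = phi_hat @ phi_j / np.linalg.norm(phi_j)
    if abs(cos) > 1 - 1e-8:
        raise DegeneratePlaneError(
            f"weights {target_k} and {comparison_j} are parallel (|cos|={abs(cos):.2e})")
    residual = phi_j - (phi_hat @ phi_j) * phi_hat
    nu = residual / np.linalg.norm(residual)
    return Plane(phi_hat=phi_hat, nu=nu, method="comparison",
                 target_id=target_k, comparison_id=comparison_j)


def make_random_plane(dictionary: Dictionary, target_k: int, seed: int) -> Plane:
    """Plane spanned by the target weight and a random orthogonal direction."""
    phi_k = dictionary.phi[:, target_k]
    phi_hat = phi_k / np.linalg.norm(phi_k)
    rng = np.random.default_rng(seed)
    while True:
        v = rng.standard_normal(dictionary.n_pixels)
        residual = v - (phi_hat @ v) * phi_hat
        norm = np.linalg.norm(residual)
        if norm > 1e-8:
            return Plane(phi_hat=phi_hat, nu=residual / norm, method="random",
                         target_id=target_k, seed=seed)


# ---------------------------------------------------------------------------
# Response grids
# ---------------------------------------------------------------------------

@dataclass
class ResponseGrid:
    """Target-neuron responses on a regular grid in a stimulus plane.

    ``responses[i, j]`` is the raw activation at (xs[j], ys[i]);
    ``normalized`` divides by the grid maximum and ``bins`` partitions the
    normalized response into 10 equal bins.  ``degenerate`` flags an
    all-zero grid (no normalization possible).
    """

    xs: np.ndarray
    ys: np.ndarray
    responses: np.ndarray
    normalized: np.ndarray
    bins: np.ndarray
    plane: Plane
    degenerate: bool = False


def response_grid(encoder: Encoder, plane: Plane, extent: float = 2.0,
                  n_side: int = 30) -> ResponseGrid:
    """Probe the target neuron on an n_side x n_side grid in the plane.

    The stimulus at grid point (x, y) is ``x * phi_hat + y * nu``; the grid
    spans [-extent, extent]^2 centered on the origin (900 points at the
    default side of 30).
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    xs = np.linspace(-extent, extent, n_side)
    ys = np.linspace(-extent, extent, n_side)
    X, Y = np.meshgrid(xs, ys)                    # shape (n_side, n_side)
    stimuli = plane.embed(X.ravel(), Y.ravel())
    responses = encoder.response(stimuli, plane.target_id).reshape(n_side, n_side)
    peak = responses.max()
    if peak <= 0:
        zeros = np.zeros_like(responses)
        return ResponseGrid(xs, ys, responses, zeros,
                            zeros.astype(int), plane, degenerate=True)
    normalized = responses / peak
    bins = np.clip((normalized * N_BINS).astype(int), 0, N_BINS - 1)
    return ResponseGrid(xs, ys, responses, normalized, bins, plane)


# ---------------------------------------------------------------------------
# Contours and curvature
# ---------------------------------------------------------------------------

class EmptyContourError(ValueError):
    """The requested level is not attained anywhere on the grid."""


def _index_to_coord(idx: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Linear map from fractional array index to grid coordinate."""
    step = coords[1] - coords[0]
    return coords[0] + idx * step


def extract_iso_contour(grid: ResponseGrid, level: float = 0.5) -> np.ndarray:
    """Sub-pixel points (x, y) of the normalized-response level set.

    Marching squares with linear interpolation (via scikit-image); when the
    level set has several connected components, only the one nearest the
    positive x axis — the component around the on-axis preferred-stimulus
    crossing — is returned.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if grid.degenerate:
        raise ValueError("cannot extract contours from a degenerate grid")
    contours = measure.find_contours(grid.normalized, level)
    if not contours:
        raise EmptyContourError(f"level {level} not attained")
    best, best_d = None, np.inf
    for c in contours:                # c[:, 0] = row (y index), c[:, 1] = col
        x = _index_to_coord(c[:, 1], grid.xs)
        y = _index_to_coord(c[:, 0], grid.ys)
        # distance to the +x half-axis {(t, 0): t >= 0}
        d = np.min(np.hypot(np.maximum(0.0, -x), y))
        if d < best_d:
            best, best_d = np.column_stack([x, y]), d
    return best


@dataclass
class CurvatureRecord:
    """Quadratic coefficients for one plane's contour fits.

    ``c_iso`` > 0 means the iso-response contour bends away from the origin
    (exo-origin); ``c_att`` > 0 means the response attenuates away from the
    weight-vector axis.  ``ok`` is False when a fit could not be performed
    (flagged, never raised, so population sweeps keep going).
    """

    c_iso: float
    c_att: float
    level: float
    plane: Plane
    ok: bool = True
    note: str = ""


def fit_iso_quadratic(points: np.ndarray) -> float:
    """Quadratic coefficient of the least-squares fit x(y) = c2 y^2 + c1 y + c0."""
    x, y = points[:, 0], points[:, 1]
    if len(points) < 5 or np.ptp(y) <= 0:
        raise ValueError("need >= 5 contour points spanning a y range")
    return float(np.polyfit(y, x, 2)[0])


def _on_axis_crossing(grid: ResponseGrid, level: float) -> float:
    """Smallest x > 0 where the on-axis normalized response crosses `level`.

    The on-axis profile is the average of the two grid rows bracketing y=0
    (exact for even n_side; the row itself for odd n_side).
    """
    mid = len(grid.ys) // 2
    if len(grid.ys) % 2 == 1:
        profile = grid.normalized[mid]
    else:
        profile = 0.5 * (grid.normalized[mid - 1] + grid.normalized[mid])
    xs = grid.xs
    crossings = []
    for j in range(len(xs) - 1):
        lo, hi = profile[j] - level, profile[j + 1] - level
        if lo == 0.0:
            crossings.append(xs[j])
        elif lo * hi < 0:
            frac = lo / (lo - hi)
            crossings.append(xs[j] + frac * (xs[j + 1] - xs[j]))
    if not crossings:
        raise EmptyContourError(f"on-axis response never attains level {level}")
    positive = [x for x in crossings if x > 0]
    # prefer the crossing on the preferred-stimulus side; an encoder whose
    # half-max sits exactly on the origin (e.g. unbiased sigmoid) may only
    # cross at x <= 0, in which case take the crossing nearest the +x axis
    return min(positive) if positive else max(crossings)


def fit_curvature(grid: ResponseGrid, level: float = 0.5,
                  points: np.ndarray | None = None) -> CurvatureRecord:
    """Fit iso-response and response-attenuation curvature for one plane.

    ``c_iso`` comes from the quadratic fit x(y) to the extracted contour;
    ``c_att`` is minus the quadratic coefficient of the normalized response
    along the grid column at the on-axis point attaining ``level``.  Fit
    failures are recorded in the result, not raised.
    """
    plane = grid.plane
    try:
        if points is None:
            points = extract_iso_contour(grid, level)
        c_iso = fit_iso_quadratic(points)
        x_star = _on_axis_crossing(grid, level)
        j_star = int(np.argmin(np.abs(grid.xs - x_star)))
        d2 = np.polyfit(grid.ys, grid.normalized[:, j_star], 2)[0]
        c_att = -float(d2)
    except (ValueError, EmptyContourError) as err:
        return CurvatureRecord(c_iso=np.nan, c_att=np.nan, level=level,
                               plane=plane, ok=False, note=str(err))
    return CurvatureRecord(c_iso=c_iso, c_att=c_att, level=level, plane=plane)


# ---------------------------------------------------------------------------
# Population sweep
# ---------------------------------------------------------------------------

def population_curvature(
    encoder: Encoder,
    dictionary: Dictionary | None = None,
    n_neurons: int = 100,
    planes_per_method: int = 300,
    seed: int = 0,
    extent: float = 2.0,
    n_side: int = 30,
    level: float = 0.5,
    methods: tuple[str, ...] = ("comparison", "random"),
) -> pd.DataFrame:
    """Curvature records for a random sample of neurons and planes.

    For every sampled neuron, ``planes_per_method`` comparison planes
    (random other neurons) and as many random-orthogonal planes are probed
    with the grid protocol and fitted.  Failed fits appear as flagged rows
    (``ok = False``) rather than being dropped silently.
    """
    dictionary = dictionary or encoder.dictionary
    n_atoms = dictionary.n_atoms
    if n_atoms <= n_neurons:
        raise ValueError("dictionary must have more atoms than sampled neurons")
    rng = np.random.default_rng(seed)
    neuron_ids = rng.choice(n_atoms, size=n_neurons, replace=False)
    rows = []
    for k in neuron_ids:
        others = np.delete(np.arange(n_atoms), k)
        planes: list[Plane] = []
        if "comparison" in methods:
            comp = rng.choice(others, size=min(planes_per_method, len(others)),
                              replace=planes_per_method > len(others))
            for j in comp:
                try:
                    planes.append(make_comparison_plane(dictionary, int(k), int(j)))
                except DegeneratePlaneError:
                    continue
        if "random" in methods:
            for _ in range(planes_per_method):
                planes.append(make_random_plane(
                    dictionary, int(k), int(rng.integers(0, 2**31 - 1))))
        for plane in planes:
            grid = response_grid(encoder, plane, extent=extent, n_side=n_side)
            if grid.degenerate:
                rec = CurvatureRecord(np.nan, np.nan, level, plane,
                                      ok=False, note="degenerate grid")
            else:
                rec = fit_curvature(grid, level)
            rows.append(dict(
                neuron_id=int(k), plane_method=plane.method,
                comparison_id=plane.comparison_id, plane_seed=plane.seed,
                level=level, c_iso=rec.c_iso, c_att=rec.c_att, ok=rec.ok,
                note=rec.note,
            ))
    return pd.DataFrame(rows)


def presentation_count(n_neurons: int, planes_per_method: int,
                       n_side: int = 30, n_methods: int = 2) -> int:
    """Total stimulus presentations for a population curvature sweep."""
    return n_neurons * n_methods * planes_per_method * n_side**2
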
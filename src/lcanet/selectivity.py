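"""Stimulus selectivity: orientation tuning and selected-image analysis.

Two complementary probes of how sharply a neuron is tuned:

* **Gratings.**  For a battery of full-field sinusoidal gratings, a
  neuron's tuning curve is its maximal activation at each orientation
  (envelope over phase and spatial frequency).  Circular variance
  ``CV = 1 - |sum_j r_j exp(2i theta_j)| / sum_j r_j`` summarizes tuning
  sharpness on [0, 1]: 0 is perfectly orientation-locked, 1 untuned (the
  doubled angle accounts for the pi-periodicity of orientation).

* **Generic images.**  A neuron's "selected images" are the members of a
  probe set whose activation reaches at least a fraction (default 50%) of
  the neuron's maximum over the set.  Fewer selected images, and smaller
  angles between the selected images and the weight vector, mean higher
  selectivity.  Comparing a lateral-inhibition encoder against a pointwise
  control with *identical* feedforward weights isolates the effect of the
  population nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoders import Encoder
from .synthetic_data import StimulusBatch


# ---------------------------------------------------------------------------
# Orientation tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Orientation (rad, in [0, pi)) versus nonnegative response."""

    thetas: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.thetas.shape != self.responses.shape:
            raise ValueError("thetas and responses must align")
        if np.any(self.responses < 0):
            raise ValueError("tuning responses must be nonnegative")


class UndefinedCV(ValueError):
    """Circular variance of an all-zero tuning curve (neuron excluded)."""


def orientation_tuning(encoder: Encoder, neuron_k: int,
                       battery: StimulusBatch) -> TuningCurve:
    """Envelope tuning: max activation over phase/frequency per orientation.

    Negative responses (possible for the raw linear control) are floored at
    zero so the curve is a valid nonnegative tuning function for CV.
    """
    if battery.meta is None or "orientation" not in battery.meta:
        raise ValueError("battery must carry orientation meta")
    acts = np.maximum(0.0, encoder.response(battery.data, neuron_k))
    df = pd.DataFrame({"orientation": battery.meta["orientation"].to_numpy(),
                       "response": acts})
    env = df.groupby("orientation", sort=True)["response"].max()
    return TuningCurve(thetas=env.index.to_numpy(), responses=env.to_numpy())


def circular_variance(tuning: TuningCurve) -> float:
    """CV = 1 - |resultant of responses at doubled angles| / total response."""
    total = tuning.responses.sum()
    if total <= 0:
        raise UndefinedCV("all-zero tuning curve")
    resultant = np.abs(np.sum(tuning.responses * np.exp(2j * tuning.thetas)))
    return float(1.0 - resultant / total)


def population_circular_variance(encoder: Encoder, battery: StimulusBatch,
                                 neuron_ids: np.ndarray | None = None) -> pd.DataFrame:
    """CV for every (or a subset of) neuron; untuned all-zero neurons flagged.

    Activations for the whole battery are computed once and reused across
    neurons.
    """
    if battery.meta is None or "orientation" not in battery.meta:
        raise ValueError("battery must carry orientation meta")
    acts = np.maximum(0.0, encoder.encode(battery.data))
    orientation = battery.meta["orientation"].to_numpy()
    if neuron_ids is None:
        neuron_ids = np.arange(acts.shape[1])
    rows = []
    for k in neuron_ids:
        df = pd.DataFrame({"orientation": orientation, "response": acts[:, k]})
        env = df.groupby("orientation", sort=True)["response"].max()
        curve = TuningCurve(env.index.to_numpy(), env.to_numpy())
        try:
            cv = circular_variance(curve)
            rows.append(dict(neuron_id=int(k), cv=cv, ok=True))
        except UndefinedCV:
            rows.append(dict(neuron_id=int(k), cv=np.nan, ok=False))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Selected images
# ---------------------------------------------------------------------------

@dataclass
class SelectivityReport:
    """Selected-image statistics for one neuron under one encoder."""

    neuron_id: int
    n_selected: int
    angles: np.ndarray            # degrees between weight vector and images
    encoder_tag: str
    ok: bool = True

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.ok and self.n_selected != len(self.angles):
            raise ValueError("n_selected must match the number of angles")
        if np.any((self.angles < 0) | (self.angles > 180)):
            raise ValueError("angles must lie in [0, 180] degrees")


def _weight_image_angles(weight: np.ndarray, images: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(images, axis=1) * np.linalg.norm(weight)
    cos = np.divide(images @ weight, norms, out=np.zeros(len(images)),
                    where=norms > 1e-300)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def selected_images(encoder: Encoder, neuron_k: int, batch: StimulusBatch,
                    fraction: float = 0.5,
                    activations: np.ndarray | None = None) -> SelectivityReport:
    """Images whose activation reaches ``fraction`` of the neuron's maximum.

    ``activations`` may carry precomputed responses of neuron k over the
    batch (used by the population comparison to avoid re-encoding).
    """
    if batch.n == 0:
        raise ValueError("probe batch is empty")
    acts = encoder.response(batch.data, neuron_k) if activations is None \
        else np.asarray(activations, dtype=float)
    peak = acts.max()
    if peak <= 0:
        return SelectivityReport(neuron_id=neuron_k, n_selected=0,
                                 angles=np.array([]), encoder_tag=encoder.tag,
                                 ok=False)
    mask = acts >= fraction * peak
    angles = _weight_image_angles(encoder.weight(neuron_k), batch.data[mask])
    return SelectivityReport(neuron_id=neuron_k, n_selected=int(mask.sum()),
                             angles=angles, encoder_tag=encoder.tag)


def selectivity_table(encoder: Encoder, batch: StimulusBatch,
                      fraction: float = 0.5,
                      neuron_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-neuron selected-image counts and mean angles for one encoder."""
    acts = encoder.encode(batch.data)
    if neuron_ids is None:
        neuron_ids = np.arange(acts.shape[1])
    rows = []
    for k in neuron_ids:
        rep = selected_images(encoder, int(k), batch, fraction,
                              activations=acts[:, k])
        rows.append(dict(neuron_id=int(k), encoder_tag=encoder.tag,
                         n_selected=rep.n_selected,
                         mean_angle=rep.angles.mean() if rep.ok else np.nan,
                         ok=rep.ok))
    return pd.DataFrame(rows)


def compare_selectivity(encoder_a: Encoder, encoder_b: Encoder,
                        batch: StimulusBatch, fraction: float = 0.5,
                        neuron_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Paired per-neuron selected-image comparison for two encoders.

    Both encoders must share one dictionary (the identical-weights control
    design); the returned frame has one row per neuron with counts and mean
    angles under each encoder.
    """
    if encoder_a.dictionary is not encoder_b.dictionary and \
            not np.array_equal(encoder_a.dictionary.phi, encoder_b.dictionary.phi):
        raise ValueError("encoders must share the same dictionary")
    ta = selectivity_table(encoder_a, batch, fraction, neuron_ids)
    tb = selectivity_table(encoder_b, batch, fraction, neuron_ids)
    suffixes = (f"_{encoder_a.tag}", f"_{encoder_b.tag}")
    if suffixes[0] == suffixes[1]:
        suffixes = (f"{suffixes[0]}_a", f"{suffixes[1]}_b")
    return ta.merge(tb, on="neuron_id", suffixes=suffixes)


def save_tuning_curves(curves: dict[int, TuningCurve], path) -> None:
    """Persist a set of tuning curves to one array container.

    Keys are neuron ids; stored as ``thetas`` plus one response row per
    neuron (all curves share the orientation grid of a common battery).
    """
    import numpy as _np
    ids = sorted(curves)
    thetas = curves[ids[0]].thetas
    rows = _np.stack([curves[k].responses for k in ids])
    _np.savez(path, neuron_ids=_np.array(ids), thetas=thetas, responses=rows)


def selectivity_summary(table: pd.DataFrame, column: str) -> dict:
    """Median/quartiles/5-95 percentiles of one column (box-plot convention)."""
    vals = table[column].dropna().to_numpy()
    q = np.percentile(vals, [5, 25, 50, 75, 95]) if len(vals) else [np.nan] * 5
    return dict(p05=float(q[0]), q1=float(q[1]), median=float(q[2]),
                q3=float(q[3]), p95=float(q[4]), mean=float(np.mean(vals)) if len(vals) else np.nan,
                n=int(len(vals)))
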
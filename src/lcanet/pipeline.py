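"""Config-driven experiment orchestration.

Bundles the four experiment families — dictionary preparation, population
curvature, selectivity, robustness — behind one serializable configuration
so that complete runs are reproducible from a single YAML file and a seed.
Desk-scale defaults keep a full run in minutes; paper-scale settings
(16x16 patches, 100 neurons, 300 planes per method, 100,000 probe images)
are reachable by editing the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import encoders, geometry, robustness, selectivity, synthetic_data
from .encoders import (Dictionary, LCAEncoder, LCAParams, LearnConfig,
                       LinearEncoder, ReluEncoder, SigmoidEncoder)

log = logging.getLogger("lcanet")


@dataclass
class ExperimentConfig:
    """Every knob of an end-to-end run; round-trips losslessly through YAML."""

    # patch geometry / generative model
    height: int = 8
    width: int = 8
    overcompleteness: tuple[float, ...] = (1.0, 2.0, 4.0)
    sparsity: float = 0.05
    noise_sd: float = 0.02
    n_train_patches: int = 2000

    # LCA / learning
    lam: float = 0.2
    n_steps: int = 150
    step: float = 0.05
    eta: float = 0.1
    batch_size: int = 100
    n_epochs: int = 10
    train_dictionary: bool = True

    # geometry sampling
    n_neurons: int = 20
    planes_per_method: int = 50
    grid_side: int = 30
    grid_extent: float = 2.0
    contour_level: float = 0.5

    # selectivity
    n_orientations: int = 32
    n_phases: int = 8
    frequencies: tuple[float, ...] = (0.1, 0.2, 0.3)
    n_probe_images: int = 20000
    selected_fraction: float = 0.5

    # robustness
    n_classes: int = 10
    n_per_class_train: int = 100
    n_per_class_test: int = 10
    jitter_sd: float = 0.5
    class_noise_sd: float = 0.05
    attack_step: float = 0.01
    attack_max_iters: int = 2000
    conf_target: float = 0.90
    conf_snapshot: float = 0.95
    accuracy_margin: float = 0.02
    n_robustness_seeds: int = 10

    # bookkeeping
    seed: int = 0
    out_dir: str = "lcanet_outputs"

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def lca_params(self) -> LCAParams:
        return LCAParams(lam=self.lam, n_steps=self.n_steps, step=self.step)

    def learn_config(self, seed_offset: int = 0) -> LearnConfig:
        return LearnConfig(eta=self.eta, batch_size=self.batch_size,
                           n_epochs=self.n_epochs, seed=self.seed + seed_offset)

    def attack_config(self) -> robustness.AttackConfig:
        return robustness.AttackConfig(
            step=self.attack_step, max_iters=self.attack_max_iters,
            conf_target=self.conf_target, conf_snapshot=self.conf_snapshot)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["overcompleteness"] = list(self.overcompleteness)
        d["frequencies"] = list(self.frequencies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "overcompleteness" in d:
            d["overcompleteness"] = tuple(d["overcompleteness"])
        if "frequencies" in d:
            d["frequencies"] = tuple(d["frequencies"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def paper_scale_config() -> ExperimentConfig:
    """The full-scale protocol: 16x16 patches, 100 neurons, 300 planes/method,
    100,000 probe images."""
    return ExperimentConfig(height=16, width=16, n_neurons=100,
                            planes_per_method=300, n_probe_images=100_000)


# ---------------------------------------------------------------------------
# Shared preparation
# ---------------------------------------------------------------------------

def prepare_dictionary(config: ExperimentConfig, overcompleteness: float,
                       seed_offset: int = 0) -> Dictionary:
    """Ground-truth Gabor bank at the requested overcompleteness; optionally
    refined by sparse-coding dictionary learning on model-generated patches."""
    n_atoms = int(round(overcompleteness * config.n_pixels))
    gt = synthetic_data.make_gabor_ground_truth(
        config.height, config.width, n_atoms, seed=config.seed + seed_offset,
        noise_sd=config.noise_sd)
    phi0 = synthetic_data.make_gabor_dictionary(
        config.height, config.width, n_atoms, seed=config.seed + seed_offset + 104729)
    init = Dictionary.from_columns(phi0)
    if not config.train_dictionary:
        return Dictionary.from_columns(gt.phi_star)
    patches = synthetic_data.sample_sparse_patches(
        gt, config.n_train_patches, config.sparsity,
        seed=config.seed + seed_offset + 1)
    patches = synthetic_data.standardize(patches)
    learned = encoders.learn_dictionary(
        patches, init, config.learn_config(seed_offset + 2),
        config.lca_params())
    return learned


def probe_patches(config: ExperimentConfig, n: int, seed_offset: int = 0,
                  overcompleteness: float = 2.0) -> synthetic_data.StimulusBatch:
    """Standardized patches from the generative model, for probing."""
    n_atoms = int(round(overcompleteness * config.n_pixels))
    gt = synthetic_data.make_gabor_ground_truth(
        config.height, config.width, n_atoms, seed=config.seed + seed_offset,
        noise_sd=config.noise_sd)
    batch = synthetic_data.sample_sparse_patches(
        gt, n, config.sparsity, seed=config.seed + seed_offset + 7)
    return synthetic_data.standardize(batch)


def _write(df: pd.DataFrame, config: ExperimentConfig, out: Path,
           name: str) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    df = df.copy()
    df.attrs["config_hash"] = config.config_hash()
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------

def run_curvature_study(config: ExperimentConfig,
                        write: bool = True) -> dict:
    """Population curvature for LCA across overcompleteness levels, plus the
    pointwise controls, with presentation-count bookkeeping."""
    out = Path(config.out_dir)
    results: dict = {"tables": {}, "presentations_per_level":
                     geometry.presentation_count(
                         config.n_neurons, config.planes_per_method,
                         config.grid_side)}
    for oc in config.overcompleteness:
        dictionary = prepare_dictionary(config, oc, seed_offset=int(oc * 10))
        enc = LCAEncoder(dictionary, config.lca_params())
        table = geometry.population_curvature(
            enc, n_neurons=config.n_neurons,
            planes_per_method=config.planes_per_method, seed=config.seed,
            extent=config.grid_extent, n_side=config.grid_side,
            level=config.contour_level)
        table["overcompleteness"] = oc
        table["encoder"] = "lca"
        results["tables"][f"lca_{oc}x"] = table
        if write:
            _write(table, config, out, f"curvature_lca_{oc}x.csv")
    # pointwise controls on the middle dictionary
    oc = config.overcompleteness[min(1, len(config.overcompleteness) - 1)]
    dictionary = prepare_dictionary(config, oc, seed_offset=int(oc * 10))
    for enc in (LinearEncoder(dictionary), ReluEncoder(dictionary),
                SigmoidEncoder(dictionary)):
        table = geometry.population_curvature(
            enc, n_neurons=config.n_neurons,
            planes_per_method=config.planes_per_method, seed=config.seed,
            extent=config.grid_extent, n_side=config.grid_side,
            level=config.contour_level)
        table["overcompleteness"] = oc
        table["encoder"] = enc.tag
        results["tables"][enc.tag] = table
        if write:
            _write(table, config, out, f"curvature_{enc.tag}.csv")
    summary = []
    for name, table in results["tables"].items():
        good = table[table["ok"]]
        for method, sub in good.groupby("plane_method"):
            summary.append(dict(
                table=name, plane_method=method, n=len(sub),
                median_c_iso=float(sub["c_iso"].median()),
                frac_c_iso_positive=float((sub["c_iso"] > 0).mean()),
                median_c_att=float(sub["c_att"].median())))
    results["summary"] = pd.DataFrame(summary)
    if write:
        _write(results["summary"], config, out, "curvature_summary.csv")
    log.info("curvature study: %d presentations/level",
             results["presentations_per_level"])
    return results


def run_selectivity_study(config: ExperimentConfig, write: bool = True) -> dict:
    """Circular variance (LCA vs controls, shared dictionary) and
    selected-image analysis across overcompleteness levels."""
    out = Path(config.out_dir)
    battery = synthetic_data.make_grating_battery(
        config.height, config.width, config.n_orientations, config.n_phases,
        config.frequencies)
    oc_mid = config.overcompleteness[min(1, len(config.overcompleteness) - 1)]
    dictionary = prepare_dictionary(config, oc_mid, seed_offset=int(oc_mid * 10))
    lca = LCAEncoder(dictionary, config.lca_params())
    controls = {"linear": LinearEncoder(dictionary),
                "sigmoid": SigmoidEncoder(dictionary)}
    cv_tables = {"lca": selectivity.population_circular_variance(lca, battery)}
    for tag, enc in controls.items():
        cv_tables[tag] = selectivity.population_circular_variance(enc, battery)
    cv_summary = {tag: float(t["cv"].median()) for tag, t in cv_tables.items()}

    probe = probe_patches(config, config.n_probe_images, seed_offset=91,
                          overcompleteness=oc_mid)
    paired = selectivity.compare_selectivity(
        lca, controls["linear"], probe, config.selected_fraction)

    counts_by_oc = {}
    for oc in config.overcompleteness:
        d_oc = prepare_dictionary(config, oc, seed_offset=int(oc * 10))
        lca_oc = LCAEncoder(d_oc, config.lca_params())
        t = selectivity.selectivity_table(lca_oc, probe,
                                          config.selected_fraction)
        counts_by_oc[oc] = float(t["n_selected"].mean())

    results = dict(cv_tables=cv_tables, cv_median=cv_summary, paired=paired,
                   mean_selected_by_overcompleteness=counts_by_oc)
    if write:
        for tag, t in cv_tables.items():
            _write(t, config, out, f"cv_{tag}.csv")
        _write(paired, config, out, "selected_images_paired.csv")
        (out / "selectivity_summary.json").write_text(json.dumps(dict(
            cv_median=cv_summary,
            mean_selected_by_overcompleteness={str(k): v for k, v
                                               in counts_by_oc.items()},
            config_hash=config.config_hash()), indent=2))
    return results


def build_paired_models(config: ExperimentConfig, seed: int):
    """Train the "w/ LCA" and parameter-matched "w/o LCA" classifiers on one
    draw of the labelled toy set; returns (models, test_images, test_labels)."""
    n_train = config.n_per_class_train
    n_test = config.n_per_class_test
    full = synthetic_data.make_toy_classes(
        config.height, config.width, config.n_classes, n_train + n_test,
        config.jitter_sd, config.class_noise_sd, seed=seed)
    labels = full.meta["label"].to_numpy()
    train_mask = np.zeros(full.n, dtype=bool)
    for c in range(config.n_classes):
        idx = np.flatnonzero(labels == c)
        train_mask[idx[:n_train]] = True
    S_train, y_train = full.data[train_mask], labels[train_mask]
    S_test, y_test = full.data[~train_mask], labels[~train_mask]

    n_atoms = int(round(2.0 * config.n_pixels))
    init = Dictionary.from_columns(synthetic_data.make_gabor_dictionary(
        config.height, config.width, n_atoms, seed=seed + 13))
    lca_params = config.lca_params()
    learned = encoders.learn_dictionary(
        S_train, init,
        LearnConfig(eta=config.eta, batch_size=config.batch_size,
                    n_epochs=config.n_epochs, seed=seed),
        lca_params)
    lca_enc = LCAEncoder(learned, lca_params)
    codes = lca_enc.encode(S_train)
    clf = robustness.train_softmax(codes, y_train, seed=seed)
    with_lca = robustness.LCAClassifierModel(lca_enc, clf)
    hidden = robustness.matched_hidden_size(config.n_pixels, n_atoms,
                                            config.n_classes)
    without_lca = robustness.train_pixel_mlp(S_train, y_train, hidden,
                                             seed=seed)
    models = {"with_lca": with_lca, "without_lca": without_lca}
    return models, S_test, y_test


def run_robustness_study(config: ExperimentConfig, write: bool = True) -> dict:
    """Seed-paired targeted-attack comparison of the two classifier families.

    Seed pairs whose models fail the accuracy-matching requirement are
    skipped (and counted); further seeds are drawn until the configured
    number of matched pairs is collected, so the comparison is always
    between classifiers of comparable competence.
    """
    out = Path(config.out_dir)
    attack_cfg = config.attack_config()
    per_seed = []
    tables = []
    skipped = []
    attempts = 0
    max_attempts = 3 * config.n_robustness_seeds
    while len(per_seed) < config.n_robustness_seeds and attempts < max_attempts:
        seed = config.seed + 1000 + attempts
        attempts += 1
        models, S_test, y_test = build_paired_models(config, seed)
        try:
            table = robustness.robustness_experiment(
                models, S_test, y_test, config.n_classes, attack_cfg,
                seed=seed, accuracy_margin=config.accuracy_margin)
        except robustness.AccuracyMismatch as err:
            log.warning("seed %d skipped: %s", seed, err)
            skipped.append(seed)
            continue
        table["seed"] = seed
        tables.append(table)
        summ = robustness.mse_summary(table).set_index("model")
        per_seed.append(dict(
            seed=seed,
            median_mse_with_lca=float(summ.loc["with_lca", "median"]),
            median_mse_without_lca=float(summ.loc["without_lca", "median"]),
        ))
    per_seed = pd.DataFrame(per_seed)
    per_seed["lca_larger"] = per_seed["median_mse_with_lca"] > \
        per_seed["median_mse_without_lca"]
    results = dict(per_seed=per_seed, tables=pd.concat(tables, ignore_index=True),
                   frac_seeds_lca_larger=float(per_seed["lca_larger"].mean()),
                   skipped_seeds=skipped)
    if write:
        _write(per_seed, config, out, "robustness_per_seed.csv")
        _write(results["tables"], config, out, "robustness_attacks.csv")
    return results
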
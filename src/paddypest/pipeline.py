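"""End-to-end orchestration: images -> preprocess -> extract ->
select -> classify -> report.

A run is configured by a :class:`RunConfig` (loadable from YAML), uses
one top-level seed fanned out to per-stage derived seeds by a fixed
rule, and emits a :class:`RunReport` whose metrics grid is byte-stable
across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as ppio
from .classify import (
    ClassifierSpec,
    cross_validate,
    evaluate_predictions,
    fit_predict,
    holdout_split,
    metrics_table,
)
from .features import BackboneSpec, extract_features
from .loa import LOAConfig
from .preprocessing import AugmentSpec, FilterSpec, apply_filter, augment_batch
from .selection import FeatureMatrix, SelectionMask, loa_select, pca_reduce, lda_reduce, rfe_select
from .classify import make_classifier

SELECTORS = ("none", "pca", "lda", "rfe", "loa", "rfe+loa", "pca+loa")

# fixed fan-out of the top-level seed to stages (documented rule:
# stage_seed = (seed * 1000003 + stage_index) mod 2^31)
_STAGE_INDEX = {"simulate": 1, "preprocess": 2, "extract": 3, "select": 4,
                "classify": 5}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGE_INDEX[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one of ``images_dir`` / ``features_path`` / ``simulate``
    supplies the input. ``selector`` is one of none, pca, lda, rfe, loa,
    or a chain like ``rfe+loa`` (classical selector first, lion wrapper
    on the survivors).
    """

    output_dir: str = "run_output"
    seed: int = 0
    images_dir: Optional[str] = None
    features_path: Optional[str] = None
    simulate: bool = False
    simulate_n_per_class: int = 24
    simulate_image_size: int = 64
    filter: FilterSpec = field(default_factory=lambda: FilterSpec(kind="median"))
    augment_enabled: bool = False
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    backbone: BackboneSpec = field(default_factory=lambda: BackboneSpec(name="mock", output_dim=64))
    selector: str = "loa"
    n_keep: int = 16                # pca/lda/rfe target dimensionality
    classifiers: tuple = ("logistic_regression", "svm", "knn", "naive_bayes")
    protocol: str = "holdout"       # holdout | cv | both
    loa: Optional[LOAConfig] = None
    loa_population: int = 24
    loa_iterations: int = 10

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.protocol not in ("holdout", "cv", "both"):
            raise ValueError("protocol must be holdout, cv or both")
        sources = [self.images_dir is not None, self.features_path is not None,
                   self.simulate]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one of images_dir, features_path or simulate "
                "must be given"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (("filter", FilterSpec), ("augment", AugmentSpec),
                           ("backbone", BackboneSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        if "loa" in raw and isinstance(raw["loa"], dict):
            raw["loa"] = LOAConfig(**raw["loa"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced: the metrics grid (rows = classifier x
    protocol), the selection summary and a provenance block."""

    grid: pd.DataFrame
    selected_count: int
    d_input: int
    selector: str
    provenance: dict
    loa_best_fitness: Optional[float] = None

    @property
    def best(self):
        """The grid row with the highest accuracy."""
        return self.grid.loc[self.grid["accuracy"].idxmax()]

    def save(self, output_dir) -> None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        self.grid.to_csv(output_dir / "metrics_grid.tsv", sep="\t")
        summary = [
            f"selector: {self.selector}",
            f"input features: {self.d_input}",
            f"selected features: {self.selected_count}",
            f"best: {self.best.name} (accuracy {self.best['accuracy']:.2f})",
            f"config hash: {self.provenance['config_hash']}",
            f"seed: {self.provenance['seed']}",
        ]
        (output_dir / "summary.txt").write_text("\n".join(summary) + "\n")


def _acquire_features(config: RunConfig):
    """Stages up to and including extraction; returns (X, y)."""
    from .synthetic import generate_toy_images

    if config.features_path is not None:
        X, y = ppio.read_feature_table(config.features_path)
        if y is None:
            raise ValueError(f"{config.features_path} has no label column")
        return X, y
    if config.simulate:
        images, labels = generate_toy_images(
            config.simulate_n_per_class, config.simulate_image_size,
            seed=stage_seed(config.seed, "simulate"),
        )
    else:
        images, labels = ppio.load_image_tree(config.images_dir)
    images = [apply_filter(img, config.filter) for img in images]
    if config.augment_enabled:
        expanded = []
        new_labels = []
        per_image = len(config.augment.operations) + 1
        for img, label in zip(images, labels):
            expanded.extend(augment_batch([img], config.augment))
            new_labels.extend([label] * per_image)
        images, labels = expanded, np.asarray(new_labels)
    X = extract_features(images, config.backbone)
    return X, np.asarray(labels)


def _apply_selector(config: RunConfig, X: FeatureMatrix, y: np.ndarray):
    """Returns (X_selected, selected_count, loa_best_fitness)."""
    sel_seed = stage_seed(config.seed, "select")
    parts = config.selector.split("+")
    best_fitness = None
    for part in parts:
        if part == "none":
            continue
        if part == "pca":
            _, reduced = pca_reduce(X, min(config.n_keep, X.d))
            X = FeatureMatrix(values=reduced)
        elif part == "lda":
            model = lda_reduce(X, y, 1)
            X = FeatureMatrix(values=model.projected)
        elif part == "rfe":
            from sklearn.linear_model import LogisticRegression

            est = LogisticRegression(max_iter=2000, random_state=sel_seed)
            mask = rfe_select(X, y, est, min(config.n_keep, X.d))
            X = FeatureMatrix(values=mask.apply(X.values),
                              feature_names=[n for n, m in
                                             zip(X.feature_names, mask.mask) if m])
        elif part == "loa":
            loa_config = config.loa or LOAConfig(
                lower_bounds=np.zeros(X.d),
                upper_bounds=np.ones(X.d),
                population_size=config.loa_population,
                num_prides=3,
                max_iterations=config.loa_iterations,
                patience=max(1, config.loa_iterations // 2),
                seed=sel_seed,
            )
            est = make_classifier(ClassifierSpec("logistic_regression", seed=sel_seed))
            mask, best_fitness, _ = loa_select(X, y, est, loa_config, seed=sel_seed)
            X = FeatureMatrix(values=mask.apply(X.values),
                              feature_names=[n for n, m in
                                             zip(X.feature_names, mask.mask) if m])
    return X, X.d, best_fitness


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages and return the report.

    Identical config + seed produces an identical metrics grid.
    """
    X, y = _acquire_features(config)
    d_input = X.d
    X_sel, selected_count, loa_fit = _apply_selector(config, X, y)

    clf_seed = stage_seed(config.seed, "classify")
    rows = {}
    if config.protocol in ("holdout", "both"):
        train_idx, test_idx = holdout_split(X_sel.values, y, seed=clf_seed)
        for kind in config.classifiers:
            spec = ClassifierSpec(kind, seed=clf_seed)
            y_pred = fit_predict(spec, X_sel.values[train_idx], y[train_idx],
                                 X_sel.values[test_idx])
            rows[f"{kind}[holdout]"] = evaluate_predictions(y[test_idx], y_pred)
    if config.protocol in ("cv", "both"):
        for kind in config.classifiers:
            spec = ClassifierSpec(kind, seed=clf_seed)
            _, mean = cross_validate(spec, X_sel.values, y, folds=5,
                                     seed=clf_seed)
            rows[f"{kind}[cv5]"] = mean

    grid = metrics_table(rows)
    report = RunReport(
        grid=grid,
        selected_count=selected_count,
        d_input=d_input,
        selector=config.selector,
        provenance={"config_hash": config.config_hash(), "seed": config.seed},
        loa_best_fitness=loa_fit,
    )
    report.save(config.output_dir)
    return report
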
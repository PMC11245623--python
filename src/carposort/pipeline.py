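"""End-to-end experiment orchestration.

One config drives the whole study: generate per-variety reference libraries
of synthetic pips, char them under controlled conditions, render and convert
stereoscopic scans, canonicalize and length-normalize, run the
ICP-similarity LDA tournament for each test condition, fit the
ratio-vs-temperature calibration curve, and sort a mixed-provenance seed set
into classifiable vs rejected.  A single top-level seed is fanned out to
fixed per-stage child seeds, so e.g. changing the session count does not
perturb seed generation, and the report is byte-identical for identical
config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import morphometry, scan_preprocess
from .charring_curve import CharringCurve, fit_curve, reference_curve, sort_seeds
from .similarity_classifier import all_pairs_mse, build_test_matrix, tournament
from .synthetic_seeds import (
    DEFAULT_VARIETIES,
    CharringCondition,
    DeformationModel,
    PointCloud,
    VarietyShape,
    apply_charring,
    auto_intrinsics,
    default_deformation_model,
    generate_fresh_cloud,
    sample_shape,
    simulate_scan,
)

__all__ = ["ExperimentConfig", "run_experiment", "generate_labeled_pool"]

#: charring conditions considered mild enough for classification (≤ 250 °C)
LOW_CONDITIONS = [(200.0, 2.0), (200.0, 8.0), (250.0, 2.0), (250.0, 8.0)]
#: drastic conditions (≥ 300 °C) expected to fail the sorting model
HIGH_CONDITIONS = [(300.0, 2.0), (300.0, 8.0), (350.0, 2.0), (350.0, 8.0)]


@dataclass(frozen=True)
class ExperimentConfig:
    varieties: tuple[VarietyShape, ...] = tuple(DEFAULT_VARIETIES.values())
    train_condition: CharringCondition = CharringCondition(200.0, 2.0)
    test_conditions: tuple[CharringCondition, ...] = (
        CharringCondition(200.0, 2.0),
        CharringCondition(250.0, 2.0),
        CharringCondition(300.0, 2.0),
    )
    test_variety: str = "cabernet_sauvignon"
    n_seeds_per_group: int = 10
    n_sessions: int = 25
    n_points: int = 300
    mm_per_pixel: float = 0.05
    target_length: float = 1.0
    train_fraction: float = 0.8
    gamma: float = 1e-3
    use_scans: bool = True
    threshold_C: float = 275.0
    n_unknown_seeds: int = 0
    unknown_low_fraction: float = 0.54
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds_per_group < 2:
            raise ValueError("n_seeds_per_group must be >= 2")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if not 0.0 <= self.unknown_low_fraction <= 1.0:
            raise ValueError("unknown_low_fraction must lie in [0, 1]")


def _child_seed(root: int, *key: int) -> int:
    """Stable derivation of per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(entropy=root, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _make_seed_cloud(
    shape: VarietyShape,
    condition: CharringCondition,
    model: DeformationModel,
    seed: int,
    n_points: int,
    mm_per_pixel: float,
    target_length: float | None,
    use_scans: bool,
) -> PointCloud:
    """Generate one pip through the full physical pipeline."""
    rng = np.random.default_rng(seed)
    cv_size, cv_ratio = model.fresh_cvs.get(shape.name, (0.022, 0.053))
    jittered = sample_shape(shape, rng, cv_size=cv_size, cv_ratio=cv_ratio)
    cloud = generate_fresh_cloud(jittered, n_points, rng_seed=_child_seed(seed, 1))
    cloud = apply_charring(
        cloud, condition, model, rng_seed=_child_seed(seed, 2), variety=shape.name
    )
    if use_scans:
        intrinsics, grid = auto_intrinsics(cloud, mm_per_pixel)
        scan = simulate_scan(cloud, intrinsics, grid)
        cloud = scan_preprocess.scan_to_cloud(scan, intrinsics)
    cloud = scan_preprocess.canonicalize_pose(cloud)
    if target_length is not None:
        cloud = scan_preprocess.normalize_length(cloud, target_length)
    return cloud


def generate_labeled_pool(
    varieties: Sequence[VarietyShape],
    condition: CharringCondition,
    n_per_variety: int,
    model: DeformationModel,
    rng_seed: int,
    n_points: int = 300,
    mm_per_pixel: float = 0.05,
    target_length: float | None = 1.0,
    use_scans: bool = True,
) -> tuple[list[PointCloud], list[str]]:
    """A labeled pool of processed pips, one charring condition, all varieties."""
    clouds: list[PointCloud] = []
    labels: list[str] = []
    for vi, shape in enumerate(varieties):
        for si in range(n_per_variety):
            seed = _child_seed(rng_seed, vi, si)
            clouds.append(
                _make_seed_cloud(
                    shape,
                    condition,
                    model,
                    seed,
                    n_points,
                    mm_per_pixel,
                    target_length,
                    use_scans,
                )
            )
            labels.append(shape.name)
    return clouds, labels


def _simulate_unknown_set(
    config: ExperimentConfig,
    model: DeformationModel,
    rng_seed: int,
):
    """Seeds of unknown charring history: a mild/drastic condition mixture."""
    rng = np.random.default_rng(rng_seed)
    n = config.n_unknown_seeds
    n_low = int(round(config.unknown_low_fraction * n))
    shapes = [s for s in config.varieties if s.name in model.fresh_cvs] or list(
        config.varieties
    )
    rows = []
    for i in range(n):
        low = i < n_low
        pool = LOW_CONDITIONS if low else HIGH_CONDITIONS
        T, d = pool[int(rng.integers(len(pool)))]
        shape = shapes[int(rng.integers(len(shapes)))]
        seed = _child_seed(rng_seed, 7, i)
        cloud = _make_seed_cloud(
            shape,
            CharringCondition(T, d),
            model,
            seed,
            config.n_points,
            config.mm_per_pixel,
            None,  # physical size retained: ratios are scale-free anyway
            config.use_scans,
        )
        m = morphometry.morphometrics(cloud)
        rows.append(
            {
                "id": i,
                "lw_ratio": m.lw_ratio,
                "group": "mild" if low else "drastic",
                "true_temperature_C": T,
                "true_duration_h": d,
                "variety": shape.name,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns a JSON-serializable report."""
    model = default_deformation_model()
    root = config.rng_seed

    train_clouds, train_labels = generate_labeled_pool(
        config.varieties,
        config.train_condition,
        config.n_seeds_per_group,
        model,
        rng_seed=_child_seed(root, 0),
        n_points=config.n_points,
        mm_per_pixel=config.mm_per_pixel,
        target_length=config.target_length,
        use_scans=config.use_scans,
    )

    test_shape = next(s for s in config.varieties if s.name == config.test_variety)
    cache_tt = all_pairs_mse(train_clouds)
    accuracies: dict[str, dict] = {}
    for ci, condition in enumerate(config.test_conditions):
        test_clouds, _ = generate_labeled_pool(
            [test_shape],
            condition,
            config.n_seeds_per_group,
            model,
            rng_seed=_child_seed(root, 1, ci),
            n_points=config.n_points,
            mm_per_pixel=config.mm_per_pixel,
            target_length=config.target_length,
            use_scans=config.use_scans,
        )
        cache_st = build_test_matrix(test_clouds, train_clouds)
        result = tournament(
            train_clouds,
            train_labels,
            test_clouds,
            [config.test_variety] * len(test_clouds),
            n_sessions=config.n_sessions,
            rng_seed=_child_seed(root, 2, ci),
            train_fraction=config.train_fraction,
            gamma=config.gamma,
            cache=(cache_tt, cache_st),
        )
        accuracies[condition.label()] = {
            "accumulative_accuracy": result.accumulative_accuracy,
            "per_session_accuracy": list(result.per_session_accuracy),
            "confusion": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in result.confusion.to_dict(orient="index").items()
            },
        }

    curve = reference_curve()
    report: dict = {
        "config": {
            "varieties": [s.name for s in config.varieties],
            "train_condition": config.train_condition.label(),
            "test_conditions": [c.label() for c in config.test_conditions],
            "n_seeds_per_group": config.n_seeds_per_group,
            "n_sessions": config.n_sessions,
            "n_points": config.n_points,
            "rng_seed": config.rng_seed,
        },
        "tournament": accuracies,
        "curve": {
            "a": curve.a,
            "b": curve.b,
            "t_zero": curve.t_zero,
            "t_one": curve.t_one,
            "fit_residual": curve.fit_residual,
        },
    }

    if config.n_unknown_seeds > 0:
        unknown = _simulate_unknown_set(config, model, _child_seed(root, 3))
        decisions, summary = sort_seeds(unknown, curve, config.threshold_C)
        report["sorting"] = {
            "threshold_C": config.threshold_C,
            "n_seeds": int(len(decisions)),
            "n_accepted": int(sum(d.accepted for d in decisions)),
            "accepted_fraction": float(np.mean([d.accepted for d in decisions])),
            "by_group": {
                str(row["group"]): {
                    "n": int(row["n"]),
                    "n_accepted": int(row["n_accepted"]),
                    "accepted_fraction": float(row["accepted_fraction"]),
                }
                for _, row in summary.iterrows()
            },
        }
    return report


def report_json(report: dict) -> str:
    """Canonical serialization used for byte-identity checks."""
    return json.dumps(report, sort_keys=True, indent=2)
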
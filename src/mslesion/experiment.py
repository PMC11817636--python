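"""End-to-end band-ablation experiment: full spectral cubes vs an RGB-like
three-band subset.

The pipeline is simulate -> calibrate -> balance -> split/fold -> per band
mode: subset bands, train (continued across folds), evaluate on the held-out
test set.  Both arms share the identical fold plan and seeds so the band
subset is the only varying factor, making the accuracy gap a clean measure
of the value of spectral information beyond RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .calibration import RGB_BANDS, calibrate, resize_cube, select_bands
from .dataset import LabeledDataset, balance_downsample, make_fold_plan
from .evaluation import MetricsReport, evaluate_predictions
from .models import spec_cnn2d, spec_vgg16_3d
from .phantom import SimulationConfig, simulate_dataset
from .training import TrainConfig, train_cross_validated

BAND_MODES = ("all", "rgb")


class ExperimentStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"experiment failed in stage {stage!r}: {original}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig
    train: TrainConfig
    architecture: str = "cnn2d"
    band_modes: tuple[str, ...] = ("all", "rgb")
    cube_side: int = 128
    test_fraction: float = 0.2
    folds: int = 5
    output_dir: str | Path | None = None

    def __post_init__(self):
        if not self.band_modes:
            raise ValueError("band_modes must be non-empty")
        for mode in self.band_modes:
            if mode not in BAND_MODES:
                raise ValueError(f"unknown band mode {mode!r}")
        if self.architecture not in ("cnn2d", "vgg16_3d"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class ComparisonReport:
    reports: dict[str, MetricsReport]
    accuracy_gap: float | None
    seed: int
    architecture: str
    band_modes: tuple[str, ...]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "seed": self.seed,
            "band_modes": list(self.band_modes),
            "accuracy_gap": self.accuracy_gap,
            "reports": {mode: r.to_dict() for mode, r in self.reports.items()},
            "extras": self.extras,
        }

    def to_markdown(self) -> str:
        lines = [f"# Band-ablation report ({self.architecture})", ""]
        for mode, report in self.reports.items():
            lines.append(f"## bands = {mode}")
            lines.append(f"top-1 accuracy: {report.top1_accuracy:.2f}")
            lines.append("")
            lines.append(report.to_table().to_string())
            lines.append("")
        if self.accuracy_gap is not None:
            lines.append(f"accuracy gap (all - rgb): {self.accuracy_gap:+.2f}")
        return "\n".join(lines)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ExperimentStageError:
                raise
            except Exception as exc:
                raise ExperimentStageError(name, exc) from exc
        return inner
    return wrap


@_stage("simulate")
def _simulate(config: ExperimentConfig):
    return simulate_dataset(config.simulation)


@_stage("calibrate")
def _calibrate(config: ExperimentConfig, captures) -> LabeledDataset:
    cubes = []
    for cap in captures:
        cube = calibrate(cap)
        if cube.shape[:2] != (config.cube_side, config.cube_side):
            cube = resize_cube(cube, config.cube_side)
        cubes.append(cube)
    return LabeledDataset(cubes)


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Execute the complete ablation; a single seed governs every stage."""
    ss = np.random.SeedSequence(config.simulation.seed)
    balance_rng = np.random.default_rng(ss.spawn(1)[0])

    captures = _simulate(config)
    data = _calibrate(config, captures)

    try:
        balanced = balance_downsample(data, balance_rng)
        plan = make_fold_plan(balanced, test_fraction=config.test_fraction,
                              folds=config.folds, seed=config.simulation.seed)
    except Exception as exc:
        raise ExperimentStageError("split", exc) from exc

    reports: dict[str, MetricsReport] = {}
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        plan.to_json(out_dir / "plan.json")

    for mode in config.band_modes:
        try:
            if mode == "rgb":
                arm = LabeledDataset(
                    [select_bands(c, RGB_BANDS) for c in balanced.cubes],
                    balanced.class_names)
            else:
                arm = balanced
            n_bands = arm.cubes[0].band_count
            if config.architecture == "cnn2d":
                spec = spec_cnn2d((config.cube_side, config.cube_side, n_bands),
                                  len(arm.class_names))
            else:
                spec = spec_vgg16_3d((config.cube_side, config.cube_side,
                                      n_bands, 1), len(arm.class_names))
            model, trace = train_cross_validated(spec, arm, plan, config.train)
            report = evaluate_predictions(model, arm, plan.test_indices)
            report.provenance.update({"band_mode": mode,
                                      "seed": config.simulation.seed})
            reports[mode] = report
            if out_dir:
                mode_dir = out_dir / mode
                mode_dir.mkdir(exist_ok=True)
                trace.to_csv(mode_dir / "trace.csv")
                (mode_dir / "metrics.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                report.to_table().to_csv(mode_dir / "metrics_table.csv")
        except ExperimentStageError:
            raise
        except Exception as exc:
            raise ExperimentStageError(f"train/evaluate[{mode}]", exc) from exc

    gap = None
    if "all" in reports and "rgb" in reports:
        gap = reports["all"].top1_accuracy - reports["rgb"].top1_accuracy
    result = ComparisonReport(
        reports=reports, accuracy_gap=gap, seed=config.simulation.seed,
        architecture=config.architecture, band_modes=config.band_modes,
        extras={"n_total": len(data), "n_balanced": len(balanced),
                "n_test": len(plan.test_indices)})
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(result.to_dict(), indent=2))
        (out_dir / "report.md").write_text(result.to_markdown())
    return result


def smoke_experiment_config(seed: int, separability_mode: str = "nir_only",
                            epochs_per_fold: int = 3,
                            output_dir=None) -> ExperimentConfig:
    """Desk-scale study profile: 32x32x8 cubes, 70 lesions per class,
    continued training over 5 folds x 3 epochs with Adam at 1e-3.

    This is the package's standard configuration for fast, CPU-only
    replication of the band-ablation ordering; see docs/methods.md.
    """
    sim = SimulationConfig(
        frame_shape=(32, 32), separability_mode=separability_mode,
        class_counts={"nevus": 70, "melanoma": 70, "bcc": 70}, seed=seed)
    train = TrainConfig(batch_size=8, learning_rate=1e-3,
                        epochs_per_fold=epochs_per_fold, strategy="continued",
                        seed=seed)
    return ExperimentConfig(simulation=sim, train=train, architecture="cnn2d",
                            cube_side=32, output_dir=output_dir)
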
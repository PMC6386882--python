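"""End-to-end experiment driver: simulate, extract, train, evaluate.

One root seed drives everything: three child seeds (training data, test
data, weight initialization/shuffling) are spawned deterministically
from it, so two runs with the same configuration produce identical
artifacts. All artifacts (sensor logs, feature files, model JSON,
confusion report) are written under one output directory in the
package's text formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pockethar import sensor_io
from pockethar.evaluation import AccuracyReport, ConfusionMatrix, evaluate, render_report
from pockethar.features import FeatureExtractionConfig, extract_features
from pockethar.mlp_classifier import MLPConfig, init_model, train
from pockethar.synthetic_data import AcquisitionParams, generate_dataset
from pockethar.types import LabeledRecording
from pockethar.windowing import WindowingConfig, segment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_train_per_class: int = 120
    n_test_per_class: int = 60
    out_dir: str = "pockethar-run"
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    features: FeatureExtractionConfig = field(default_factory=FeatureExtractionConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    write_raw_logs: bool = True


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _windows(recordings: list[LabeledRecording], config: PipelineConfig):
    out = []
    for rec in recordings:
        out.extend(segment(rec, config.windowing))
    return out


def run_end_to_end(
    config: PipelineConfig = PipelineConfig(),
) -> tuple[ConfusionMatrix, AccuracyReport]:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_seed, test_seed, mlp_seed = _child_seeds(config.seed, 3)

    logger.info("generating datasets (seed=%d)", config.seed)
    train_recs = generate_dataset(
        config.n_train_per_class, seed=train_seed, acq=config.acquisition
    )
    test_recs = generate_dataset(
        config.n_test_per_class, seed=test_seed, acq=config.acquisition
    )

    if config.write_raw_logs:
        for split, recs in (("train", train_recs), ("test", test_recs)):
            d = out / "recordings" / split
            d.mkdir(parents=True, exist_ok=True)
            for i, rec in enumerate(recs):
                sensor_io.write_sensor_log(
                    rec, d / f"{rec.label.value}_{i:04d}.csv"
                )

    train_windows = _windows(train_recs, config)
    test_windows = _windows(test_recs, config)
    logger.info(
        "windows: %d train, %d test", len(train_windows), len(test_windows)
    )

    train_rows = [
        (extract_features(w, config.features), w.label) for w in train_windows
    ]
    sensor_io.write_feature_file(
        [(fv.values, lab) for fv, lab in train_rows],
        out / "train_features.csv",
        n_features=config.features.n_features,
    )

    mlp_config = replace(config.mlp, seed=mlp_seed)
    model = train(init_model(mlp_config), train_rows, mlp_config)
    sensor_io.save_model(model, out / "model.json")

    matrix, report = evaluate(model, test_windows, config.features)
    text = render_report(matrix, report)
    (out / "report.txt").write_text(text, encoding="utf-8")
    (out / "report.json").write_text(
        json.dumps(
            {
                "per_class_accuracy": {
                    a.value: report.per_class[a] for a in matrix.labels
                },
                "average_accuracy": report.average,
                "confusion": matrix.counts.tolist(),
                "labels": [a.value for a in matrix.labels],
                "n_train_windows": len(train_windows),
                "n_test_windows": len(test_windows),
                "seed": config.seed,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return matrix, report
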
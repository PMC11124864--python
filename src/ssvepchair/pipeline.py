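"""End-to-end orchestration: recordings in, evaluation report + commands out.

The stages mirror the online system: filter each recording, cut sliding
windows, extract features, train and evaluate the SVM on a stratified split,
then replay every recording's window stream through the trained model and
the debouncing command mapper.  Every stage is deterministic given the
config seed, so two runs on the same dataset produce identical reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, control, decode, preprocess
from .config import PipelineConfig
from .simulate import RawRecording

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: classify.EvaluationReport
    command_log: pd.DataFrame  # columns: recording, t_s, command, votes
    model: classify.TrainedModel

    def save(self, out_dir: str | Path) -> None:
        """Write the confusion matrix and command log as CSV files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cm = pd.DataFrame(
            self.report.confusion_matrix,
            index=list(self.report.classes),
            columns=list(self.report.classes),
        )
        cm.to_csv(out / "confusion_matrix.csv")
        self.command_log.to_csv(out / "command_log.csv", index=False)
        summary = pd.DataFrame(
            {
                "class": list(self.report.classes),
                "recall": self.report.per_class_recall,
            }
        )
        summary.loc[len(summary)] = ["accuracy", self.report.accuracy]
        summary.to_csv(out / "report.csv", index=False)


def _stage(name: str, start: float) -> float:
    now = time.perf_counter()
    logger.info("stage %-10s %6.2f s", name, now - start)
    return now


def run_pipeline(
    config: PipelineConfig, dataset: list[RawRecording]
) -> PipelineResult:
    """Execute filter → window → features → split/train/evaluate → commands."""
    if not dataset:
        raise ValueError("dataset is empty")
    t0 = time.perf_counter()

    filtered = [preprocess.apply_filters(rec, config.filter) for rec in dataset]
    t0 = _stage("filter", t0)

    per_rec_windows = [
        preprocess.sliding_windows(rec, config.window_s, config.step_s)
        for rec in filtered
    ]
    t0 = _stage("window", t0)

    n_samples = round(config.window_s * dataset[0].fs_hz)
    refs = None
    if config.feature_set in ("fft+cca", "cca-only"):
        refs = decode.ReferenceSet.for_frequencies(
            config.stimulus.frequencies_hz,
            fs_hz=dataset[0].fs_hz,
            n_samples=n_samples,
            n_harmonics=config.n_harmonics,
        )
    per_rec_features = [
        decode.extract_features(ws, refs=refs, with_cca=refs is not None)
        for ws in per_rec_windows
    ]
    t0 = _stage("features", t0)

    all_features = [fv for feats in per_rec_features for fv in feats]
    train_set, val_set = classify.split_dataset(
        all_features, config.train_fraction, seed=config.seed
    )
    model = classify.train(
        train_set,
        feature_set=config.feature_set,
        degree=config.svm_degree,
        c=config.svm_c,
    )
    report = classify.evaluate(model, val_set)
    t0 = _stage("train/eval", t0)

    rows = []
    for i, feats in enumerate(per_rec_features):
        if not feats:
            continue
        labels = classify.predict(model, feats)
        events = control.map_stream(
            labels,
            config=config.stimulus,
            debounce_k=config.debounce_k,
            step_s=config.step_s,
        )
        rows.extend(
            {"recording": i, "t_s": e.t_s, "command": e.command,
             "votes": e.source_windows}
            for e in events
        )
    command_log = pd.DataFrame(rows, columns=["recording", "t_s", "command", "votes"])
    _stage("commands", t0)

    return PipelineResult(report=report, command_log=command_log, model=model)
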
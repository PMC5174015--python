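"""End-to-end orchestration: simulate → segment → graph → measure →
features → select → evaluate.

Every stage writes its artifacts into a run directory as plain files, so
any stage can be rerun independently; the resolved configuration is always
written alongside.  One global seed fixes synthesis, splitting and
classifier initialization.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import classify, features as feat, io, measures, preprocessing, synth
from .errors import MyovisError

log = logging.getLogger(__name__)

#: every configuration key with its documented default
DEFAULTS: dict = {
    # global
    "seed": 0,
    "log_level": "INFO",
    # synthesis
    "n_per_class": 60,
    "amplitude_jitter": 0.1,
    "duration_jitter": 0.1,
    "noise_sd_uv": 20.0,
    "bursts_per_recording": 1,
    "sampling_rate": 10000.0,
    # segmentation
    "amp_threshold_frac": 0.3,
    "slope_eps_frac": 0.01,
    "min_gap_ms": 5.0,
    "smooth_ms": 2.0,
    "decimation_factor": 1,
    "rectify": True,
    # measures
    "clustering_weighted": True,
    "distance_mode": "shortest_path",
    "candidate_measures": list(measures.MEASURE_NAMES),
    # selection
    "alpha": 0.001,
    "bonferroni": False,
    # classification
    "test_fractions": list(classify.DEFAULT_TEST_FRACTIONS),
    "repeats": 10,
    "classifiers": list(classify.CLASSIFIER_NAMES),
}


class PipelineConfig(dict):
    """Flat key-value configuration; unknown keys are rejected."""

    def __init__(self, **overrides):
        unknown = set(overrides) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        super().__init__({**DEFAULTS, **overrides})

    def __getattr__(self, key):
        try:
            return self[key]
        except KeyError as exc:
            raise AttributeError(key) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(
            amplitude_jitter=self.amplitude_jitter,
            duration_jitter=self.duration_jitter,
            noise_sd_uv=self.noise_sd_uv,
            bursts_per_recording=self.bursts_per_recording,
            sampling_rate=self.sampling_rate,
            seed=self.seed,
        )

    def segmenter(self) -> preprocessing.EpochSegmenter:
        return preprocessing.EpochSegmenter(
            amp_threshold_frac=self.amp_threshold_frac,
            slope_eps_frac=self.slope_eps_frac,
            min_gap_ms=self.min_gap_ms,
            smooth_ms=self.smooth_ms,
            decimation_factor=self.decimation_factor,
            rectify=self.rectify,
        )


def run_study(config: PipelineConfig | None = None):
    """Run the full in-memory study on synthetic data.

    Returns a dict with the ground-truth table, epochs, adjacency matrices,
    measures table, assembled feature matrix, ANOVA result and
    classification report.
    """
    config = config or PipelineConfig()
    signals, truth = synth.generate_dataset(config.n_per_class,
                                            config.synth_config())
    labels = [s.source_id.split("-")[0] for s in signals]
    result = _run_on_signals(config, signals, labels)
    result["truth"] = truth
    return result


def run_pipeline(config: PipelineConfig | None = None, out_dir=".",
                 signals=None, labels=None):
    """Run the study and write every intermediate artifact under ``out_dir``.

    With ``signals`` (a list of :class:`~myovis.io.RawSignal`) and
    ``labels`` the synthesis stage is skipped.  Returns the
    :class:`~myovis.classify.ClassificationReport`.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)

    if signals is None:
        result = run_study(config)
        result["truth"].to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    else:
        result = _run_on_signals(config, signals, labels)

    epochs = result["epochs"]
    windows = [{"start": ep.window.start + 1, "end": ep.window.end + 1,
                "peak": ep.window.peak + 1, "label": ep.label or ""}
               for ep in epochs]
    io.write_report({"n_epochs": len(epochs)}, out / "counts.yaml")
    pd.DataFrame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    result["measures"].to_csv(out / "measures.csv", index=False)
    io.write_feature_matrix(result["feature_matrix"], out / "features.csv")
    result["anova"].to_frame().to_csv(out / "anova.csv", index=False)
    report = result["report"]
    report.to_wide().to_csv(out / "report_table.csv")
    io.write_report(report.to_dict(), out / "report.yaml")
    return report


def _run_on_signals(config: PipelineConfig, signals, labels):
    from .visibility import VisibilityGraphTransformer

    epochs = config.segmenter().transform(signals, y=labels)
    if not epochs:
        raise MyovisError("stage 'segment' failed: no epochs detected")
    log.info("segment: %d epochs from %d signals", len(epochs), len(signals))
    graphs = VisibilityGraphTransformer().transform(epochs)
    extractor = measures.NetworkMeasureExtractor(
        clustering_weighted=config.clustering_weighted,
        distance_mode=config.distance_mode,
        measures=config.candidate_measures)
    table = extractor.transform(graphs)
    fm = feat.assemble(table, feature_names=config.candidate_measures,
                       labels=[ep.label for ep in epochs])
    anova = feat.anova_select(fm, alpha=config.alpha,
                              bonferroni=config.bonferroni)
    selected = anova.selected_names() or feat.default_feature_set()
    fm_sel = feat.assemble(table, feature_names=selected,
                           labels=[ep.label for ep in epochs])
    protocol = classify.SplitProtocol(
        test_fractions=tuple(config.test_fractions),
        repeats=config.repeats, seed=config.seed)
    report = classify.run_protocol(fm_sel, protocol,
                                   classifiers=config.classifiers)
    return {"epochs": epochs, "graphs": graphs, "measures": table,
            "feature_matrix": fm_sel, "anova": anova, "report": report}
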
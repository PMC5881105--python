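"""Model/Results front end over the training pipeline.

``AIPPredModel`` holds a labeled peptide dataset and a pipeline
configuration; ``fit()`` runs encoding, feature-importance scoring, the
cutoff sweep, repeated-CV grid search, consensus-parameter selection,
cutoff tuning and the final fit, returning an ``AIPPredResults`` that
carries the trained bundle, the sweep report and the cross-validation
diagnostics, with ``summary()``, ``predict()``, ``evaluate()`` and
``save()`` hanging off it.

Example
-------
>>> from aippred import synthetic
>>> from aippred.model import AIPPredModel
>>> from aippred.modeling import PipelineConfig
>>> data = synthetic.generate(60, 60, synthetic.get_profile("figure1_strong"), seed=7)
>>> cfg = PipelineConfig(fis_trees=200, fis_mtry=(1, 10), repeats=2,
...                      grid={"ntree": (100,), "mtry": (1, 2), "nsplit": (2,)},
...                      sweep_low=0.002, sweep_high=0.004, sweep_step=0.001,
...                      sweep_floor=0.0005, seed=7)
>>> results = AIPPredModel(data, cfg).fit()
>>> print(results.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, evaluate_model
from .exceptions import ParameterError
from .modeling import ModelBundle, PipelineConfig, PipelineResult, predict, run_pipeline
from .seqio import PeptideDataset, read_fasta


class AIPPredModel:
    """A peptide classifier specification: data plus pipeline configuration."""

    def __init__(self, dataset: PeptideDataset, config: PipelineConfig | None = None):
        if not dataset.is_labeled():
            raise ParameterError("AIPPredModel requires a fully labeled dataset")
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_fasta(cls, path, labels=None,
                   config: PipelineConfig | None = None) -> "AIPPredModel":
        return cls(read_fasta(path, labels=labels), config=config)

    def fit(self) -> "AIPPredResults":
        return AIPPredResults(self, run_pipeline(self.dataset, self.config))


class AIPPredResults:
    """Fitted pipeline: trained bundle, sweep report, CV diagnostics."""

    def __init__(self, model: AIPPredModel, pipeline: PipelineResult):
        self.model = model
        self._pipeline = pipeline

    # -- principal artifacts -------------------------------------------------
    @property
    def bundle(self) -> ModelBundle:
        return self._pipeline.bundle

    @property
    def sweep_report(self) -> pd.DataFrame:
        """Per-cutoff table: cutoff, n_features, mean CV AUC, sd."""
        return self._pipeline.sweep_report

    @property
    def fis(self):
        return self._pipeline.fis

    @property
    def selected_features(self) -> list[str]:
        return list(self._pipeline.selected.feature_names)

    @property
    def params(self):
        return self._pipeline.consensus

    @property
    def probability_cutoff(self) -> float:
        return self.bundle.probability_cutoff

    @property
    def cv_auc_mean(self) -> float:
        return self._pipeline.cv_auc_mean

    @property
    def cv_auc_sd(self) -> float:
        return self._pipeline.cv_auc_sd

    @property
    def oof_probabilities(self) -> np.ndarray:
        return self._pipeline.oof_probabilities

    # -- actions -------------------------------------------------------------
    def predict(self, dataset: PeptideDataset) -> pd.DataFrame:
        return predict(self.bundle, dataset)

    def evaluate(self, dataset: PeptideDataset) -> MetricsReport:
        return evaluate_model(self.bundle, dataset)

    def save(self, path: str | Path) -> None:
        self.bundle.save(path)

    def summary(self) -> str:
        """Plain-text summary table of the fitted pipeline."""
        cfg = self.model.config
        p = self.params
        lines = [
            "Anti-inflammatory peptide classifier — pipeline fit",
            "=" * 55,
            f"records:            {len(self.model.dataset)} "
            f"({self.model.dataset.positives_count} pos / "
            f"{self.model.dataset.negatives_count} neg)",
            f"encoder:            {cfg.encoder}",
            f"algorithm:          {p.algorithm}",
            f"tuned parameters:   "
            + ", ".join(f"{k}={v}" for k, v in p.as_dict().items()),
            f"selected features:  {len(self.selected_features)} "
            f"(FIS cutoff {self._pipeline.selected.cutoff:.6g})",
            f"probability cutoff: {self.probability_cutoff:.2f}",
            f"CV AUC:             {self.cv_auc_mean:.3f} "
            f"(sd {self.cv_auc_sd:.3f}, {cfg.repeats}x{cfg.folds}-fold)",
            "-" * 55,
            "sweep (cutoff, n_features, mean AUC, sd):",
        ]
        for _, row in self.sweep_report.iterrows():
            lines.append(
                f"  {row['cutoff']:.4f}  {int(row['n_features']):4d}  "
                f"{row['mean_auc']:.3f}  {row['sd_auc']:.3f}"
            )
        return "\n".join(lines)
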
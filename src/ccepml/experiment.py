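"""Model-object interface over the resampling benchmark.

``CcepSpeechExperiment`` plays the role of a statsmodels ``Model``: it is
built from a per-test feature table (or straight from a cohort manifest)
plus an :class:`~ccepml.evaluation.ExperimentConfig`, and ``fit()`` returns
a :class:`CcepSpeechResults` carrying the averaged metric table, its
dispersions, the per-run log, and a ``summary()`` rendering in the familiar
models × metrics layout.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from . import features as feat
from . import io_edf
from .evaluation import ExperimentConfig, METRIC_NAMES, run_experiment_grid
from .preprocess import PreprocessParams

__all__ = ["CcepSpeechExperiment", "CcepSpeechResults"]

_SUMMARY_HEADERS = {"cv_accuracy": "CV", "specificity": "Spec",
                    "sensitivity": "Sens", "precision": "Prec",
                    "recall": "Rec", "accuracy": "Acc", "f1": "F1-score",
                    "auc": "AUC"}


class CcepSpeechExperiment:
    """Speech-deterioration prediction benchmark on a CCEP feature table.

    Parameters
    ----------
    feature_table
        One row per stimulation test: identifiers, binary target, and the
        descriptive features from :func:`ccepml.features.build_feature_table`
        (missing extrema as NaN — restitution happens inside each
        resampling repetition).
    config
        Grid specification; defaults reproduce the full 20-cell design.
    """

    def __init__(self, feature_table: pd.DataFrame,
                 config: ExperimentConfig | None = None) -> None:
        required = {"patient_id", "target"} | set(feat.MODEL_INPUT_COLUMNS)
        missing = required - set(feature_table.columns)
        if missing:
            raise ValueError(f"feature table lacks columns: {sorted(missing)}")
        self.feature_table = feature_table.reset_index(drop=True)
        self.config = config or ExperimentConfig()

    @classmethod
    def from_cohort(cls, manifest_path: str | Path,
                    data_dir: str | Path | None = None,
                    config: ExperimentConfig | None = None,
                    feature_params: feat.FeatureParams = feat.FeatureParams(),
                    preprocess_params: PreprocessParams = PreprocessParams(),
                    ) -> "CcepSpeechExperiment":
        """Build the experiment straight from EDF files + manifest."""
        tests = io_edf.load_cohort(manifest_path, data_dir)
        table = feat.build_feature_table(tests, feature_params,
                                         preprocess_params)
        return cls(table, config)

    def fit(self, *, n_jobs: int = 1,
            log_path: str | Path | None = None) -> "CcepSpeechResults":
        """Run the full repeated-resampling grid."""
        metrics = run_experiment_grid(self.feature_table, self.config,
                                      n_jobs=n_jobs, log_path=log_path)
        return CcepSpeechResults(self, metrics)


class CcepSpeechResults:
    """Averaged grid results with dispersion and a printable summary."""

    def __init__(self, model: CcepSpeechExperiment,
                 metrics: pd.DataFrame) -> None:
        self.model = model
        self.config = model.config
        self.metrics = metrics

    def best(self, metric: str = "f1") -> pd.Series:
        """The grid cell maximizing ``metric`` (mean over repetitions)."""
        return self.metrics.loc[self.metrics[metric].idxmax()]

    def variant_table(self, split_mode: str, impute_scheme: str
                      ) -> pd.DataFrame:
        """One input variant: rows = models, columns = the metric suite."""
        sub = self.metrics[(self.metrics["split_mode"] == split_mode)
                           & (self.metrics["impute_scheme"] == impute_scheme)]
        out = sub[["model"] + METRIC_NAMES].set_index("model")
        return out.rename(columns=_SUMMARY_HEADERS)

    def summary(self, digits: int = 3) -> str:
        """Models × metrics tables, one block per input variant."""
        lines = [
            "CCEP speech-outcome resampling benchmark",
            f"  tests: {len(self.model.feature_table)}   "
            f"patients: {self.model.feature_table['patient_id'].nunique()}   "
            f"repetitions/cell: {self.config.n_repetitions}   "
            f"runs: {self.config.n_runs}",
        ]
        for sm in self.config.split_modes:
            for im in self.config.impute_schemes:
                lines.append("")
                lines.append(f"split: {sm}   missing-value scheme: {im}")
                tab = self.variant_table(sm, im)
                lines.append(tab.to_string(
                    float_format=lambda v: ("" if math.isnan(v)
                                            else f"{v:.{digits}f}")))
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path, digits: int = 6) -> list[Path]:
        """One CSV per input variant (rows = models), plus the full table."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        fmt = f"%.{digits}f"
        for sm in self.config.split_modes:
            for im in self.config.impute_schemes:
                p = out_dir / f"results_{sm}_{im}.csv"
                self.variant_table(sm, im).to_csv(p, float_format=fmt)
                paths.append(p)
        full = out_dir / "metrics_full.csv"
        self.metrics.to_csv(full, index=False, float_format=fmt)
        paths.append(full)
        return paths
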
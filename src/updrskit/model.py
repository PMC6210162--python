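"""Model/Results facade for the severity-assessment core.

`UpdrsAssessment` is built from a feature table (one row per task
performance, columns the named kinematic parameters plus the clinician
score and the cohort tag); ``fit()`` runs healthy-control normalization,
the elastic-net + Spearman selection chain with its PCA consistency check,
trains the final classifier on the selected parameters, and cross-validates
it.  The returned `UpdrsAssessmentResults` carries the selection table,
the fitted classifier, the cross-validated agreement diagnostics and a
``summary()`` in the familiar fitted-model style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, EvaluationReport, cross_validate, train
from .kinematics import cohort_feature_matrix
from .selection import (FeatureMatrix, SelectionResult, normalize_by_hc,
                        select_features)
from .trajectories import TaskKind

__all__ = ["UpdrsAssessment", "UpdrsAssessmentResults"]


class UpdrsAssessment:
    """Severity-assessment model for one UPDRS upper-limb task.

    Parameters
    ----------
    features : FeatureMatrix
        Kinematic parameters per recording with clinician scores and
        cohort tags.
    task : TaskKind or str
        Which task the features describe (FT, OC or PS).

    Examples
    --------
    >>> model = UpdrsAssessment.from_dataframe(df, task="FT")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, features: FeatureMatrix, task: TaskKind | str = TaskKind.FT):
        self.features = features
        self.task = TaskKind.coerce(task)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, task: TaskKind | str = TaskKind.FT,
                       score_col: str = "score", cohort_col: str = "cohort"
                       ) -> "UpdrsAssessment":
        """Build from a flat table with feature columns plus ``score`` and
        ``cohort`` columns (score NaN for healthy controls)."""
        return cls(FeatureMatrix.from_dataframe(df, score_col, cohort_col), task)

    @classmethod
    def from_recordings(cls, recordings, rate: float = 100.0) -> "UpdrsAssessment":
        """Build by extracting kinematic features from task recordings."""
        df = cohort_feature_matrix(recordings, rate=rate)
        task = recordings[0].task
        return cls.from_dataframe(df, task=task)

    def fit(self, alpha: float = 0.5, rho_min: float = 0.3, p_max: float = 0.01,
            pca_variance: float = 0.98, classifier: str = "svm-poly",
            five_class: bool = True, cv_scheme: str = "loocv",
            cv_repeats: int = 500, seed: int = 0,
            run_selection: bool = True) -> "UpdrsAssessmentResults":
        """Normalize, select, train and cross-validate.

        Selection runs on the PD rows of the HC-normalized matrix; the
        classifier is trained (and evaluated) on the selected columns of
        every row, against the five-class (HC + UPDRS 0-3) or binary
        (HC vs PD) labels.
        """
        norm = normalize_by_hc(self.features)
        selection = None
        cols = list(norm.data.columns)
        if run_selection:
            selection = select_features(self.features, alpha=alpha, rho_min=rho_min,
                                        p_max=p_max, pca_variance=pca_variance, seed=seed)
            if selection.selected:
                cols = selection.selected
        X = norm.data[cols]
        y = self.features.class_labels(five_class=five_class)
        spec = ClassifierSpec(method=classifier, seed=seed)
        report = cross_validate(X, y, spec, scheme=cv_scheme, repeats=cv_repeats)
        final = train(X, y, spec)
        return UpdrsAssessmentResults(model=self, normalized=norm, selection=selection,
                                      columns=cols, classifier=final, spec=spec,
                                      cv_report=report, five_class=five_class)


@dataclass
class UpdrsAssessmentResults:
    """Fitted severity-assessment pipeline and its diagnostics."""

    model: UpdrsAssessment
    normalized: FeatureMatrix
    selection: SelectionResult | None
    columns: list[str]
    classifier: object
    spec: ClassifierSpec
    cv_report: EvaluationReport
    five_class: bool

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predict severity classes for new (already HC-normalized) feature rows."""
        return self.classifier.predict(features[self.columns].to_numpy(dtype=float))

    def summary(self) -> str:
        m = self.model
        lines = [
            "UPDRS task severity assessment",
            "=" * 46,
            f"Task:                {m.task.value}",
            f"Recordings:          {len(m.features.data)} "
            f"(PD {int(m.features.pd_rows.sum())}, "
            f"HC {int((~m.features.pd_rows).sum())})",
            f"Problem:             {'HC + UPDRS 0-3 (5-class)' if self.five_class else 'HC vs PD (binary)'}",
            f"Classifier:          {self.spec.method}",
        ]
        if self.selection is not None:
            tab = self.selection.table
            lines.append(f"Selected parameters ({len(self.columns)}):")
            for c in self.columns:
                if c in tab.index:
                    lines.append(f"    {c:<6} rho = {tab.loc[c, 'rho']:+.2f}  "
                                 f"p = {tab.loc[c, 'p']:.2e}")
                else:
                    lines.append(f"    {c}")
            if self.selection.pca is not None:
                p = self.selection.pca
                lines.append(f"PCA check:           {p.n_components} components carry "
                             f"{p.variance_retained:.1%} of variance")
        lines.append(self.cv_report.summary())
        return "\n".join(lines)
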
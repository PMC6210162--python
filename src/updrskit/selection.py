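"""Healthy-control normalization and discriminative-feature selection.

Patient parameters are normalized by the healthy-control cohort means
(``p_norm = p_PD / mean(p_HC)``), removing scale differences between
parameters that have nothing to do with the clinical signal.  Selection then
chains three standard steps: an elastic-net regression path against the
clinician score (the L1/L2 blend keeps groups of correlated kinematic
parameters together, unlike the pure LASSO), a PCA consistency check
(how many components carry 98% of the variance, and whether their
top-loading parameters agree with the elastic-net choice), and a final
Spearman rank-correlation filter (|rho| > 0.3 at p < 0.01) that keeps only
parameters monotonically related to the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .kinematics import NEGATIVE_CORRELATION_FEATURES

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "normalize_by_hc",
    "orient_worse_is_larger",
    "elastic_net_coefficients",
    "elastic_net_select",
    "spearman_filter",
    "pca_consistency_check",
    "select_features",
]


@dataclass
class FeatureMatrix:
    """Rows = recordings, columns = named kinematic parameters.

    ``score`` is the clinician UPDRS class per row (NaN for healthy
    controls); ``cohort`` tags each row "PD" or "HC".
    """

    data: pd.DataFrame
    score: pd.Series
    cohort: pd.Series

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValueError("feature columns must be uniquely named")
        self.score = pd.Series(self.score, index=self.data.index, dtype=float)
        self.cohort = pd.Series(self.cohort, index=self.data.index)
        pd_rows = self.cohort == "PD"
        if self.score[pd_rows].isna().any():
            raise ValueError("PD rows must all carry a clinician score")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_col: str = "score",
                       cohort_col: str = "cohort") -> "FeatureMatrix":
        cols = [c for c in df.columns if c not in (score_col, cohort_col)]
        cohort = (df[cohort_col] if cohort_col in df
                  else pd.Series(np.where(df[score_col].isna(), "HC", "PD"), index=df.index))
        return cls(df[cols].astype(float), df[score_col], cohort)

    @property
    def pd_rows(self) -> pd.Series:
        return self.cohort == "PD"

    def class_labels(self, five_class: bool = True) -> pd.Series:
        """Classification labels: HC is its own class (0) in five-class mode,
        PD scores shifted up by one; in binary mode HC=0, PD=1."""
        if five_class:
            lab = np.where(self.cohort == "HC", 0, self.score + 1)
        else:
            lab = np.where(self.cohort == "HC", 0, 1)
        return pd.Series(lab, index=self.data.index).astype(int)


def normalize_by_hc(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide every column by its healthy-control mean (``p / mean(p_HC)``).

    HC rows are normalized by the same means, so HC column means become 1.
    Columns whose HC mean is zero are dropped with a warning.  Applied to
    already-normalized data the HC means are 1, so the operation is
    idempotent.
    """
    hc = matrix.cohort == "HC"
    if not hc.any():
        raise ValueError("normalization requires at least one HC row")
    means = matrix.data.loc[hc].mean(axis=0)
    zero = means == 0
    if zero.any():
        warnings.warn(f"dropping columns with zero HC mean: {list(means.index[zero])}")
    keep = means.index[~zero]
    return FeatureMatrix(matrix.data[keep] / means[keep], matrix.score, matrix.cohort)


def orient_worse_is_larger(data: pd.DataFrame) -> pd.DataFrame:
    """Reporting orientation for radar-style plots: reciprocate the
    parameters that fall with severity (means and frequency) so that every
    column increases as performance worsens.  Never applied to model input —
    the classifiers and the rank-based filter are unaffected by monotone
    transforms of this kind."""
    out = data.copy()
    for col in out.columns:
        if col in NEGATIVE_CORRELATION_FEATURES:
            out[col] = 1.0 / out[col]
    return out


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def elastic_net_coefficients(X, y, alpha: float, lam: float) -> np.ndarray:
    """Elastic-net coefficients at a single penalty value.

    ``alpha`` in [0, 1] blends ridge (0) and LASSO (1); ``lam`` is the
    penalty strength, with the objective
    ``1/(2n) ||y - Xb||^2 + lam * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)``.
    At ``alpha = 0`` this has the closed form
    ``b = (X'X/n + lam I)^{-1} X'y/n`` for centred data.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    # sklearn disallows l1_ratio=0 in ElasticNet only for coordinate-descent
    # convergence reasons; it still accepts it with a warning, but the ridge
    # end of the path has an exact solution we use directly.
    if alpha == 0:
        n = len(y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        p = X.shape[1]
        return np.linalg.solve(Xc.T @ Xc / n + lam * np.eye(p), Xc.T @ yc / n)
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=50000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_


@dataclass
class ENSelection:
    selected: list[str]
    coef: pd.Series
    lam: float
    alpha: float
    lambdas: np.ndarray
    cv_mse: np.ndarray            # (n_lambdas,) mean CV error along the path
    cv_se: np.ndarray
    path: pd.DataFrame = None     # coefficients along the path


def elastic_net_select(X: pd.DataFrame, y: pd.Series, alpha: float = 0.5,
                       n_lambdas: int = 50, cv: int = 10, seed: int = 0,
                       one_se: bool = True) -> ENSelection:
    """Cross-validated elastic-net selection against the clinician score.

    Columns are standardized; the penalty path is scored by K-fold CV and
    the penalty chosen by the one-standard-error rule (the sparsest model
    within one SE of the minimum CV error).  The selected subset is the set
    of parameters with nonzero coefficients there.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    cols = list(X.columns)
    Xs = _standardize(X.to_numpy(dtype=float))
    yv = np.asarray(y, dtype=float)
    eps = 1e-3
    l1 = max(alpha, 1e-3)  # path geometry; alpha=0 handled by ridge form below
    lam_max = np.max(np.abs(Xs.T @ (yv - yv.mean()))) / (len(yv) * l1)
    lambdas = lam_max * np.logspace(0, np.log10(eps), n_lambdas)

    cv = min(cv, len(yv))
    if cv < 2:
        raise ValueError("elastic-net CV needs at least 2 rows")
    folds = list(KFold(n_splits=cv, shuffle=True, random_state=seed).split(Xs))
    err = np.empty((cv, n_lambdas))
    for k, (tr, te) in enumerate(folds):
        coefs = _path_coefs(Xs[tr], yv[tr], alpha, lambdas)
        pred = Xs[te] @ coefs + (yv[tr].mean() - Xs[tr].mean(0) @ coefs)
        err[k] = np.mean((yv[te, None] - pred) ** 2, axis=0)
    cv_mse = err.mean(axis=0)
    cv_se = err.std(axis=0, ddof=1) / np.sqrt(cv)
    best = int(np.argmin(cv_mse))
    if one_se:
        limit = cv_mse[best] + cv_se[best]
        lam_idx = int(np.argmax(cv_mse <= limit))  # largest penalty within 1 SE
    else:
        lam_idx = best
    lam = float(lambdas[lam_idx])
    coef = elastic_net_coefficients(Xs, yv, alpha, lam)
    path = pd.DataFrame(_path_coefs(Xs, yv, alpha, lambdas).T, columns=cols)
    selected = [c for c, b in zip(cols, coef) if abs(b) > 1e-10]
    return ENSelection(selected=selected, coef=pd.Series(coef, index=cols), lam=lam,
                       alpha=alpha, lambdas=lambdas, cv_mse=cv_mse, cv_se=cv_se, path=path)


def _path_coefs(X, y, alpha, lambdas) -> np.ndarray:
    """Coefficients (p, n_lambdas) along a fixed penalty path."""
    if alpha == 0:
        return np.column_stack([elastic_net_coefficients(X, y, 0.0, lam) for lam in lambdas])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(X, y, l1_ratio=alpha, alphas=np.sort(lambdas)[::-1],
                                max_iter=20000)
    # enet_path returns in decreasing-penalty order matching our lambdas
    return coefs


# ---------------------------------------------------------------------------
# Spearman filter and PCA check
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float,
                      n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value (two-sided) for small samples, vectorized over
    permutations of the rank vectors."""
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array([rng.permutation(ry) for _ in range(n_perm)])
    rhos = perms @ rx / len(rx)
    hits = int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))
    return (hits + 1) / (n_perm + 1)


@dataclass
class SelectionResult:
    """Per-parameter outcome of the elastic-net + Spearman chain."""

    table: pd.DataFrame            # rho, p, in_elastic_net, passes_spearman, selected
    rho_min: float
    p_max: float
    en: ENSelection | None = None
    pca: "PCAReport | None" = None
    notes: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def spearman_filter(X: pd.DataFrame, y: pd.Series, rho_min: float = 0.3,
                    p_max: float = 0.01, en_subset: list[str] | None = None,
                    exact_below: int = 20) -> SelectionResult:
    """Spearman rank correlation of every parameter with the score.

    Ties get average ranks; two-sided p-values use the t approximation
    (exact permutation below ``exact_below`` rows).  A parameter is selected
    iff |rho| > rho_min and p < p_max, intersected with the elastic-net
    subset when one is given.  Constant columns have undefined rank
    correlation and are excluded with a note.
    """
    if len(X) < 10:
        raise ValueError("Spearman filter needs at least 10 rows")
    yv = np.asarray(y, dtype=float)
    notes = []
    rows = {}
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            notes.append(f"column {col!r} is constant; rank correlation undefined, excluded")
            rows[col] = (np.nan, np.nan)
            continue
        res = stats.spearmanr(x, yv)
        rho = float(res.statistic)
        if len(x) < exact_below:
            p = _spearman_exact_p(x, yv, rho)
        else:
            p = float(res.pvalue)
        rows[col] = (rho, p)
    tab = pd.DataFrame(rows, index=["rho", "p"]).T
    tab["passes_spearman"] = (tab["rho"].abs() > rho_min) & (tab["p"] < p_max)
    tab["passes_spearman"] &= tab["rho"].notna()
    tab["in_elastic_net"] = (tab.index.isin(en_subset) if en_subset is not None else True)
    tab["selected"] = tab["passes_spearman"] & tab["in_elastic_net"]
    return SelectionResult(table=tab, rho_min=rho_min, p_max=p_max, notes=notes)


@dataclass
class PCAReport:
    n_components: int
    variance_retained: float
    explained_ratio: np.ndarray
    top_loadings: list[list[str]]   # per retained component
    overlap_with_en: list[str] | None = None


def pca_consistency_check(X: pd.DataFrame, variance: float = 0.98,
                          en_subset: list[str] | None = None,
                          top_k: int = 3) -> PCAReport:
    """How many principal components carry ``variance`` of the (standardized)
    data, which parameters load them most, and how that set overlaps the
    elastic-net selection."""
    if len(X) < len(X.columns):
        warnings.warn("fewer rows than columns; PCA spectrum is rank-limited")
    Xs = _standardize(X.to_numpy(dtype=float))
    p = PCA().fit(Xs)
    cum = np.cumsum(p.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance) + 1)
    k = min(k, len(cum))
    top = [list(X.columns[np.argsort(-np.abs(p.components_[i]))[:top_k]]) for i in range(k)]
    overlap = None
    if en_subset is not None:
        loading_set = {c for comp in top for c in comp}
        overlap = sorted(loading_set & set(en_subset))
    return PCAReport(n_components=k, variance_retained=float(cum[k - 1]),
                     explained_ratio=p.explained_variance_ratio_, top_loadings=top,
                     overlap_with_en=overlap)


def select_features(matrix: FeatureMatrix, alpha: float = 0.5, rho_min: float = 0.3,
                    p_max: float = 0.01, pca_variance: float = 0.98,
                    seed: int = 0, normalize: bool = True) -> SelectionResult:
    """The full selection chain on the PD rows of a feature matrix:
    HC normalization (optional), elastic net, Spearman filter, PCA check."""
    m = normalize_by_hc(matrix) if normalize else matrix
    pdr = m.pd_rows
    X, y = m.data.loc[pdr], m.score.loc[pdr]
    en = elastic_net_select(X, y, alpha=alpha, seed=seed)
    res = spearman_filter(X, y, rho_min=rho_min, p_max=p_max, en_subset=en.selected)
    res.en = en
    res.pca = pca_consistency_check(X, variance=pca_variance, en_subset=en.selected)
    return res
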
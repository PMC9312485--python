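"""Family-wise correlation analysis, PCA reduction and rank-test selection.

The pipeline mirrors the dimensionality-reduction stage of the dysphonia
study: Pearson correlation matrices are computed within each acoustic
parameter family; families with strong internal correlation are compressed by
PCA on standardized parameters, keeping the minimal number of leading
components whose eigenvalues account for at least 90% of total variance; the
PCA-projected features together with the raw nonlinear parameters are then
screened by a two-sided Mann-Whitney-Wilcoxon test between the healthy and
diseased groups, and only features with p < alpha enter the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import FAMILIES, FeatureTable, RunConfig

#: Families compressed by PCA; the nonlinear measures enter the candidate set
#: as raw parameters (they are only weakly inter-correlated).
PCA_FAMILIES = ("jitter", "shimmer", "hnr", "mfcc", "delta")

_FAMILY_DISPLAY = {"jitter": "Jitter", "shimmer": "Shimmer", "hnr": "HNR",
                   "mfcc": "MFCC", "delta": "Delta"}

STRONG_CORRELATION = 0.75


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a zero-variance input."""


class EmptySelectionError(ValueError):
    """No candidate feature reached significance; revisit alpha or the data.

    Carries the full :class:`SelectionReport` as ``report`` so callers can
    inspect the per-candidate p-values.
    """

    def __init__(self, message: str, report: "SelectionReport | None" = None):
        super().__init__(message)
        self.report = report


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient cov(a, b) / (SD_a * SD_b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("pearson requires two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class FamilyCorrelation:
    family: str
    parameter_names: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal
    strong_flag: bool  # any off-diagonal |rho| > 0.75


def family_correlations(table: FeatureTable) -> list[FamilyCorrelation]:
    """Within-family Pearson correlation matrices with the strong-flag rule."""
    if table.n_records < 2:
        raise ValueError("need at least 2 records")
    out = []
    for fam in table.families:
        params = table.family_parameters(fam)
        x = table.family_values(fam)
        sds = x.std(axis=0)
        if np.any(sds == 0):
            bad = params[int(np.argmax(sds == 0))]
            raise UndefinedCorrelationError(f"parameter {bad!r} is constant")
        mat = np.corrcoef(x, rowvar=False)
        mat = np.atleast_2d(mat)
        off = mat[~np.eye(len(params), dtype=bool)]
        out.append(FamilyCorrelation(
            family=fam, parameter_names=params, matrix=mat,
            strong_flag=bool(off.size and np.max(np.abs(off)) > STRONG_CORRELATION),
        ))
    return out


def retained_components(eigenvalues: np.ndarray, threshold: float) -> int:
    """Minimal h with sum(lambda[:h]) / sum(lambda) >= threshold."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(lam) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


@dataclass
class PCAModel:
    """Correlation-matrix PCA of one parameter family.

    Centering and scaling statistics come from the training data and are
    reused verbatim at projection time; components are sign-fixed so each
    component's largest-magnitude loading is positive.
    """

    family: str
    parameter_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray  # descending, >= 0
    components: np.ndarray  # (Q, Q) orthonormal columns
    h: int
    threshold: float


def fit_pca(table: FeatureTable, family: str, threshold: float = 0.90) -> PCAModel:
    """Fit standardized PCA on one family; h follows the retention rule."""
    x = table.family_values(family)
    params = table.family_parameters(family)
    if x.shape[1] < 1:
        raise ValueError(f"family {family!r} has no parameters")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 records to fit PCA")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = params[int(np.argmax(scale == 0))]
        raise UndefinedCorrelationError(f"parameter {bad!r} is constant")
    z = (x - mean) / scale
    corr = (z.T @ z) / (x.shape[0] - 1)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vec.shape[1]):
        k = int(np.argmax(np.abs(vec[:, j])))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    h = min(retained_components(lam, threshold), vec.shape[1])
    return PCAModel(family=family, parameter_names=params, mean=mean, scale=scale,
                    eigenvalues=lam, components=vec, h=h, threshold=threshold)


def project(model: PCAModel, table: FeatureTable) -> np.ndarray:
    """Project a table onto the model's h retained components."""
    params = table.family_parameters(model.family)
    if params != model.parameter_names:
        raise ValueError(
            f"table parameters for family {model.family!r} do not match the model"
        )
    z = (table.family_values(model.family) - model.mean) / model.scale
    return z @ model.components[:, : model.h]


def mww_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact null enumeration when the smaller sample has <= 8 observations and
    the pooled data are tie-free; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class SelectionReport:
    feature_names: list[str]  # all candidates, stable order
    p_values: np.ndarray
    rejected_null: np.ndarray  # bool, p < alpha
    selected: list[str]
    alpha: float

    def to_rows(self) -> list[dict]:
        return [
            {"feature": f, "null_hypothesis_rejected": int(r), "p_value": p}
            for f, p, r in zip(self.feature_names, self.p_values, self.rejected_null)
        ]


@dataclass
class ReducedFeatures:
    """Post-selection feature matrix with carried-over record metadata."""

    values: np.ndarray  # (n_records, n_selected)
    feature_names: list[str]
    subject_id: np.ndarray
    record_index: np.ndarray
    label: np.ndarray
    gender: np.ndarray


@dataclass
class FeaturePipeline:
    """Fitted reduction+selection stage, applicable frozen to new tables."""

    pca_models: dict[str, PCAModel]
    candidate_names: list[str]
    selected_names: list[str]
    alpha: float
    report: SelectionReport

    def candidate_matrix(self, table: FeatureTable) -> np.ndarray:
        cols, names = _candidate_columns(table, self.pca_models)
        if names != self.candidate_names:
            raise ValueError("table families/parameters do not match the fitted pipeline")
        return cols

    def transform(self, table: FeatureTable) -> ReducedFeatures:
        cols = self.candidate_matrix(table)
        idx = [self.candidate_names.index(f) for f in self.selected_names]
        return ReducedFeatures(
            values=cols[:, idx],
            feature_names=list(self.selected_names),
            subject_id=table.subject_id,
            record_index=table.record_index,
            label=table.label,
            gender=table.gender,
        )


def _pca_feature_names(model: PCAModel) -> list[str]:
    disp = _FAMILY_DISPLAY[model.family]
    if model.h == 1:
        return [f"{disp}-PCA"]
    return [f"{disp}-PCA{i + 1}" for i in range(model.h)]


def _candidate_columns(
    table: FeatureTable, pca_models: dict[str, PCAModel]
) -> tuple[np.ndarray, list[str]]:
    """Candidate feature block in the canonical (report) family order."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for fam in FAMILIES:  # jitter, shimmer, hnr, nonlinear, mfcc, delta
        if fam == "nonlinear":
            if "nonlinear" in table.families:
                cols.append(table.family_values("nonlinear"))
                names += table.family_parameters("nonlinear")
            continue
        model = pca_models.get(fam)
        if model is None:
            continue
        cols.append(project(model, table))
        names += _pca_feature_names(model)
    return np.hstack(cols), names


def build_and_select(
    table: FeatureTable,
    config: RunConfig | None = None,
    pin_components: dict[str, int] | None = None,
) -> tuple[ReducedFeatures, SelectionReport, FeaturePipeline]:
    """Fit the reduction stage on a labeled table and select dominant features.

    Candidates are the PCA projections of the jitter/shimmer/HNR/MFCC/Delta
    families plus the raw nonlinear parameters; a candidate is selected when
    its two-sided MWW p-value between the two label groups is below alpha.
    ``pin_components`` can fix a family's retained component count instead of
    deriving it from the eigenvalue-retention rule.
    """
    config = config or RunConfig()
    labeled = table.label >= 0
    if not np.any(table.label[labeled] == 0) or not np.any(table.label[labeled] == 1):
        raise ValueError("selection requires labeled records from both classes")

    pca_models: dict[str, PCAModel] = {}
    for fam in PCA_FAMILIES:
        if fam not in table.families:
            continue
        model = fit_pca(table, fam, config.pca_threshold)
        if pin_components and fam in pin_components:
            model.h = int(pin_components[fam])
        pca_models[fam] = model

    cols, names = _candidate_columns(table, pca_models)
    y = table.label
    p_values = np.array([
        mww_test(cols[labeled & (y == 0), j], cols[labeled & (y == 1), j])
        for j in range(cols.shape[1])
    ])
    rejected = p_values < config.alpha
    selected = [f for f, r in zip(names, rejected) if r]
    report = SelectionReport(feature_names=names, p_values=p_values,
                             rejected_null=rejected, selected=selected,
                             alpha=config.alpha)
    if not selected:
        raise EmptySelectionError(
            "no feature reached p < alpha; consider a larger alpha or check "
            "that the data carry a group difference",
            report=report,
        )
    pipeline = FeaturePipeline(pca_models=pca_models, candidate_names=names,
                               selected_names=selected, alpha=config.alpha,
                               report=report)
    return pipeline.transform(table), report, pipeline
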
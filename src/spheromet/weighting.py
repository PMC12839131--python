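"""PCA-weighted composite response metric.

The framework collapses several morphometric features into one per-well
score in four steps, applied per cell line:

1. normalise each feature to the mean of that cell line's zero-dose
   (control) wells, so the control level is 1;
2. align directionality: a feature whose treated-well mean exceeds 1 and
   whose reciprocal has a smaller mean is replaced by its reciprocal
   (so every feature decreases as the compound takes effect);
3. re-check: an inversion that raised the feature mean is undone;
4. run PCA on the (standardised) matrix, keep the smallest number of
   components whose cumulative explained-variance ratio reaches the
   threshold (default 0.90), score each feature j as
   sum_i a_i * |c_ij| over the kept components i (a_i = explained-variance
   ratio, c_ij = loading), normalise the scores to sum to 1, and take the
   per-well weighted sum of the transformed features as the composite
   metric sigma.

On clean data the control wells score exactly 1 and sigma falls
monotonically with dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .plate_io import META_COLUMNS, FeatureTable


@dataclass
class ControlReference:
    """Per-feature control-well means, one set per cell line."""

    means: dict[str, pd.Series]  # cell_line -> feature means over zero-dose wells


@dataclass
class NormalizedFeatureMatrix:
    """Fraction-of-control feature matrix plus the inversion audit trail.

    ``data`` keeps the metadata columns of the source table; feature values
    are fractions of the per-cell-line control mean (control mean = 1).
    ``inversion_log`` records, per (cell_line, feature), the action taken
    ('inverted', 'reverted' or absent) and the triggering means.
    """

    data: pd.DataFrame
    feature_columns: list[str]
    inversion_log: dict[tuple[str, str], dict] = field(default_factory=dict)

    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.data["cell_line"]))

    def _rows(self, cell_line: str, treated_only: bool = False) -> pd.Series:
        sel = self.data["cell_line"] == cell_line
        if treated_only:
            sel &= self.data["concentration_nM"] > 0
        return sel


@dataclass
class PCAWeighting:
    """Explained variance, loadings, selected components and final weights."""

    explained_variance_ratios: np.ndarray  # a_i, all components
    loadings: np.ndarray  # c_ij, shape (components, features)
    k: int  # smallest count with cumulative ratio >= threshold
    cum_var_threshold: float
    feature_names: list[str]
    raw_weights: np.ndarray
    weights: np.ndarray  # omega_final, sums to 1

    def as_dict(self) -> dict:
        return {
            "explained_variance_ratios": self.explained_variance_ratios.tolist(),
            "loadings": self.loadings.tolist(),
            "k": self.k,
            "cum_var_threshold": self.cum_var_threshold,
            "features": list(self.feature_names),
            "weights": dict(zip(self.feature_names, self.weights.tolist())),
        }


def normalize_to_control(
    table: FeatureTable,
) -> tuple[NormalizedFeatureMatrix, ControlReference]:
    """Divide each feature by the mean of the cell line's control wells.

    The paper-style percent-of-control display is a presentation choice;
    internally values stay on the fraction scale (control mean = 1) so the
    inversion rule's comparison against 1 is meaningful.
    """
    table.validate_values()
    df = table.data.copy()
    feats = table.feature_columns
    ref: dict[str, pd.Series] = {}
    for cl, grp in df.groupby("cell_line", sort=False):
        ctrl = grp[grp["concentration_nM"] == 0]
        if ctrl.empty:
            raise ValueError(f"cell line {cl!r} has no control (zero-dose) wells")
        means = ctrl[feats].mean()
        if (means <= 0).any():
            raise ValueError(f"cell line {cl!r} has a non-positive control mean")
        ref[cl] = means
        df.loc[grp.index, feats] = grp[feats] / means
    return NormalizedFeatureMatrix(df, feature_columns=list(feats)), ControlReference(ref)


def conditional_invert(m: NormalizedFeatureMatrix) -> NormalizedFeatureMatrix:
    """Reciprocal transform for features trending upwards with dose.

    Per cell line and feature, means are taken over treated (non-zero dose)
    wells only: if mean(x) > 1 and mean(1/x) < mean(x), the whole column
    (controls included) is replaced by its reciprocal and logged.  The
    transform only aligns direction; relative contributions are settled
    later by PCA.
    """
    df = m.data.copy()
    log = dict(m.inversion_log)
    for cl in m.cell_lines():
        all_rows = m._rows(cl)
        treated = m._rows(cl, treated_only=True)
        for f in m.feature_columns:
            x = df.loc[treated, f].to_numpy(dtype=float)
            if x.size == 0:
                continue
            mean_x = x.mean()
            mean_inv = (1.0 / x).mean()
            if mean_x > 1 and mean_inv < mean_x:
                original = df.loc[all_rows, f].copy()
                df.loc[all_rows, f] = 1.0 / df.loc[all_rows, f]
                log[(cl, f)] = {
                    "action": "inverted",
                    "mean_before": float(mean_x),
                    "mean_after": float(mean_inv),
                    "original": original,
                }
    return NormalizedFeatureMatrix(df, m.feature_columns, log)


def recheck_revert(m: NormalizedFeatureMatrix) -> NormalizedFeatureMatrix:
    """Undo inversions that raised the treated-well mean.

    For each feature flagged 'inverted', the current treated-well mean is
    compared with the recorded pre-inversion mean; if it rose, the original
    column is restored and the flag set to 'reverted'.  This matters when
    the matrix changed between the two steps (e.g. outlier replacement) or
    the inversion was triggered by edge noise on an essentially flat
    feature.
    """
    df = m.data.copy()
    log = dict(m.inversion_log)
    for (cl, f), entry in list(log.items()):
        if entry.get("action") != "inverted":
            continue
        treated = m._rows(cl, treated_only=True)
        mean_now = df.loc[treated, f].to_numpy(dtype=float).mean()
        if mean_now > entry["mean_before"]:
            original = entry.get("original")
            if original is not None:
                df.loc[original.index, f] = original
            else:  # fall back to algebraic undo
                all_rows = m._rows(cl)
                df.loc[all_rows, f] = 1.0 / df.loc[all_rows, f]
            log[(cl, f)] = {**entry, "action": "reverted"}
    return NormalizedFeatureMatrix(df, m.feature_columns, log)


def pca_feature_weights(
    m: "NormalizedFeatureMatrix | pd.DataFrame | np.ndarray",
    cum_var_threshold: float = 0.90,
    cell_line: str | None = None,
    standardize: bool = True,
    treated_only: bool = True,
) -> PCAWeighting:
    """Feature weights from the PCA of the processed feature matrix.

    Columns are centred and (by default) scaled to unit variance, because
    raw morphometric features span orders of magnitude.  The smallest k
    with cumulative explained-variance ratio >= ``cum_var_threshold`` is
    kept; feature j scores raw_j = sum_{i<=k} a_i * |c_ij| and the scores
    are normalised to sum to 1.  Weights are invariant to the sign of any
    loading vector.
    """
    if not 0 < cum_var_threshold <= 1:
        raise ValueError("cum_var_threshold must be in (0, 1]")
    if isinstance(m, NormalizedFeatureMatrix):
        sel = m._rows(cell_line, treated_only=treated_only) if cell_line else (
            (m.data["concentration_nM"] > 0) if treated_only else slice(None)
        )
        X = m.data.loc[sel, m.feature_columns].to_numpy(dtype=float)
        names = list(m.feature_columns)
    elif isinstance(m, pd.DataFrame):
        X = m.to_numpy(dtype=float)
        names = list(m.columns)
    else:
        X = np.asarray(m, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2D matrix with >= 2 rows and >= 1 feature")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")

    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).all():
            raise ValueError("zero-variance matrix: PCA undefined")
        sd = np.where(sd == 0, 1.0, sd)
        Xc = Xc / sd
    elif (Xc == 0).all():
        raise ValueError("zero-variance matrix: PCA undefined")

    n_comp = min(Xc.shape[0] - 1, Xc.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(Xc)
    a = pca.explained_variance_ratio_
    c = pca.components_  # rows = components, unit-norm loading vectors
    cum = np.cumsum(a)
    k = int(np.searchsorted(cum, cum_var_threshold - 1e-12) + 1)
    k = min(k, len(a))
    raw = (a[:k, None] * np.abs(c[:k, :])).sum(axis=0)
    total = raw.sum()
    if total <= 0:
        raise ValueError("degenerate loadings: weights undefined")
    return PCAWeighting(
        explained_variance_ratios=a,
        loadings=c,
        k=k,
        cum_var_threshold=cum_var_threshold,
        feature_names=names,
        raw_weights=raw,
        weights=raw / total,
    )


def composite_metric(m: NormalizedFeatureMatrix, w: PCAWeighting) -> pd.DataFrame:
    """Per-well composite score sigma = sum_j omega_j * feature_j.

    Applied to every well (controls included); with noiseless data the
    control wells score exactly 1 because every normalised feature is 1 and
    the weights sum to 1.
    """
    if list(w.feature_names) != list(m.feature_columns):
        raise ValueError("feature sets of matrix and weighting differ")
    meta_cols = [c for c in META_COLUMNS if c in m.data.columns]
    out = m.data[meta_cols].copy()
    X = m.data[m.feature_columns].to_numpy(dtype=float)
    out["sigma"] = X @ w.weights
    return out


def compute_weights_per_cell_line(
    m: NormalizedFeatureMatrix,
    cum_var_threshold: float = 0.90,
    standardize: bool = True,
) -> dict[str, PCAWeighting]:
    """PCA weighting fitted independently for each cell line."""
    return {
        cl: pca_feature_weights(m, cum_var_threshold, cell_line=cl, standardize=standardize)
        for cl in m.cell_lines()
    }


def composite_metric_per_cell_line(
    m: NormalizedFeatureMatrix, weights: dict[str, PCAWeighting]
) -> pd.DataFrame:
    """Composite scores using each cell line's own weights."""
    parts = []
    for cl in m.cell_lines():
        sub = NormalizedFeatureMatrix(
            m.data[m.data["cell_line"] == cl], m.feature_columns, m.inversion_log
        )
        parts.append(composite_metric(sub, weights[cl]))
    return pd.concat(parts, ignore_index=True)
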
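"""Seizure-likeness classification of flash responses.

The method treats every (larva, flash) response as one multivariate
observation.  Responses from all groups and replicates are pooled, a
movement quantile filter removes non-moving observations, each feature is
standardized, and a 2-component PCA summarizes the correlated kinematic
readouts.  Variables are retained by their quality of representation on
the retained components (``cos2``, the summed squared correlation between
variable and component; threshold 0.75) and the PCA is refit on the
retained set.  The Mahalanobis distance of each response from the pooled
centre is computed in the PC subspace:

.. math::

    MD^2 = \\sum_k s_k^2 / \\lambda_k

with :math:`s_k` the PC scores and :math:`\\lambda_k` the component
variances of the fitting sample.  Since PC scores are uncorrelated, this
equals the full inverse-covariance Mahalanobis distance in score space.
For approximately normal bulk data :math:`MD^2` is chi-squared with
``n_components`` degrees of freedom, so each distance converts to an
upper-tail probability (for 2 components, ``p = exp(-MD^2/2)`` exactly).
A response is called **high activity** (seizure-like) when
``MD > md_threshold`` and ``p < p_threshold`` (defaults 2.5 and 0.1),
otherwise **low activity**.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .errors import ComputationError, ValidationError
from .platemap import PlateMap

__all__ = [
    "DEFAULT_FEATURES", "SeizureActivityClassifier",
    "assemble_matrix", "moving_filter", "md_to_pvalue",
    "group_proportions", "classify_responses",
]

#: default classifier feature set (seven variables; angular velocity is
#: computed upstream but not used by default)
DEFAULT_FEATURES = [
    "max_acceleration", "max_velocity", "dur_highly_mobile", "dur_mobile",
    "mobility_pct", "n_turns", "dur_immobile",
]


def md_to_pvalue(md, df: int = 2):
    """Upper-tail chi-squared probability of ``MD^2`` with ``df`` degrees
    of freedom; strictly decreasing in ``md``, equals 1 at ``md = 0``."""
    md = np.asarray(md, dtype=float)
    if np.any(md < 0):
        raise ValidationError("Mahalanobis distance must be >= 0")
    if df < 1:
        raise ValidationError("df must be >= 1")
    out = stats.chi2.sf(md ** 2, df)
    return float(out) if out.ndim == 0 else out


def assemble_matrix(responses: pd.DataFrame,
                    feature_set: list[str] | None = None) -> pd.DataFrame:
    """Pool valid flash responses into an observation x feature matrix.

    Rows keep their (subject_id, flash_index) identity in the index;
    responses flagged invalid (tracking dropout) are excluded.
    """
    feature_set = list(feature_set or DEFAULT_FEATURES)
    unknown = [f for f in feature_set if f not in responses.columns]
    if unknown:
        raise ValidationError(f"unknown feature name(s): {unknown}")
    df = responses
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if {"subject_id", "flash_index"}.issubset(df.columns):
        df = df.set_index(["subject_id", "flash_index"])
    return df[feature_set].astype(float)


def moving_filter(X: pd.DataFrame, moving_quantile: float = 0.0,
                  movement_column: str = "max_velocity"):
    """Quantile filter on a movement score ('colMoving' style).

    The movement column is rank-transformed to quantile scores
    ``(rank - 1) / n`` (min rank for ties); rows with score below
    ``moving_quantile`` are removed.  Rows with exactly zero movement are
    always removed.  Returns ``(filtered, kept_mask)``.
    """
    if not 0.0 <= moving_quantile < 1.0:
        raise ValidationError("moving_quantile must be in [0, 1)")
    if len(X) == 0:
        raise ValidationError("empty feature matrix")
    if movement_column not in X.columns:
        raise ValidationError(f"movement column {movement_column!r} not in matrix")
    v = X[movement_column].to_numpy(dtype=float)
    score = (stats.rankdata(v, method="min") - 1.0) / len(v)
    keep = (v > 0) & (score >= moving_quantile)
    if not keep.any():
        raise ComputationError("moving filter removed every observation")
    return X.loc[keep], pd.Series(keep, index=X.index, name="kept")


class SeizureActivityClassifier(TransformerMixin, BaseEstimator):
    """Pooled PCA + Mahalanobis-distance flash-response classifier.

    Parameters
    ----------
    feature_set : list of str, default the seven standard flash variables
    moving_quantile : float in [0, 1), default 0.0
        Quantile cut of the movement filter applied to the fitting sample
        (0.0 removes only zero-movement responses).
    movement_column : str, default ``"max_velocity"``
    cos2_threshold : float, default 0.75
        Variables whose summed squared correlation with the retained
        components is at or below this are dropped and the PCA refit.
    n_components : int, default 2
    md_threshold, p_threshold : float, defaults 2.5 and 0.1
        The high-activity region is ``MD > md_threshold`` and
        ``p < p_threshold``.

    Attributes (after :meth:`fit`)
    ------------------------------
    feature_names_in_ : ndarray of fitted column names
    retained_features_ : list of variables surviving cos2 selection
    mean_, scale_ : standardization of the retained variables
    loadings_ : (n_retained, n_components) orthonormal-column matrix
    explained_variance_ : PC-score variances (ddof=1) of the fitting sample
    explained_variance_ratio_ : fractions of total variance
    cos2_ : per-variable cos2 on the first pass (all variables)
    fallback_ : True when cos2 selection left < 2 variables and the
        all-variable model was kept
    df_ : Mahalanobis chi-squared degrees of freedom (= n_components)
    """

    def __init__(self, feature_set=None, moving_quantile: float = 0.0,
                 movement_column: str = "max_velocity",
                 cos2_threshold: float = 0.75, n_components: int = 2,
                 md_threshold: float = 2.5, p_threshold: float = 0.1):
        self.feature_set = feature_set
        self.moving_quantile = moving_quantile
        self.movement_column = movement_column
        self.cos2_threshold = cos2_threshold
        self.n_components = n_components
        self.md_threshold = md_threshold
        self.p_threshold = p_threshold

    # ------------------------------------------------------------------ #

    def _check_config(self):
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.md_threshold <= 0 or self.p_threshold <= 0:
            raise ValidationError("md/p thresholds must be positive")
        # the two thresholds should describe one region consistently
        if stats.chi2.sf(self.md_threshold ** 2, self.n_components) > self.p_threshold:
            warnings.warn(
                "inconsistent thresholds: P(chi2 >= md_threshold^2) "
                f"= {stats.chi2.sf(self.md_threshold ** 2, self.n_components):.3g} "
                f"> p_threshold = {self.p_threshold}; the p criterion dominates")

    def _as_frame(self, X) -> pd.DataFrame:
        features = list(self.feature_set or DEFAULT_FEATURES)
        if isinstance(X, pd.DataFrame):
            missing = [f for f in features if f not in X.columns]
            if missing:
                raise ValidationError(f"missing feature column(s): {missing}")
            return X[features].astype(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(features):
            raise ValidationError(
                f"expected a 2-D array with {len(features)} columns, got {X.shape}")
        return pd.DataFrame(X, columns=features)

    @staticmethod
    def _cos2(loadings: np.ndarray, explained_variance: np.ndarray,
              n: int) -> np.ndarray:
        """Per-variable summed squared correlation with the components.

        For unit-variance (population-scaled) columns the correlation of
        variable j with component k is ``loading_jk * sqrt(lambda_k)``
        with ``lambda_k`` the population-scaled component variance, so
        degenerate components contribute exactly zero.
        """
        lam = np.asarray(explained_variance) * (n - 1) / n
        corr = loadings * np.sqrt(np.clip(lam, 0.0, None))
        return (corr ** 2).sum(axis=1)

    def _standardize_fit(self, X: pd.DataFrame):
        mean = X.mean(axis=0).to_numpy()
        scale = X.std(axis=0, ddof=0).to_numpy()
        # guard against float-noise "variance" of constant columns
        keep = scale > 1e-12 * np.maximum(1.0, np.abs(mean))
        if not keep.all():
            dropped = list(X.columns[~keep])
            warnings.warn(f"dropping constant column(s) before standardization: {dropped}")
        return mean, scale, list(X.columns[keep])

    def fit(self, X, y=None):
        """Fit the pooled model: movement filter, standardize, two-pass
        PCA with cos2 variable retention."""
        self._check_config()
        X = self._as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        if self.movement_column in X.columns:
            X, kept = moving_filter(X, self.moving_quantile, self.movement_column)
            self.n_filtered_ = int((~kept).sum())
        else:
            self.n_filtered_ = 0
        if len(X) <= self.n_components:
            raise ValidationError(
                f"need more than n_components={self.n_components} observations, "
                f"got {len(X)}")

        mean, scale, usable = self._standardize_fit(X)
        if len(usable) < 2:
            raise ValidationError("fewer than 2 non-constant feature columns")
        Xu = X[usable]

        # pass 1: all usable variables
        Z1 = (Xu - Xu.mean(axis=0)) / Xu.std(axis=0, ddof=0)
        pca1 = PCA(n_components=min(self.n_components, len(usable)))
        pca1.fit(Z1.to_numpy())
        cos2 = self._cos2(pca1.components_.T, pca1.explained_variance_, len(X))
        self.cos2_ = pd.Series(cos2, index=usable, name="cos2")

        retained = [f for f, c in zip(usable, cos2) if c > self.cos2_threshold]
        self.fallback_ = len(retained) < 2
        if self.fallback_:
            warnings.warn(
                f"cos2 selection left {len(retained)} variable(s); "
                "keeping the all-variable model")
            retained = usable
        self.retained_features_ = retained

        # pass 2: refit on the retained set
        Xr = X[retained]
        self.mean_ = Xr.mean(axis=0).to_numpy()
        self.scale_ = Xr.std(axis=0, ddof=0).to_numpy()
        Zr = (Xr.to_numpy() - self.mean_) / self.scale_
        n_comp = min(self.n_components, len(retained))
        pca2 = PCA(n_components=n_comp)
        pca2.fit(Zr)
        self.loadings_ = pca2.components_.T  # (n_retained, n_comp)
        self.explained_variance_ = pca2.explained_variance_.copy()
        self.explained_variance_ratio_ = pca2.explained_variance_ratio_.copy()
        self.center_ = Zr.mean(axis=0)
        self.retained_cos2_ = pd.Series(
            self._cos2(self.loadings_, self.explained_variance_, len(X)),
            index=retained, name="cos2")
        self.df_ = n_comp
        self.n_samples_fit_ = len(X)
        return self

    # ------------------------------------------------------------------ #

    def transform(self, X) -> np.ndarray:
        """Project observations onto the retained principal components."""
        check_is_fitted(self, "loadings_")
        X = self._as_frame(X)
        Z = (X[self.retained_features_].to_numpy() - self.mean_) / self.scale_
        return (Z - self.center_) @ self.loadings_

    def mahalanobis(self, X) -> np.ndarray:
        """Mahalanobis distance of each observation from the pooled centre,
        in the retained PC subspace."""
        scores = self.transform(X)
        return np.sqrt((scores ** 2 / self.explained_variance_).sum(axis=1))

    def pvalues(self, X) -> np.ndarray:
        return md_to_pvalue(self.mahalanobis(X), self.df_)

    def predict(self, X) -> np.ndarray:
        """Label each observation ``"high"`` (seizure-like) or ``"low"``."""
        md = self.mahalanobis(X)
        p = md_to_pvalue(md, self.df_)
        high = (md > self.md_threshold) & (p < self.p_threshold)
        return np.where(high, "high", "low")

    def activity_calls(self, X) -> pd.DataFrame:
        """Full per-response call table: PC scores, MD, p and label."""
        check_is_fitted(self, "loadings_")
        Xf = self._as_frame(X)
        scores = self.transform(Xf)
        md = np.sqrt((scores ** 2 / self.explained_variance_).sum(axis=1))
        p = md_to_pvalue(md, self.df_)
        label = np.where((md > self.md_threshold) & (p < self.p_threshold),
                         "high", "low")
        out = pd.DataFrame(
            {f"pc{k + 1}": scores[:, k] for k in range(scores.shape[1])})
        out["md"] = md
        out["p_value"] = p
        out["label"] = label
        if isinstance(X, pd.DataFrame) and isinstance(X.index, pd.MultiIndex):
            out.index = X.index
            out = out.reset_index()
        elif isinstance(X, pd.DataFrame):
            out.index = X.index
        return out

    def summary(self) -> dict:
        """Model diagnostics for serialization (YAML-friendly)."""
        check_is_fitted(self, "loadings_")
        return {
            "feature_set": [str(f) for f in self.feature_names_in_],
            "retained_features": list(map(str, self.retained_features_)),
            "fallback_all_variables": bool(self.fallback_),
            "cos2": {str(k): float(v) for k, v in self.cos2_.items()},
            "explained_variance": [float(v) for v in self.explained_variance_],
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio_],
            "loadings": [[float(v) for v in row] for row in self.loadings_],
            "n_samples_fit": int(self.n_samples_fit_),
            "n_filtered": int(self.n_filtered_),
            "md_threshold": float(self.md_threshold),
            "p_threshold": float(self.p_threshold),
            "moving_quantile": float(self.moving_quantile),
            "df": int(self.df_),
        }


def group_proportions(calls: pd.DataFrame, plate_map: PlateMap) -> pd.DataFrame:
    """Per-group high-activity proportions, counting responses as the unit.

    Returns one row per group: number of larvae, number of flash
    responses, number and percentage of high-activity responses.
    """
    if not {"subject_id", "label"}.issubset(calls.columns):
        raise ValidationError("calls table needs subject_id and label columns")
    meta = plate_map.subject_table()
    missing = set(calls["subject_id"]) - set(meta.index)
    if missing:
        raise ValidationError(f"subjects absent from plate map: {sorted(missing)}")
    df = calls.merge(meta[["group_label"]], left_on="subject_id", right_index=True)
    rows = []
    for group, grp in df.groupby("group_label", sort=False):
        n_resp = len(grp)
        n_high = int((grp["label"] == "high").sum())
        rows.append({
            "group_label": group,
            "n_larvae": grp["subject_id"].nunique(),
            "n_responses": n_resp,
            "n_high": n_high,
            "pct_high": 100.0 * n_high / n_resp,
        })
    return pd.DataFrame(rows)


def classify_responses(responses: pd.DataFrame, plate_map: PlateMap,
                       **config):
    """Convenience wrapper: assemble, fit, score and summarize in one call.

    Returns ``(model, calls, summaries)``.
    """
    model = SeizureActivityClassifier(**config)
    X = assemble_matrix(responses, model.feature_set)
    model.fit(X)
    calls = model.activity_calls(X)
    summaries = group_proportions(calls, plate_map)
    return model, calls, summaries
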
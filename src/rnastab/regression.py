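"""Quantitative half-life modelling.

Screened features feed two regressors: an ordinary-least-squares linear
baseline judged by adjusted R-squared, and a feed-forward network (ReLU,
minibatch Adam, MSE loss on log half-life) judged by the Spearman
correlation between observed and predicted half-lives, both in-sample and
under k-fold cross-validation. The in-sample vs cross-validated gap is the
diagnostic of interest: a heavily over-parameterised network memorises the
training set (high in-sample correlation) while generalising poorly.

:class:`StabilityRegression` / :class:`RegressionResults` follow the
statsmodels model/results convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .screening import bonferroni_adjust, spearman_test

__all__ = [
    "select_features",
    "fit_linear",
    "fit_mlp",
    "StabilityRegression",
    "RegressionResults",
    "PRESETS",
]

#: hidden-layer presets; "full" is the six-layer architecture, "desk" a
#: small configuration for routine runs and tests
PRESETS = {"full": (500, 250, 100, 50, 30, 10), "desk": (32, 16, 8)}


def select_features(halflives, feature_matrix: pd.DataFrame,
                    threshold: float = 0.05,
                    use_adjusted: bool = False) -> list[str]:
    """Features whose Spearman p (or Bonferroni-adjusted p) beats threshold."""
    if isinstance(halflives, pd.DataFrame):
        halflives = halflives.set_index("transcript_id")["t_half_mean"]
    common = feature_matrix.index.intersection(halflives.index)
    y = halflives.loc[common].to_numpy(float)
    names, ps = [], []
    for name in feature_matrix.columns:
        x = feature_matrix.loc[common, name].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4 or np.ptp(x[ok]) == 0:
            continue
        _, p = spearman_test(x[ok], y[ok])
        names.append(name)
        ps.append(p)
    ps = bonferroni_adjust(ps) if use_adjusted else np.asarray(ps)
    return [n for n, p in zip(names, ps) if p < threshold]


def fit_linear(X, y) -> tuple[float, np.ndarray]:
    """OLS fit; returns adjusted R-squared and coefficients (incl. intercept).

    Rank-deficient design matrices are rejected, naming collinear columns
    when X is a DataFrame.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 rows")
    rank = np.linalg.matrix_rank(Xa)
    if rank < p:
        offenders = ""
        if cols is not None:
            # name columns linearly dependent on their predecessors
            bad = [cols[j] for j in range(p)
                   if np.linalg.matrix_rank(Xa[:, :j + 1]) <= np.linalg.matrix_rank(Xa[:, :j])]
            offenders = f": collinear columns {bad}"
        raise ValueError(f"rank-deficient design matrix{offenders}")
    model = sm.OLS(ya, sm.add_constant(Xa)).fit()
    return float(model.rsquared_adj), np.asarray(model.params)


@dataclass(frozen=True)
class RegressionReport:
    """Fit-vs-cross-validation summary of one network run."""

    n_features_selected: int
    fit_spearman: float
    cv_spearman: float
    adj_r2_linear: float
    folds: int


def _make_mlp(layers, epochs, batch, val_split, seed) -> MLPRegressor:
    return MLPRegressor(hidden_layer_sizes=tuple(layers), activation="relu",
                        solver="adam", max_iter=epochs, batch_size=batch,
                        validation_fraction=val_split, early_stopping=False,
                        random_state=seed)


def fit_mlp(X, y, layers=PRESETS["full"], epochs: int = 100,
            batch: int = 1000, val_split: float = 0.2, cv_folds: int = 5,
            seed: int = 0, adj_r2_linear: float = np.nan) -> RegressionReport:
    """Feed-forward regression of log half-life on standardised features.

    fit_spearman correlates observed half-lives with in-sample predictions;
    cv_spearman with out-of-fold predictions from ``cv_folds``-fold CV
    stratified by half-life quartile (every sample predicted exactly once).
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite inputs")
    if np.ptp(ya) == 0:
        raise ValueError("constant target: correlations undefined")
    logy = np.log(ya)
    batch = min(batch, Xa.shape[0])

    scaler = StandardScaler().fit(Xa)
    Xs = scaler.transform(Xa)
    full = _make_mlp(layers, epochs, batch, val_split, seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence at fixed epochs is expected
        full.fit(Xs, logy)
        fit_rho, _ = spearman_test(ya, full.predict(Xs))

        quartile = pd.qcut(ya, 4, labels=False, duplicates="drop")
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        oof = np.empty_like(logy)
        for train, test in skf.split(Xs, quartile):
            sc = StandardScaler().fit(Xa[train])
            net = _make_mlp(layers, epochs, min(batch, train.size), val_split, seed)
            net.fit(sc.transform(Xa[train]), logy[train])
            oof[test] = net.predict(sc.transform(Xa[test]))
    cv_rho, _ = spearman_test(ya, oof)
    return RegressionReport(Xa.shape[1], float(fit_rho), float(cv_rho),
                            float(adj_r2_linear), cv_folds)


class StabilityRegression:
    """Half-life regression model over a screened feature matrix.

    Parameters
    ----------
    halflives
        Series indexed by transcript_id (or DataFrame with t_half_mean).
    feature_matrix
        Transcript x feature DataFrame.
    threshold, use_adjusted
        Feature pre-selection: Spearman p (adjusted p when ``use_adjusted``)
        below ``threshold``.
    preset
        "desk" (default, small network) or "full" (six hidden layers of
        500/250/100/50/30/10 units).
    """

    def __init__(self, halflives, feature_matrix: pd.DataFrame,
                 threshold: float = 0.05, use_adjusted: bool = False,
                 preset: str = "desk"):
        if isinstance(halflives, pd.DataFrame):
            halflives = halflives.set_index("transcript_id")["t_half_mean"]
        self.halflives = halflives
        self.feature_matrix = feature_matrix
        self.threshold = threshold
        self.use_adjusted = use_adjusted
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        self.preset = preset
        self.selected_: list[str] | None = None

    def fit(self, seed: int = 0, cv_folds: int = 5, epochs: int = 100,
            batch: int = 1000) -> "RegressionResults":
        self.selected_ = select_features(self.halflives, self.feature_matrix,
                                         self.threshold, self.use_adjusted)
        if not self.selected_:
            raise ValueError("no features selected at this threshold")
        common = self.feature_matrix.index.intersection(self.halflives.index)
        X = self.feature_matrix.loc[common, self.selected_]
        X = X.loc[:, X.notna().all()]
        y = self.halflives.loc[common].to_numpy(float)
        adj_r2 = np.nan
        if len(common) >= len(X.columns) + 2:
            try:
                adj_r2, _ = fit_linear(X, np.log(y))
            except ValueError:
                pass  # collinear selection: linear baseline unavailable
        report = fit_mlp(X, y, layers=PRESETS[self.preset], epochs=epochs,
                         batch=batch, cv_folds=cv_folds, seed=seed,
                         adj_r2_linear=adj_r2)
        return RegressionResults(self, report)


@dataclass
class RegressionResults:
    model: StabilityRegression
    report: RegressionReport

    def summary(self) -> str:
        r = self.report
        return "\n".join([
            "Half-life regression (feed-forward network)",
            "=" * 44,
            f"features selected   {r.n_features_selected:>8d}",
            f"preset              {self.model.preset:>8s}",
            f"linear adj R2       {r.adj_r2_linear:>8.3f}",
            f"fit Spearman rho    {r.fit_spearman:>8.3f}",
            f"CV Spearman rho     {r.cv_spearman:>8.3f}",
            f"CV folds            {r.folds:>8d}",
        ])
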
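"""Sparse linear modelling of protein adsorption from polymer descriptors.

The modelling stage relates log10 adsorption to molecular descriptors in
two steps, per protein:

1.  **LASSO feature selection** — L1-penalised regression with the penalty
    chosen by k-fold cross-validation under the 1-SE rule (the sparsest
    model within one standard error of the CV optimum), removing
    low-relevance descriptors before the final fit.

2.  **Sparse multiple linear regression by expectation maximization** —
    MAP estimation under a Laplace (double-exponential) prior expressed as
    a normal scale mixture.  The E-step turns the current coefficient
    magnitudes into per-coefficient precision weights u_j = λ/|w_j|; the
    M-step solves the weighted ridge system (XᵀX + diag(u)) w = Xᵀy.  This
    is a majorize–minimise scheme for the L1-penalised least-squares
    objective, so the penalised objective is monotone non-increasing — the
    implementation asserts this at every iteration.  Coefficients falling
    below a pruning tolerance are set to exactly zero and leave the active
    set, yielding exactly sparse fits.  λ defaults to σ̂·sqrt(2·n·log p)
    (universal-threshold scaling, σ̂ from a ridge pilot fit), so noise-free
    data are fit essentially unshrunk.

Model quality is assessed by repeated random 80/20 train/test splits
("bootstraps"): RMSE and R² on the held-out 20%, with feature selection
re-run inside every split so no information leaks from test to train.
Coefficient sign and size across the splits are summarised into a ranked
feature table.

The public surface follows the statsmodels convention: build a
:class:`ProteinAdsorptionModel` from data, call ``fit()`` /
``fit_bootstrap()``, get results objects with ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

__all__ = [
    "ModelConfig",
    "SparseFit",
    "BootstrapResult",
    "lasso_select",
    "em_sparse_regression",
    "bootstrap_evaluate",
    "rank_coefficients",
    "ProteinAdsorptionModel",
    "SparseRegressionResults",
    "BootstrapResults",
]


@dataclass
class ModelConfig:
    """Tunable parameters of the LASSO + EM modelling stage."""

    n_boot: int = 50
    train_fraction: float = 0.8
    lasso_cv_folds: int = 5
    lasso_one_se: bool = True
    lasso_n_alphas: int = 60
    em_max_iter: int = 500
    em_tol: float = 1e-6
    em_penalty_scale: float = 1.0
    prune_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if min(self.em_tol, self.prune_tol) <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SparseFit:
    """An EM sparse-regression fit on standardized features."""

    feature_names: list[str]
    selected: list[str]
    coefficients: dict[str, float]  # standardized scale, exactly sparse
    intercept: float  # on the original y scale
    converged: bool
    n_iter: int
    objective_path: list[float]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    sigma_hat: float
    lam: float

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        w = np.array([self.coefficients.get(n, 0.0) for n in self.feature_names])
        return self.intercept + Xs @ w


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-mean unit-variance columns; constant columns get scale 1 (stay 0)."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def lasso_select(
    X: pd.DataFrame,
    y: Sequence[float],
    config: ModelConfig | None = None,
    seed: int | None = None,
) -> list[str]:
    """Descriptors with nonzero LASSO coefficients at the CV-chosen penalty.

    Columns are standardized internally; the penalty comes from k-fold CV
    with the 1-SE rule (largest alpha whose mean CV error is within one
    standard error of the minimum), which biases toward sparsity.  May
    return an empty list when nothing predicts y.
    """
    config = config or ModelConfig()
    seed = config.seed if seed is None else seed
    y = np.asarray(list(y), dtype=float)
    if np.std(y) == 0:
        raise ValueError("no variance to model: y is constant")
    if len(X) != len(y):
        raise ValueError("X rows and y length differ")
    if len(y) < config.lasso_cv_folds:
        raise ValueError("need at least as many samples as CV folds")
    names = list(X.columns)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    cv = KFold(n_splits=config.lasso_cv_folds, shuffle=True, random_state=seed % (2**32))
    lcv = LassoCV(
        cv=cv,
        alphas=config.lasso_n_alphas,
        random_state=seed % (2**32),
        max_iter=5000,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-interpolating folds stop on max_iter; the 1-SE alpha is unaffected
        warnings.simplefilter("ignore", ConvergenceWarning)
        lcv.fit(Xs, y)
    if config.lasso_one_se:
        mean_mse = lcv.mse_path_.mean(axis=1)
        se_mse = lcv.mse_path_.std(axis=1, ddof=1) / math.sqrt(lcv.mse_path_.shape[1])
        i_min = int(np.argmin(mean_mse))
        cutoff = mean_mse[i_min] + se_mse[i_min]
        # alphas_ are descending: the first (largest) alpha within the band
        i_1se = int(np.nonzero(mean_mse <= cutoff)[0][0])
        alpha = float(lcv.alphas_[i_1se])
    else:
        alpha = float(lcv.alpha_)
    final = Lasso(alpha=alpha, max_iter=10000)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        final.fit(Xs, y)
    return [n for n, c in zip(names, final.coef_) if c != 0.0]


def em_sparse_regression(
    X: pd.DataFrame,
    y: Sequence[float],
    config: ModelConfig | None = None,
) -> SparseFit:
    """MAP-EM fit of a linear model under a Laplace prior (see module docs).

    X holds the (LASSO-)selected columns only; an empty X yields the
    intercept-only fit.  Raises if the penalised objective ever increases —
    the monotonicity guarantee of the MM scheme is load-bearing.
    """
    config = config or ModelConfig()
    y = np.asarray(list(y), dtype=float)
    names = list(X.columns)
    n = len(y)
    y_mean = float(y.mean())
    yc = y - y_mean
    if not names:
        return SparseFit(
            feature_names=[], selected=[], coefficients={}, intercept=y_mean,
            converged=True, n_iter=0, objective_path=[float(0.5 * yc @ yc)],
            x_mean=np.array([]), x_scale=np.array([]), y_mean=y_mean,
            sigma_hat=float(np.std(y, ddof=1)) if n > 1 else 0.0, lam=0.0,
        )
    Xraw = X.to_numpy(dtype=float)
    Xs, x_mean, x_scale = _standardize(Xraw)
    p = Xs.shape[1]

    # Pilot ridge fit -> residual scale sigma_hat -> penalty lambda.
    G = Xs.T @ Xs
    ridge = 1e-6 * max(np.trace(G) / max(p, 1), 1.0)
    w_pilot = np.linalg.solve(G + ridge * np.eye(p), Xs.T @ yc)
    resid = yc - Xs @ w_pilot
    dof = max(n - p - 1, 1)
    sigma_hat = float(np.sqrt(resid @ resid / dof))
    lam = config.em_penalty_scale * sigma_hat * math.sqrt(2.0 * n * math.log(max(p, 2)))

    def objective(w: np.ndarray) -> float:
        r = yc - Xs @ w
        return float(0.5 * (r @ r) + lam * np.abs(w).sum())

    w = w_pilot.copy()
    active = np.abs(w) >= config.prune_tol
    w[~active] = 0.0
    obj_path = [objective(w)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.em_max_iter + 1):
        if not active.any():
            converged = True
            break
        idx = np.nonzero(active)[0]
        # E-step: Laplace scale-mixture weights; M-step: weighted ridge solve.
        u = lam / np.abs(w[idx])
        A = G[np.ix_(idx, idx)] + np.diag(u)
        b = Xs[:, idx].T @ yc
        try:
            w_new_active = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            w_new_active = np.linalg.solve(A + 1e-10 * np.eye(len(idx)), b)
        w_new = np.zeros_like(w)
        w_new[idx] = w_new_active
        newly_dead = np.abs(w_new) < config.prune_tol
        w_new[newly_dead] = 0.0
        obj = objective(w_new)
        if obj > obj_path[-1] + 1e-9 * (1.0 + abs(obj_path[-1])):
            raise RuntimeError(
                f"EM objective increased at iteration {n_iter}: "
                f"{obj_path[-1]:.12g} -> {obj:.12g}"
            )
        obj_path.append(obj)
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        active = ~newly_dead & active
        if delta < config.em_tol:
            converged = True
            break
    coefficients = {
        names[j]: float(w[j]) for j in range(p) if w[j] != 0.0
    }
    return SparseFit(
        feature_names=names,
        selected=sorted(coefficients),
        coefficients=coefficients,
        intercept=y_mean,
        converged=converged,
        n_iter=n_iter,
        objective_path=obj_path,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        sigma_hat=sigma_hat,
        lam=lam,
    )


@dataclass
class BootstrapResult:
    """Per-split metrics and per-feature selection statistics."""

    rmse: np.ndarray
    r2: np.ndarray  # NaN where the test split had zero variance
    fits: list[SparseFit]
    splits: list[tuple[np.ndarray, np.ndarray]]
    seeds: list[int]
    feature_names: list[str]

    @property
    def mean_rmse(self) -> float:
        return float(np.nanmean(self.rmse))

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean(self.r2))

    @property
    def sd_rmse(self) -> float:
        return float(np.nanstd(self.rmse, ddof=1))

    @property
    def sd_r2(self) -> float:
        return float(np.nanstd(self.r2, ddof=1))

    def selection_frequency(self) -> pd.Series:
        counts = {name: 0 for name in self.feature_names}
        for fit in self.fits:
            for name in fit.selected:
                counts[name] += 1
        return pd.Series(counts, dtype=float) / max(len(self.fits), 1)


def bootstrap_evaluate(
    X: pd.DataFrame,
    y: Sequence[float],
    config: ModelConfig | None = None,
    lasso_once: bool = False,
) -> BootstrapResult:
    """Repeated random 80/20 splits with selection + EM refit inside each.

    Each split draws ceil(train_fraction·n) training rows without
    replacement; LASSO selection and the EM fit see only the training rows
    (standardization statistics included), and RMSE / R² are computed on
    the held-out rows, R² about the test-split mean.  A test split with
    zero variance records R² as NaN and is excluded from summaries.
    ``lasso_once`` runs selection a single time on all data instead
    (leaky; off by default).
    """
    config = config or ModelConfig()
    y = np.asarray(list(y), dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("bootstrap evaluation needs n >= 10")
    rng = np.random.default_rng(config.seed)
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, config.lasso_cv_folds), n - 1)
    global_selection = lasso_select(X, y, config) if lasso_once else None

    rmse = np.empty(config.n_boot)
    r2 = np.empty(config.n_boot)
    fits: list[SparseFit] = []
    splits = []
    seeds = []
    for b in range(config.n_boot):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seeds.append(sub_seed)
        perm = np.random.default_rng(sub_seed).permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        splits.append((train, test))
        Xtr, ytr = X.iloc[train], y[train]
        Xte, yte = X.iloc[test], y[test]
        if global_selection is None:
            try:
                selected = lasso_select(Xtr, ytr, config, seed=sub_seed)
            except ValueError:
                selected = []
        else:
            selected = global_selection
        fit = em_sparse_regression(Xtr[selected], ytr, config)
        fits.append(fit)
        pred = fit.predict(Xte[selected]) if selected else np.full(len(test), fit.intercept)
        err = yte - pred
        rmse[b] = float(np.sqrt(np.mean(err**2)))
        ss_tot = float(np.sum((yte - yte.mean()) ** 2))
        if ss_tot == 0.0:
            r2[b] = np.nan
        else:
            r2[b] = 1.0 - float(np.sum(err**2)) / ss_tot
    return BootstrapResult(
        rmse=rmse, r2=r2, fits=fits, splits=splits, seeds=seeds,
        feature_names=list(X.columns),
    )


def rank_coefficients(
    fits: Sequence[SparseFit],
    feature_names: Sequence[str] | None = None,
    significance_fraction: float = 0.5,
) -> pd.DataFrame:
    """Rank features by |mean coefficient| across fits.

    The mean counts a fit's coefficient as 0 when the feature was not
    selected there, so the ranking reflects both magnitude and stability.
    A feature is flagged significant when selected in strictly more than
    ``significance_fraction`` of the fits.  Sign consensus is positive /
    negative / mixed over the fits that selected it.
    """
    if not fits:
        raise ValueError("rank_coefficients needs at least one fit")
    if feature_names is None:
        feature_names = sorted({n for f in fits for n in f.feature_names})
    rows = []
    n_fits = len(fits)
    for name in feature_names:
        values = [f.coefficients.get(name, 0.0) for f in fits]
        nonzero = [v for v in values if v != 0.0]
        freq = len(nonzero) / n_fits
        if not nonzero:
            consensus = "never"
        elif all(v > 0 for v in nonzero):
            consensus = "positive"
        elif all(v < 0 for v in nonzero):
            consensus = "negative"
        else:
            consensus = "mixed"
        rows.append(
            {
                "feature": name,
                "selection_freq": freq,
                "mean_coef": float(np.mean(values)),
                "sign_consensus": consensus,
                "significant": freq > significance_fraction,
            }
        )
    df = pd.DataFrame(rows)
    df["abs_mean_coef"] = df["mean_coef"].abs()
    df = df.sort_values(
        ["abs_mean_coef", "feature"], ascending=[False, True]
    ).drop(columns="abs_mean_coef").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# statsmodels-style surface

class ProteinAdsorptionModel:
    """Sparse linear model of one protein's adsorption vs polymer descriptors.

    Parameters
    ----------
    X : DataFrame, polymers × descriptors (no missing cells).
    y : adsorption response aligned with X (log10 geometric-mean intensity).
    config : ModelConfig, defaults mirror the pipeline defaults
        (50 splits, 80/20, 5-fold LASSO CV with 1-SE rule).

    Examples
    --------
    >>> model = ProteinAdsorptionModel.from_tables(adsorption, descriptors,
    ...                                            protein="insulin")
    >>> res = model.fit_bootstrap()
    >>> print(res.summary())
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[float],
        config: ModelConfig | None = None,
        protein: str = "",
    ) -> None:
        self.X = X
        self.y = np.asarray(list(y), dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X rows and y length differ")
        self.config = config or ModelConfig()
        self.protein = protein

    @classmethod
    def from_tables(
        cls,
        adsorption: pd.DataFrame,
        descriptors: pd.DataFrame,
        protein: str,
        config: ModelConfig | None = None,
        response: str = "log10_geomean",
        apply_filter: bool = True,
    ) -> "ProteinAdsorptionModel":
        """Join the quantification output with a descriptor matrix.

        ``adsorption`` is the polymer × protein table from the quantify
        stage (columns polymer_id, protein_id, log10_geomean, snr,
        passed_filter); rows failing the SNR filter are dropped when
        ``apply_filter`` is set.
        """
        sub = adsorption[adsorption["protein_id"] == protein]
        if apply_filter and "passed_filter" in sub.columns:
            sub = sub[sub["passed_filter"]]
        if sub.empty:
            raise ValueError(f"no usable adsorption rows for protein {protein!r}")
        sub = sub.set_index("polymer_id")
        common = sub.index.intersection(descriptors.index)
        if common.empty:
            raise ValueError("no polymers shared between adsorption and descriptors")
        sub = sub.loc[common]
        return cls(
            descriptors.loc[common], sub[response].to_numpy(), config, protein
        )

    def fit(self) -> "SparseRegressionResults":
        """LASSO selection then EM sparse regression on the full data."""
        selected = lasso_select(self.X, self.y, self.config)
        fit = em_sparse_regression(self.X[selected], self.y, self.config)
        return SparseRegressionResults(self, fit)

    def fit_bootstrap(self, lasso_once: bool = False) -> "BootstrapResults":
        """Repeated 80/20 split evaluation (see :func:`bootstrap_evaluate`)."""
        result = bootstrap_evaluate(self.X, self.y, self.config, lasso_once)
        return BootstrapResults(self, result)


class SparseRegressionResults:
    """Results of a single LASSO + EM fit."""

    def __init__(self, model: ProteinAdsorptionModel, fit: SparseFit) -> None:
        self.model = model
        self.fit_ = fit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit_.coefficients, dtype=float).sort_values(
            key=np.abs, ascending=False
        )

    @property
    def intercept(self) -> float:
        return self.fit_.intercept

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        X = self.model.X if X is None else X
        if self.fit_.feature_names:
            return self.fit_.predict(X[self.fit_.feature_names])
        return np.full(len(X), self.fit_.intercept)

    def rsquared(self) -> float:
        resid = self.model.y - self.predict()
        ss_tot = float(np.sum((self.model.y - self.model.y.mean()) ** 2))
        return 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else float("nan")

    def summary(self) -> str:
        lines = [
            f"Sparse EM regression — {self.model.protein or 'response'}",
            f"  n polymers      : {len(self.model.y)}",
            f"  descriptors     : {self.model.X.shape[1]} offered, "
            f"{len(self.fit_.selected)} retained",
            f"  converged       : {self.fit_.converged} ({self.fit_.n_iter} EM iterations)",
            f"  in-sample R^2   : {self.rsquared():.3f}",
            f"  intercept       : {self.fit_.intercept:.3f}",
            "  coefficients (standardized scale):",
        ]
        for name, coef in self.params.items():
            lines.append(f"    {name:<24s} {coef:+.4f}")
        if not len(self.params):
            lines.append("    (none retained)")
        return "\n".join(lines)


class BootstrapResults:
    """Results of the repeated-split evaluation of one protein's model."""

    def __init__(self, model: ProteinAdsorptionModel, result: BootstrapResult) -> None:
        self.model = model
        self.result = result

    @property
    def rmse(self) -> np.ndarray:
        return self.result.rmse

    @property
    def r2(self) -> np.ndarray:
        return self.result.r2

    @property
    def mean_rmse(self) -> float:
        return self.result.mean_rmse

    @property
    def mean_r2(self) -> float:
        return self.result.mean_r2

    def ranked_features(self, significance_fraction: float = 0.5) -> pd.DataFrame:
        return rank_coefficients(
            self.result.fits, self.result.feature_names, significance_fraction
        )

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bootstrap": np.arange(len(self.rmse)),
                "seed": self.result.seeds,
                "rmse": self.rmse,
                "r2": self.r2,
            }
        )

    def plot_predictions(self, ax=None):
        """Observed vs predicted on the held-out rows, pooled over splits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        for fit, (train, test) in zip(self.result.fits, self.result.splits):
            names = fit.feature_names
            X_test = self.model.X.iloc[test]
            pred = (
                fit.predict(X_test[names]) if names
                else np.full(len(test), fit.intercept)
            )
            ax.scatter(self.model.y[test], pred, s=8, alpha=0.3, color="tab:blue")
        lims = [self.model.y.min(), self.model.y.max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("observed log10 adsorption")
        ax.set_ylabel("predicted (held-out)")
        ax.set_title(
            f"{self.model.protein}: test R² = {self.mean_r2:.2f}"
            if self.model.protein else f"test R² = {self.mean_r2:.2f}"
        )
        return ax

    def plot_coefficients(self, top: int = 10, ax=None):
        """Signed mean coefficients of the top-ranked features."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ranked = self.ranked_features().head(top)
        ranked = ranked[ranked["selection_freq"] > 0].iloc[::-1]
        colors = ["tab:red" if c < 0 else "tab:blue" for c in ranked["mean_coef"]]
        ax.barh(ranked["feature"], ranked["mean_coef"], color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("mean regression coefficient (standardized)")
        return ax

    def summary(self, top: int = 10) -> str:
        ranked = self.ranked_features()
        sig = ranked[ranked["significant"]]
        lines = [
            f"Bootstrap evaluation — {self.model.protein or 'response'}",
            f"  n polymers   : {len(self.model.y)}",
            f"  splits       : {len(self.rmse)} × "
            f"{self.model.config.train_fraction:.0%}/"
            f"{1 - self.model.config.train_fraction:.0%}",
            f"  test RMSE    : {self.mean_rmse:.3f} ± {self.result.sd_rmse:.3f}",
            f"  test R^2     : {self.mean_r2:.3f} ± {self.result.sd_r2:.3f}",
            f"  significant features (selected in >50% of splits): {len(sig)}",
        ]
        for _, row in ranked.head(top).iterrows():
            if row["selection_freq"] == 0:
                continue
            lines.append(
                f"    {row['feature']:<24s} mean coef {row['mean_coef']:+.4f}  "
                f"freq {row['selection_freq']:.2f}  {row['sign_consensus']}"
            )
        return "\n".join(lines)
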